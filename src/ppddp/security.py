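"""Executable security analysis of the OPHI-protected protocol.

Three analyses, mirroring how the scheme's guarantees are argued:

* one-wayness arithmetic — the exhaustive-search probability bounds for a
  single ciphertext, ``1/(k*|M|)``, and for a whole DDP instance,
  ``(1/(k*|M|))^(m+n+k)``, computed exactly;
* the lazy-server bound — a random mapping pair is accepted with
  probability ``1/(p! * q!)``;
* ciphertext-distribution indistinguishability — quantile-quantile
  comparison of first-coordinate ciphertexts against a reference family:
  normal keys and noise yield ciphertexts statistically indistinguishable
  from a normal distribution, while uniform keys and noise produce a
  visible shape mismatch (the sum of two uniforms is triangular).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .ophi import KEY_MAGNITUDE_BOUND

__all__ = [
    "SecurityParams",
    "exhaustive_search_bounds",
    "lazy_server_probability",
    "ciphertext_distribution_sample",
    "qq_statistic",
    "QQResult",
]

#: Calibrated pass criterion for "the QQ points coincide with y = x":
#: Pearson correlation of the quantile pairs, and the maximum absolute
#: deviation from the identity line over the central 98% of quantiles
#: (the extreme order statistics fluctuate too much to be informative),
#: in standardized units at sample size 50000.
QQ_CORR_THRESHOLD = 0.999
QQ_MAXDEV_THRESHOLD = 0.05


@dataclass(frozen=True)
class SecurityParams:
    """Inputs to the one-wayness bounds.

    ``key_bound`` — ciphertext-space expansion factor (the key magnitude
    bound, 2^10).  ``message_space`` — plaintext-space cardinality |M|;
    2^7 is the minimal value consistent with the per-element bound 2^-17.
    ``m``, ``n``, ``k`` — the sizes of A, B, C (so m+n+k plaintexts in all).
    """

    key_bound: int = 2**10
    message_space: int = 2**7
    m: int = 2
    n: int = 2
    k: int = 3

    def __post_init__(self) -> None:
        if min(self.key_bound, self.message_space, self.m, self.n, self.k) < 1:
            raise ValueError("all security parameters must be positive")


def exhaustive_search_bounds(params: SecurityParams) -> tuple[Fraction, Fraction]:
    """Exact per-element and full-instance exhaustive-search probabilities.

    Returns ``(1/(key_bound*|M|), (1/(key_bound*|M|))**(m+n+k))`` as exact
    rationals; use ``math.log2`` on them for the bit view.
    """
    per_element = Fraction(1, params.key_bound * params.message_space)
    full = per_element ** (params.m + params.n + params.k)
    return per_element, full


def lazy_server_probability(p: int, q: int) -> Fraction:
    """Probability that a uniformly random mapping pair is the owner's
    accepted arrangement: 1/(p! * q!)."""
    if p < 1 or q < 1:
        raise ValueError("p and q must be at least 1")
    return Fraction(1, math.factorial(p) * math.factorial(q))


def ciphertext_distribution_sample(
    m: int,
    count: int,
    family: str = "normal",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """First-coordinate ciphertexts c = k*m + r over random key/noise draws.

    ``family='normal'`` draws k and r from a normal centered in the key
    range (truncated to (0, 2^10]); ``'uniform'`` draws both uniformly on
    (0, 2^10].  One (k, r) pair per ciphertext, matching the distribution
    experiment's protocol.
    """
    if count < 100:
        raise ValueError("need at least 100 draws for a meaningful sample")
    rng = rng if rng is not None else np.random.default_rng()
    bound = KEY_MAGNITUDE_BOUND

    def draw(size: int) -> np.ndarray:
        if family == "uniform":
            return rng.uniform(0.0, bound, size=size)
        if family == "normal":
            out = np.empty(size)
            filled = 0
            while filled < size:
                x = rng.normal(bound / 2.0, bound / 6.0, size=size - filled)
                x = x[(x > 0) & (x <= bound)]
                out[filled : filled + x.size] = x
                filled += x.size
            return out
        raise ValueError(f"unknown key/noise family {family!r}")

    k = draw(count)
    r = draw(count)
    return k * m + r


@dataclass(frozen=True)
class QQResult:
    correlation: float
    max_deviation: float
    sample_quantiles: np.ndarray
    reference_quantiles: np.ndarray

    def passes_identity(self) -> bool:
        return (
            self.correlation >= QQ_CORR_THRESHOLD
            and self.max_deviation <= QQ_MAXDEV_THRESHOLD
        )


def qq_statistic(sample: np.ndarray, family: str = "normal") -> QQResult:
    """Quantile-quantile comparison of a standardized sample against a
    reference family.

    The sample is standardized to zero mean and unit variance (uniform
    reference: rescaled to [0,1] moment-wise), its order statistics are
    paired with the reference quantiles at plotting positions
    (i - 0.5)/n, and the result carries the Pearson correlation of the
    pairs and the maximum |sample - reference| over the central 98%.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 observations")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance sample has no quantile structure")
    probs = (np.arange(1, n + 1) - 0.5) / n
    if family == "normal":
        z = (x - x.mean()) / sd
        ref = stats.norm.ppf(probs)
    elif family == "uniform":
        # match the reference U(0,1) moments: mean 1/2, sd 1/sqrt(12)
        z = (x - x.mean()) / sd / math.sqrt(12.0) + 0.5
        ref = probs.copy()
    else:
        raise ValueError(f"unknown reference family {family!r}")
    corr = float(np.corrcoef(z, ref)[0, 1])
    lo, hi = int(0.01 * n), int(math.ceil(0.99 * n))
    dev = float(np.abs(z[lo:hi] - ref[lo:hi]).max())
    return QQResult(
        correlation=corr, max_deviation=dev, sample_quantiles=z, reference_quantiles=ref
    )
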