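"""Order-preserving homomorphic index (OPHI) scheme.

A symmetric, probabilistic, decryption-free encryption of non-negative
integers.  A plaintext ``m`` becomes an ``n``-component real vector

    c_i = k_i * m + r_i      (1 <= i <= n-1)
    c_n = k_n * (r_1 + ... + r_{n-1})

with a secret positive key vector ``k`` and fresh positive noise ``r``.
Two properties make the scheme useful for outsourcing the double digest
problem:

* additive homomorphism — componentwise sums of ciphertexts encrypt the
  sum of the plaintexts (noise accumulates);
* order preservation — when the plaintexts of two ciphertexts differ by at
  least the minimum plaintext gap ``p_min`` and the noise stays inside its
  budget, every one of the first n-1 coordinates of the larger plaintext's
  ciphertext exceeds the corresponding coordinate of the smaller one, so
  the server can compare and sort without the key.

There is deliberately no decryption algorithm: the protocol never needs
one, and removing it is what turns the ancestral order-preserving
*encryption* scheme into an *index* scheme.

Noise discipline.  Order preservation must survive homomorphic
accumulation.  With ``R_bound = min_i(k_i) * p_min / (2 * L_max)`` the total
noise of any sum of at most ``L_max`` ciphertexts stays below
``min_i(k_i) * p_min / 2``, so two accumulated values whose plaintexts
differ by at least ``p_min`` still compare strictly on every coordinate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from functools import cmp_to_key
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import DDPInstance, MalformedInstanceError, validate_instance

__all__ = [
    "KEY_MAGNITUDE_BOUND",
    "NoiseBudget",
    "KeyVector",
    "Ciphertext",
    "EncryptedInstance",
    "Order",
    "DepthExhaustedError",
    "keygen",
    "encrypt",
    "add",
    "subtract",
    "compare",
    "sort_ciphertexts",
    "permute",
    "instance_budget",
    "encrypt_instance",
]

#: Upper bound on every key component (the scheme's 2**10 restriction).
KEY_MAGNITUDE_BOUND = 1024.0


class DepthExhaustedError(RuntimeError):
    """A homomorphic operation would exceed the additive noise budget."""


@dataclass(frozen=True)
class NoiseBudget:
    """How much noise an encryption may carry and still sort correctly.

    ``p_min``  — minimum distance between distinct plaintexts (1 for
    integer fragment lengths, including all partial-sum gaps).
    ``L_max``  — maximum number of plaintexts any ciphertext will be a
    homomorphic combination of.
    ``R_bound`` — per-encryption cap on the total noise R, derived from the
    key as ``min_i(k_i) * p_min / (2 * L_max)``; ``None`` until a key is
    available.
    """

    p_min: float = 1.0
    L_max: int = 1
    R_bound: float | None = None

    def __post_init__(self) -> None:
        if self.p_min <= 0:
            raise ValueError("p_min must be positive")
        if self.L_max < 1:
            raise ValueError("L_max must be at least 1")

    def resolved(self, key: "KeyVector") -> "NoiseBudget":
        return replace(self, R_bound=min(key.k) * self.p_min / (2.0 * self.L_max))


@dataclass(frozen=True)
class KeyVector:
    """Secret per-coordinate multipliers k_1..k_n, all in (0, 2^10]."""

    k: tuple[float, ...]

    def __post_init__(self) -> None:
        kk = tuple(float(x) for x in self.k)
        if len(kk) < 2:
            raise ValueError("key vector needs at least n=2 components")
        if any(x <= 0 or x > KEY_MAGNITUDE_BOUND for x in kk):
            raise ValueError(f"key components must lie in (0, {KEY_MAGNITUDE_BOUND}]")
        if sum(kk[:-1]) == 0:  # unreachable with positive keys; asserted anyway
            raise ValueError("k_1 + ... + k_{n-1} must be non-zero")
        object.__setattr__(self, "k", kk)

    @property
    def n(self) -> int:
        return len(self.k)

    def to_json(self, path: str | Path, budget: NoiseBudget) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n": self.n,
                    "k": [round(x, 10) for x in self.k],
                    "budget": {
                        "p_min": budget.p_min,
                        "L_max": budget.L_max,
                        "R_bound": budget.R_bound,
                    },
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> tuple["KeyVector", NoiseBudget]:
        d = json.loads(Path(path).read_text())
        key = cls(k=tuple(d["k"]))
        b = d["budget"]
        return key, NoiseBudget(p_min=b["p_min"], L_max=b["L_max"], R_bound=b["R_bound"])


#: Key sampling: normal around the middle of the admissible range, rejected
#: outside (0, 2^10]. Normal keys (and noise) make the ciphertext
#: distribution normal-indistinguishable; see the security module.
_KEY_MEAN = 512.0
_KEY_SD = 170.0


def keygen(n: int, budget: NoiseBudget | None = None, rng: np.random.Generator | None = None) -> KeyVector:
    """Draw an n-component key from a truncated normal on (0, 2^10]."""
    if n < 2:
        raise ValueError("OPHI requires at least n=2 sub-ciphertexts")
    rng = rng if rng is not None else np.random.default_rng()
    ks = []
    while len(ks) < n:
        x = rng.normal(_KEY_MEAN, _KEY_SD)
        if 0.0 < x <= KEY_MAGNITUDE_BOUND:
            ks.append(float(x))
    return KeyVector(k=tuple(ks))


@dataclass(frozen=True)
class Ciphertext:
    """One encrypted fragment length: an n-vector of reals.

    ``depth`` counts how many plaintexts were folded in homomorphically
    (1 for a fresh encryption); ``l_max`` is the budget it was encrypted
    under and caps further accumulation.
    """

    c: tuple[float, ...]
    depth: int = 1
    l_max: int = 1

    @property
    def n(self) -> int:
        return len(self.c)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.c, dtype=float)


def encrypt(
    K: KeyVector,
    m: int,
    budget: NoiseBudget,
    rng: np.random.Generator,
    noise: Sequence[float] | None = None,
) -> Ciphertext:
    """Encrypt a non-negative integer under ``K``.

    Noise r_i is half-normal with scale R_bound / (4*(n-1)), resampled until
    the total R lands strictly inside (0, R_bound); the small scale keeps
    typical accumulated noise far below the worst-case budget.  ``noise``
    forces an explicit noise vector (used by tests; still budget-checked).
    """
    if m < 0:
        raise ValueError("plaintext must be non-negative")
    b = budget if budget.R_bound is not None else budget.resolved(K)
    n = K.n
    if noise is not None:
        r = np.asarray(noise, dtype=float)
        if r.shape != (n - 1,):
            raise ValueError(f"noise vector must have n-1={n - 1} components")
        if np.any(r <= 0) or not (0.0 < r.sum() < b.R_bound):
            raise ValueError("forced noise violates 0 < R < R_bound")
    else:
        scale = b.R_bound / (4.0 * (n - 1))
        while True:
            r = np.abs(rng.normal(0.0, scale, size=n - 1))
            if np.all(r > 0) and 0.0 < r.sum() < b.R_bound:
                break
    k = np.asarray(K.k)
    body = k[:-1] * m + r
    tail = k[-1] * r.sum()
    return Ciphertext(c=tuple(body) + (float(tail),), depth=1, l_max=b.L_max)


def _check_depth(x: Ciphertext, y: Ciphertext) -> int:
    if x.n != y.n:
        raise ValueError("ciphertexts have different sub-ciphertext counts")
    l_max = max(x.l_max, y.l_max)
    d = x.depth + y.depth
    if d > l_max:
        raise DepthExhaustedError(
            f"combined depth {d} exceeds the additive budget L_max={l_max}"
        )
    return d


def add(x: Ciphertext, y: Ciphertext) -> Ciphertext:
    """Homomorphic addition: componentwise sum, noise and depth accumulate."""
    d = _check_depth(x, y)
    return Ciphertext(
        c=tuple(a + b for a, b in zip(x.c, y.c)),
        depth=d,
        l_max=max(x.l_max, y.l_max),
    )


def subtract(x: Ciphertext, y: Ciphertext) -> Ciphertext:
    """Homomorphic subtraction (plaintext of x >= plaintext of y in use)."""
    d = _check_depth(x, y)
    return Ciphertext(
        c=tuple(a - b for a, b in zip(x.c, y.c)),
        depth=d,
        l_max=max(x.l_max, y.l_max),
    )


class Order(Enum):
    LESS = -1
    INDISTINGUISHABLE = 0
    GREATER = 1


def compare(x: Ciphertext, y: Ciphertext, tie_gap: float = 0.0) -> Order:
    """Keyless order comparison on the first n-1 coordinates.

    GREATER/LESS require *every* informative coordinate to agree; anything
    else — equal plaintexts whose noise difference flips signs across
    coordinates — is INDISTINGUISHABLE and treated as a tie downstream.
    The noise coordinate c_n is never inspected.

    ``tie_gap`` declares coordinate differences of at most that magnitude
    noise-level: when every coordinate difference is within it the verdict
    is a tie even if the signs happen to agree.  The protocol passes the
    public noise scale 2*T/(n-1) here, which cleanly separates equal from
    distinct plaintexts under the noise budget; the default 0 is the raw
    all-coordinates rule.
    """
    a = x.as_array()[:-1]
    b = y.as_array()[:-1]
    d = a - b
    if np.all(np.abs(d) <= tie_gap):
        return Order.INDISTINGUISHABLE
    if np.all(d > 0):
        return Order.GREATER
    if np.all(d < 0):
        return Order.LESS
    return Order.INDISTINGUISHABLE


def sort_ciphertexts(
    xs: Sequence[Ciphertext], tie_gap: float = 0.0
) -> tuple[tuple[int, ...], list[Ciphertext]]:
    """Stable sort under :func:`compare`; ties keep input order.

    Returns ``(perm, sorted)`` with ``sorted[i] = xs[perm[i]]``.
    """
    idx = sorted(
        range(len(xs)),
        key=cmp_to_key(lambda i, j: compare(xs[i], xs[j], tie_gap=tie_gap).value),
    )
    return tuple(idx), [xs[i] for i in idx]


def permute(xs: Sequence[Ciphertext], perm: Sequence[int]) -> list[Ciphertext]:
    """Reorder ciphertexts by a 0-based permutation, leaving them unmodified."""
    if sorted(perm) != list(range(len(xs))):
        raise ValueError(f"{perm!r} is not a permutation of 0..{len(xs) - 1}")
    return [xs[i] for i in perm]


@dataclass(frozen=True)
class EncryptedInstance:
    """The public face of a DDP instance: ciphertexts plus key-free params.

    ``threshold`` is the public acceptance level T: an encrypted-domain
    residual at or below T is noise-level, i.e. an exact plaintext match.
    """

    A_c: tuple[Ciphertext, ...]
    B_c: tuple[Ciphertext, ...]
    C_c: tuple[Ciphertext, ...]
    n: int
    threshold: float

    @property
    def p(self) -> int:
        return len(self.A_c)

    @property
    def q(self) -> int:
        return len(self.B_c)

    @property
    def t(self) -> int:
        return len(self.C_c)

    def matrix(self, which: str) -> np.ndarray:
        """Ciphertexts of set ``which`` stacked into a (count, n) array."""
        return np.array([ct.c for ct in getattr(self, which + "_c")], dtype=float)

    def to_json(self, path: str | Path) -> None:
        def mat(cts: tuple[Ciphertext, ...]) -> list[list[float]]:
            return [[float(f"{v:.12g}") for v in ct.c] for ct in cts]

        Path(path).write_text(
            json.dumps(
                {
                    "n": self.n,
                    "public": {
                        "p": self.p,
                        "q": self.q,
                        "t": self.t,
                        "T": float(f"{self.threshold:.12g}"),
                    },
                    "A_c": mat(self.A_c),
                    "B_c": mat(self.B_c),
                    "C_c": mat(self.C_c),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EncryptedInstance":
        d = json.loads(Path(path).read_text())
        try:
            n = int(d["n"])
            pub = d["public"]
            p, q, t = int(pub["p"]), int(pub["q"]), int(pub["t"])
            T = float(pub["T"])
            l_max = 2 * (p + q)

            def cts(rows: list[list[float]], expect: int, label: str) -> tuple[Ciphertext, ...]:
                if len(rows) != expect or any(len(r) != n for r in rows):
                    raise MalformedInstanceError(
                        f"{label}: expected {expect} ciphertexts of {n} components"
                    )
                return tuple(Ciphertext(c=tuple(r), depth=1, l_max=l_max) for r in rows)

            return cls(
                A_c=cts(d["A_c"], p, "A_c"),
                B_c=cts(d["B_c"], q, "B_c"),
                C_c=cts(d["C_c"], t, "C_c"),
                n=n,
                threshold=T,
            )
        except (KeyError, TypeError, ValueError) as e:
            if isinstance(e, MalformedInstanceError):
                raise
            raise MalformedInstanceError(f"malformed encrypted-instance file: {e}") from e


def instance_budget(K: KeyVector, inst: DDPInstance, base: NoiseBudget | None = None) -> NoiseBudget:
    """The noise budget :func:`encrypt_instance` uses for this key/instance."""
    base = base if base is not None else NoiseBudget()
    return NoiseBudget(
        p_min=base.p_min, L_max=max(base.L_max, 2 * (inst.p + inst.q))
    ).resolved(K)


def encrypt_instance(
    K: KeyVector,
    inst: DDPInstance,
    budget: NoiseBudget | None = None,
    rng: np.random.Generator | None = None,
) -> EncryptedInstance:
    """Encrypt every fragment of a *valid* instance under one key.

    The additive budget is fixed to ``L_max = 2*(p+q)``: any cut-site sum
    folds at most p+q fragments, and the doubled headroom keeps even
    comparisons between step *differences* of accumulated sums strictly
    order-correct.  The public acceptance threshold is
    ``T = (n-1) * (p+q) * R_bound``.
    """
    v = validate_instance(inst)
    if not v.valid:
        raise MalformedInstanceError(
            f"refusing to encrypt an invalid instance "
            f"(sums {v.sum_A}, {v.sum_B}, {v.sum_C})"
        )
    rng = rng if rng is not None else np.random.default_rng()
    p, q = inst.p, inst.q
    b = instance_budget(K, inst, budget)
    enc = lambda m: encrypt(K, m, b, rng)
    return EncryptedInstance(
        A_c=tuple(enc(a) for a in inst.A),
        B_c=tuple(enc(x) for x in inst.B),
        C_c=tuple(enc(c) for c in inst.C),
        n=K.n,
        threshold=(K.n - 1) * (p + q) * b.R_bound,
    )
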