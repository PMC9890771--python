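"""Quantum-inspired genetic algorithm (QIGA) over encrypted DDP instances.

The server-side search.  Each individual is a chromosome of qubit
amplitude pairs: one gene per fragment position (p genes for the A
ordering, q for the B ordering), each gene holding ``b`` qubits with
``b = ceil(log2(max(p, q))) + 3`` resolution bits.  Measuring a chromosome
collapses every qubit to a bit with probability |beta|^2, the per-gene bit
strings become integer sort keys, and random-key decoding (stable rank
order, ties by position) turns the keys into a valid permutation pair —
every measurement is a feasible candidate solution by construction.

Evolution follows the usual QIGA loop: measure, evaluate, select
(elitism + binary tournament), then update amplitudes with a rotation gate
pulling each qubit toward the best individual's measured bit, followed by
quantum crossover and quantum (NOT-gate) mutation.

Fitness is computed entirely in the ciphertext domain through the OPHI
operations — homomorphic prefix sums give encrypted cut sites, keyless
comparison sorts them, homomorphic subtraction gives encrypted step
differences, and the residual against the encrypted target spectrum is
summed over the informative coordinates.  Because OPHI preserves order,
this ranks candidate mappings exactly as the plaintext fitness would; a
residual at or below the public threshold T is noise-level and means an
exact match (fitness 1).  The solver only ever sees the
:class:`~ppddp.ophi.EncryptedInstance`; keys and plaintexts never enter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import MappingPair
from .ophi import (
    Ciphertext,
    DepthExhaustedError,
    EncryptedInstance,
    add,
    permute,
    sort_ciphertexts,
    subtract,
)

__all__ = [
    "GAConfig",
    "QubitChromosome",
    "FitnessRecord",
    "SolveResult",
    "bits_per_gene",
    "init_population",
    "measure",
    "decode_keys",
    "fitness_encrypted",
    "encrypted_fitness_fn",
    "plaintext_fitness_fn",
    "select",
    "rotate",
    "crossover",
    "mutate",
    "solve",
]

# Saturation clamp on |beta|^2: rotation never drives a qubit fully
# deterministic, preserving a residual escape probability.
_BETA2_MIN = 0.001
_BETA2_MAX = 0.999
_THETA_MIN = math.asin(math.sqrt(_BETA2_MIN))
_THETA_MAX = math.asin(math.sqrt(_BETA2_MAX))


@dataclass(frozen=True)
class GAConfig:
    """Search parameters.

    Defaults follow common QIGA practice for this problem: population
    N=50, up to 10000 generations, crossover probability 0.85, mutation
    probability 0.5 (midpoint of the customary 0.45-0.55 band), rotation
    step 0.025*pi radians.
    """

    N: int = 50
    g_max: int = 10000
    pc: float = 0.85
    pm: float = 0.5
    dtheta: float = 0.025 * math.pi
    seed: int | None = None
    #: catastrophe operator: after this many generations without improvement
    #: the population (not the best-so-far record) is reset to the uniform
    #: superposition; 0 disables.
    restart_after: int = 300

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be at least 2")
        if self.g_max < 1:
            raise ValueError("g_max must be at least 1")
        if not (0.0 <= self.pc <= 1.0 and 0.0 <= self.pm <= 1.0):
            raise ValueError("pc and pm must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        keys = ("N", "g_max", "pc", "pm", "dtheta", "seed", "restart_after")
        return cls(**{k: d[k] for k in keys if k in d})

    def with_seed(self, seed: int | None) -> "GAConfig":
        from dataclasses import replace

        return replace(self, seed=seed)


def bits_per_gene(p: int, q: int) -> int:
    """Resolution of the random keys: ceil(log2(max(p, q))) + 3 bits."""
    return max(1, math.ceil(math.log2(max(p, q, 2)))) + 3


@dataclass(frozen=True)
class QubitChromosome:
    """Amplitude angles theta for (p+q) genes x b qubits.

    Each qubit is the real pair (alpha, beta) = (cos theta, sin theta),
    so alpha^2 + beta^2 = 1 holds identically; theta is kept inside the
    saturation clamp.
    """

    theta: np.ndarray  # shape (p+q, b)
    p: int
    q: int

    @property
    def alpha(self) -> np.ndarray:
        return np.cos(self.theta)

    @property
    def beta(self) -> np.ndarray:
        return np.sin(self.theta)


@dataclass(frozen=True)
class FitnessRecord:
    mapping: MappingPair
    fitness: float
    residual: float
    generation: int


@dataclass(frozen=True)
class SolveResult:
    mapping: MappingPair
    record: FitnessRecord
    generations: int


def init_population(cfg: GAConfig, p: int, q: int) -> list[QubitChromosome]:
    """All qubits start in the uniform superposition (alpha = beta = 1/sqrt 2)."""
    b = bits_per_gene(p, q)
    return [
        QubitChromosome(theta=np.full((p + q, b), math.pi / 4.0), p=p, q=q)
        for _ in range(cfg.N)
    ]


def decode_keys(bits: np.ndarray, p: int, q: int) -> MappingPair:
    """Random-key decoding: per-gene bit strings -> integer keys -> ranks.

    ``mu`` is the order in which the first p genes' keys sort ascending
    (stable, ties broken by gene index); ``nu`` likewise for the last q.
    """
    b = bits.shape[-1]
    weights = 1 << np.arange(b - 1, -1, -1)
    keys = bits @ weights
    mu = np.argsort(keys[:p], kind="stable")
    nu = np.argsort(keys[p:], kind="stable")
    return MappingPair(mu=tuple(int(i) for i in mu), nu=tuple(int(i) for i in nu))


def measure(ch: QubitChromosome, rng: np.random.Generator) -> tuple[MappingPair, np.ndarray]:
    """Collapse every qubit (P(1) = beta^2) and decode the mapping.

    Returns the mapping together with the measured bit array, which the
    rotation gate needs as its attractor.
    """
    bits = (rng.random(ch.theta.shape) < np.sin(ch.theta) ** 2).astype(np.int64)
    return decode_keys(bits, ch.p, ch.q), bits


# ---------------------------------------------------------------------------
# Encrypted-domain fitness
# ---------------------------------------------------------------------------


def _residual_via_ops(enc: EncryptedInstance, mp: MappingPair) -> float:
    """Reference path: the residual computed strictly through OPHI ops."""
    p, q, t = enc.p, enc.q, enc.t
    a_perm = permute(list(enc.A_c), list(mp.mu))
    b_perm = permute(list(enc.B_c), list(mp.nu))

    def prefix_sums(cts: list[Ciphertext]) -> list[Ciphertext]:
        out = [cts[0]]
        for ct in cts[1:]:
            out.append(add(out[-1], ct))
        return out

    tie_gap = 2.0 * enc.threshold / (enc.n - 1)
    sites = prefix_sums(a_perm) + prefix_sums(b_perm)
    _, sites_sorted = sort_ciphertexts(sites, tie_gap=tie_gap)
    zero = Ciphertext(c=(0.0,) * enc.n, depth=0, l_max=sites_sorted[0].l_max)
    diffs = [subtract(b_, a_) for a_, b_ in zip([zero] + sites_sorted[:-1], sites_sorted)]
    _, diffs_sorted = sort_ciphertexts(diffs, tie_gap=tie_gap)
    kept = diffs_sorted[p + q - t :]
    resid = 0.0
    for ct, target in zip(kept, enc.C_c):
        resid += float(
            np.abs(ct.as_array()[: enc.n - 1] - target.as_array()[: enc.n - 1]).sum()
        )
    return resid


def _batch_residuals(
    A_mat: np.ndarray,
    B_mat: np.ndarray,
    C_mat: np.ndarray,
    mus: np.ndarray,
    nus: np.ndarray,
) -> np.ndarray:
    """Vectorized residuals for a batch of mappings.

    Works on (count, n) ciphertext matrices; the merge and the drop rule
    sort by the first coordinate only, which OPHI's order preservation
    guarantees agrees with the all-coordinate comparison whenever the
    underlying plaintexts differ (ties between equal plaintexts are
    outcome-neutral).  Used by the solver's inner loop; tested against
    :func:`_residual_via_ops`.
    """
    t = C_mat.shape[0]
    pq = A_mat.shape[0] + B_mat.shape[0]
    sites = np.concatenate(
        [np.cumsum(A_mat[mus], axis=1), np.cumsum(B_mat[nus], axis=1)], axis=1
    )
    rows = np.arange(sites.shape[0])[:, None]
    order = np.argsort(sites[:, :, 0], axis=1, kind="stable")
    sites = sites[rows, order]
    diffs = np.diff(sites, axis=1, prepend=0.0)
    order = np.argsort(diffs[:, :, 0], axis=1, kind="stable")
    diffs = diffs[rows, order]
    kept = diffs[:, pq - t :, :-1]
    return np.abs(kept - C_mat[None, :, :-1]).sum(axis=(1, 2))


FitnessFn = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


def encrypted_fitness_fn(enc: EncryptedInstance) -> FitnessFn:
    """Batch fitness over ciphertexts: (mus, nus) -> (fitness, residual).

    A residual at or below the public threshold T is noise-level —
    fitness 1.  Otherwise fitness = 1/(1 + residual/(4T)); 4T approximates
    the key-sum scale, so the normalized residual is commensurate with the
    plaintext distance D.  Only the ranking matters to the search.
    """
    if enc.p + enc.q > enc.A_c[0].l_max:
        raise DepthExhaustedError(
            f"instance needs {enc.p + enc.q} accumulations but L_max={enc.A_c[0].l_max}"
        )
    A_mat, B_mat, C_mat = enc.matrix("A"), enc.matrix("B"), enc.matrix("C")
    T = enc.threshold

    def fn(mus: np.ndarray, nus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        resid = _batch_residuals(A_mat, B_mat, C_mat, mus, nus)
        norm = np.where(resid <= T, 0.0, resid / (4.0 * T))
        return 1.0 / (1.0 + norm), resid

    return fn


def plaintext_fitness_fn(inst) -> FitnessFn:
    """Batch fitness on plaintexts (the unencrypted comparison arm)."""
    A_mat = np.asarray(inst.A, dtype=float)[:, None]
    B_mat = np.asarray(inst.B, dtype=float)[:, None]
    C_mat = np.asarray(inst.C, dtype=float)[:, None]
    # append a dummy noise column so the shared kernel's [:-1] slice works
    pad = lambda M: np.concatenate([M, np.zeros_like(M)], axis=1)
    A_mat, B_mat, C_mat = pad(A_mat), pad(B_mat), pad(C_mat)

    def fn(mus: np.ndarray, nus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        resid = _batch_residuals(A_mat, B_mat, C_mat, mus, nus)
        return 1.0 / (1.0 + resid), resid

    return fn


def fitness_encrypted(enc: EncryptedInstance, mp: MappingPair, generation: int = 0) -> FitnessRecord:
    """Encrypted-domain fitness of one mapping, via the OPHI operations."""
    resid = _residual_via_ops(enc, mp)
    T = enc.threshold
    fitness = 1.0 if resid <= T else 1.0 / (1.0 + resid / (4.0 * T))
    return FitnessRecord(mapping=mp, fitness=fitness, residual=resid, generation=generation)


# ---------------------------------------------------------------------------
# Genetic operators
# ---------------------------------------------------------------------------


def select(
    population: Sequence[QubitChromosome],
    records: Sequence[FitnessRecord],
    rng: np.random.Generator,
) -> tuple[list[QubitChromosome], FitnessRecord, bool]:
    """Elitism plus binary tournament.

    The best individual of this generation is retained unconditionally;
    the remaining N-1 slots are winners of fitness tournaments between
    uniformly drawn pairs.  Also reports whether the termination condition
    (fitness 1) was met.
    """
    fits = np.array([r.fitness for r in records])
    best_i = int(np.argmax(fits))
    n = len(population)
    survivors = [population[best_i]]
    a = rng.integers(0, n, size=n - 1)
    b = rng.integers(0, n, size=n - 1)
    winners = np.where(fits[a] >= fits[b], a, b)
    survivors.extend(population[int(i)] for i in winners)
    return survivors, records[best_i], bool(fits[best_i] >= 1.0)


def rotate(ch: QubitChromosome, best_bits: np.ndarray, cfg: GAConfig) -> QubitChromosome:
    """Rotation gate: pull each qubit toward the best individual's bit.

    theta increases by dtheta where the attractor bit is 1 and decreases
    where it is 0, clamped so |beta|^2 stays inside [0.001, 0.999].
    """
    step = np.where(best_bits == 1, cfg.dtheta, -cfg.dtheta)
    theta = np.clip(ch.theta + step, _THETA_MIN, _THETA_MAX)
    return QubitChromosome(theta=theta, p=ch.p, q=ch.q)


def crossover(
    a: QubitChromosome, b: QubitChromosome, cfg: GAConfig, rng: np.random.Generator
) -> tuple[QubitChromosome, QubitChromosome]:
    """Single-point exchange of amplitude-pair suffixes (probability pc)."""
    if rng.random() >= cfg.pc:
        return a, b
    flat_a = a.theta.reshape(-1).copy()
    flat_b = b.theta.reshape(-1).copy()
    point = int(rng.integers(0, flat_a.size))
    flat_a[point:], flat_b[point:] = flat_b[point:].copy(), flat_a[point:].copy()
    shape = a.theta.shape
    return (
        QubitChromosome(theta=flat_a.reshape(shape), p=a.p, q=a.q),
        QubitChromosome(theta=flat_b.reshape(shape), p=b.p, q=b.q),
    )


def mutate(ch: QubitChromosome, cfg: GAConfig, rng: np.random.Generator) -> QubitChromosome:
    """Quantum NOT on one uniformly chosen qubit (probability pm):
    swapping (alpha, beta) maps theta to pi/2 - theta."""
    if rng.random() >= cfg.pm:
        return ch
    flat = ch.theta.reshape(-1).copy()
    i = int(rng.integers(0, flat.size))
    flat[i] = math.pi / 2.0 - flat[i]
    return QubitChromosome(theta=flat.reshape(ch.theta.shape), p=ch.p, q=ch.q)


# ---------------------------------------------------------------------------
# Main loop (vectorized over the population)
# ---------------------------------------------------------------------------


def solve(
    enc: EncryptedInstance | None,
    cfg: GAConfig,
    fitness_fn: FitnessFn | None = None,
    p: int | None = None,
    q: int | None = None,
) -> SolveResult:
    """Run the measure / evaluate / select / update loop to termination.

    Operates on the encrypted instance only (the plaintext comparison arm
    passes ``fitness_fn=plaintext_fitness_fn(inst)`` with explicit p, q).
    Deterministic under ``cfg.seed``.  Stops at fitness 1 or after
    ``cfg.g_max`` generations, returning the best mapping seen.

    The loop is vectorized across the population: amplitudes live in one
    (N, p+q, b) angle array and measurement, decoding, rotation, crossover
    and mutation are performed with array operations that are element-for-
    element the per-individual operators of this module.
    """
    if enc is not None:
        p, q = enc.p, enc.q
        if fitness_fn is None:
            fitness_fn = encrypted_fitness_fn(enc)
    if fitness_fn is None or p is None or q is None:
        raise ValueError("need an encrypted instance, or a fitness_fn with p and q")

    rng = np.random.default_rng(cfg.seed)
    N = cfg.N
    G = p + q
    b = bits_per_gene(p, q)
    weights = 1 << np.arange(b - 1, -1, -1)

    theta = np.full((N, G, b), math.pi / 4.0)
    best_rec: FitnessRecord | None = None
    best_bits: np.ndarray | None = None
    generations = 0
    stall = 0

    for g in range(1, cfg.g_max + 1):
        generations = g
        # measure the whole population
        bits = (rng.random(theta.shape) < np.sin(theta) ** 2).astype(np.int64)
        keys = bits @ weights
        mus = np.argsort(keys[:, :p], axis=1, kind="stable")
        nus = np.argsort(keys[:, p:], axis=1, kind="stable")
        fits, resids = fitness_fn(mus, nus)

        gen_best = int(np.argmax(fits))
        if best_rec is None or fits[gen_best] > best_rec.fitness:
            best_rec = FitnessRecord(
                mapping=MappingPair(
                    mu=tuple(int(i) for i in mus[gen_best]),
                    nu=tuple(int(i) for i in nus[gen_best]),
                ),
                fitness=float(fits[gen_best]),
                residual=float(resids[gen_best]),
                generation=g,
            )
            best_bits = bits[gen_best].copy()
            stall = 0
        else:
            stall += 1
            if fits[gen_best] == best_rec.fitness:
                # neutral drift: let the rotation attractor walk along
                # equal-fitness plateaus instead of freezing on the first
                # representative found
                best_bits = bits[gen_best].copy()
        if best_rec.fitness >= 1.0 or g == cfg.g_max:
            break

        # catastrophe: restart a stagnated population from the uniform
        # superposition, keeping only the best-so-far record
        if cfg.restart_after and stall >= cfg.restart_after:
            theta = np.full((N, G, b), math.pi / 4.0)
            stall = 0
            continue

        # selection: elite (this generation's best) + binary tournaments
        a_idx = rng.integers(0, N, size=N - 1)
        b_idx = rng.integers(0, N, size=N - 1)
        winners = np.where(fits[a_idx] >= fits[b_idx], a_idx, b_idx)
        theta = theta[np.concatenate([[gen_best], winners])].copy()

        # rotation toward the best-so-far measurement
        step = np.where(best_bits == 1, cfg.dtheta, -cfg.dtheta)
        theta = np.clip(theta + step[None, :, :], _THETA_MIN, _THETA_MAX)

        # quantum crossover: disjoint random pairs, single-point suffix swap
        flat = theta.reshape(N, G * b)
        pair_order = rng.permutation(N)
        do_cx = rng.random(N // 2) < cfg.pc
        points = rng.integers(0, G * b, size=N // 2)
        i_idx, j_idx = pair_order[0 : 2 * (N // 2) : 2], pair_order[1 : 2 * (N // 2) : 2]
        swap = do_cx[:, None] & (np.arange(G * b)[None, :] >= points[:, None])
        fi, fj = flat[i_idx], flat[j_idx]
        flat[i_idx] = np.where(swap, fj, fi)
        flat[j_idx] = np.where(swap, fi, fj)
        theta = flat.reshape(N, G, b)

        # quantum mutation: per chromosome, NOT-gate on one qubit
        do_mut = rng.random(N) < cfg.pm
        qubit = rng.integers(0, G * b, size=N)
        flat = theta.reshape(N, G * b)
        rows = np.nonzero(do_mut)[0]
        flat[rows, qubit[rows]] = math.pi / 2.0 - flat[rows, qubit[rows]]
        theta = flat.reshape(N, G, b)

    assert best_rec is not None
    return SolveResult(mapping=best_rec.mapping, record=best_rec, generations=generations)
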