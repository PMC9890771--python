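"""Plaintext model of the double digest problem (DDP).

A double digest experiment cuts one DNA molecule three ways — with
restriction enzyme alpha alone, with enzyme beta alone, and with both
simultaneously — and gel electrophoresis reports the three multisets of
fragment lengths A, B and C.  Reconstructing the physical map means finding
orderings (permutations) of A and of B whose merged cut sites reproduce C.

This module holds the plaintext side of that problem: instance containers
and validation, the accumulative-summation / step-difference operators that
convert between fragment lengths and cut-site coordinates, the implied
double-digest spectrum of a candidate ordering, the fitness functional
``f = 1/(1 + D)`` with ``D`` the L1 distance between the implied and the
observed spectrum, the owner-side verification predicate, and an exhaustive
brute-force solver used as a ground-truth oracle on small instances.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MalformedInstanceError",
    "InconsistentInstanceError",
    "DDPInstance",
    "MappingPair",
    "ImpliedSpectrum",
    "ValidityVerdict",
    "validate_instance",
    "accumulative_summation",
    "step_difference",
    "implied_C",
    "fitness_plain",
    "verify_solution",
    "brute_force_solve",
    "BruteForceResult",
]


class MalformedInstanceError(ValueError):
    """An instance that is structurally broken (empty set, non-positive
    length, bad permutation) — distinct from one that merely fails the
    equal-sums validity check."""


class InconsistentInstanceError(ValueError):
    """Instance dimensions rule out any double-digest interpretation
    (fewer simultaneous-digest fragments than one, or t > p + q)."""


def _as_multiset(name: str, values: Iterable[float]) -> tuple[int, ...]:
    vals = list(values)
    if len(vals) == 0:
        raise MalformedInstanceError(f"multiset {name} is empty")
    out = []
    for v in vals:
        iv = int(v)
        if iv != v or iv <= 0:
            raise MalformedInstanceError(
                f"multiset {name} contains non-positive or non-integer length {v!r}"
            )
        out.append(iv)
    return tuple(sorted(out))


@dataclass(frozen=True)
class DDPInstance:
    """The three fragment-length multisets of a double digest experiment.

    ``A`` (enzyme alpha digest), ``B`` (enzyme beta digest) and ``C``
    (simultaneous digest) are stored in non-decreasing order; lengths are
    positive integers in an arbitrary common unit (base pairs in practice).
    An instance is *valid* when the three sets account for the same total
    molecule length, ``sum(A) = sum(B) = sum(C)``.
    """

    A: tuple[int, ...]
    B: tuple[int, ...]
    C: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", _as_multiset("A", self.A))
        object.__setattr__(self, "B", _as_multiset("B", self.B))
        object.__setattr__(self, "C", _as_multiset("C", self.C))

    @property
    def p(self) -> int:
        return len(self.A)

    @property
    def q(self) -> int:
        return len(self.B)

    @property
    def t(self) -> int:
        return len(self.C)

    @property
    def total_length(self) -> int:
        return sum(self.A)

    def is_valid(self) -> bool:
        return validate_instance(self).valid

    # --- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {"A": list(self.A), "B": list(self.B), "C": list(self.C)}

    @classmethod
    def from_dict(cls, d: dict) -> "DDPInstance":
        try:
            return cls(A=d["A"], B=d["B"], C=d["C"])
        except KeyError as e:  # pragma: no cover - defensive
            raise MalformedInstanceError(f"instance file missing key {e}") from e

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DDPInstance":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DDPInstance":
        """Read a three-row CSV with row labels A, B, C."""
        rows: dict[str, list[int]] = {}
        for line in Path(path).read_text().strip().splitlines():
            parts = [p.strip() for p in line.split(",") if p.strip()]
            if not parts:
                continue
            rows[parts[0].upper()] = [int(x) for x in parts[1:]]
        missing = {"A", "B", "C"} - rows.keys()
        if missing:
            raise MalformedInstanceError(f"CSV instance missing rows {sorted(missing)}")
        return cls(A=rows["A"], B=rows["B"], C=rows["C"])


@dataclass(frozen=True)
class ValidityVerdict:
    valid: bool
    sum_A: int
    sum_B: int
    sum_C: int


def validate_instance(inst: DDPInstance) -> ValidityVerdict:
    """Check the equal-total-length condition sum(A) = sum(B) = sum(C).

    Structural problems (empty sets, non-positive lengths) raise
    :class:`MalformedInstanceError` at construction already; this verdict
    only decides whether a well-formed instance is a feasible double
    digest read-out.
    """
    sa, sb, sc = sum(inst.A), sum(inst.B), sum(inst.C)
    return ValidityVerdict(valid=(sa == sb == sc), sum_A=sa, sum_B=sb, sum_C=sc)


def _require_valid(inst: DDPInstance) -> None:
    v = validate_instance(inst)
    if not v.valid:
        raise MalformedInstanceError(
            f"invalid instance: sum(A)={v.sum_A}, sum(B)={v.sum_B}, sum(C)={v.sum_C}"
        )


@dataclass(frozen=True)
class MappingPair:
    """A candidate DDP solution: permutations of the A and B indices.

    ``mu`` and ``nu`` are stored 0-based internally; file formats and
    user-facing output use the conventional 1-based indices.
    """

    mu: tuple[int, ...]
    nu: tuple[int, ...]

    def __post_init__(self) -> None:
        for name, perm in (("mu", self.mu), ("nu", self.nu)):
            t = tuple(int(i) for i in perm)
            if sorted(t) != list(range(len(t))):
                raise MalformedInstanceError(f"{name}={perm!r} is not a permutation")
            object.__setattr__(self, name, t)

    def to_dict(self, fitness: float | None = None) -> dict:
        d = {"mu": [i + 1 for i in self.mu], "nu": [i + 1 for i in self.nu]}
        if fitness is not None:
            d["fitness"] = fitness
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MappingPair":
        return cls(
            mu=tuple(int(i) - 1 for i in d["mu"]),
            nu=tuple(int(i) - 1 for i in d["nu"]),
        )

    @classmethod
    def identity(cls, p: int, q: int) -> "MappingPair":
        return cls(mu=tuple(range(p)), nu=tuple(range(q)))


def accumulative_summation(v: Sequence[float]) -> np.ndarray:
    """Running prefix sums of an ordered fragment list = cut-site coordinates."""
    arr = np.asarray(v)
    if arr.size == 0:
        raise ValueError("accumulative summation of an empty list is undefined")
    return np.cumsum(arr)


def step_difference(v: Sequence[float]) -> np.ndarray:
    """Consecutive differences of a non-decreasing coordinate list.

    Inverse of :func:`accumulative_summation` up to the leading element:
    ``step_difference(accumulative_summation(x)) == x[1:]``.
    """
    arr = np.asarray(v)
    if arr.size == 0:
        raise ValueError("step difference of an empty list is undefined")
    d = np.diff(arr)
    if arr.size > 1 and np.any(d < 0):
        raise ValueError("step difference requires a non-decreasing input")
    return d


@dataclass(frozen=True)
class ImpliedSpectrum:
    """The double-digest spectrum implied by one (mu, nu) arrangement.

    ``raw`` lists the kept fragment lengths in cut-site order, ``ascending``
    is the same multiset sorted; both sum to the molecule length.
    """

    raw: tuple[int, ...]
    ascending: tuple[int, ...]


def _implied_values(inst: DDPInstance, mp: MappingPair) -> np.ndarray:
    """Kept step differences, ascending. Shared by implied_C/fitness."""
    p, q, t = inst.p, inst.q, inst.t
    if len(mp.mu) != p or len(mp.nu) != q:
        raise MalformedInstanceError(
            f"mapping dimensions ({len(mp.mu)},{len(mp.nu)}) do not match instance ({p},{q})"
        )
    n_drop = p + q - t
    if n_drop < 1:
        raise InconsistentInstanceError(
            f"t={t} >= p+q={p + q}: no duplicated terminal site is possible"
        )
    A = np.asarray(inst.A)[list(mp.mu)]
    B = np.asarray(inst.B)[list(mp.nu)]
    sites = np.concatenate([np.cumsum(A), np.cumsum(B)])
    # stable sort keeps alpha-derived sites ahead of beta-derived ones at
    # equal coordinates; the dropped-zeros rule makes the choice neutral
    sites = sites[np.argsort(sites, kind="stable")]
    diffs = np.diff(np.concatenate([[0], sites]))
    order = np.argsort(diffs, kind="stable")
    return diffs[order[n_drop:]]


def implied_C(inst: DDPInstance, mp: MappingPair) -> ImpliedSpectrum:
    """Spectrum of the simultaneous digest implied by arranging A by ``mu``
    and B by ``nu``.

    The cut sites of the two single digests are merged and sorted, a zero
    origin is prepended, and the step differences are taken; the
    ``p + q - t`` smallest differences — the zero-length artifacts from
    coincident sites, always including the duplicated terminal site — are
    dropped, leaving exactly ``t`` fragment lengths.
    """
    _require_valid(inst)
    kept = _implied_values(inst, mp)
    return ImpliedSpectrum(
        raw=tuple(int(x) for x in kept),
        ascending=tuple(int(x) for x in np.sort(kept)),
    )


def spectrum_distance(inst: DDPInstance, mp: MappingPair) -> int:
    """L1 distance D between the implied ascending spectrum and C."""
    _require_valid(inst)
    kept = np.sort(_implied_values(inst, mp))
    return int(np.abs(kept - np.asarray(inst.C)).sum())


def fitness_plain(inst: DDPInstance, mp: MappingPair) -> float:
    """f(mu, nu) = 1 / (1 + D); the optimum, an exact spectrum match, is 1."""
    return 1.0 / (1.0 + spectrum_distance(inst, mp))


def verify_solution(inst: DDPInstance, mp: MappingPair) -> bool:
    """Owner-side acceptance: true iff the arrangement reproduces C exactly."""
    return spectrum_distance(inst, mp) == 0


@dataclass(frozen=True)
class BruteForceResult:
    best_fitness: float
    solutions: tuple[MappingPair, ...]
    n_evaluated: int


def brute_force_solve(inst: DDPInstance, cap: int = 10**6) -> BruteForceResult:
    """Exhaustively enumerate all p!*q! mappings; oracle for small instances.

    Refuses when the enumeration would exceed ``cap`` pairs.
    """
    _require_valid(inst)
    total = math.factorial(inst.p) * math.factorial(inst.q)
    if total > cap:
        raise ValueError(f"p!*q! = {total} exceeds the brute-force cap {cap}")
    best_d = None
    best: list[MappingPair] = []
    for mu in itertools.permutations(range(inst.p)):
        for nu in itertools.permutations(range(inst.q)):
            mp = MappingPair(mu=mu, nu=nu)
            d = spectrum_distance(inst, mp)
            if best_d is None or d < best_d:
                best_d, best = d, [mp]
            elif d == best_d:
                best.append(mp)
    return BruteForceResult(
        best_fitness=1.0 / (1.0 + best_d),
        solutions=tuple(best),
        n_evaluated=total,
    )
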