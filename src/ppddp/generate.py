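"""Synthetic double-digest instance generator and experiment runners.

The generator emulates the wet-lab experiment directly: it plants distinct
alpha-enzyme and beta-enzyme cut sites on an integer molecule of length L,
then reads off the three fragment-length multisets — A from the alpha
sites, B from the beta sites, C from their union.  Instances built this way
are valid by construction (all three sets telescope to L) and always admit
at least one exact solution: the true cut order, which is retained as
hidden ground truth for diagnostics but never shown to the solver.

The experiment runners reproduce the random-instance protocol used to
characterize the framework: groups of instances with growing |C|, each
solved repeatedly end-to-end with distinct GA seeds, reporting per-group
success rates; and a paired-arm comparison that runs the identical GA once
with the encrypted-domain fitness and once with the plaintext fitness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DDPInstance, MappingPair
from .qiga import GAConfig

__all__ = [
    "GenSpec",
    "GeneratedInstance",
    "generate_instance",
    "success_rate_experiment",
    "compare_with_plaintext",
]


@dataclass(frozen=True)
class GenSpec:
    """What to generate.

    ``t`` — target size of the simultaneous digest C (the experiments use
    10-80).  ``length`` — total molecule length; defaults to 100*t so
    adjacent sites are typically well separated.  ``allow_coincident`` —
    when set, alpha and beta sites may coincide in the interior, producing
    instances with t < p+q-1.  ``seed`` — generator seed.
    """

    t: int
    length: int | None = None
    allow_coincident: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t < 3:
            raise ValueError("t must be at least 3")
        L = self.length if self.length is not None else 100 * self.t
        if L < self.t + 1:
            raise ValueError("total length must exceed t")
        object.__setattr__(self, "length", L)


@dataclass(frozen=True)
class GeneratedInstance:
    instance: DDPInstance
    true_mapping: MappingPair  # diagnostics only; never given to the solver


def _rank_mapping(frags: np.ndarray) -> tuple[tuple[int, ...], np.ndarray]:
    """Sorted multiset + the permutation restoring the positional order."""
    order = np.argsort(frags, kind="stable")
    inverse = np.argsort(order, kind="stable")
    # sorted_frags[inverse] == frags
    return tuple(int(x) for x in frags[order]), inverse


def generate_instance(spec: GenSpec) -> GeneratedInstance:
    """Plant cut sites and read off the digest multisets.

    Without coincidences, t-1 distinct interior sites are split between the
    two enzymes (|alpha| = floor((t-1)/2)), giving |A| + |B| = t + 1.  With
    ``allow_coincident``, the two site sets are drawn independently and may
    overlap; t then emerges from the union.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    if spec.t - 1 > L - 1:
        raise ValueError("not enough interior positions for t-1 cut sites")
    if not spec.allow_coincident:
        sites = rng.choice(np.arange(1, L), size=spec.t - 1, replace=False)
        rng.shuffle(sites)
        na = (spec.t - 1) // 2
        alpha, beta = np.sort(sites[:na]), np.sort(sites[na:])
    else:
        na = (spec.t - 1) // 2
        nb = spec.t - 1 - na
        alpha = np.sort(rng.choice(np.arange(1, L), size=na, replace=False))
        beta = np.sort(rng.choice(np.arange(1, L), size=nb, replace=False))
    union = np.union1d(alpha, beta)

    def gaps(interior: np.ndarray) -> np.ndarray:
        return np.diff(np.concatenate([[0], interior, [L]]))

    frags_a, frags_b = gaps(alpha), gaps(beta)
    A, inv_a = _rank_mapping(frags_a)
    B, inv_b = _rank_mapping(frags_b)
    C = tuple(int(x) for x in np.sort(gaps(union)))
    inst = DDPInstance(A=A, B=B, C=C)
    truth = MappingPair(mu=tuple(int(i) for i in inv_a), nu=tuple(int(i) for i in inv_b))
    return GeneratedInstance(instance=inst, true_mapping=truth)


def success_rate_experiment(
    t_values: Sequence[int],
    runs: int = 25,
    cfg: GAConfig | None = None,
    n: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group success rates of the full encrypted pipeline.

    For each t, one instance is generated (seeded from ``seed``) and the
    five-stage pipeline is run ``runs`` times with distinct GA seeds;
    success means the owner's plaintext verification accepts the returned
    mapping.  Returns the tidy table
    (t, runs, successes, success_rate, mean_generations, mean_residual).
    """
    from .framework import run_session  # deferred: framework imports qiga

    cfg = cfg if cfg is not None else GAConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for ti, t in enumerate(t_values):
        inst_seed, crypto_seed, *ga_seeds = [
            int(s) for s in ss.spawn(1)[0].generate_state(2 + runs) >> 1
        ]
        gen = generate_instance(GenSpec(t=t, seed=inst_seed))
        successes, gens, resids = 0, [], []
        for r in range(runs):
            rep = run_session(
                gen.instance,
                n=n,
                cfg=cfg.with_seed(ga_seeds[r]),
                crypto_seed=crypto_seed,
                max_retries=0,
            )
            successes += int(rep.success)
            gens.append(rep.generations)
            resids.append(rep.residual)
        rows.append(
            {
                "t": t,
                "runs": runs,
                "successes": successes,
                "success_rate": successes / runs,
                "mean_generations": float(np.mean(gens)),
                "mean_residual": float(np.mean(resids)),
            }
        )
    return pd.DataFrame(rows)


def compare_with_plaintext(
    t_values: Sequence[int],
    runs: int = 25,
    cfg: GAConfig | None = None,
    n: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired arms: identical instances and GA seeds, one arm evaluating
    fitness on ciphertexts, the other on plaintexts.

    Returns one row per t with both arms' success rates, their absolute
    difference and its binomial standard error.
    """
    from .framework import run_session
    from .qiga import plaintext_fitness_fn, solve

    from .model import verify_solution

    cfg = cfg if cfg is not None else GAConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for t in t_values:
        inst_seed, crypto_seed, *ga_seeds = [
            int(s) for s in ss.spawn(1)[0].generate_state(2 + runs) >> 1
        ]
        gen = generate_instance(GenSpec(t=t, seed=inst_seed))
        inst = gen.instance
        enc_succ = plain_succ = 0
        for r in range(runs):
            run_cfg = cfg.with_seed(ga_seeds[r])
            rep = run_session(inst, n=n, cfg=run_cfg, crypto_seed=crypto_seed,
                              max_retries=0)
            enc_succ += int(rep.success)
            res = solve(None, run_cfg, fitness_fn=plaintext_fitness_fn(inst),
                        p=inst.p, q=inst.q)
            plain_succ += int(verify_solution(inst, res.mapping))
        r_enc, r_plain = enc_succ / runs, plain_succ / runs
        diff = abs(r_enc - r_plain)
        se = float(
            np.sqrt(r_enc * (1 - r_enc) / runs + r_plain * (1 - r_plain) / runs)
        )
        rows.append(
            {
                "t": t,
                "runs": runs,
                "rate_encrypted": r_enc,
                "rate_plaintext": r_plain,
                "abs_difference": diff,
                "binomial_se": se,
            }
        )
    return pd.DataFrame(rows)
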