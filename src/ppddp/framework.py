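"""Five-stage outsourcing protocol between data owner and cloud server.

Stage 1 (owner)   — protect: generate a key, encrypt the instance.
Stage 2 (channel) — publish the encrypted instance file.
Stage 3 (server)  — solve: run the QIGA on ciphertexts only.
Stage 4 (channel) — publish the mapping file (plain permutations).
Stage 5 (owner)   — extract: apply the mappings to the private plaintexts,
                    verify, and emit the reconstructed physical map.

The two roles are simulated as separate functions with a strict interface
boundary: the server-side code path receives nothing but the public
encrypted-instance file (or object) and a GA configuration — keys and
plaintexts structurally cannot reach it.  A lazy-server hook returns a
random mapping instead of searching, for exercising the owner's rejection
path; the owner retries a rejected result up to a configurable count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .model import (
    DDPInstance,
    MalformedInstanceError,
    MappingPair,
    fitness_plain,
    verify_solution,
)
from .ophi import EncryptedInstance, encrypt_instance, instance_budget, keygen
from .qiga import GAConfig, SolveResult, solve

__all__ = [
    "SessionReport",
    "ExtractionResult",
    "stage1_protect",
    "stage3_solve",
    "stage5_extract",
    "run_session",
    "run_end_to_end",
]


@dataclass(frozen=True)
class ExtractionResult:
    """Owner-side verdict plus, on success, the reconstructed physical map."""

    accepted: bool
    fitness: float
    a_order: tuple[int, ...] | None  # fragment lengths of A in map order
    b_order: tuple[int, ...] | None
    merged_sites: tuple[int, ...] | None


@dataclass(frozen=True)
class SessionReport:
    success: bool
    generations: int
    residual: float
    fitness: float
    mapping: MappingPair
    retries: int = 0
    crypto_seed: int | None = None
    ga_seed: int | None = None


# ---------------------------------------------------------------------------
# File-based stages (the CLI surface)
# ---------------------------------------------------------------------------


def stage1_protect(
    instance_file: str | Path,
    n: int = 3,
    seed: int | None = None,
    key_file: str | Path = "key.json",
    encrypted_file: str | Path = "encrypted.json",
) -> EncryptedInstance:
    """Owner: encrypt the instance; write the secret key file and the
    public encrypted-instance file.  Refuses invalid instances."""
    inst = DDPInstance.from_json(instance_file)
    rng = np.random.default_rng(seed)
    key = keygen(n, rng=rng)
    enc = encrypt_instance(key, inst, rng=rng)
    key.to_json(key_file, instance_budget(key, inst))
    enc.to_json(encrypted_file)
    return enc


def stage3_solve(
    encrypted_file: str | Path,
    cfg: GAConfig | None = None,
    mapping_file: str | Path = "mapping.json",
    lazy: bool = False,
) -> SolveResult:
    """Server: search over ciphertexts, write the mapping file.

    This function's only inputs are the public file and the GA settings;
    it is the entire server role.  ``lazy`` simulates a server that skips
    the work and returns a uniformly random mapping.
    """
    enc = EncryptedInstance.from_json(encrypted_file)
    res = _server_solve(enc, cfg if cfg is not None else GAConfig(), lazy=lazy)
    Path(mapping_file).write_text(
        json.dumps(
            res.mapping.to_dict(fitness=res.record.fitness)
            | {"generations": res.generations, "residual": res.record.residual}
        )
    )
    return res


def _server_solve(enc: EncryptedInstance, cfg: GAConfig, lazy: bool = False) -> SolveResult:
    if lazy:
        rng = np.random.default_rng(cfg.seed)
        mp = MappingPair(
            mu=tuple(int(i) for i in rng.permutation(enc.p)),
            nu=tuple(int(i) for i in rng.permutation(enc.q)),
        )
        from .qiga import fitness_encrypted

        rec = fitness_encrypted(enc, mp)
        return SolveResult(mapping=mp, record=rec, generations=0)
    return solve(enc, cfg)


def stage5_extract(
    instance_file: str | Path, mapping_file: str | Path
) -> ExtractionResult:
    """Owner: combine the public mapping with the private instance."""
    inst = DDPInstance.from_json(instance_file)
    d = json.loads(Path(mapping_file).read_text())
    mp = MappingPair.from_dict(d)
    return extract(inst, mp)


def extract(inst: DDPInstance, mp: MappingPair) -> ExtractionResult:
    """Verify a mapping and, on acceptance, reconstruct the physical map."""
    if len(mp.mu) != inst.p or len(mp.nu) != inst.q:
        raise MalformedInstanceError(
            f"mapping dimensions ({len(mp.mu)},{len(mp.nu)}) do not match "
            f"instance ({inst.p},{inst.q})"
        )
    f = fitness_plain(inst, mp)
    if not verify_solution(inst, mp):
        return ExtractionResult(accepted=False, fitness=f, a_order=None,
                                b_order=None, merged_sites=None)
    a_order = tuple(inst.A[i] for i in mp.mu)
    b_order = tuple(inst.B[i] for i in mp.nu)
    sites = np.unique(np.concatenate([np.cumsum(a_order), np.cumsum(b_order)]))
    return ExtractionResult(
        accepted=True,
        fitness=f,
        a_order=a_order,
        b_order=b_order,
        merged_sites=tuple(int(s) for s in sites),
    )


# ---------------------------------------------------------------------------
# In-process end-to-end session
# ---------------------------------------------------------------------------


def run_session(
    inst: DDPInstance,
    n: int = 3,
    cfg: GAConfig | None = None,
    crypto_seed: int | None = None,
    lazy: bool = False,
    max_retries: int = 3,
) -> SessionReport:
    """Stages 1-5 chained in-process on objects (no files).

    A rejected mapping triggers recomputation with a reseeded GA, up to
    ``max_retries`` times — the owner's answer to a lazy server.
    """
    cfg = cfg if cfg is not None else GAConfig()
    rng = np.random.default_rng(crypto_seed)
    key = keygen(n, rng=rng)
    enc = encrypt_instance(key, inst, rng=rng)

    retries = 0
    ga_seed = cfg.seed
    while True:
        run_cfg = cfg.with_seed(ga_seed)
        res = _server_solve(enc, run_cfg, lazy=lazy)
        verdict = extract(inst, res.mapping)
        if verdict.accepted or retries >= max_retries:
            return SessionReport(
                success=verdict.accepted,
                generations=res.generations,
                residual=res.record.residual,
                fitness=verdict.fitness,
                mapping=res.mapping,
                retries=retries,
                crypto_seed=crypto_seed,
                ga_seed=ga_seed,
            )
        retries += 1
        ga_seed = None if ga_seed is None else (ga_seed + 1) % (2**31)


def run_end_to_end(
    instance_file: str | Path,
    n: int = 3,
    cfg: GAConfig | None = None,
    workdir: str | Path = ".",
    crypto_seed: int | None = None,
    lazy: bool = False,
    max_retries: int = 3,
) -> SessionReport:
    """File-based stages 1->3->5; public-channel files retained for audit."""
    cfg = cfg if cfg is not None else GAConfig()
    workdir = Path(workdir)
    key_file = workdir / "key.json"
    enc_file = workdir / "encrypted.json"
    map_file = workdir / "mapping.json"
    stage1_protect(instance_file, n=n, seed=crypto_seed,
                   key_file=key_file, encrypted_file=enc_file)

    retries = 0
    ga_seed = cfg.seed
    while True:
        run_cfg = cfg.with_seed(ga_seed)
        res = stage3_solve(enc_file, run_cfg, mapping_file=map_file, lazy=lazy)
        verdict = stage5_extract(instance_file, map_file)
        if verdict.accepted or retries >= max_retries:
            return SessionReport(
                success=verdict.accepted,
                generations=res.generations,
                residual=res.record.residual,
                fitness=verdict.fitness,
                mapping=res.mapping,
                retries=retries,
                crypto_seed=crypto_seed,
                ga_seed=ga_seed,
            )
        retries += 1
        ga_seed = None if ga_seed is None else (ga_seed + 1) % (2**31)
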