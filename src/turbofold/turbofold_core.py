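"""Iterative estimation of base-pairing probabilities for a sequence set.

The procedure alternates two message-passing steps, in the spirit of turbo
decoding.  One-time setup computes pairwise co-incidence matrices and
sequence identities for all pairs.  Iteration t = 0 folds every sequence
with the neutral (all-ones) extrinsic prior, i.e. the plain single-sequence
partition function.  Each subsequent iteration computes, for every
sequence, extrinsic information from the *previous* iteration's pairing
probabilities of all other sequences (a synchronous, Jacobi-style update:
every extrinsic matrix of iteration t is built from the same iteration
t - 1 snapshot), then recomputes the modified partition function.  After
eta + 1 total iterations the final probability matrices are returned.

Per-sequence partition computations within an iteration are independent
and may run on several threads; results are bitwise identical to the
sequential order regardless of thread count.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_hmm import (
    DEFAULT_COINCIDENCE_THRESHOLD,
    AlignmentModelParams,
    coincidence,
    constraint_sets,
    default_hmm_params,
)
from .energy_model import EnergyParams, default_energy_params
from .extrinsic import ExtrinsicMatrix, aggregate_extrinsic, induced_proclivity
from .io_formats import RnaSequence
from .partition import PairProbabilityMatrix, modified_partition, unpaired_probabilities
from .predict import mea_structure
from .scoring import score_structure

__all__ = ["TurboConfig", "TurboResult", "run_turbofold", "iteration_trace"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TurboConfig:
    """Run configuration.

    ``gamma`` is the extrinsic weight in units of RT (default 0.3);
    ``iterations`` is eta, the number of refinement iterations after the
    initialisation pass (default 3).
    """

    gamma: float = 0.3
    iterations: int = 3
    coincidence_threshold: float = DEFAULT_COINCIDENCE_THRESHOLD
    mode: str = "mea"
    p_thresh: float = 0.51
    pair_weight: float = 2.0
    threads: int = 1
    keep_history: bool = True
    hmm_params: AlignmentModelParams | None = None
    energy_params: EnergyParams | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if not (0.0 <= self.coincidence_threshold < 1.0):
            raise ValueError("coincidence threshold must be in [0, 1)")
        if self.mode not in {"probabilities", "threshold", "mea"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.p_thresh <= 1.0):
            raise ValueError("P_thresh must be in (0, 1]")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


@dataclass
class TurboResult:
    """Final pairing-probability matrices plus run diagnostics."""

    sequences: list
    matrices: dict  # id -> PairProbabilityMatrix (final iteration)
    history: list | None  # per-iteration dict id -> matrix, length eta + 1
    identities: dict  # (id_m, id_s) -> psi
    constraint_d: dict  # (id_m, id_s) -> mean constraint-set size
    config: TurboConfig

    def unpaired(self, seq_id: str) -> np.ndarray:
        return unpaired_probabilities(self.matrices[seq_id])


def run_turbofold(seqs: list, cfg: TurboConfig | None = None) -> TurboResult:
    """Run the full iterative procedure on a set of homologous sequences."""
    cfg = cfg or TurboConfig()
    if len(seqs) < 1:
        raise ValueError("at least one sequence required")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    if len(seqs) == 1:
        warnings.warn(
            "single-sequence input: result is the plain partition function",
            stacklevel=2,
        )
    hmm = cfg.hmm_params or default_hmm_params()
    energy = cfg.energy_params or default_energy_params()
    gamma_kcal = cfg.gamma * energy.RT

    # --- one-time setup: co-incidence, identities, constraint sets ---------
    coin: dict = {}
    masks: dict = {}
    identities: dict = {}
    constraint_d: dict = {}
    for a in range(len(seqs)):
        for b in range(a + 1, len(seqs)):
            cm = coincidence(seqs[a], seqs[b], hmm)
            cs = constraint_sets(cm, cfg.coincidence_threshold)
            coin[(ids[a], ids[b])] = cm
            coin[(ids[b], ids[a])] = cm.transpose()
            masks[(ids[a], ids[b])] = cs
            masks[(ids[b], ids[a])] = constraint_sets(
                cm.transpose(), cfg.coincidence_threshold
            )
            identities[(ids[a], ids[b])] = cm.identity
            identities[(ids[b], ids[a])] = cm.identity
            constraint_d[(ids[a], ids[b])] = cs.d
            constraint_d[(ids[b], ids[a])] = masks[(ids[b], ids[a])].d

    def fold_all(exts: dict, iteration: int) -> dict:
        """Modified partition for every sequence (parallelisable)."""

        def one(seq: RnaSequence) -> PairProbabilityMatrix:
            ext = exts[seq.id]
            res = modified_partition(
                seq,
                None if ext.neutral else ext.values,
                gamma_kcal,
                energy,
                iteration=iteration,
            )
            return res.matrix

        if cfg.threads == 1 or len(seqs) == 1:
            return {s.id: one(s) for s in seqs}
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            results = list(pool.map(one, seqs))
        return dict(zip(ids, results))

    # --- t = 0: neutral extrinsic ------------------------------------------
    neutral = {s.id: ExtrinsicMatrix.neutral_for(s.length) for s in seqs}
    current = fold_all(neutral, iteration=0)
    history = [current] if cfg.keep_history else None
    logger.info("iteration 0 complete (neutral extrinsic), K=%d", len(seqs))

    # --- iterations t = 1..eta ---------------------------------------------
    for t in range(1, cfg.iterations + 1):
        exts: dict = {}
        for m, seq_m in enumerate(seqs):
            if len(seqs) == 1:
                exts[seq_m.id] = ExtrinsicMatrix.neutral_for(seq_m.length)
                continue
            procs = {}
            psis = {}
            for s, seq_s in enumerate(seqs):
                if s == m:
                    continue  # a sequence never contributes to its own prior
                key = (seq_m.id, seq_s.id)
                procs[seq_s.id] = induced_proclivity(
                    current[seq_s.id],
                    coin[key],
                    masks[key],
                    target_id=seq_m.id,
                    source_id=seq_s.id,
                )
                psis[seq_s.id] = identities[key]
            exts[seq_m.id] = aggregate_extrinsic(procs, psis)
        current = fold_all(exts, iteration=t)
        if cfg.keep_history:
            history.append(current)
        logger.info("iteration %d complete", t)

    return TurboResult(
        sequences=list(seqs),
        matrices=current,
        history=history,
        identities=identities,
        constraint_d=constraint_d,
        config=cfg,
    )


def iteration_trace(result: TurboResult, known: dict) -> pd.DataFrame:
    """Mean MEA prediction accuracy per iteration.

    ``known`` maps sequence id to the reference structure.  Returns a frame
    with one row per iteration t = 0..eta and columns ``t``,
    ``sensitivity``, ``ppv`` and ``f_measure`` (means over sequences).
    """
    if result.history is None:
        raise ValueError("run with keep_history=True to trace iterations")
    rows = []
    for t, mats in enumerate(result.history):
        scores = []
        for seq in result.sequences:
            mat = mats[seq.id]
            pred = mea_structure(mat, pair_weight=result.config.pair_weight)
            scores.append(score_structure(pred, known[seq.id]))
        rows.append(
            {
                "t": t,
                "sensitivity": float(np.mean([s.sensitivity for s in scores])),
                "ppv": float(np.mean([s.ppv for s in scores])),
                "f_measure": float(np.mean([s.f_measure for s in scores])),
            }
        )
    return pd.DataFrame(rows)
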