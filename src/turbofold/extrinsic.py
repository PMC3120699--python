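"""Extrinsic information: homolog pairing probabilities mapped through
co-incidence.

A base pair (k, l) in a source homolog with pairing probability p induces a
proclivity ``p * c(i, k) * c(j, l)`` for the target pair (i, j), where the
``c`` are posterior co-incidence probabilities between the two sequences.
Proclivity matrices from all other homologs are combined with the inverse
identity weight ``(1 - psi)`` — an identical sequence carries no extrinsic
information — and the aggregate is normalised so its maximum entry is one.
If the aggregate vanishes entirely, the neutral all-ones matrix is returned
and the modified partition function reduces to the single-sequence case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_hmm import CoincidenceMatrix, ConstraintSets
from .partition import PairProbabilityMatrix

__all__ = ["ProclivityMatrix", "ExtrinsicMatrix", "induced_proclivity", "aggregate_extrinsic"]


@dataclass
class ProclivityMatrix:
    """Induced pairing proclivities for a target sequence from one source.

    ``values[i-1, j-1]`` (1-based ``i < j``, upper triangle) is the summed
    proclivity induced onto target pair (i, j).
    """

    values: np.ndarray
    target_id: str = ""
    source_id: str = ""


@dataclass
class ExtrinsicMatrix:
    """Aggregated, max-normalised extrinsic information for one sequence.

    ``neutral`` marks the all-ones initialisation (or degenerate) matrix
    under which folding reduces to the single-sequence partition function.
    """

    values: np.ndarray
    neutral: bool = False

    @staticmethod
    def neutral_for(n: int) -> "ExtrinsicMatrix":
        return ExtrinsicMatrix(values=np.ones((n, n)), neutral=True)


def induced_proclivity(
    bpp_s: PairProbabilityMatrix,
    cm: CoincidenceMatrix,
    cs: ConstraintSets | None = None,
    target_id: str = "",
    source_id: str = "",
) -> ProclivityMatrix:
    """Proclivities induced on the target by one source homolog.

    ``cm`` (and ``cs``) must be oriented target x source, i.e. entry (i, k)
    relates target position i to source position k.  When constraint sets
    are given, source indices with co-incidence below the significance
    threshold are excluded; with ``tau = 0`` the result equals the full
    double sum.
    """
    c = cm.probs
    n_m, n_s = c.shape
    if bpp_s.n != n_s:
        raise ValueError(
            f"source pairing matrix is {bpp_s.n}x{bpp_s.n}, but co-incidence "
            f"matrix has {n_s} source columns"
        )
    if cs is not None:
        if cs.mask.shape != c.shape:
            raise ValueError("constraint-set mask shape mismatch")
        c = np.where(cs.mask, c, 0.0)
    # values(i, j) = sum_{k < l} c(i, k) * p_s(k, l) * c(j, l); orientation
    # is preserved (i maps to k, j maps to l) because alignment paths are
    # monotone.  Two matrix products give the full double sum.
    vals = c @ np.triu(bpp_s.probs, 1) @ c.T
    vals = np.triu(vals, 1)
    return ProclivityMatrix(values=vals, target_id=target_id, source_id=source_id)


def aggregate_extrinsic(
    proclivities: dict, identities: dict
) -> ExtrinsicMatrix:
    """Identity-weighted sum of proclivity matrices, max-normalised to 1.

    Parameters
    ----------
    proclivities
        Map source id -> :class:`ProclivityMatrix` for every other homolog.
    identities
        Map source id -> pairwise sequence identity ``psi`` with the target.
    """
    if not proclivities:
        raise ValueError(
            "no proclivity matrices given; use the neutral initialisation "
            "for a single-sequence run"
        )
    raw = None
    for sid in sorted(proclivities):  # fixed order for reproducibility
        pm = proclivities[sid]
        weight = 1.0 - identities[sid]
        term = weight * pm.values
        raw = term if raw is None else raw + term
    mx = raw.max()
    if mx <= 0.0:
        return ExtrinsicMatrix.neutral_for(raw.shape[0])
    return ExtrinsicMatrix(values=raw / mx, neutral=False)
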