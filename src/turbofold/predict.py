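"""Structure prediction from base-pairing probability matrices.

Two predictors are provided: *thresholding*, which keeps every pair whose
probability strictly exceeds ``P_thresh`` (any threshold above 0.5
guarantees a valid, pseudoknot-free structure; lower thresholds may yield
crossing or conflicting pairs and are only index-checked), and *maximum
expected accuracy* (MEA), which maximises

    score(S) = sum_{(i,j) in S} w * p(i, j) + sum_{i unpaired} q(i)

over pseudoknot-free structures by Nussinov-style dynamic programming.  The
default pair weight ``w = 2`` counts both nucleotides of a pair, the common
convention.  An exhaustive-enumeration MEA oracle is included for testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SecondaryStructure
from .partition import PairProbabilityMatrix, unpaired_probabilities

__all__ = [
    "ThresholdedStructure",
    "threshold_structure",
    "mea_structure",
    "brute_force_mea",
]

DEFAULT_PAIR_WEIGHT = 2.0
MAX_BRUTE_FORCE_N = 16


@dataclass(frozen=True)
class ThresholdedStructure:
    """Pair set obtained by probability thresholding.

    ``validity_class`` is ``"guaranteed_valid"`` for thresholds above 0.5
    and ``"unchecked"`` otherwise (pseudoknots or multi-pairing possible).
    """

    pairs: frozenset
    sequence_length: int
    p_thresh: float

    @property
    def validity_class(self) -> str:
        return "guaranteed_valid" if self.p_thresh > 0.5 else "unchecked"

    def as_structure(self) -> SecondaryStructure:
        return SecondaryStructure(self.pairs, self.sequence_length)


def threshold_structure(
    matrix: PairProbabilityMatrix, p_thresh: float
) -> ThresholdedStructure:
    """Pairs with probability strictly greater than ``p_thresh``."""
    if not (0.0 < p_thresh <= 1.0):
        raise ValueError("P_thresh must be in (0, 1]")
    idx = np.argwhere(np.triu(matrix.probs, 1) > p_thresh)
    pairs = frozenset((int(i) + 1, int(j) + 1) for i, j in idx)
    return ThresholdedStructure(
        pairs=pairs, sequence_length=matrix.n, p_thresh=p_thresh
    )


def _mea_tables(probs: np.ndarray, q: np.ndarray, w: float):
    """Fill the MEA DP table.

    W[i, j] = best score on subsequence [i, j] (0-based, inclusive);
    decomposed at position i: unpaired, or paired with some k.
    """
    n = len(q)
    best = np.zeros((n, n))
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1  # inclusive
            # option 1: i unpaired
            sc = q[i] + (best[i + 1, j] if i + 1 <= j else 0.0)
            best[i, j] = sc
            # option 2: i paired with k
            for k in range(i + 1, j + 1):
                inner = best[i + 1, k - 1] if i + 1 <= k - 1 else 0.0
                outer = best[k + 1, j] if k + 1 <= j else 0.0
                cand = w * probs[i, k] + inner + outer
                if cand > best[i, j]:
                    best[i, j] = cand
    return best


def mea_structure(
    matrix: PairProbabilityMatrix,
    q: np.ndarray | None = None,
    pair_weight: float = DEFAULT_PAIR_WEIGHT,
) -> SecondaryStructure:
    """Maximum expected accuracy structure.

    Ties are broken deterministically: prefer leaving a position unpaired,
    then prefer the pairing partner closest to it.
    """
    if pair_weight <= 0:
        raise ValueError("pair_weight must be positive")
    probs = matrix.probs
    n = matrix.n
    if q is None:
        q = unpaired_probabilities(matrix)
    q = np.asarray(q, dtype=float)
    if q.shape != (n,):
        raise ValueError("q length mismatch")
    best = _mea_tables(probs, q, pair_weight)

    pairs: set = set()

    def traceback(i: int, j: int) -> None:
        while i <= j:
            target = best[i, j]
            unpaired = q[i] + (best[i + 1, j] if i + 1 <= j else 0.0)
            if unpaired >= target - 1e-12:  # prefer unpaired on ties
                i += 1
                continue
            chosen = None
            for k in range(i + 1, j + 1):  # ascending span: closest k first
                inner = best[i + 1, k - 1] if i + 1 <= k - 1 else 0.0
                outer = best[k + 1, j] if k + 1 <= j else 0.0
                if pair_weight * probs[i, k] + inner + outer >= target - 1e-12:
                    chosen = k
                    break
            assert chosen is not None, "MEA traceback failed"
            pairs.add((i + 1, chosen + 1))
            if i + 1 <= chosen - 1:
                traceback(i + 1, chosen - 1)
            i = chosen + 1

    if n > 0:
        traceback(0, n - 1)
    return SecondaryStructure(frozenset(pairs), n)


def mea_score(
    structure: SecondaryStructure,
    matrix: PairProbabilityMatrix,
    q: np.ndarray,
    pair_weight: float = DEFAULT_PAIR_WEIGHT,
) -> float:
    """Expected-accuracy objective of a given structure (recomputed directly)."""
    paired = set()
    score = 0.0
    for i, j in structure.pairs:
        score += pair_weight * matrix.probs[i - 1, j - 1]
        paired.update((i, j))
    for i in range(1, structure.sequence_length + 1):
        if i not in paired:
            score += q[i - 1]
    return score


def brute_force_mea(
    matrix: PairProbabilityMatrix,
    q: np.ndarray | None = None,
    pair_weight: float = DEFAULT_PAIR_WEIGHT,
):
    """Exhaustive maximisation of the MEA objective (guarded to N <= 16).

    Returns ``(score, structure)``; the structure space is all
    pseudoknot-free pair sets over the sequence.
    """
    n = matrix.n
    if n > MAX_BRUTE_FORCE_N:
        raise ValueError(f"brute-force MEA limited to N <= {MAX_BRUTE_FORCE_N}")
    if q is None:
        q = unpaired_probabilities(matrix)
    q = np.asarray(q, dtype=float)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple:
        if i > j:
            return (frozenset(),)
        out = [s for s in region(i + 1, j)]
        for k in range(i + 1, j + 1):
            for left in region(i + 1, k - 1):
                for right in region(k + 1, j):
                    out.append(left | right | {(i, k)})
        return tuple(out)

    best_score, best_pairs = -np.inf, frozenset()
    for pairs0 in region(0, n - 1):
        paired = {p for ij in pairs0 for p in ij}
        sc = sum(pair_weight * matrix.probs[i, j] for i, j in pairs0)
        sc += sum(q[i] for i in range(n) if i not in paired)
        if sc > best_score:
            best_score, best_pairs = sc, pairs0
    structure = SecondaryStructure(
        frozenset((i + 1, j + 1) for i, j in best_pairs), n
    )
    return best_score, structure
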