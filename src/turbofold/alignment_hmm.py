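"""Pairwise alignment hidden Markov model and co-incidence probabilities.

A three-state pair HMM (ALN, INS1, INS2) with affine-gap semantics aligns
two RNA sequences.  The posterior probability that the alignment path visits
lattice cell ``(i, k)`` in any of the three states is the *co-incidence*
probability of position ``i`` in the first sequence with position ``k`` in
the second: the event that the two positions are aligned or that one lies in
an insertion anchored at the other's position.  The maximum-likelihood
(Viterbi) path additionally yields the pairwise sequence identity ``psi``,
the fraction of path columns that align identical nucleotides.

Forward/backward is computed in linear space with per-row scaling, so
sequence pairs of several hundred nucleotides do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .energy_model import NT_INDEX
from .io_formats import RnaSequence

__all__ = [
    "AlignmentModelParams",
    "CoincidenceMatrix",
    "ConstraintSets",
    "load_hmm_params",
    "forward_backward",
    "coincidence",
    "viterbi",
    "sequence_identity",
    "constraint_sets",
]

ALN, INS1, INS2 = 0, 1, 2
_STATE_NAMES = ("ALN", "INS1", "INS2")
#: default co-incidence significance threshold for constraint sets
DEFAULT_COINCIDENCE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class AlignmentModelParams:
    """Validated pair-HMM parameters.

    ``transition`` is a 3x3 row-stochastic matrix over (ALN, INS1, INS2);
    ``match_emission`` a 4x4 joint probability table over nucleotide pairs;
    ``insert_emission`` a length-4 probability vector.  The silent begin
    state enters the three states with the stationary distribution of the
    transition matrix.
    """

    transition: np.ndarray
    match_emission: np.ndarray
    insert_emission: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, dtype=float)
        M = np.asarray(self.match_emission, dtype=float)
        e = np.asarray(self.insert_emission, dtype=float)
        if T.shape != (3, 3) or M.shape != (4, 4) or e.shape != (4,):
            raise ValueError("HMM parameter blocks have wrong shapes")
        if np.any(T <= 0) or np.any(M <= 0) or np.any(e <= 0):
            raise ValueError("all HMM probabilities must be strictly positive")
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition rows must sum to 1")
        if abs(M.sum() - 1.0) > 1e-12 or abs(e.sum() - 1.0) > 1e-12:
            raise ValueError("emission tables must sum to 1")
        object.__setattr__(self, "transition", T)
        object.__setattr__(self, "match_emission", M)
        object.__setattr__(self, "insert_emission", e)

    @property
    def start(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        vals, vecs = np.linalg.eig(self.transition.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


def load_hmm_params(path: str | Path | None = None) -> AlignmentModelParams:
    """Load pair-HMM parameters from YAML; ``None`` loads shipped defaults."""
    if path is None:
        text = resources.files("turbofold.data").joinpath("hmm_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    T = np.array([raw["transition"][s] for s in _STATE_NAMES], dtype=float)
    return AlignmentModelParams(
        transition=T,
        match_emission=np.array(raw["match_emission"], dtype=float),
        insert_emission=np.array(raw["insert_emission"], dtype=float),
    )


_DEFAULT: AlignmentModelParams | None = None


def default_hmm_params() -> AlignmentModelParams:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_hmm_params()
    return _DEFAULT


@dataclass
class CoincidenceMatrix:
    """Posterior co-incidence probabilities between two sequences.

    ``probs[i-1, k-1]`` is the posterior probability that the alignment path
    visits lattice cell ``(i, k)`` in any state; ``identity`` is the
    Viterbi-path sequence identity ``psi``.
    """

    probs: np.ndarray
    identity: float

    @property
    def shape(self) -> tuple:
        return self.probs.shape

    def transpose(self) -> "CoincidenceMatrix":
        return CoincidenceMatrix(probs=self.probs.T.copy(), identity=self.identity)


@dataclass
class ConstraintSets:
    """Per-position sets of plausibly co-incident partner indices.

    ``mask[i-1, k-1]`` is True iff the co-incidence probability exceeds the
    significance threshold ``tau``; ``d`` is the average set size.
    """

    mask: np.ndarray
    tau: float

    @property
    def d(self) -> float:
        return float(self.mask.sum(axis=1).mean())

    def partners(self, i: int) -> np.ndarray:
        """1-based partner indices retained for 1-based position ``i``."""
        return np.nonzero(self.mask[i - 1])[0] + 1


def _codes(seq: RnaSequence) -> np.ndarray:
    return np.array([NT_INDEX[c] for c in seq.residues], dtype=int)


def forward_backward(
    x_m: RnaSequence, x_s: RnaSequence, params: AlignmentModelParams | None = None
):
    """Per-cell, per-state alignment posteriors.

    Returns ``(posterior, log_total)`` where ``posterior[s, i, k]`` is the
    probability that a complete path emits residue ``i`` of ``x_m`` and/or
    residue ``k`` of ``x_s`` at cell ``(i, k)`` in state ``s`` (1-based
    sequence indices; index 0 rows/columns are the pre-emission boundary),
    and ``log_total`` is the log of the forward terminal value.
    """
    params = params or default_hmm_params()
    if x_m.length == 0 or x_s.length == 0:
        raise ValueError("both sequences must be non-empty")
    a, b = _codes(x_m), _codes(x_s)
    n, m = len(a), len(b)
    T = params.transition
    M = params.match_emission
    e = params.insert_emission
    pi = params.start

    F, logf = _forward(a, b, T, M, e, pi)
    logZ = logf[n] + math.log(F[ALN, n, m] + F[INS1, n, m] + F[INS2, n, m])
    B, logb = _backward(a, b, T, M, e)
    # posterior[s, i, k] = F * B / Z with per-row scale logs reinstated
    post = np.zeros((3, n + 1, m + 1))
    for i in range(n + 1):
        scale = logf[i] + logb[i] - logZ
        with np.errstate(divide="ignore"):
            lp = np.log(F[:, i, :] * B[:, i, :])
        post[:, i, :] = np.exp(lp + scale)
    np.clip(post, 0.0, 1.0, out=post)
    return post, logZ


def _forward(a, b, T, M, e, pi):
    n, m = len(a), len(b)
    F = np.zeros((3, n + 1, m + 1))
    logf = np.zeros(n + 1)  # cumulative log-scale applied to row i
    # row 0: only INS2 runs along k
    for k in range(1, m + 1):
        prev = pi[INS2] if k == 1 else T[INS2, INS2] * F[INS2, 0, k - 1]
        F[INS2, 0, k] = e[b[k - 1]] * prev
    for i in range(1, n + 1):
        Fa, F1, F2 = F[ALN], F[INS1], F[INS2]
        for k in range(0, m + 1):
            if k == 0:
                src = pi[INS1] if i == 1 else (
                    T[ALN, INS1] * Fa[i - 1, 0]
                    + T[INS1, INS1] * F1[i - 1, 0]
                    + T[INS2, INS1] * F2[i - 1, 0]
                )
                F1[i, 0] = e[a[i - 1]] * src
                continue
            # ALN from (i-1, k-1)
            if i == 1 and k == 1:
                src = pi[ALN]
            else:
                src = (
                    T[ALN, ALN] * Fa[i - 1, k - 1]
                    + T[INS1, ALN] * F1[i - 1, k - 1]
                    + T[INS2, ALN] * F2[i - 1, k - 1]
                )
            F[ALN, i, k] = M[a[i - 1], b[k - 1]] * src
            # INS1 from (i-1, k)
            src = (
                T[ALN, INS1] * Fa[i - 1, k]
                + T[INS1, INS1] * F1[i - 1, k]
                + T[INS2, INS1] * F2[i - 1, k]
            )
            F[INS1, i, k] = e[a[i - 1]] * src
            # INS2 from (i, k-1), same row
            src = (
                T[ALN, INS2] * Fa[i, k - 1]
                + T[INS1, INS2] * F1[i, k - 1]
                + T[INS2, INS2] * F2[i, k - 1]
            )
            F[INS2, i, k] = e[b[k - 1]] * src
        mx = F[:, i, :].max()
        if mx > 0:
            F[:, i, :] /= mx
            logf[i] = logf[i - 1] + math.log(mx)
        else:
            logf[i] = logf[i - 1]
    return F, logf


def _backward(a, b, T, M, e):
    n, m = len(a), len(b)
    B = np.zeros((3, n + 1, m + 1))
    logb = np.zeros(n + 1)
    B[:, n, m] = 1.0
    for i in range(n, -1, -1):
        for k in range(m, -1, -1):
            if i == n and k == m:
                continue
            acc = np.zeros(3)
            if i < n and k < m:
                acc += T[:, ALN] * M[a[i], b[k]] * B[ALN, i + 1, k + 1]
            if i < n:
                acc += T[:, INS1] * e[a[i]] * B[INS1, i + 1, k]
            if k < m:
                acc += T[:, INS2] * e[b[k]] * B[INS2, i, k + 1]
            B[:, i, k] = acc
        # rescale row i; rows below are already scaled by logb[i+1]
        if i < n:
            mx = B[:, i, :].max()
            if mx > 0:
                B[:, i, :] /= mx
                logb[i] = logb[i + 1] + math.log(mx)
            else:
                logb[i] = logb[i + 1]
    return B, logb


def coincidence(
    x_m: RnaSequence, x_s: RnaSequence, params: AlignmentModelParams | None = None
) -> CoincidenceMatrix:
    """Posterior co-incidence matrix plus Viterbi sequence identity.

    Co-incidence is symmetric, so the pair is evaluated in a canonical
    orientation and transposed if needed; this makes
    ``coincidence(m, s).probs == coincidence(s, m).probs.T`` hold exactly,
    including Viterbi tie-breaking for ``psi``.
    """
    params = params or default_hmm_params()
    if (x_s.residues, x_s.id) < (x_m.residues, x_m.id):
        return coincidence(x_s, x_m, params).transpose()
    post, _ = forward_backward(x_m, x_s, params)
    probs = np.clip(post.sum(axis=0)[1:, 1:], 0.0, 1.0)
    path = viterbi(x_m, x_s, params)
    psi = sequence_identity(path, x_m, x_s)
    return CoincidenceMatrix(probs=probs, identity=psi)


def viterbi(
    x_m: RnaSequence, x_s: RnaSequence, params: AlignmentModelParams | None = None
) -> list:
    """Maximum-likelihood alignment path as ``[(state_name, i, k), ...]``.

    Ties are broken deterministically preferring ALN, then INS1, then INS2.
    """
    params = params or default_hmm_params()
    if x_m.length == 0 or x_s.length == 0:
        raise ValueError("both sequences must be non-empty")
    a, b = _codes(x_m), _codes(x_s)
    n, m = len(a), len(b)
    lT = np.log(params.transition)
    lM = np.log(params.match_emission)
    le = np.log(params.insert_emission)
    lpi = np.log(params.start)
    NEG = -math.inf
    V = np.full((3, n + 1, m + 1), NEG)
    ptr = np.full((3, n + 1, m + 1), -1, dtype=int)

    def best_into(state, i, k):
        """(score, argmax prev state) with ALN < INS1 < INS2 tie order."""
        if i == 0 and k == 0:
            return lpi[state], -1
        cand = V[:, i, k] + lT[:, state]
        s = int(np.argmax(cand))  # argmax returns lowest index on ties
        return float(cand[s]), s

    for i in range(0, n + 1):
        for k in range(0, m + 1):
            if i > 0 and k > 0:
                sc, s = best_into(ALN, i - 1, k - 1)
                V[ALN, i, k] = lM[a[i - 1], b[k - 1]] + sc
                ptr[ALN, i, k] = s
            if i > 0:
                sc, s = best_into(INS1, i - 1, k)
                V[INS1, i, k] = le[a[i - 1]] + sc
                ptr[INS1, i, k] = s
            if k > 0:
                sc, s = best_into(INS2, i, k - 1)
                V[INS2, i, k] = le[b[k - 1]] + sc
                ptr[INS2, i, k] = s
    state = int(np.argmax(V[:, n, m]))
    path = []
    i, k = n, m
    while i > 0 or k > 0:
        path.append((_STATE_NAMES[state], i, k))
        prev = ptr[state, i, k]
        if state == ALN:
            i, k = i - 1, k - 1
        elif state == INS1:
            i -= 1
        else:
            k -= 1
        state = prev
        if state < 0:
            break
    path.reverse()
    return path


def viterbi_score(
    x_m: RnaSequence, x_s: RnaSequence, params: AlignmentModelParams | None = None
) -> float:
    """Log-probability of the maximum-likelihood alignment path."""
    params = params or default_hmm_params()
    path = viterbi(x_m, x_s, params)
    a, b = _codes(x_m), _codes(x_s)
    lT = np.log(params.transition)
    lM = np.log(params.match_emission)
    le = np.log(params.insert_emission)
    lpi = np.log(params.start)
    score = 0.0
    prev = None
    for name, i, k in path:
        s = _STATE_NAMES.index(name)
        score += lpi[s] if prev is None else lT[prev, s]
        if s == ALN:
            score += lM[a[i - 1], b[k - 1]]
        elif s == INS1:
            score += le[a[i - 1]]
        else:
            score += le[b[k - 1]]
        prev = s
    return score


def sequence_identity(path: list, x_m: RnaSequence, x_s: RnaSequence) -> float:
    """Fraction of Viterbi path columns aligning identical nucleotides.

    The denominator counts all path columns (ALN, INS1 and INS2 alike).
    """
    if not path:
        raise ValueError("empty alignment path")
    matches = sum(
        1
        for name, i, k in path
        if name == "ALN" and x_m.residues[i - 1] == x_s.residues[k - 1]
    )
    return matches / len(path)


def constraint_sets(cm: CoincidenceMatrix, tau: float = DEFAULT_COINCIDENCE_THRESHOLD) -> ConstraintSets:
    """Retain exactly the lattice cells with co-incidence probability > tau."""
    if not (0.0 <= tau < 1.0):
        raise ValueError("tau must satisfy 0 <= tau < 1")
    return ConstraintSets(mask=cm.probs > tau, tau=tau)
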