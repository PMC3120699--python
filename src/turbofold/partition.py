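"""Modified partition function over pseudoknot-free RNA structures.

Each structure ``S`` is weighted ``exp(-dG0(S)/RT) * prod_{(i,j) in S}
ext(i,j)^(gamma/RT)``: the nearest-neighbor Boltzmann weight times a
per-pair multiplicative prior derived from extrinsic information.
Equivalently the modified free energy is ``dG0(S) - gamma * sum ln ext(i,j)``.
Base-pairing probabilities are obtained with McCaskill-style inside/outside
dynamic programming in O(N^3) time; a brute-force enumeration oracle with
the identical contract is provided for small sequences.

Numerical notes
---------------
* Internal/bulge loops in the DP are limited to a combined unpaired length
  of 30 nucleotides (the standard cap); the loop tables extrapolate
  logarithmically beyond their tabulated range.
* Long sequences are handled by a per-nucleotide scale factor chosen
  adaptively (deterministically) so the partition function stays inside
  double range; the scale cancels exactly in every probability.
* Extrinsic entries are floored at ``ext_floor`` before exponentiation so a
  zero prior yields a negligibly probable, not forbidden, pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .energy_model import (
    CANONICAL,
    NT_INDEX,
    EnergyParams,
    default_energy_params,
    structure_free_energy,
)
from .io_formats import RnaSequence, SecondaryStructure

__all__ = [
    "PairProbabilityMatrix",
    "PartitionResult",
    "modified_partition",
    "brute_force_pair_probs",
    "unpaired_probabilities",
    "enumerate_structures",
]

#: floor applied to extrinsic entries before taking logarithms
EXT_FLOOR = 1e-12
#: maximum combined unpaired length of internal/bulge loops in the DP
MAX_INTERNAL_LOOP = 30
#: brute-force enumeration guard
MAX_BRUTE_FORCE_N = 20


@dataclass
class PairProbabilityMatrix:
    """Posterior base-pairing probabilities for one sequence.

    ``probs[i-1, j-1]`` (1-based ``i < j``) is the probability that ``i``
    pairs ``j``; only the upper triangle is populated.
    """

    probs: np.ndarray
    iteration: int = 0

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def get(self, i: int, j: int) -> float:
        """Probability that 1-based positions ``i`` and ``j`` pair."""
        if i == j:
            return 0.0
        i, j = min(i, j), max(i, j)
        return float(self.probs[i - 1, j - 1])

    def row_sums(self) -> np.ndarray:
        """Total pairing probability per position (both triangle halves)."""
        return self.probs.sum(axis=1) + self.probs.sum(axis=0)

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.probs < -tol) or np.any(self.probs > 1 + tol):
            raise ValueError("pair probabilities outside [0, 1]")
        if np.any(self.row_sums() > 1 + tol):
            raise ValueError("per-position pairing probability exceeds 1")


@dataclass
class PartitionResult:
    log_z: float
    matrix: PairProbabilityMatrix

    @property
    def z(self) -> float:
        """Modified partition function (may overflow to inf for long RNAs)."""
        try:
            return math.exp(self.log_z)
        except OverflowError:
            return math.inf


def unpaired_probabilities(matrix: PairProbabilityMatrix) -> np.ndarray:
    """``q(i) = 1 - sum_j p(i, j)``, clipped to [0, 1]."""
    return np.clip(1.0 - matrix.row_sums(), 0.0, 1.0)


def _neutral_ext(n: int) -> np.ndarray:
    return np.ones((n, n))


def _pair_weights(
    seq: str, ext: np.ndarray | None, gamma: float, params: EnergyParams
) -> np.ndarray:
    """Per-pair multiplicative weights: canonical mask * ext^(gamma/RT)."""
    n = len(seq)
    if ext is None:
        ext = _neutral_ext(n)
    ext = np.asarray(ext, dtype=float)
    if ext.shape != (n, n):
        raise ValueError(f"extrinsic matrix shape {ext.shape} != ({n}, {n})")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    codes = np.array([NT_INDEX[c] for c in seq])
    w = np.zeros((n, n))
    exponent = gamma / params.RT
    for i in range(n):
        for j in range(i + params.min_hairpin + 1, n):
            if (codes[i], codes[j]) in CANONICAL:
                w[i, j] = max(ext[i, j], EXT_FLOOR) ** exponent
    return w


class _Tables:
    """Precomputed Boltzmann factors for one (sequence, scale) combination."""

    def __init__(self, seq: str, wpair: np.ndarray, params: EnergyParams, log_sigma: float):
        n = len(seq)
        self.n = n
        self.params = params
        self.sigma = math.exp(log_sigma)
        self.log_sigma = log_sigma
        RT = params.RT
        codes = [NT_INDEX[c] for c in seq]
        self.codes = codes
        # helix-end penalty factor per (i, j)
        self.au = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if (codes[i], codes[j]) in {(0, 3), (3, 0), (2, 3), (3, 2)}:
                    self.au[i, j] = math.exp(-params.terminal_AU / RT)
        # each paired nucleotide carries one sigma; fold sigma^2 into wpair
        self.wpair = wpair * self.sigma**2
        # hairpin weights by unpaired length (scaled)
        self.hp = np.zeros(n + 1)
        for L in range(params.min_hairpin, n + 1):
            self.hp[L] = math.exp(-params.hairpin_energy(L) / RT + L * log_sigma)
        # internal/bulge weights by (n1, n2) side lengths (scaled)
        m = MAX_INTERNAL_LOOP
        self.loop = np.zeros((m + 1, m + 1))
        for n1 in range(m + 1):
            for n2 in range(m + 1 - n1):
                if n1 == 0 and n2 == 0:
                    continue
                tot = n1 + n2
                e = params.bulge_energy(tot) if min(n1, n2) == 0 else params.internal_energy(tot)
                self.loop[n1, n2] = math.exp(-e / RT + tot * log_sigma)
        a, b, c = params.multibranch
        self.wa = math.exp(-a / RT)
        self.wb = math.exp(-b / RT)
        self.wc = math.exp(-c / RT + log_sigma)  # per multiloop-unpaired nt
        self.wcpow = self.wc ** np.arange(n + 1)
        # flipped copy of the loop table: column c of ``loop_flip[:, :w]``
        # holds side length n2 = w - 1 - c, aligning with ascending l
        self.loop_flip = self.loop[:, ::-1].copy()
        # stack factor lookup per (i, j, k=i+1, l=j-1)
        self.stack = np.zeros((n, n))
        for i in range(n - 1):
            for j in range(i + 2, n):
                outer = (codes[i], codes[j])
                inner = (codes[i + 1], codes[j - 1])
                if outer in CANONICAL and inner in CANONICAL:
                    self.stack[i, j] = math.exp(-params.stack_energy(outer, inner) / RT)


def _loop_window(i: int, j: int):
    """Index window of enclosed pairs (k, l) reachable through a bulge or
    internal loop from closing pair (i, j), under the combined-length cap."""
    k0, k1 = i + 1, min(i + MAX_INTERNAL_LOOP + 1, j - 2)
    l0, l1 = max(j - 1 - MAX_INTERNAL_LOOP, i + 2), j - 1
    return k0, k1, l0, l1


def _inside(t: _Tables):
    n = t.n
    Zb = np.zeros((n, n))
    ZbAu = np.zeros((n, n))  # Zb * helix-end factor, the "branch" weight
    ZM1 = np.zeros((n, n))
    ZM = np.zeros((n, n))
    minh = t.params.min_hairpin
    for span in range(minh + 1, n):
        for i in range(0, n - span):
            j = i + span
            if t.wpair[i, j] > 0.0:
                total = t.hp[j - i - 1] * t.au[i, j]
                # stack on (i+1, j-1)
                if Zb[i + 1, j - 1] > 0.0:
                    total += t.stack[i, j] * Zb[i + 1, j - 1]
                # bulge/internal loops up to the combined-length cap
                k0, k1, l0, l1 = _loop_window(i, j)
                if k1 >= k0 and l1 >= l0:
                    w = t.loop_flip[
                        : k1 - k0 + 1, MAX_INTERNAL_LOOP - (l1 - l0) : MAX_INTERNAL_LOOP + 1
                    ]
                    total += t.au[i, j] * float(
                        np.sum(ZbAu[k0 : k1 + 1, l0 : l1 + 1] * w)
                    )
                # multibranch closing: >= 2 interior branches
                if span >= 2 * minh + 4:
                    ks = np.arange(i + 2, j - 1)
                    ml = float(np.dot(ZM[i + 1, ks - 1], ZM1[ks, j - 1]))
                    total += t.wa * t.wb * t.au[i, j] * ml
                Zb[i, j] = t.wpair[i, j] * total
                ZbAu[i, j] = Zb[i, j] * t.au[i, j]
            # one branch starting exactly at i, trailing unpaired to j
            ZM1[i, j] = t.wc * ZM1[i, j - 1] + t.wb * ZbAu[i, j]
            # >= 1 branch on [i, j], decomposed at the start of the last branch
            ks = np.arange(i, j + 1)
            lead = t.wcpow[ks - i]
            prev = np.concatenate(([0.0], ZM[i, i:j]))
            ZM[i, j] = float(np.dot(lead + prev, ZM1[ks, j]))
    # exterior loop
    Zf = np.zeros(n + 1)
    Zf[0] = 1.0
    for j in range(n):
        Zf[j + 1] = Zf[j] * t.sigma + float(np.dot(Zf[:j], ZbAu[:j, j]))
    Zr = np.zeros(n + 1)
    Zr[n] = 1.0
    for i in range(n - 1, -1, -1):
        Zr[i] = Zr[i + 1] * t.sigma + float(np.dot(ZbAu[i, i + 1 :], Zr[i + 2 :]))
    return Zb, ZbAu, ZM1, ZM, Zf, Zr


def _outside(t: _Tables, Zb, ZbAu, ZM1, ZM, Zf, Zr):
    """Reverse sweep computing OB = dZ/dZb; P = Zb * OB / Z."""
    n = t.n
    OB = np.zeros((n, n))
    OM = np.zeros((n, n))
    OM1 = np.zeros((n, n))
    minh = t.params.min_hairpin
    for span in range(n - 1, minh, -1):
        for i in range(0, n - span):
            j = i + span
            # --- ZM[i, j] children ---
            om = OM[i, j]
            if om != 0.0:
                ks = np.arange(i, j + 1)
                lead = t.wcpow[ks - i]
                prev = np.concatenate(([0.0], ZM[i, i:j]))
                OM1[ks, j] += om * (lead + prev)
                OM[i, i:j] += om * ZM1[i + 1 : j + 1, j]
            # --- ZM1[i, j] children ---
            om1 = OM1[i, j]
            if om1 != 0.0:
                OM1[i, j - 1] += om1 * t.wc
                OB[i, j] += om1 * t.wb * t.au[i, j]
            # --- Zb[i, j]: exterior context, then its children ---
            OB[i, j] += Zf[i] * t.au[i, j] * Zr[j + 1]
            ob = OB[i, j] * t.wpair[i, j]
            if ob == 0.0:
                continue
            if t.stack[i, j] > 0.0:
                OB[i + 1, j - 1] += ob * t.stack[i, j]
            k0, k1, l0, l1 = _loop_window(i, j)
            if k1 >= k0 and l1 >= l0:
                w = t.loop_flip[
                    : k1 - k0 + 1, MAX_INTERNAL_LOOP - (l1 - l0) : MAX_INTERNAL_LOOP + 1
                ]
                OB[k0 : k1 + 1, l0 : l1 + 1] += (
                    ob * t.au[i, j] * w * t.au[k0 : k1 + 1, l0 : l1 + 1]
                )
            if span >= 2 * minh + 4:
                ks = np.arange(i + 2, j - 1)
                f = ob * t.wa * t.wb * t.au[i, j]
                OM[i + 1, ks - 1] += f * ZM1[ks, j - 1]
                OM1[ks, j - 1] += f * ZM[i + 1, ks - 1]
    return OB


def modified_partition(
    seq: RnaSequence,
    ext: np.ndarray | None = None,
    gamma: float | None = None,
    params: EnergyParams | None = None,
    iteration: int = 0,
) -> PartitionResult:
    """Partition function and pairing probabilities under extrinsic priors.

    Parameters
    ----------
    seq
        The RNA sequence to fold.
    ext
        N x N extrinsic matrix with entries in [0, 1] (upper triangle used);
        ``None`` means the neutral all-ones prior.
    gamma
        Extrinsic weight in kcal/mol; default ``0.3 * RT``.
    """
    params = params or default_energy_params()
    if gamma is None:
        gamma = 0.3 * params.RT
    wpair = _pair_weights(seq.residues, ext, gamma, params)
    n = seq.length
    # deterministic adaptive scaling: start neutral for short sequences
    log_sigma = 0.0 if n <= 300 else -0.8
    for _attempt in range(8):
        t = _Tables(seq.residues, wpair, params, log_sigma)
        Zb, ZbAu, ZM1, ZM, Zf, Zr = _inside(t)
        z_scaled = Zf[n]
        if not np.isfinite(z_scaled) or not np.all(np.isfinite(Zb)):
            log_sigma -= 0.6
            continue
        if z_scaled <= 0.0:
            log_sigma += 0.6
            continue
        OB = _outside(t, Zb, ZbAu, ZM1, ZM, Zf, Zr)
        if not np.all(np.isfinite(OB)):
            log_sigma -= 0.6
            continue
        probs = Zb * OB / z_scaled
        np.clip(probs, 0.0, 1.0, out=probs)
        matrix = PairProbabilityMatrix(probs=probs, iteration=iteration)
        return PartitionResult(log_z=math.log(z_scaled) - n * log_sigma, matrix=matrix)
    raise FloatingPointError("partition function scaling failed to converge")


# ---------------------------------------------------------------------------
# Brute-force oracle


def enumerate_structures(
    seq: RnaSequence, params: EnergyParams | None = None
) -> list[SecondaryStructure]:
    """All pseudoknot-free sets of canonical pairs respecting min_hairpin."""
    params = params or default_energy_params()
    n = seq.length
    if n > MAX_BRUTE_FORCE_N:
        raise ValueError(f"enumeration limited to N <= {MAX_BRUTE_FORCE_N}")
    codes = [NT_INDEX[c] for c in seq.residues]
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple:
        """All pair sets (as frozensets of 1-based tuples) on [i, j]."""
        if j - i < params.min_hairpin + 1:
            return (frozenset(),)
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + params.min_hairpin + 1, j + 1):
            if (codes[i], codes[k]) in CANONICAL:
                for left in region(i + 1, k - 1):
                    for right in region(k + 1, j):
                        out.append(left | right | {(i + 1, k + 1)})
        return tuple(out)

    return [SecondaryStructure(p, n) for p in region(0, n - 1)]


def brute_force_pair_probs(
    seq: RnaSequence,
    ext: np.ndarray | None = None,
    gamma: float | None = None,
    params: EnergyParams | None = None,
) -> PartitionResult:
    """Exhaustive-enumeration oracle with the same contract as
    :func:`modified_partition` (guarded to N <= 20)."""
    params = params or default_energy_params()
    if gamma is None:
        gamma = 0.3 * params.RT
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    n = seq.length
    if ext is None:
        ext = _neutral_ext(n)
    ext = np.asarray(ext, dtype=float)
    if ext.shape != (n, n):
        raise ValueError("ill-shaped extrinsic matrix")
    exponent = gamma / params.RT
    z = 0.0
    mass = np.zeros((n, n))
    for s in enumerate_structures(seq, params):
        w = math.exp(-structure_free_energy(seq, s, params) / params.RT)
        for i, j in s.pairs:
            w *= max(ext[i - 1, j - 1], EXT_FLOOR) ** exponent
        z += w
        for i, j in s.pairs:
            mass[i - 1, j - 1] += w
    probs = mass / z
    return PartitionResult(
        log_z=math.log(z), matrix=PairProbabilityMatrix(probs=probs, iteration=0)
    )
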