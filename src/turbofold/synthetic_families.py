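"""Seeded generator of homologous RNA families with conserved structure.

Family members are derived from a template sequence carrying a consensus
secondary structure.  Divergence is introduced by point mutations at
unpaired (loop) positions, compensatory double mutations at paired
positions (each mutated pair is replaced by a uniformly drawn canonical
pair, so pairability is preserved in every member), and insertions or
deletions restricted to loops so that each member's true structure remains
well defined after remapping through the indels.  Optionally a designated
helix (a "variable arm") is lost by some members, emulating the variable
structural elements common in conserved ncRNA families.  Generation is
fully deterministic given the seed.

Mutation rates are calibrated to a target mean pairwise identity with a
closed-form approximation of the identity between two independently
mutated copies of the template (see ``mutation_rate_for_identity``); the
realised identity is a statistical target, not an exact one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .energy_model import CANONICAL, NT_INDEX, NT_LETTER, default_energy_params
from .io_formats import RnaSequence, SecondaryStructure

__all__ = ["FamilySpec", "generate_family", "default_family_spec", "mutation_rate_for_identity"]

CANONICAL_PAIRS = ["AU", "UA", "GC", "CG", "GU", "UG"]


@dataclass(frozen=True)
class FamilySpec:
    """Specification of a synthetic homologous family."""

    template: RnaSequence
    consensus: SecondaryStructure
    k: int = 5
    target_identity: float = 0.5
    indel_rate: float = 0.02
    variable_arm_prob: float = 0.0
    variable_arm: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("family size must be >= 1")
        if not (0.0 < self.target_identity < 1.0):
            raise ValueError("target_identity must be in (0, 1)")
        if not (0.0 <= self.indel_rate < 0.5):
            raise ValueError("indel_rate out of range")
        if self.consensus.sequence_length != self.template.length:
            raise ValueError("consensus structure does not fit template")
        params = default_energy_params()
        for i, j in self.consensus.pairs:
            a = self.template.residues[i - 1]
            b = self.template.residues[j - 1]
            if (NT_INDEX[a], NT_INDEX[b]) not in CANONICAL:
                raise ValueError(f"template pair ({i}, {j}) = {a}-{b} not canonical")
        paired = {p for ij in self.consensus.pairs for p in ij}
        for i, j in self.consensus.pairs:
            is_hairpin = not any(p in paired for p in range(i + 1, j))
            if is_hairpin and j - i - 1 < params.min_hairpin:
                raise ValueError(f"template hairpin at ({i}, {j}) too short")
        if not self.consensus.is_valid():
            raise ValueError("consensus structure invalid")
        if self.variable_arm and not self.variable_arm <= self.consensus.pairs:
            raise ValueError("variable arm must be a subset of consensus pairs")


def mutation_rate_for_identity(
    target: float, frac_paired: float, left_nt_freq: np.ndarray | None = None
) -> float:
    """Per-position mutation rate whose expected pairwise identity is ``target``.

    Two members are independent mutants of the template.  At an unpaired
    position a mutant substitutes one of the three other nucleotides
    uniformly; two mutants match with probability ``(1-r)^2 + r^2/3``.  At
    a paired position the whole pair is resampled uniformly from the six
    canonical pairs with probability ``r``; the chance that a resampled
    left (right) nucleotide matches the original or another resample is
    governed by how often each nucleotide occurs at that pair end (1/6 for
    A and C, 2/6 for G and U, averaged here as ``s1 = 1/4`` against the
    template and ``s2 = 10/36`` between two resamples).
    """
    s1, s2 = 0.25, 10.0 / 36.0

    def identity(r: float) -> float:
        m_unpaired = (1 - r) ** 2 + (r**2) / 3.0
        m_paired = (1 - r) ** 2 + 2 * r * (1 - r) * s1 + (r**2) * s2
        return (1 - frac_paired) * m_unpaired + frac_paired * m_paired

    if not identity(0.999) < target < identity(0.0):
        raise ValueError(f"target identity {target} out of achievable range")
    return float(brentq(lambda r: identity(r) - target, 0.0, 0.999, xtol=1e-10))


def _mutate_member(
    template: str,
    pairs: list,
    rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple:
    """One mutated member: returns (residues, remapped pair list)."""
    n = len(template)
    residues = list(template)
    paired_pos = {p for ij in pairs for p in ij}
    # compensatory pair replacement
    for i, j in pairs:
        if rng.random() < rate:
            new = CANONICAL_PAIRS[rng.integers(len(CANONICAL_PAIRS))]
            residues[i - 1], residues[j - 1] = new[0], new[1]
    # point mutations at unpaired positions
    for pos in range(1, n + 1):
        if pos not in paired_pos and rng.random() < rate:
            current = residues[pos - 1]
            choices = [c for c in NT_LETTER if c != current]
            residues[pos - 1] = choices[rng.integers(3)]
    # hairpin-loop membership, so deletions never shrink a loop below the
    # minimum hairpin size
    min_hairpin = default_energy_params().min_hairpin
    loop_of = {}
    loop_size = {}
    for i, j in pairs:
        if not any(p in paired_pos for p in range(i + 1, j)):
            loop_size[(i, j)] = j - i - 1
            for p in range(i + 1, j):
                loop_of[p] = (i, j)
    # loop indels: per unpaired position, delete or insert a random base after
    out_res: list = []
    new_index = np.zeros(n + 2, dtype=int)
    for pos in range(1, n + 1):
        if pos in paired_pos:
            out_res.append(residues[pos - 1])
            new_index[pos] = len(out_res)
            continue
        roll = rng.random()
        deletable = loop_of.get(pos) is None or loop_size[loop_of[pos]] > min_hairpin
        if roll < indel_rate / 2.0 and deletable:
            new_index[pos] = 0  # deleted
            if pos in loop_of:
                loop_size[loop_of[pos]] -= 1
        elif indel_rate / 2.0 <= roll < indel_rate:
            out_res.append(residues[pos - 1])
            new_index[pos] = len(out_res)
            out_res.append(NT_LETTER[rng.integers(4)])
            if pos in loop_of:
                loop_size[loop_of[pos]] += 1
        else:
            out_res.append(residues[pos - 1])
            new_index[pos] = len(out_res)
    remapped = [(int(new_index[i]), int(new_index[j])) for i, j in pairs]
    return "".join(out_res), remapped


def generate_family(spec: FamilySpec) -> tuple:
    """Generate ``(sequences, structures)`` for one family.

    ``structures`` maps each sequence id to that member's true secondary
    structure (consensus pairs remapped through the member's indels, minus
    the variable arm where it was lost).
    """
    rng = np.random.default_rng(spec.seed)
    rate = mutation_rate_for_identity(
        spec.target_identity,
        frac_paired=2 * spec.consensus.n_pairs / spec.template.length,
    )
    ordered_pairs = sorted(spec.consensus.pairs)
    seqs: list = []
    structures: dict = {}
    for m in range(spec.k):
        keep_arm = (
            not spec.variable_arm or rng.random() >= spec.variable_arm_prob
        )
        member_pairs = [
            p for p in ordered_pairs if keep_arm or p not in spec.variable_arm
        ]
        res, remapped = _mutate_member(
            spec.template.residues, member_pairs, rate, spec.indel_rate, rng
        )
        sid = f"member_{m + 1}"
        seq = RnaSequence(sid, res)
        structure = SecondaryStructure(
            frozenset(p for p in remapped if p[0] > 0 and p[1] > 0), len(res)
        )
        seqs.append(seq)
        structures[sid] = structure
    return seqs, structures


def _helix(seq5: str, seq3: str, start5: int, start3: int) -> set:
    """Pairs of a helix given 5' arm start and 3' arm start (both 1-based),
    where seq3 is the reverse strand read 5'->3'."""
    pairs = set()
    L = len(seq5)
    for t in range(L):
        pairs.add((start5 + t, start3 + (L - 1 - t)))
    return pairs


def default_family_spec(
    k: int = 5,
    target_identity: float = 0.5,
    indel_rate: float = 0.02,
    variable_arm_prob: float = 0.0,
    seed: int = 0,
) -> FamilySpec:
    """Three-arm cloverleaf template of 76 nt, reminiscent of small
    structured ncRNAs, with the third arm designated as the variable arm."""
    # segments: closing stem P1 (8 bp), two-nt linkers, three hairpin arms
    p1_5 = "GGCAGGCC"  # 1-8
    link1 = "AU"  # 9-10
    p2_5, loop2, p2_3 = "GCGGC", "UUCGA", "GCCGC"  # 11-15, 16-20, 21-25
    link2 = "AA"  # 26-27
    p3_5, loop3, p3_3 = "GGCAG", "GAAAC", "CUGCC"  # 28-32, 33-37, 38-42
    link3 = "CA"  # 43-44
    p4_5, loop4, p4_3 = "GCGUG", "UCAAG", "CACGC"  # 45-49, 50-54, 55-59
    link4 = "AGU"  # 60-62
    p1_3 = "GGCCUGCC"  # 63-70
    tail = "ACCAUC"  # 71-76
    template = (
        p1_5 + link1 + p2_5 + loop2 + p2_3 + link2 + p3_5 + loop3 + p3_3
        + link3 + p4_5 + loop4 + p4_3 + link4 + p1_3 + tail
    )
    pairs: set = set()
    pairs |= _helix(p1_5, p1_3, 1, 63)
    pairs |= _helix(p2_5, p2_3, 11, 21)
    pairs |= _helix(p3_5, p3_3, 28, 38)
    arm4 = _helix(p4_5, p4_3, 45, 55)
    pairs |= arm4
    consensus = SecondaryStructure(frozenset(pairs), len(template))
    return FamilySpec(
        template=RnaSequence("template", template),
        consensus=consensus,
        k=k,
        target_identity=target_identity,
        indel_rate=indel_rate,
        variable_arm_prob=variable_arm_prob,
        variable_arm=frozenset(arm4),
        seed=seed,
    )
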