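"""Readers and writers for sequences, structures and pairing-probability files.

All interfaces use 1-based inclusive nucleotide coordinates, matching the CT
convention.  Sequences are normalised to the RNA alphabet {A, C, G, U} on
input (``T`` is mapped to ``U``, lowercase is folded to uppercase).  Ambiguity
codes are rejected: the thermodynamic model and the alignment HMM emissions
are defined only over the four standard nucleotides, and silently treating
``N`` as unpairable would corrupt the probability calculus downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "RnaSequence",
    "SecondaryStructure",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_ct",
    "write_ct",
    "parse_dotbracket",
    "write_dotbracket",
    "write_bpp",
    "read_bpp",
]

_VALID = set("ACGU")
#: write floor for the plain-text pairing-probability format; well below any
#: threshold or MEA-relevant magnitude.
BPP_WRITE_FLOOR = 1e-6


class FormatError(ValueError):
    """Raised for malformed external files or invalid structures."""


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA homolog.

    Residues are stored as an uppercase string over {A, C, G, U}; residue
    ``i`` (1-based) is ``residues[i - 1]``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = [i for i, r in enumerate(self.residues, start=1) if r not in _VALID]
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: invalid residue "
                f"{self.residues[bad[0] - 1]!r} at position {bad[0]}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @staticmethod
    def from_raw(seq_id: str, raw: str) -> "RnaSequence":
        """Build a sequence from raw text, normalising T->U and case."""
        cleaned = raw.strip().upper().replace("T", "U")
        for pos, ch in enumerate(cleaned, start=1):
            if ch not in _VALID:
                raise FormatError(
                    f"sequence {seq_id!r}: unsupported residue {ch!r} at "
                    f"position {pos} (alphabet is A, C, G, U/T)"
                )
        return RnaSequence(seq_id, cleaned)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of base pairs ``{(i, j)}`` with ``1 <= i < j <= N``."""

    pairs: frozenset
    sequence_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))
        for i, j in self.pairs:
            if not (1 <= i < j <= self.sequence_length):
                raise FormatError(
                    f"pair ({i}, {j}) outside 1 <= i < j <= {self.sequence_length}"
                )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner_of(self, i: int) -> int:
        """Partner of position ``i`` (0 if unpaired). Errors on multi-pairing."""
        partners = [j for p in self.pairs for j in p if i in p and j != i]
        if len(partners) > 1:
            raise FormatError(f"position {i} participates in {len(partners)} pairs")
        return partners[0] if partners else 0

    def is_valid(self) -> bool:
        """Full validity: one pair per position and no crossing pairs."""
        seen: set[int] = set()
        for i, j in self.pairs:
            if i in seen or j in seen:
                return False
            seen.update((i, j))
        ordered = sorted(self.pairs)
        for a in range(len(ordered)):
            i1, j1 = ordered[a]
            for b in range(a + 1, len(ordered)):
                i2, j2 = ordered[b]
                if i1 < i2 < j1 < j2:
                    return False
        return True

    def require_valid(self) -> "SecondaryStructure":
        if not self.is_valid():
            raise FormatError("structure violates nesting/uniqueness invariants")
        return self


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a multi-FASTA file into a list of normalised RNA sequences.

    Duplicate record ids are disambiguated deterministically by suffixing
    ``_2``, ``_3``, ... in file order.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: dict[str, int] = {}
    out: list[RnaSequence] = []
    for rec in records:
        base = rec.id if rec.id else "seq"
        seen[base] = seen.get(base, 0) + 1
        seq_id = base if seen[base] == 1 else f"{base}_{seen[base]}"
        out.append(RnaSequence.from_raw(seq_id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# CT (6-column connectivity table, as used across the RNAstructure ecosystem)


def read_ct(path: str | Path) -> tuple[RnaSequence, SecondaryStructure]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed CT header {lines[0]!r}") from exc
    title = " ".join(header[1:]) or Path(path).stem
    if len(lines) - 1 < n:
        raise FormatError(f"{path}: expected {n} CT rows, found {len(lines) - 1}")
    partner = np.zeros(n + 1, dtype=int)
    residues = []
    for row in range(1, n + 1):
        cols = lines[row].split()
        if len(cols) < 6:
            raise FormatError(f"{path}: CT row {row} has fewer than 6 columns")
        idx, base, pair_col = int(cols[0]), cols[1], int(cols[4])
        if idx != row:
            raise FormatError(f"{path}: CT row {row} has index {idx}")
        if not (0 <= pair_col <= n):
            raise FormatError(f"{path}: row {row} partner {pair_col} out of range")
        partner[row] = pair_col
        residues.append(base)
    for i in range(1, n + 1):
        j = partner[i]
        if j and partner[j] != i:
            raise FormatError(f"{path}: asymmetric pair at rows {i}/{j}")
    seq = RnaSequence.from_raw(title, "".join(residues))
    pairs = frozenset((i, int(partner[i])) for i in range(1, n + 1) if partner[i] > i)
    return seq, SecondaryStructure(pairs, n)


def write_ct(seq: RnaSequence, structure: SecondaryStructure, path: str | Path) -> None:
    if structure.sequence_length != seq.length:
        raise FormatError("structure length does not match sequence length")
    structure.require_valid()
    n = seq.length
    partner = np.zeros(n + 1, dtype=int)
    for i, j in structure.pairs:
        partner[i], partner[j] = j, i
    with open(path, "w") as fh:
        fh.write(f"{n} {seq.id}\n")
        for i in range(1, n + 1):
            fh.write(
                f"{i} {seq.residues[i - 1]} {i - 1} "
                f"{(i + 1) if i < n else 0} {partner[i]} {i}\n"
            )


# ---------------------------------------------------------------------------
# Dot-bracket (Vienna dialect, pseudoknot-free)


def parse_dotbracket(text: str) -> SecondaryStructure:
    text = text.strip()
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise FormatError(f"invalid dot-bracket character {ch!r} at position {pos}")
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    pairs = {(min(i, j), max(i, j)) for i, j in pairs}
    return SecondaryStructure(frozenset(pairs), len(text))


def write_dotbracket(structure: SecondaryStructure) -> str:
    structure.require_valid()
    chars = ["."] * structure.sequence_length
    for i, j in structure.pairs:
        chars[i - 1], chars[j - 1] = "(", ")"
    return "".join(chars)


# ---------------------------------------------------------------------------
# Plain-text base pairing probabilities: header "# seq_id N", rows "i\tj\tp"


def write_bpp(
    probs: np.ndarray,
    path: str | Path,
    seq_id: str = "seq",
    floor: float = BPP_WRITE_FLOOR,
) -> None:
    """Write the upper triangle (i < j) of a pairing-probability matrix.

    Entries below ``floor`` are omitted to keep files compact; probabilities
    are serialised with 12+ significant digits so the round trip is lossless
    above the floor.
    """
    probs = np.asarray(probs, dtype=float)
    n = probs.shape[0]
    if probs.shape != (n, n):
        raise FormatError("probability matrix must be square")
    with open(path, "w") as fh:
        fh.write(f"# {seq_id} {n}\n")
        for i in range(n):
            for j in range(i + 1, n):
                p = probs[i, j]
                if p >= floor:
                    fh.write(f"{i + 1}\t{j + 1}\t{p:.12e}\n")


def read_bpp(path: str | Path, n: int) -> np.ndarray:
    """Read a pairing-probability file into a dense upper-triangular matrix."""
    probs = np.zeros((n, n))
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise FormatError(f"{path}:{lineno}: expected 'i<TAB>j<TAB>p'")
        i, j, p = int(cols[0]), int(cols[1]), float(cols[2])
        if not (1 <= i < j <= n):
            raise FormatError(f"{path}:{lineno}: indices ({i}, {j}) invalid for N={n}")
        if not (0.0 <= p <= 1.0):
            raise FormatError(f"{path}:{lineno}: probability {p} outside [0, 1]")
        probs[i - 1, j - 1] = p
    return probs
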