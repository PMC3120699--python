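"""Nearest-neighbor thermodynamic model of RNA secondary structure.

The free energy change of a structure is the sum over its loop decomposition:
stacked pairs, hairpin loops, bulge and internal loops (penalised by total
unpaired length), multibranch loops under a linear ``a + b*branches +
c*unpaired`` model, and a terminal AU/GU penalty per non-stacked helix-end
side.  The exterior loop is free.  Parameters ship as a versioned YAML data
file and any file with the same schema can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .io_formats import FormatError, RnaSequence, SecondaryStructure

__all__ = ["EnergyParams", "load_energy_params", "can_pair", "structure_free_energy"]

NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
NT_LETTER = "ACGU"
#: canonical pairs, as (5' nucleotide, 3' nucleotide) index tuples
CANONICAL = {(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)}
#: pairs carrying the terminal helix-end penalty
WEAK_CLOSING = {(0, 3), (3, 0), (2, 3), (3, 2)}

GAS_CONSTANT = 0.0019872  # kcal/(mol*K)


def can_pair(a: str, b: str) -> bool:
    """True exactly for the canonical pairs AU, UA, GC, CG, GU, UG."""
    try:
        return (NT_INDEX[a], NT_INDEX[b]) in CANONICAL
    except KeyError as exc:
        raise ValueError(f"nucleotide outside A/C/G/U: {exc}") from exc


@dataclass(frozen=True)
class EnergyParams:
    """Loaded nearest-neighbor parameter set (energies in kcal/mol)."""

    RT: float
    temperature: float
    min_hairpin: int
    terminal_AU: float
    lxc: float
    multibranch: tuple  # (a, b, c)
    stack: dict  # ("XY", "WZ") -> kcal/mol
    hairpin_by_len: dict
    bulge_by_len: dict
    internal_by_len: dict

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ValueError("RT must be positive")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        for name, table, start in (
            ("hairpin_by_len", self.hairpin_by_len, self.min_hairpin),
            ("bulge_by_len", self.bulge_by_len, 1),
            ("internal_by_len", self.internal_by_len, 2),
        ):
            lengths = sorted(table)
            if lengths != list(range(start, start + len(lengths))):
                raise ValueError(f"{name}: lengths must be contiguous from {start}")

    def _extrapolate(self, table: dict, n: int) -> float:
        top = max(table)
        if n <= top:
            return table[n]
        return table[top] + self.lxc * math.log(n / top)

    def hairpin_energy(self, n_unpaired: int) -> float:
        if n_unpaired < self.min_hairpin:
            raise ValueError(f"hairpin of {n_unpaired} < min {self.min_hairpin}")
        return self._extrapolate(self.hairpin_by_len, n_unpaired)

    def bulge_energy(self, n_unpaired: int) -> float:
        return self._extrapolate(self.bulge_by_len, n_unpaired)

    def internal_energy(self, n_unpaired: int) -> float:
        return self._extrapolate(self.internal_by_len, n_unpaired)

    def stack_energy(self, outer: tuple, inner: tuple) -> float:
        key = (
            NT_LETTER[outer[0]] + NT_LETTER[outer[1]],
            NT_LETTER[inner[0]] + NT_LETTER[inner[1]],
        )
        return self.stack[key]

    def end_penalty(self, pair: tuple) -> float:
        return self.terminal_AU if pair in WEAK_CLOSING else 0.0

    def with_temperature(self, temperature: float) -> "EnergyParams":
        """Same parameter table with RT recomputed for another temperature."""
        return EnergyParams(
            RT=GAS_CONSTANT * temperature,
            temperature=temperature,
            min_hairpin=self.min_hairpin,
            terminal_AU=self.terminal_AU,
            lxc=self.lxc,
            multibranch=self.multibranch,
            stack=self.stack,
            hairpin_by_len=self.hairpin_by_len,
            bulge_by_len=self.bulge_by_len,
            internal_by_len=self.internal_by_len,
        )


def load_energy_params(path: str | Path | None = None) -> EnergyParams:
    """Load energy parameters from YAML; ``None`` loads the shipped defaults."""
    if path is None:
        text = resources.files("turbofold.data").joinpath("energy_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    stack = {}
    for key, val in raw["stack"].items():
        outer, inner = key.split("/")
        stack[(outer, inner)] = float(val)
    # reverse-complement symmetry of the stacking table
    for (outer, inner), val in stack.items():
        mirror = (inner[::-1], outer[::-1])
        if abs(stack[mirror] - val) > 1e-9:
            raise ValueError(f"stack table breaks symmetry at {outer}/{inner}")
    mb = raw["multibranch"]
    return EnergyParams(
        RT=float(raw["RT"]),
        temperature=float(raw["temperature"]),
        min_hairpin=int(raw["min_hairpin"]),
        terminal_AU=float(raw["terminal_AU"]),
        lxc=float(raw["lxc"]),
        multibranch=(float(mb["a"]), float(mb["b"]), float(mb["c"])),
        stack=stack,
        hairpin_by_len={int(k): float(v) for k, v in raw["hairpin_by_len"].items()},
        bulge_by_len={int(k): float(v) for k, v in raw["bulge_by_len"].items()},
        internal_by_len={int(k): float(v) for k, v in raw["internal_by_len"].items()},
    )


_DEFAULT: EnergyParams | None = None


def default_energy_params() -> EnergyParams:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_energy_params()
    return _DEFAULT


def _pair_code(seq: str, i: int, j: int) -> tuple:
    """(5', 3') nucleotide index tuple for 1-based positions i < j."""
    return (NT_INDEX[seq[i - 1]], NT_INDEX[seq[j - 1]])


def structure_free_energy(
    seq: RnaSequence, structure: SecondaryStructure, params: EnergyParams | None = None
) -> float:
    """Gibbs free energy change of folding, in kcal/mol (empty structure = 0).

    The structure must be valid on ``seq``: nested, at most one pair per
    position, all pairs canonical, and every hairpin at least ``min_hairpin``
    nucleotides.
    """
    params = params or default_energy_params()
    if structure.sequence_length != seq.length:
        raise FormatError("structure/sequence length mismatch")
    structure.require_valid()
    n = seq.length
    partner = [0] * (n + 2)
    for i, j in structure.pairs:
        partner[i], partner[j] = j, i
        if _pair_code(seq.residues, i, j) not in CANONICAL:
            raise FormatError(
                f"non-canonical pair ({i}, {j}) = "
                f"{seq.residues[i - 1]}-{seq.residues[j - 1]}"
            )

    energy = 0.0
    for i, j in sorted(structure.pairs):
        pair = _pair_code(seq.residues, i, j)
        # terminal penalty once per non-stacked side of a weak closing pair
        if i == 1 or partner[i - 1] != j + 1:
            energy += params.end_penalty(pair)
        if partner[i + 1] != j - 1:
            energy += params.end_penalty(pair)
        inner = _enclosed_branches(partner, i, j)
        if not inner:
            loop_len = j - i - 1
            if loop_len < params.min_hairpin:
                raise FormatError(
                    f"hairpin closed by ({i}, {j}) has {loop_len} unpaired "
                    f"nucleotides (minimum {params.min_hairpin})"
                )
            energy += params.hairpin_energy(loop_len)
        elif len(inner) == 1:
            k, l = inner[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                energy += params.stack_energy(pair, _pair_code(seq.residues, k, l))
            elif min(n1, n2) == 0:
                energy += params.bulge_energy(n1 + n2)
            else:
                energy += params.internal_energy(n1 + n2)
        else:
            a, b, c = params.multibranch
            unpaired = (j - i - 1) - sum(l2 - k2 + 1 for k2, l2 in inner)
            energy += a + b * (1 + len(inner)) + c * unpaired
    return energy


def _enclosed_branches(partner: list, i: int, j: int) -> list:
    """Pairs directly enclosed by (i, j), left to right."""
    out = []
    k = i + 1
    while k < j:
        if partner[k] > k:
            out.append((k, partner[k]))
            k = partner[k] + 1
        else:
            k += 1
    return out
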