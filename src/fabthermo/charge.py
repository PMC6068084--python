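"""Mutant construction and protein charge bookkeeping.

Light-chain framework mutants are built by point substitution at plain
1-based sequential positions (no Kabat/IMGT renumbering; a label such as
"LS63R" reads "light chain, Ser at sequential position 63 mutated to Arg").

Net charge at a given pH follows the Henderson–Hasselbalch approximation:
every ionizable group titrates independently, contributing

    basic  (R, K, H, N-terminus): +1 / (1 + 10**(pH - pKa))
    acidic (D, E, C, Y, C-terminus): -1 / (1 + 10**(pKa - pH))

The isoelectric point is the unique zero of this strictly decreasing
charge curve, found by bisection.  The default pKa set is the EMBOSS one;
alternative published sets can be passed in, since computed charges and pI
shift by a few tenths of a unit between sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: EMBOSS pKa values (side chains plus termini).
PKA_EMBOSS: dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    "nterm": 8.6, "cterm": 3.6,
}

#: Textbook (Lehninger) pKa values, an alternative standard set.
PKA_LEHNINGER: dict[str, float] = {
    "C": 8.18, "D": 3.65, "E": 4.25, "H": 6.0, "K": 10.53, "R": 12.48, "Y": 10.07,
    "nterm": 9.69, "cterm": 2.34,
}

PKA_TABLES = {"emboss": PKA_EMBOSS, "lehninger": PKA_LEHNINGER}

_BASIC = "RKH"
_ACIDIC = "DECY"

#: Human preproinsulin (110 aa: signal peptide, B chain, C-peptide, A chain).
INSULIN_PREPROPROTEIN = (
    "MALWMRLLPLLALLALWGPDPAAA"
    "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"
    "RREAEDLQVGQVELGGGPGAGSLQPLALEGSLQKR"
    "GIVEQCCTSICSLYQLENYCN"
)

#: Mature human insulin chains.
INSULIN_B_CHAIN = "FVNQHLCGSHLVEALYLVCGERGFFYTPKT"
INSULIN_A_CHAIN = "GIVEQCCTSICSLYQLENYCN"


@dataclass(frozen=True)
class ChainSequence:
    """A protein chain as a one-letter amino-acid string, 1-based numbering."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residue letters in {self.identifier!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise ValueError(f"position {position} outside sequence of length {len(self.residues)}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution: ``original`` at 1-based ``position`` becomes ``replacement``."""

    position: int
    original: str
    replacement: str

    def __post_init__(self) -> None:
        for aa in (self.original, self.replacement):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"invalid residue letter {aa!r}")
        if self.original == self.replacement:
            raise ValueError(f"mutation at position {self.position} is a no-op")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    def __str__(self) -> str:
        return f"{self.original}{self.position}{self.replacement}"


_MUTATION_RE = re.compile(r"^(?:L)?([A-Z])(\d+)([A-Z])$")


def parse_mutation(token: str) -> MutationSpec:
    """Parse ``"S63R"`` or chain-prefixed ``"LS63R"`` into a spec.

    A leading ``L`` before a two-letter residue pair denotes the light
    chain; only light chains are handled here, so the prefix is accepted
    and dropped.
    """
    token = token.strip()
    m = _MUTATION_RE.match(token)
    if m is None:
        raise ValueError(f"cannot parse mutation token {token!r} (expected e.g. S63R or LS63R)")
    return MutationSpec(position=int(m.group(2)), original=m.group(1), replacement=m.group(3))


def apply_mutations(seq: ChainSequence, specs: list[MutationSpec], identifier: str | None = None) -> ChainSequence:
    """Apply point substitutions, verifying each original residue.

    Raises if a spec's original residue does not match the sequence at its
    position, or if two specs address the same position.
    """
    positions = [s.position for s in specs]
    if len(positions) != len(set(positions)):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate mutation positions: {dupes}")
    residues = list(seq.residues)
    for spec in specs:
        actual = seq.residue_at(spec.position)
        if actual != spec.original:
            raise ValueError(
                f"original-residue mismatch at position {spec.position}: "
                f"sequence has {actual}, spec expects {spec.original}"
            )
        residues[spec.position - 1] = spec.replacement
    name = identifier if identifier is not None else f"{seq.identifier}+{','.join(map(str, specs))}"
    return ChainSequence(identifier=name, residues="".join(residues))


def net_charge(
    seq: ChainSequence | str,
    pH: float,
    pka_table: dict[str, float] | str = "emboss",
    include_termini: bool = True,
) -> float:
    """Henderson–Hasselbalch net charge in elementary units at ``pH``."""
    if not 0 < pH < 14:
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    if isinstance(pka_table, str):
        pka_table = PKA_TABLES[pka_table.lower()]
    residues = seq.residues if isinstance(seq, ChainSequence) else seq
    bad = set(residues) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")

    charge = 0.0
    for aa in residues:
        if aa in _BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka_table[aa]))
        elif aa in _ACIDIC:
            charge -= 1.0 / (1.0 + 10.0 ** (pka_table[aa] - pH))
    if include_termini and residues:
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka_table["nterm"]))
        charge -= 1.0 / (1.0 + 10.0 ** (pka_table["cterm"] - pH))
    return charge


def isoelectric_point(
    seq: ChainSequence | str,
    pka_table: dict[str, float] | str = "emboss",
    include_termini: bool = True,
    tol: float = 1e-6,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0.1, 13.9].

    Undefined (raises) when the charge curve does not change sign, e.g. a
    sequence with only acidic or only basic groups.
    """
    lo, hi = 0.1, 13.9
    f_lo = net_charge(seq, lo, pka_table, include_termini)
    f_hi = net_charge(seq, hi, pka_table, include_termini)
    if f_lo <= 0 or f_hi >= 0:
        if abs(f_lo) < tol and abs(f_hi) < tol:
            raise ValueError("no ionizable groups; pI undefined")
        if f_lo <= 0 and abs(f_lo) >= tol:
            raise ValueError("net charge negative across the pH range; pI undefined")
        if f_hi >= 0 and abs(f_hi) >= tol:
            raise ValueError("net charge positive across the pH range; pI undefined")
        raise ValueError("charge curve does not cross zero; pI undefined")
    while hi - lo > tol / 10:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_table, include_termini) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
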