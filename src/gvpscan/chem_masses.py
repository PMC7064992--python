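"""Monoisotopic mass ledger: elements, residues, modifications, substitution deltas.

Every mass used anywhere in the package comes from the :class:`MassLedger`,
which is built from standard elemental monoisotopic masses (CODATA/AME values,
>= 6 decimals) and elemental compositions.  Named modification deltas are
registered with their net elemental formula, so each delta is *derived*, never
typed in as a bare number; composite modifications (e.g. ``"Formyl + Acetyl"``)
are signed sums of base entries and may include C-13 isotope-offset terms.

Isotope misassignment offsets (k x one-C13 mass difference, k in -2..+5) are a
separate axis, exposed as :attr:`MassLedger.c13_offset`, not modifications.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ELEMENT_MASSES",
    "RESIDUE_FORMULAS",
    "PROTON_MASS",
    "ModificationDef",
    "SubstitutionDelta",
    "MassLedger",
    "default_ledger",
    "mass_of_formula",
    "ppm_window",
]

# Standard monoisotopic masses of the elements occurring in peptides and the
# registered modifications.  "C13" is the heavy carbon isotope itself.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "C13": 13.00335483507,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
}

PROTON_MASS = 1.007276466879

# Residue (i.e. amino acid minus water) elemental compositions.
RESIDUE_FORMULAS: dict[str, str] = {
    "G": "C2H3NO",
    "A": "C3H5NO",
    "S": "C3H5NO2",
    "P": "C5H7NO",
    "V": "C5H9NO",
    "T": "C4H7NO2",
    "C": "C3H5NOS",
    "L": "C6H11NO",
    "I": "C6H11NO",
    "N": "C4H6N2O2",
    "D": "C4H5NO3",
    "Q": "C5H8N2O2",
    "K": "C6H12N2O",
    "E": "C5H7NO3",
    "M": "C5H9NOS",
    "H": "C6H7N3O",
    "F": "C9H9NO",
    "R": "C6H12N4O",
    "Y": "C9H9NO2",
    "W": "C11H10N2O",
}

def mass_of_formula(formula: str) -> float:
    """Monoisotopic mass of a (possibly signed) elemental formula.

    A leading ``-`` negates the whole formula; individual element counts may
    also be negative (e.g. ``"O-1N1H1"`` is not needed — write ``Amidation``
    as ``"-ONH"`` is ambiguous, so use per-element signs: ``"N1H1O-1"``).
    """
    formula = formula.strip()
    sign = 1.0
    if formula.startswith("-"):
        sign = -1.0
        formula = formula[1:]
    total = 0.0
    pos = 0
    # C13 must be matched before bare C
    token = re.compile(r"(C13|[A-Z][a-z]?)(-?\d*)")
    for m in token.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        pos = m.end()
        elem, count = m.group(1), m.group(2)
        if elem not in ELEMENT_MASSES:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        n = int(count) if count else 1
        total += ELEMENT_MASSES[elem] * n
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
    return sign * total


WATER_MASS = mass_of_formula("H2O")


@dataclass(frozen=True)
class ModificationDef:
    """A named modification with its net elemental composition.

    ``targets`` is a set of one-letter residue codes and/or the terminus
    markers ``"N-term"`` / ``"C-term"``; empty means "any".
    """

    name: str
    composition: str
    targets: frozenset[str] = frozenset()
    fixed: bool = False
    delta: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", mass_of_formula(self.composition))
        if self.fixed and not (self.targets - {"N-term", "C-term"}):
            raise ValueError(f"fixed modification {self.name!r} needs residue targets")


@dataclass(frozen=True)
class SubstitutionDelta:
    """Mass difference of a single amino-acid substitution ``from_aa -> to_aa``."""

    from_aa: str
    to_aa: str
    delta: float

    @property
    def label(self) -> str:
        return f"{self.from_aa}->{self.to_aa}"


class MassLedger:
    """Registry of residue masses, modification deltas and substitution deltas."""

    def __init__(self) -> None:
        self.elements = dict(ELEMENT_MASSES)
        self.residues: dict[str, float] = {
            aa: mass_of_formula(f) for aa, f in RESIDUE_FORMULAS.items()
        }
        self.water = WATER_MASS
        self.proton = PROTON_MASS
        #: mass difference of one 12C -> 13C substitution
        self.c13_offset = ELEMENT_MASSES["C13"] - ELEMENT_MASSES["C"]
        self.modifications: dict[str, ModificationDef] = {}

    # -- registration -------------------------------------------------------

    def register(
        self,
        name: str,
        composition: str,
        targets: frozenset[str] | set[str] | None = None,
        fixed: bool = False,
    ) -> ModificationDef:
        mod = ModificationDef(
            name, composition, frozenset(targets or ()), fixed=fixed
        )
        self.modifications[name] = mod
        return mod

    def register_composite(
        self, name: str, parts: list[tuple[str, int]], c13: int = 0
    ) -> ModificationDef:
        """Register ``name`` as a signed sum of already-registered entries.

        ``parts`` is a list of (base entry name, signed count); ``c13`` adds
        k isotope offsets (adduct rows in the frequency table mix the two
        axes; the decomposition is recorded as given, no mechanism asserted).
        """
        pieces = []
        for base, count in parts:
            if base not in self.modifications:
                raise KeyError(f"composite {name!r} refers to unknown entry {base!r}")
            comp = self.modifications[base].composition
            pieces.append((comp, count))
        formula = _combine_formulas(pieces, c13=c13)
        return self.register(name, formula)

    # -- queries ------------------------------------------------------------

    def residue_mass(self, aa: str) -> float:
        try:
            return self.residues[aa]
        except KeyError:
            raise KeyError(f"unknown residue code {aa!r}") from None

    def modification_delta(self, name: str) -> float:
        """Theoretical mass delta of a registered modification."""
        try:
            return self.modifications[name].delta
        except KeyError:
            known = ", ".join(sorted(self.modifications))
            raise KeyError(
                f"unknown modification {name!r}; known: {known}"
            ) from None

    def substitution_delta(self, from_aa: str, to_aa: str) -> float:
        """residue_mass(to) - residue_mass(from); antisymmetric, zero on identity."""
        return self.residue_mass(to_aa) - self.residue_mass(from_aa)

    def all_substitutions(self, include_isobaric: bool = False) -> list[SubstitutionDelta]:
        """All 380 ordered residue substitutions (I<->L excluded by default).

        I<->L has delta exactly zero and is indistinguishable by mass, so it
        only adds noise to mimic reports.
        """
        out = []
        for a in self.residues:
            for b in self.residues:
                if a == b:
                    continue
                if not include_isobaric and {a, b} == {"I", "L"}:
                    continue
                out.append(SubstitutionDelta(a, b, self.substitution_delta(a, b)))
        return out

    def ambiguous_substitutions(
        self, delta_mass: float, tol: float, include_isobaric: bool = False
    ) -> list[SubstitutionDelta]:
        """Substitutions whose delta lies within ``tol`` Da of ``delta_mass``.

        Sorted by |difference|; ties broken by (from, to) for determinism.
        """
        if tol <= 0:
            raise ValueError("tol must be > 0")
        hits = [
            s
            for s in self.all_substitutions(include_isobaric=include_isobaric)
            if abs(s.delta - delta_mass) <= tol
        ]
        hits.sort(key=lambda s: (abs(s.delta - delta_mass), s.from_aa, s.to_aa))
        return hits

    def peptide_mass(
        self,
        sequence: str,
        mods: list[tuple[int | str, ModificationDef | str]] | None = None,
    ) -> float:
        """Neutral monoisotopic mass of a peptide with localized modifications.

        ``mods`` holds (position, modification) pairs where position is a
        1-based residue index or a terminus marker ("N-term"/"C-term"); the
        modification may be a name registered in this ledger.
        """
        if not sequence:
            raise ValueError("sequence must be nonempty")
        total = self.water
        for aa in sequence:
            if aa not in self.residues:
                raise KeyError(f"unknown residue code {aa!r} in {sequence!r}")
            total += self.residues[aa]
        for pos, mod in mods or ():
            if isinstance(mod, str):
                mod_delta = self.modification_delta(mod)
            else:
                mod_delta = mod.delta
            if isinstance(pos, int):
                if not 1 <= pos <= len(sequence):
                    raise ValueError(
                        f"modification position {pos} outside 1..{len(sequence)}"
                    )
            elif pos not in ("N-term", "C-term"):
                raise ValueError(f"bad modification position {pos!r}")
            total += mod_delta
        return total

    # -- serialization ------------------------------------------------------

    def to_table(self) -> "pandas.DataFrame":  # noqa: F821 - deferred import
        import pandas as pd

        rows = [
            {
                "name": m.name,
                "composition": m.composition,
                "delta": round(m.delta, 6),
                "targets": ";".join(sorted(m.targets)),
                "fixed": m.fixed,
            }
            for m in self.modifications.values()
        ]
        return pd.DataFrame(rows, columns=["name", "composition", "delta", "targets", "fixed"])

    def write_table(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path) -> "MassLedger":
        import pandas as pd

        ledger = cls()
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        for row in df.itertuples(index=False):
            targets = frozenset(t for t in str(row.targets).split(";") if t)
            mod = ledger.register(
                row.name, row.composition, targets, fixed=bool(row.fixed)
            )
            if abs(mod.delta - float(row.delta)) > 1e-5:
                raise ValueError(
                    f"ledger table entry {row.name!r}: stored delta {row.delta} "
                    f"disagrees with composition mass {mod.delta:.6f}"
                )
        return ledger


def _combine_formulas(pieces: list[tuple[str, int]], c13: int = 0) -> str:
    """Net signed formula from (formula, count) pieces plus k C13 offsets."""
    counts: dict[str, int] = {}
    for formula, mult in pieces:
        sign = 1
        f = formula.strip()
        if f.startswith("-"):
            sign = -1
            f = f[1:]
        token = re.compile(r"(C13|[A-Z][a-z]?)(-?\d*)")
        pos = 0
        for m in token.finditer(f):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = m.end()
            n = int(m.group(2)) if m.group(2) else 1
            counts[m.group(1)] = counts.get(m.group(1), 0) + sign * mult * n
    if c13:
        # one C13 offset = swap one 12C for one 13C
        counts["C13"] = counts.get("C13", 0) + c13
        counts["C"] = counts.get("C", 0) - c13
    parts = []
    for elem in sorted(counts):
        n = counts[elem]
        if n == 0:
            continue
        parts.append(f"{elem}{n}" if n != 1 else elem)
    return "".join(parts) if parts else "H0"


def ppm_window(mass: float, tol_ppm: float) -> float:
    """Half-width in Da of a ppm tolerance window around ``mass``."""
    if tol_ppm < 0:
        raise ValueError("ppm tolerance must be >= 0")
    if mass <= 0:
        raise ValueError("mass must be > 0")
    return mass * tol_ppm * 1e-6


def default_ledger() -> MassLedger:
    """Ledger preloaded with every named modification the pipeline references.

    Base entries come from the library's modification set (fixed CAM at Cys,
    Met oxidation, N-terminal acetyl/acetaldehyde, pyro-Glu) plus the
    recurring artifactual mass shifts seen in open searches of hair digests
    (formylation, methylation, carbamylation, DTT and cysteine adducts,
    sodiation, deamidation, ammonia/water losses).  Composite rows are signed
    sums of base entries, optionally with C-13 isotope-offset terms.
    """
    lg = MassLedger()
    # base entries
    lg.register("Carbamidomethyl", "C2H3NO", {"C"}, fixed=True)
    lg.register("Oxidation", "O", {"M"})
    lg.register("Acetyl", "C2H2O", {"N-term", "K"})
    lg.register("Acetaldehyde", "C2H2", {"N-term"})
    lg.register("Gln->pyro-Glu", "N-1H-3", {"Q", "N-term"})
    lg.register("Glu->pyro-Glu", "H-2O-1", {"E", "N-term"})
    lg.register("Formyl", "CO", {"N-term"})
    lg.register("Methyl", "CH2")
    lg.register("-NH3", "N-1H-3")
    lg.register("Formaldehyde Adduct", "C")
    lg.register("Carbamyl", "CHNO", {"N-term", "K"})
    lg.register("Dehydration", "H-2O-1")
    lg.register("Sodiated", "NaH-1")
    lg.register("Deamidation", "ON-1H-1", {"N", "Q"})
    lg.register("Amidation", "NH1O-1", {"C-term"})
    lg.register("Dioxidation", "O2")
    lg.register("+DTT", "C4H8O2S2", {"C"})
    lg.register("Add-Cys", "C3H5NOS", {"C"})
    lg.register("Cys(CAM)->Dehydroalanine", "C-2H-5N-1O-1S-1", {"C"})
    # net composition DTT - S; decomposition recorded as given
    lg.register("Desulfurization + CAM + DTT", "C4H8O2S")
    # composites
    lg.register_composite("Formyl + Acetyl", [("Formyl", 1), ("Acetyl", 1)])
    lg.register_composite("Deamidation + CAM", [("Deamidation", 1), ("Carbamidomethyl", 1)])
    lg.register_composite("Add-Cys + CAM", [("Add-Cys", 1), ("Carbamidomethyl", 1)])
    lg.register_composite("Sodiated + 2C-13", [("Sodiated", 1)], c13=2)
    return lg
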