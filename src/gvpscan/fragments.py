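"""Theoretical b/y fragment ladders for HCD spectra of tryptic peptides.

Shared by decoy-spectrum construction and the synthetic-data generator.
Modifications localize to their residue, so an N-terminal modification rides
on every b ion and a C-terminal one on every y ion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chem_masses import MassLedger, PROTON_MASS, default_ledger
from .spectra_io import PeptideIon

__all__ = ["Fragment", "fragment_ladder"]


@dataclass(frozen=True)
class Fragment:
    kind: str  # "b" or "y"
    index: int  # ladder index, 1..n-1
    charge: int
    mz: float


def fragment_ladder(
    ion: PeptideIon,
    ledger: MassLedger | None = None,
    max_fragment_charge: int | None = None,
) -> list[Fragment]:
    """All b/y fragments of ``ion`` for fragment charges 1..max(1, z-1)."""
    ledger = ledger or default_ledger()
    seq = ion.sequence
    n = len(seq)
    if max_fragment_charge is None:
        max_fragment_charge = max(1, ion.charge - 1)
    res = [ledger.residue_mass(aa) for aa in seq]
    # per-position modification mass; termini tracked separately
    pos_mod = [0.0] * n
    nterm_mod = cterm_mod = 0.0
    for pos, _aa, name in ion.mods:
        delta = ledger.modification_delta(name)
        if pos == "N-term":
            nterm_mod += delta
        elif pos == "C-term":
            cterm_mod += delta
        else:
            pos_mod[pos - 1] += delta
    prefix = [0.0]
    for i in range(n):
        prefix.append(prefix[-1] + res[i] + pos_mod[i])
    frags = []
    for i in range(1, n):
        b_neutral = prefix[i] + nterm_mod
        # y_i holds the C-terminal i residues plus water
        y_neutral = (prefix[n] - prefix[n - i]) + cterm_mod + ledger.water
        for z in range(1, max_fragment_charge + 1):
            frags.append(Fragment("b", i, z, (b_neutral + z * PROTON_MASS) / z))
            frags.append(Fragment("y", i, z, (y_neutral + z * PROTON_MASS) / z))
    return frags
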