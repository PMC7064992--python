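"""Decoy library generation and target-decoy FDR control.

Decoys are built by reversing the peptide sequence while keeping the
C-terminal residue fixed — the standard scheme for tryptic searches, since it
preserves the precursor mass, the terminal K/R statistics, and the residue
composition.  Searching a concatenated target+decoy library then lets the
decoy hit rate estimate the false-match rate:

    FDR(s) = #{decoy hits >= s} / max(1, #{target hits >= s})

q-values are the monotonized FDR; the working threshold is the smallest
score whose q-value is at or below the requested level (1% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_masses import MassLedger, default_ledger
from .fragments import fragment_ladder
from .library_search import SearchHit
from .spectra_io import LibraryEntry, PeptideIon, Spectrum

__all__ = ["make_decoys", "estimate_fdr", "accept_at_fdr", "QValueTable"]


def _reverse_ion(ion: PeptideIon, rng: np.random.Generator,
                 taken: set[str]) -> PeptideIon | None:
    """Reverse all but the C-terminal residue; reshuffle on target collision.

    Modifications travel with their residue.  Returns None for sequences too
    short to reverse (length <= 2).
    """
    seq = ion.sequence
    n = len(seq)
    if n <= 2:
        return None
    prefix = list(seq[:-1])
    perm = list(range(n - 1))[::-1]
    attempt = 0
    while True:
        new_seq = "".join(prefix[i] for i in perm) + seq[-1]
        if new_seq not in taken:
            break
        attempt += 1
        if attempt > 50:
            return None
        perm = list(rng.permutation(n - 1))
    pos_map = {old + 1: new + 1 for new, old in enumerate(perm)}
    pos_map[n] = n
    mods = []
    for pos, aa, name in ion.mods:
        new_pos = pos if isinstance(pos, str) else pos_map[pos]
        mods.append((new_pos, aa, name))
    mods.sort(key=lambda m: (isinstance(m[0], str), m[0] if isinstance(m[0], int) else 0))
    return PeptideIon(new_seq, ion.charge, tuple(mods))


def make_decoys(
    library: list[LibraryEntry],
    ledger: MassLedger | None = None,
    seed: int = 0,
) -> list[LibraryEntry]:
    """Decoy entries for a target library (one per reversible target).

    Each decoy gets a theoretical b/y spectrum at the decoy fragment m/z
    positions carrying over the target's intensity-vs-rank profile (the i-th
    decoy peak by m/z receives the i-th target intensity by m/z, resampled
    when the peak counts differ).
    """
    ledger = ledger or default_ledger()
    rng = np.random.default_rng(seed)
    taken = {e.ion.sequence for e in library}
    decoys = []
    for entry in library:
        decoy_ion = _reverse_ion(entry.ion, rng, taken)
        if decoy_ion is None:
            warnings.warn(f"skipping un-reversible entry {entry.entry_id}")
            continue
        taken.add(decoy_ion.sequence)
        frag_mz = np.array(
            sorted({round(f.mz, 6) for f in fragment_ladder(decoy_ion, ledger)})
        )
        src_int = np.sort(entry.spectrum.intensity)[::-1]
        src_by_mz = entry.spectrum.intensity[np.argsort(entry.spectrum.mz)]
        if len(src_by_mz) == len(frag_mz):
            intensities = src_by_mz
        elif len(src_by_mz) == 0:
            intensities = np.ones(len(frag_mz))
        else:
            # resample the intensity-vs-rank profile onto the decoy ladder
            xp = np.linspace(0, 1, len(src_by_mz))
            xq = np.linspace(0, 1, len(frag_mz))
            intensities = np.interp(xq, xp, src_by_mz)
        spectrum = Spectrum(
            frag_mz,
            np.asarray(intensities, dtype=float),
            precursor_mz=decoy_ion.precursor_mz(ledger),
            charge=decoy_ion.charge,
        )
        annotations = dict(entry.annotations)
        annotations.pop("GVP", None)
        annotations["Decoy"] = "1"
        annotations["DecoyOf"] = entry.entry_id.replace(" ", "_")
        decoys.append(LibraryEntry(decoy_ion, spectrum, annotations))
    return decoys


@dataclass
class QValueTable:
    """Scored hits with q-values and the score threshold at the target FDR."""

    table: pd.DataFrame  # columns: query_id, score, is_decoy, q_value
    alpha: float
    threshold: float | None  # smallest score with q <= alpha; None if unreachable

    @property
    def n_accepted(self) -> int:
        if self.threshold is None:
            return 0
        acc = self.table[
            (self.table["score"] >= self.threshold) & (~self.table["is_decoy"])
        ]
        return len(acc)


def estimate_fdr(hits: list[SearchHit], alpha: float = 0.01) -> QValueTable:
    """Target-decoy q-values over a scored hit list.

    Hits must carry decoy flags via their library entries; raises if the list
    contains no decoy hits at all (the decoy rate is then unestimable).
    """
    if not hits:
        raise ValueError("no hits to estimate FDR from")
    flags = np.array([h.is_decoy for h in hits])
    if not flags.any():
        raise ValueError("no decoy hits present; cannot estimate FDR")
    scores = np.array([h.match_factor for h in hits], dtype=float)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_flags = flags[order]
    cum_decoy = np.cumsum(sorted_flags)
    cum_target = np.cumsum(~sorted_flags)
    fdr = cum_decoy / np.maximum(cum_target, 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    # ties share the q-value of the last hit at that score
    for i in range(len(q) - 2, -1, -1):
        if sorted_scores[i] == sorted_scores[i + 1]:
            q[i] = q[i + 1]
    q_by_pos = np.empty_like(q)
    q_by_pos[order] = q
    table = pd.DataFrame(
        {
            "query_id": [h.query_id for h in hits],
            "score": scores,
            "is_decoy": flags,
            "q_value": q_by_pos,
        }
    )
    passing = sorted_scores[q <= alpha]
    threshold = float(passing.min()) if len(passing) else None
    return QValueTable(table, alpha, threshold)


def accept_at_fdr(hits: list[SearchHit], alpha: float = 0.01) -> list[SearchHit]:
    """Target hits passing the q-value threshold; annotates hits with q-values.

    Returns an empty list when no decoys are present among the hits (nothing
    can be confidently accepted without an error estimate) unless the hit
    list itself is empty.
    """
    if not hits:
        return []
    try:
        qt = estimate_fdr(hits, alpha)
    except ValueError:
        # no decoy hits at all: every hit is above the highest decoy score
        for h in hits:
            h.q_value = 0.0
        return [h for h in hits if not h.is_decoy]
    qvals = qt.table["q_value"].to_numpy()  # rows align with the hit list
    accepted = []
    for h, qv in zip(hits, qvals):
        h.q_value = float(qv)
        if not h.is_decoy and h.q_value <= alpha:
            accepted.append(h)
    return accepted
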