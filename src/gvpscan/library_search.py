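"""Spectral library search: preprocessing, match-factor scoring, precursor filter.

The match factor (MF) is the field's 0-999 spectral similarity scale:
``MF = round(999 x cosine)`` over greedily matched, weighted peak pairs.
Peak weights are ``intensity**intensity_power * mz**mz_power`` (defaults 0.5
and 0, i.e. square-root intensity scaling), and each peak is used at most
once; matching is nearest-neighbor within the fragment ppm tolerance with
ties broken toward the smaller m/z difference.  Identical spectra score 999,
disjoint spectra 0, and the score is invariant under uniform intensity
scaling of either spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_masses import ppm_window
from .spectra_io import LibraryEntry, Spectrum

__all__ = ["SearchParams", "SearchHit", "preprocess", "match_factor", "search",
           "LibraryIndex", "matched_pairs"]


@dataclass(frozen=True)
class SearchParams:
    precursor_tol_ppm: float = 20.0
    fragment_tol_ppm: float = 50.0
    min_peaks: int = 3
    intensity_power: float = 0.5
    mz_power: float = 0.0

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class SearchHit:
    query_id: str
    entry: LibraryEntry
    match_factor: int
    rank: int = 0
    matched_peak_count: int = 0
    q_value: float | None = None

    @property
    def is_decoy(self) -> bool:
        return self.entry.is_decoy


class UnsearchableSpectrum(ValueError):
    """Spectrum has too few peaks to be scored."""


def preprocess(spectrum: Spectrum, params: SearchParams) -> np.ndarray:
    """Unit-norm weight vector aligned with the spectrum's peak array."""
    if len(spectrum) < params.min_peaks:
        raise UnsearchableSpectrum(
            f"spectrum has {len(spectrum)} peaks; need >= {params.min_peaks}"
        )
    w = np.power(spectrum.intensity, params.intensity_power)
    if params.mz_power:
        w = w * np.power(spectrum.mz, params.mz_power)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise UnsearchableSpectrum("all-zero intensities")
    return w / norm


def matched_pairs(
    query_mz: np.ndarray,
    lib_mz: np.ndarray,
    tol_ppm: float,
    shift: float = 0.0,
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-neighbor peak matching within a ppm window.

    Candidate pairs (|q - (l + shift)| <= window at the library peak) are
    taken in order of ascending m/z difference; each peak is used once.
    """
    shifted = np.asarray(lib_mz, dtype=float) + shift
    if len(query_mz) == 0 or len(shifted) == 0:
        return []
    # window scale uses the (shifted) library peak mass
    tol = np.maximum(shifted, 1e-6) * tol_ppm * 1e-6
    diff = np.abs(np.asarray(query_mz, dtype=float)[:, None] - shifted[None, :])
    ii, jj = np.nonzero(diff <= tol[None, :])
    cands = sorted(zip(diff[ii, jj], ii, jj), key=lambda t: (t[0], t[1], t[2]))
    used_q: set[int] = set()
    used_l: set[int] = set()
    pairs = []
    for _d, i, j in cands:
        if i in used_q or j in used_l:
            continue
        used_q.add(i)
        used_l.add(j)
        pairs.append((i, j))
    return pairs


def match_factor(
    query: Spectrum, entry_spectrum: Spectrum, params: SearchParams | None = None
) -> tuple[int, int]:
    """(MF, matched peak count) between a query and a library spectrum."""
    params = params or SearchParams()
    wq = preprocess(query, params)
    wl = preprocess(entry_spectrum, params)
    pairs = matched_pairs(query.mz, entry_spectrum.mz, params.fragment_tol_ppm)
    cosine = float(sum(wq[i] * wl[j] for i, j in pairs))
    mf = int(round(999 * min(max(cosine, 0.0), 1.0)))
    return mf, len(pairs)


class LibraryIndex:
    """Library entries indexed by precursor neutral mass for fast windowed lookup."""

    def __init__(self, entries: list[LibraryEntry]):
        self.entries = list(entries)
        masses = np.array([e.spectrum.neutral_mass for e in self.entries])
        order = np.argsort(masses, kind="stable")
        self._masses = masses[order]
        self._order = order

    def candidates(self, neutral_mass: float, tol_da: float) -> list[LibraryEntry]:
        lo = np.searchsorted(self._masses, neutral_mass - tol_da, side="left")
        hi = np.searchsorted(self._masses, neutral_mass + tol_da, side="right")
        return [self.entries[self._order[k]] for k in range(lo, hi)]

    def __len__(self) -> int:
        return len(self.entries)


def search(
    query: Spectrum,
    library: LibraryIndex | list[LibraryEntry],
    params: SearchParams | None = None,
    query_id: str | None = None,
    require_charge_match: bool = True,
) -> list[SearchHit]:
    """Precursor-filtered library search, ranked by match factor.

    Candidates are restricted to entries whose precursor neutral mass lies
    within the ppm window of the query's; charge states are distinct peptide
    ions, so by default the entry charge must equal the query charge.
    Ties are broken by entry id for determinism.
    """
    params = params or SearchParams()
    if not isinstance(library, LibraryIndex):
        library = LibraryIndex(library)
    qid = query_id or query.metadata.get("title", "query")
    qmass = query.neutral_mass
    tol = ppm_window(max(qmass, 1e-6), params.precursor_tol_ppm)
    hits = []
    for entry in library.candidates(qmass, tol):
        if require_charge_match and entry.ion.charge != query.charge:
            continue
        try:
            mf, nmatch = match_factor(query, entry.spectrum, params)
        except UnsearchableSpectrum:
            continue
        hits.append(SearchHit(qid, entry, mf, matched_peak_count=nmatch))
    hits.sort(key=lambda h: (-h.match_factor, h.entry.entry_id))
    for rank, h in enumerate(hits, start=1):
        h.rank = rank
    return hits
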