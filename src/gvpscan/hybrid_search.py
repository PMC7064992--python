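"""Open-modification ("hybrid") search, DeltaMass clustering and annotation.

A hybrid search drops the precursor filter (up to an open window, default
±200 Da) and lets each query peak match a library peak either at its nominal
position or shifted by the precursor DeltaMass (query neutral mass minus
library peptide neutral mass, shift applied at fragment charge 1).  Recurring
DeltaMass values reveal chemical modifications; a DeltaMass that happens to
fall within the precursor mass tolerance of an amino-acid substitution delta
is flagged as a *GVP mimic* — an artifact that could masquerade as a
genetically variant peptide (e.g. N-terminal acetaldehyde, +26.01565 Da,
versus His→Tyr, +26.004417 Da).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_masses import MassLedger, SubstitutionDelta, default_ledger, ppm_window
from .library_search import (
    LibraryIndex,
    SearchHit,
    SearchParams,
    UnsearchableSpectrum,
    preprocess,
)
from .spectra_io import LibraryEntry, Spectrum

__all__ = [
    "HybridHit",
    "DeltaMassCluster",
    "DeltaMassAnnotation",
    "hybrid_match",
    "hybrid_search",
    "deltamass_table",
    "annotate_delta",
    "classify_ions",
]


@dataclass
class HybridHit(SearchHit):
    delta_mass: float = 0.0
    direct_matched: int = 0
    shifted_matched: int = 0


@dataclass(frozen=True)
class DeltaMassCluster:
    representative: float  # 3-decimal label
    count: int
    percent: float  # of all hybrid identifications
    annotations: tuple[str, ...] = ()


@dataclass(frozen=True)
class DeltaMassAnnotation:
    observed: float
    candidates: tuple[tuple[str, float, float], ...]  # (name, theoretical, |diff|)
    mimic_warnings: tuple[SubstitutionDelta, ...]

    @property
    def best(self) -> str | None:
        return self.candidates[0][0] if self.candidates else None


def hybrid_match(
    query: Spectrum,
    entry: LibraryEntry,
    params: SearchParams | None = None,
    query_id: str | None = None,
) -> HybridHit:
    """Score a query against one entry allowing DeltaMass-shifted fragments.

    Direct and shifted candidate pairs compete in a single greedy one-to-one
    assignment ordered by m/z difference, so a zero DeltaMass reduces exactly
    to the regular match factor.
    """
    params = params or SearchParams()
    delta = query.neutral_mass - entry.spectrum.neutral_mass
    wq = preprocess(query, params)
    wl = preprocess(entry.spectrum, params)
    lib_mz = entry.spectrum.mz
    tol = np.maximum(lib_mz, 1e-6) * params.fragment_tol_ppm * 1e-6

    cands = []  # (diff, qi, lj, shifted?)
    for shifted_flag, shift in ((0, 0.0), (1, delta)):
        if shifted_flag and abs(delta) <= ppm_window(
            max(query.neutral_mass, 1.0), params.fragment_tol_ppm
        ):
            continue  # shift indistinguishable from direct matching
        target = lib_mz + shift
        diff = np.abs(query.mz[:, None] - target[None, :])
        ii, jj = np.nonzero(diff <= tol[None, :])
        cands.extend(
            (diff[i, j], i, j, shifted_flag) for i, j in zip(ii, jj)
        )
    cands.sort(key=lambda t: (t[0], t[3], t[1], t[2]))
    used_q: set[int] = set()
    used_l: set[int] = set()
    cosine = 0.0
    n_direct = n_shifted = 0
    for _d, i, j, shifted_flag in cands:
        if i in used_q or j in used_l:
            continue
        used_q.add(i)
        used_l.add(j)
        cosine += wq[i] * wl[j]
        if shifted_flag:
            n_shifted += 1
        else:
            n_direct += 1
    mf = int(round(999 * min(max(cosine, 0.0), 1.0)))
    return HybridHit(
        query_id=query_id or query.metadata.get("title", "query"),
        entry=entry,
        match_factor=mf,
        matched_peak_count=n_direct + n_shifted,
        delta_mass=delta,
        direct_matched=n_direct,
        shifted_matched=n_shifted,
    )


def hybrid_search(
    query: Spectrum,
    library: LibraryIndex | list[LibraryEntry],
    params: SearchParams | None = None,
    open_window: float = 200.0,
    query_id: str | None = None,
    require_charge_match: bool = True,
) -> list[HybridHit]:
    """Rank library entries within ±open_window Da of the query's neutral mass."""
    params = params or SearchParams()
    if not isinstance(library, LibraryIndex):
        library = LibraryIndex(library)
    hits = []
    for entry in library.candidates(query.neutral_mass, open_window):
        if require_charge_match and entry.ion.charge != query.charge:
            continue
        try:
            hit = hybrid_match(query, entry, params, query_id=query_id)
        except UnsearchableSpectrum:
            continue
        hits.append(hit)
    hits.sort(key=lambda h: (-h.match_factor, h.entry.entry_id))
    for rank, h in enumerate(hits, start=1):
        h.rank = rank
    return hits


def deltamass_table(
    hits: list[HybridHit],
    n: int = 20,
    cluster_width: float = 0.01,
    hist_bin_width: float = 0.01,
    ledger: MassLedger | None = None,
    annotation_tol: float = 0.02,
) -> tuple[list[DeltaMassCluster], pd.DataFrame]:
    """Top-n DeltaMass clusters plus a full histogram of all DeltaMass values.

    Values are rounded to 3 decimals; the mode bin seeds each cluster and
    absorbs all values within ±cluster_width of it, so percentages are over
    all hybrid identifications and sum to ≤100.
    """
    ledger = ledger or default_ledger()
    deltas = np.array([round(h.delta_mass, 3) for h in hits])
    total = len(deltas)
    # full histogram
    if total:
        lo = np.floor(deltas.min() / hist_bin_width) * hist_bin_width
        hi = np.ceil(deltas.max() / hist_bin_width) * hist_bin_width + hist_bin_width
        edges = np.arange(lo, hi + hist_bin_width / 2, hist_bin_width)
        counts, edges = np.histogram(deltas, bins=edges)
        hist = pd.DataFrame({"bin_left": edges[:-1], "count": counts})
        hist = hist[hist["count"] > 0].reset_index(drop=True)
    else:
        hist = pd.DataFrame({"bin_left": [], "count": []})

    clusters: list[DeltaMassCluster] = []
    remaining = deltas.copy()
    while len(remaining) and len(clusters) < n:
        values, counts = np.unique(remaining, return_counts=True)
        k = int(np.argmax(counts))  # ties: smallest value (np.unique is sorted)
        rep = float(values[k])
        member = np.abs(remaining - rep) <= cluster_width + 1e-12
        m = int(member.sum())
        ann = annotate_delta(rep, tol=annotation_tol, ledger=ledger)
        clusters.append(
            DeltaMassCluster(
                representative=round(rep, 3),
                count=m,
                percent=100.0 * m / total,
                annotations=tuple(name for name, _t, _d in ann.candidates[:3]),
            )
        )
        remaining = remaining[~member]
    clusters.sort(key=lambda c: (-c.count, c.representative))
    return clusters, hist


def _candidate_pool(ledger: MassLedger) -> list[tuple[str, float]]:
    """Annotation candidates: ledger entries, pairwise composites, isotope
    offsets, and entry ± small isotope offsets."""
    c13 = ledger.c13_offset
    pool: dict[str, float] = {}
    names = sorted(ledger.modifications)
    for name in names:
        pool[name] = ledger.modification_delta(name)
    for k in range(-2, 6):
        if k == 0:
            continue
        label = f"{k}-C13" if k > 0 else f"{k}-C13"
        pool[label] = k * c13
    for i, a in enumerate(names):
        da = ledger.modification_delta(a)
        for b in names[i:]:
            label = f"{a} + {b}" if a != b else f"2x {a}"
            pool.setdefault(label, da + ledger.modification_delta(b))
        for k in (-2, -1, 1, 2):
            pool.setdefault(f"{a} + {k}-C13", da + k * c13)
    return sorted(pool.items())


def annotate_delta(
    observed: float,
    tol: float = 0.02,
    precursor_mass: float | None = None,
    ledger: MassLedger | None = None,
    precursor_tol_ppm: float = 20.0,
) -> DeltaMassAnnotation:
    """Propose modifications for an observed DeltaMass and flag GVP mimics.

    Candidates within ``tol`` Da are drawn from the ledger, composites of two
    entries, and C-13 isotope offsets.  Mimic warnings list every amino-acid
    substitution whose delta falls inside the precursor's ppm tolerance
    window of the observed value — the condition under which an artifact is
    indistinguishable from a variant peptide by precursor mass alone.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ledger = ledger or default_ledger()
    if abs(observed) <= tol and abs(observed) < 0.005:
        cands = [("unmodified", 0.0, abs(observed))]
        return DeltaMassAnnotation(observed, tuple(cands), ())
    cands = [
        (name, theo, abs(theo - observed))
        for name, theo in _candidate_pool(ledger)
        if abs(theo - observed) <= tol
    ]
    cands.sort(key=lambda t: (t[2], t[0]))
    warnings_: tuple[SubstitutionDelta, ...] = ()
    if precursor_mass is not None:
        window = ppm_window(precursor_mass, precursor_tol_ppm)
        warnings_ = tuple(ledger.ambiguous_substitutions(observed, window))
    return DeltaMassAnnotation(observed, tuple(cands), warnings_)


@dataclass
class IonClassification:
    """Partition of query spectra into identified / hybrid-identified / not."""

    identified: list[SearchHit]
    hybrid_identified: list[HybridHit]
    not_identified: list[str]  # query ids
    n_spectra: int
    table: pd.DataFrame = field(repr=False, default=None)

    @property
    def fractions(self) -> dict[str, float]:
        n = max(self.n_spectra, 1)
        return {
            "identified": len(self.identified) / n,
            "hybrid_identified": len(self.hybrid_identified) / n,
            "not_identified": len(self.not_identified) / n,
        }


def classify_ions(
    queries: list[Spectrum],
    library: list[LibraryEntry],
    params: SearchParams | None = None,
    open_window: float = 200.0,
    alpha: float = 0.01,
    decoy_seed: int = 0,
    ledger: MassLedger | None = None,
) -> IonClassification:
    """Classify each query as identified, hybrid-identified, or not identified.

    Regular and hybrid searches each run against a concatenated target-decoy
    library and are thresholded at ``alpha`` FDR independently; a spectrum
    identified by the regular search is not also counted as hybrid.  GVP ions
    are flagged as a sub-class via library annotations.
    """
    from .fdr_decoy import accept_at_fdr, make_decoys
    from .library_search import search as _search

    params = params or SearchParams()
    ledger = ledger or default_ledger()
    decoys = make_decoys(library, ledger=ledger, seed=decoy_seed)
    index = LibraryIndex(list(library) + list(decoys))

    best_regular: list[SearchHit] = []
    best_hybrid: list[HybridHit] = []
    qids = []
    for i, q in enumerate(queries):
        qid = q.metadata.get("title", f"query_{i}")
        qids.append(qid)
        hits = _search(q, index, params, query_id=qid)
        if hits:
            best_regular.append(hits[0])
        hhits = hybrid_search(q, index, params, open_window, query_id=qid)
        if hhits:
            best_hybrid.append(hhits[0])

    accepted_reg = {h.query_id: h for h in accept_at_fdr(best_regular, alpha)}
    accepted_hyb = {h.query_id: h for h in accept_at_fdr(best_hybrid, alpha)}

    identified, hybrid_identified, not_identified = [], [], []
    rows = []
    for qid in qids:
        if qid in accepted_reg:
            cls, hit = "identified", accepted_reg[qid]
            identified.append(hit)
        elif qid in accepted_hyb:
            cls, hit = "hybrid_identified", accepted_hyb[qid]
            hybrid_identified.append(hit)
        else:
            cls, hit = "not_identified", None
            not_identified.append(qid)
        rows.append(
            {
                "query_id": qid,
                "class": cls,
                "ion": hit.entry.entry_id if hit else "",
                "match_factor": hit.match_factor if hit else np.nan,
                "delta_mass": getattr(hit, "delta_mass", np.nan) if hit else np.nan,
                "is_gvp": bool(hit.entry.gvp) if hit else False,
            }
        )
    table = pd.DataFrame(rows)
    return IonClassification(
        identified, hybrid_identified, not_identified, len(queries), table
    )
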