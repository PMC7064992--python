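"""Fraction-resolved GVP panel assembly with confidence tiers and mimic warnings.

A panel row collects, for one variant site, every accepted identification of
the variant and nonvariant peptide ions across the ten gel fractions
(F1..F10), their intensity profiles, the fraction of maximum intensity, a
confidence tier, and warnings about artifactual mass shifts that could mimic
the site's substitution.

Confidence tiers, strongest first:

- ``paired_consistent`` — both alleles observed, intensity maxima within
  ±1 fraction (co-migration of the two allelic forms).
- ``paired`` — both alleles observed.
- ``variant_only_asymmetric`` — nonvariant absent, but the pair is
  K/R-asymmetric, so its absence is structurally expected (the nonvariant is
  a different tryptic backbone).
- ``variant_only`` — nonvariant absent with no structural excuse
  (legitimate for a homozygous source, otherwise weak evidence).
- ``low_confidence`` — best match factor below the configured floor, or a
  single observation in a single fraction.

Abundance proxy: the precursor intensity recorded with the assigned MS/MS
spectrum (summed matched fragment intensity when absent).  MS1 chromatogram
peak areas would be the direct measure but require profile MS1 data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_masses import MassLedger, default_ledger, ppm_window
from .library_search import SearchHit
from .variant_digest import GVPPair, name_gvp

__all__ = [
    "FRACTIONS",
    "IonObservation",
    "FractionRun",
    "PanelRow",
    "fraction_profile",
    "assemble_panel",
    "compare_runs",
    "panel_to_frame",
]

FRACTIONS = tuple(f"F{i}" for i in range(1, 11))

TIER_ORDER = (
    "paired_consistent",
    "paired",
    "variant_only_asymmetric",
    "variant_only",
    "low_confidence",
)


@dataclass(frozen=True)
class IonObservation:
    ion_id: str  # peptide-ion notation
    gvp: str | None  # GVP annotation "GENE RefPosAlt_Obs" if any
    gene: str | None
    intensity: float
    match_factor: int
    q_value: float | None
    sequence: str


@dataclass
class FractionRun:
    """Accepted identifications from one gel fraction (or a combined run)."""

    fraction: str  # "F1".."F10" or "combined"
    observations: list[IonObservation]
    source_file: str = ""

    @classmethod
    def from_hits(
        cls,
        fraction: str,
        hits: list[SearchHit],
        spectra_by_id: dict | None = None,
        source_file: str = "",
    ) -> "FractionRun":
        """Build a run from FDR-accepted hits; the most abundant observation
        of each peptide ion carries its intensity."""
        best: dict[str, IonObservation] = {}
        for h in hits:
            intensity = 0.0
            if spectra_by_id and h.query_id in spectra_by_id:
                spec = spectra_by_id[h.query_id]
                intensity = spec.metadata.get(
                    "precursor_intensity", float(np.sum(spec.intensity))
                )
            obs = IonObservation(
                ion_id=h.entry.entry_id,
                gvp=h.entry.gvp,
                gene=h.entry.annotations.get("Gene"),
                intensity=intensity,
                match_factor=h.match_factor,
                q_value=h.q_value,
                sequence=h.entry.ion.sequence,
            )
            prev = best.get(obs.ion_id)
            if prev is None or obs.intensity > prev.intensity:
                best[obs.ion_id] = obs
        return cls(fraction, list(best.values()), source_file)


def identify_runs(
    run_spectra: dict[str, list],
    library: list,
    params=None,
    alpha: float = 0.01,
    decoy_seed: int = 0,
    ledger: MassLedger | None = None,
) -> dict[str, FractionRun]:
    """Search every run against a concatenated target-decoy library and keep
    the best hit per spectrum; q-values are estimated over the pooled hit
    list (one search mode, one FDR) and runs are returned as accepted
    :class:`FractionRun` objects."""
    from .fdr_decoy import accept_at_fdr, make_decoys
    from .library_search import LibraryIndex, SearchParams
    from .library_search import search as _search

    ledger = ledger or default_ledger()
    params = params or SearchParams()
    decoys = make_decoys(library, ledger=ledger, seed=decoy_seed)
    index = LibraryIndex(list(library) + list(decoys))
    best_hits: list[SearchHit] = []
    hit_run: dict[str, str] = {}
    spectra_by_id: dict[str, object] = {}
    for run_id, spectra in run_spectra.items():
        for i, q in enumerate(spectra):
            qid = q.metadata.get("title", f"{run_id} query_{i}")
            hits = _search(q, index, params, query_id=qid)
            if not hits:
                continue
            best_hits.append(hits[0])
            hit_run[qid] = run_id
            spectra_by_id[qid] = q
    accepted = accept_at_fdr(best_hits, alpha)
    runs_out: dict[str, FractionRun] = {}
    for run_id in run_spectra:
        run_hits = [h for h in accepted if hit_run[h.query_id] == run_id]
        runs_out[run_id] = FractionRun.from_hits(run_id, run_hits, spectra_by_id)
    return runs_out


def fraction_profile(
    ion_key: str, runs: list[FractionRun], by: str = "gvp"
) -> tuple[np.ndarray, str | None]:
    """Intensity vector over F1..F10 for one ion/GVP key plus argmax fraction.

    Missing fractions are zero; ties go to the lower fraction index; an
    all-zero profile has no argmax (the form is absent).
    """
    if not runs:
        raise ValueError("need at least one fraction run")
    profile = np.zeros(len(FRACTIONS))
    for run in runs:
        if run.fraction not in FRACTIONS:
            continue
        idx = FRACTIONS.index(run.fraction)
        for obs in run.observations:
            key = obs.gvp if by == "gvp" else obs.ion_id
            if key == ion_key:
                # per fraction, an ion is measured by its most abundant form
                profile[idx] = max(profile[idx], obs.intensity)
    if not profile.any():
        return profile, None
    return profile, FRACTIONS[int(np.argmax(profile))]


@dataclass
class PanelRow:
    pair: GVPPair
    variant_name: str
    nonvariant_name: str
    variant_profile: np.ndarray
    nonvariant_profile: np.ndarray
    variant_argmax: str | None
    nonvariant_argmax: str | None
    variant_observations: int
    nonvariant_observations: int
    best_match_factor: int
    tier: str
    mimic_warnings: tuple[str, ...] = ()
    protein_peptide_count: int = 0

    @property
    def detected(self) -> bool:
        # combined runs carry observations without a fraction coordinate
        return self.variant_observations > 0 and self.tier != "low_confidence"

    @property
    def protein_supported(self) -> bool:
        return self.protein_peptide_count >= 2


def _site_observations(
    name: str, runs: list[FractionRun]
) -> list[tuple[str, IonObservation]]:
    out = []
    for run in runs:
        for obs in run.observations:
            if obs.gvp == name:
                out.append((run.fraction, obs))
    return out


def assemble_panel(
    runs: list[FractionRun],
    gvp_pairs: list[GVPPair],
    hybrid_hits: list | None = None,
    mf_floor: int = 600,
    consistency_tol: int = 1,
    ledger: MassLedger | None = None,
    precursor_tol_ppm: float = 20.0,
) -> list[PanelRow]:
    """One panel row per GVP site from FDR-accepted fraction runs.

    ``hybrid_hits`` (optional, FDR-accepted open-search hits) feed the mimic
    warnings: any hybrid DeltaMass within the precursor ppm window of a
    site's substitution delta means an artifact could be masquerading as
    that variant.
    """
    ledger = ledger or default_ledger()
    # protein-level support: distinct peptide sequences per gene
    gene_peptides: dict[str, set[str]] = {}
    for run in runs:
        for obs in run.observations:
            if obs.gene:
                gene_peptides.setdefault(obs.gene, set()).add(obs.sequence)

    rows = []
    for pair in gvp_pairs:
        vname = name_gvp(pair.gene, pair.site, pair.site.alt_aa)
        nname = name_gvp(pair.gene, pair.site, pair.site.ref_aa)
        vprof, vmax = fraction_profile(vname, runs)
        nprof, nmax = fraction_profile(nname, runs)
        vobs = _site_observations(vname, runs)
        nobs = _site_observations(nname, runs)
        best_mf = max((o.match_factor for _f, o in vobs), default=0)

        if vobs and nobs:
            if (
                vmax is not None
                and nmax is not None
                and abs(FRACTIONS.index(vmax) - FRACTIONS.index(nmax))
                <= consistency_tol
            ):
                tier = "paired_consistent"
            else:
                tier = "paired"
        elif vobs and not pair.symmetric:
            tier = "variant_only_asymmetric"
        elif vobs:
            tier = "variant_only"
        else:
            tier = "low_confidence"
        if vobs:
            # a lone observation in a single gel fraction is weak evidence
            # unless the nonvariant form corroborates the site; combined runs
            # have no fraction coordinate and are exempt
            fraction_obs = [f for f, _o in vobs if f in FRACTIONS]
            singleton = (
                len(fraction_obs) == 1
                and len(vobs) == 1
                and tier not in ("paired_consistent", "paired")
            )
            if best_mf < mf_floor or singleton:
                tier = "low_confidence"

        warnings_: list[str] = []
        if hybrid_hits:
            sub_delta = ledger.substitution_delta(pair.site.ref_aa, pair.site.alt_aa)
            for h in hybrid_hits:
                dm = getattr(h, "delta_mass", None)
                if dm is None or abs(dm) < 1e-9:  # unmodified hit, no shift
                    continue
                pmass = h.entry.spectrum.neutral_mass
                if abs(dm - sub_delta) <= ppm_window(max(pmass, 1.0), precursor_tol_ppm):
                    warnings_.append(
                        f"DeltaMass {dm:+.4f} on {h.entry.entry_id} mimics "
                        f"{pair.site.ref_aa}->{pair.site.alt_aa} "
                        f"({sub_delta:+.6f})"
                    )

        rows.append(
            PanelRow(
                pair=pair,
                variant_name=vname,
                nonvariant_name=nname,
                variant_profile=vprof,
                nonvariant_profile=nprof,
                variant_argmax=vmax,
                nonvariant_argmax=nmax,
                variant_observations=len(vobs),
                nonvariant_observations=len(nobs),
                best_match_factor=best_mf,
                tier=tier,
                mimic_warnings=tuple(sorted(set(warnings_))),
                protein_peptide_count=len(gene_peptides.get(pair.gene, ())),
            )
        )
    return rows


def compare_runs(panels: dict[str, list[PanelRow]]) -> pd.DataFrame:
    """Presence/absence matrix: runs/methods as rows, GVP sites as columns.

    All panels must share the same GVP site universe (the layout mirrors a
    methods-by-sites detection table with X marks).
    """
    universes = {
        name: tuple(r.variant_name for r in rows) for name, rows in panels.items()
    }
    first = next(iter(universes.values()), ())
    for name, uni in universes.items():
        if set(uni) != set(first):
            raise ValueError(f"panel {name!r} has a different GVP site universe")
    sites = list(first)
    data = {}
    for name, rows in panels.items():
        detected = {r.variant_name: ("X" if r.detected else "") for r in rows}
        data[name] = [detected[s] for s in sites]
    return pd.DataFrame.from_dict(data, orient="index", columns=sites)


def panel_to_frame(rows: list[PanelRow]) -> pd.DataFrame:
    """Long-format evidence table for TSV export."""
    recs = []
    for r in rows:
        recs.append(
            {
                "gene": r.pair.gene,
                "site": r.pair.site.label,
                "variant_name": r.variant_name,
                "nonvariant_name": r.nonvariant_name,
                "symmetric": r.pair.symmetric,
                "tier": r.tier,
                "variant_argmax": r.variant_argmax or "",
                "nonvariant_argmax": r.nonvariant_argmax or "",
                "variant_observations": r.variant_observations,
                "nonvariant_observations": r.nonvariant_observations,
                "best_match_factor": r.best_match_factor,
                "protein_peptide_count": r.protein_peptide_count,
                "protein_supported": r.protein_supported,
                "mimic_warnings": "; ".join(r.mimic_warnings),
                "variant_profile": ",".join(f"{x:.1f}" for x in r.variant_profile),
                "nonvariant_profile": ",".join(
                    f"{x:.1f}" for x in r.nonvariant_profile
                ),
            }
        )
    return pd.DataFrame(recs)
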