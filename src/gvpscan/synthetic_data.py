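"""Synthetic proteomes, spectral libraries and gel-fraction runs with ground truth.

The generator emulates the structure of a hair-shaft proteomics experiment:

- a proteome in four molecular-weight classes — type-I-keratin-like
  (46–52 kDa, gel fraction F7), type-II-like (53.5–64.8 kDa, F6), large
  (>250 kDa, F1–F2) and small (<30 kDa, F9–F10) — with tryptic K/R content
  around 11%;
- heterozygous single-residue variant sites, a configurable share of which
  touch K/R cleavage sites and therefore produce asymmetric variant/
  nonvariant peptide pairs;
- HCD-style b/y fragment spectra (y series above b), log-normal intensity
  noise and uniform chaff peaks;
- per-fraction intensity profiles: a Gaussian centered at the protein's
  MW-mapped fraction plus a uniform smear standing in for cross-linked
  material, so every protein's peptides leak into neighboring fractions;
- artifactual modification spikes (N-terminal acetyl, acetaldehyde, formyl,
  methyl, carbamyl) at rates mirroring their relative open-search
  frequencies, plus a fraction of pure-chaff spectra;
- a data-dependent-acquisition cap on spectra per run, which is what makes a
  "combined" (unfractionated) run lose low-abundance ions.

Everything is driven by one seed; identical parameters and seed give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .chem_masses import MassLedger, default_ledger
from .fragments import fragment_ladder
from .spectra_io import (
    LibraryEntry,
    PeptideIon,
    Spectrum,
    write_mgf,
    write_msp,
)
from .variant_digest import (
    GVPPair,
    ProteinRecord,
    VariantSite,
    digest,
    gvp_pair,
    name_gvp,
    write_variant_sites,
)

__all__ = ["SimParams", "GroundTruthManifest", "Simulation",
           "make_proteome", "simulate_spectrum", "simulate_fraction_runs"]

# residue sampling frequencies: roughly vertebrate-average composition with
# K+R tuned to ~11% so tryptic peptide lengths are realistic
_AA_FREQS = {
    "A": 0.075, "C": 0.025, "D": 0.050, "E": 0.062, "F": 0.038,
    "G": 0.068, "H": 0.022, "I": 0.050, "K": 0.055, "L": 0.090,
    "M": 0.022, "N": 0.040, "P": 0.048, "Q": 0.042, "R": 0.055,
    "S": 0.075, "T": 0.052, "V": 0.062, "W": 0.012, "Y": 0.029,
}

# average residue mass for MW bookkeeping
_MEAN_RESIDUE_DA = 110.0

#: length ranges (residues) per MW class
MW_CLASSES = {
    "type_I": (420, 470),   # ~46-52 kDa
    "type_II": (490, 590),  # ~53.5-64.8 kDa
    "large": (2300, 2700),  # >250 kDa
    "small": (140, 260),    # <30 kDa
}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic experiment."""

    seed: int = 0
    class_counts: dict = field(
        default_factory=lambda: {"type_I": 6, "type_II": 6, "large": 2, "small": 6}
    )
    #: probability that a protein carries one variant site
    variant_density: float = 0.7
    #: share of variant sites that touch a K/R cleavage site (asymmetric pairs)
    kr_site_fraction: float = 0.2
    #: expression share of the variant allele (heterozygous source)
    allele_ratio: float = 0.5
    #: per-modification spike probability per emitted spectrum
    mod_spike_rates: dict = field(
        default_factory=lambda: {
            "Acetyl": 0.06,
            "Acetaldehyde": 0.035,
            "Methyl": 0.03,
            "Formyl": 0.02,
            "Carbamyl": 0.015,
        }
    )
    #: share of spectra per run that are pure chaff
    chaff_fraction: float = 0.2
    #: multiplicative log-normal intensity noise (sigma of ln intensity)
    noise_sigma: float = 0.3
    #: protein abundance: 10**Normal(mean, sigma), arbitrary units
    abundance_log10_mean: float = 6.3
    abundance_log10_sigma: float = 0.3
    #: per-peptide release efficiency: 10**Normal(0, sigma)
    peptide_eff_log10_sigma: float = 0.25
    #: chaff peaks added per spectrum, as a fraction of real peaks
    chaff_peak_fraction: float = 0.3
    #: precursor m/z error, ppm (1 s.d.)
    precursor_ppm_sigma: float = 3.0
    #: Gaussian width (in fractions) of a protein's gel profile; bands are
    #: mostly confined to one slice with spillover into adjacent ones
    fraction_sigma: float = 0.6
    #: uniform cross-link smear weight (share of protein mass spread evenly)
    smear_weight: float = 0.08
    #: emission floor for per-fraction ion intensity (arbitrary units)
    intensity_floor: float = 4.0e4
    #: DDA cap: top-N spectra by precursor intensity per run
    spectra_per_run_cap: int = 1000
    #: pooling 10 fractions into one injection at fixed load dilutes each
    #: component roughly this factor relative to its own fraction
    combined_dilution: float = 10.0
    #: y-series over b-series intensity weight
    y_over_b: float = 2.0
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 50

    def validate(self) -> None:
        for name, rate in [
            ("variant_density", self.variant_density),
            ("kr_site_fraction", self.kr_site_fraction),
            ("allele_ratio", self.allele_ratio),
            ("chaff_fraction", self.chaff_fraction),
            *[(f"spike[{k}]", v) for k, v in self.mod_spike_rates.items()],
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass
class GroundTruthManifest:
    """Per-spectrum origin records; every generated spectrum appears once."""

    records: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.records.append(kw)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1)

    def spectra_for(self, **criteria) -> list[dict]:
        return [
            r for r in self.records if all(r.get(k) == v for k, v in criteria.items())
        ]


# -- proteome ----------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(_AA_FREQS))
    probs = np.array(list(_AA_FREQS.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


_CLASS_GENE_PREFIX = {
    "type_I": "KTA",
    "type_II": "KTB",
    "large": "BIG",
    "small": "KAP",
}


def make_proteome(
    params: SimParams,
) -> tuple[list[ProteinRecord], list[VariantSite], list[GVPPair], dict[str, str]]:
    """Random proteome + variant sites + validated GVP pairs.

    Returns (proteins, sites, pairs, protein class map).  Site sampling
    retries until the intended symmetry class is realized: symmetric sites
    avoid K/R on both alleles; asymmetric sites either abolish a cleavage
    site (ref K/R -> non-K/R alt) or create one (alt K/R).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    proteins: list[ProteinRecord] = []
    classes: dict[str, str] = {}
    idx = 0
    for cls, count in params.class_counts.items():
        lo, hi = MW_CLASSES[cls]
        for _ in range(count):
            idx += 1
            gene = f"{_CLASS_GENE_PREFIX[cls]}{idx}"
            length = int(rng.integers(lo, hi + 1))
            proteins.append(
                ProteinRecord(gene, f"SYN|{gene}", _random_sequence(rng, length))
            )
            classes[gene] = cls

    sites: list[VariantSite] = []
    pairs: list[GVPPair] = []
    non_kr = [a for a in _AA_FREQS if a not in "KR"]
    kw = dict(
        max_missed=params.max_missed, min_len=params.min_len, max_len=params.max_len
    )
    for prot in proteins:
        if rng.random() >= params.variant_density:
            continue
        want_asymmetric = rng.random() < params.kr_site_fraction
        site = _sample_site(rng, prot, want_asymmetric, non_kr, kw)
        if site is None:
            continue
        sites.append(site)
        pairs.append(gvp_pair(prot, site, **kw))
    return proteins, sites, pairs, classes


def _sample_site(rng, prot, want_asymmetric, non_kr, digest_kw, tries=200):
    seq = prot.sequence
    n = len(seq)
    for _ in range(tries):
        pos = int(rng.integers(2, n))  # avoid position 1 (initiator-like)
        ref = seq[pos - 1]
        if want_asymmetric:
            if ref in "KR":
                alt = str(rng.choice([a for a in non_kr if a != "P"]))
            else:
                if ref == "P":
                    continue
                alt = str(rng.choice(["K", "R"]))
        else:
            if ref in "KR" or ref == "P":
                continue
            # I<->L is massless and undetectable by MS; never implant it
            forbidden = {ref, "P"} | ({"I", "L"} if ref in "IL" else set())
            alt = str(rng.choice([a for a in non_kr if a not in forbidden]))
        site = VariantSite(prot.gene, pos, ref, alt)
        try:
            pair = gvp_pair(prot, site, **digest_kw)
        except ValueError:
            continue
        if pair.symmetric == (not want_asymmetric) and pair.nonvariant_peptide is not None:
            if not pair.symmetric or 6 <= len(pair.variant_peptide.sequence) <= 50:
                return site
    return None


# -- spectra -----------------------------------------------------------------


def _fixed_cam_mods(sequence: str) -> tuple:
    return tuple(
        (i + 1, "C", "Carbamidomethyl")
        for i, aa in enumerate(sequence)
        if aa == "C"
    )


def peptide_ion(sequence: str, ledger: MassLedger | None = None) -> PeptideIon:
    """Canonical ion for a tryptic peptide: CAM on every Cys, charge by length."""
    charge = 2 if len(sequence) <= 14 else 3
    return PeptideIon(sequence, charge, _fixed_cam_mods(sequence))


def theoretical_spectrum(
    ion: PeptideIon,
    ledger: MassLedger | None = None,
    y_over_b: float = 2.0,
) -> Spectrum:
    """Noise-free library-style spectrum: b/y ladder with a smooth positional
    intensity profile and the y series weighted above the b series."""
    ledger = ledger or default_ledger()
    frags = fragment_ladder(ion, ledger)
    n = len(ion.sequence)
    mz, inten = [], []
    for f in frags:
        base = 100.0 * np.exp(-0.5 * ((f.index - n / 2) / (n / 3.0)) ** 2)
        w = y_over_b if f.kind == "y" else 1.0
        w /= f.charge  # higher fragment charges are weaker
        mz.append(f.mz)
        inten.append(base * w)
    return Spectrum(
        np.array(mz),
        np.array(inten),
        precursor_mz=ion.precursor_mz(ledger),
        charge=ion.charge,
    )


def simulate_spectrum(
    ion: PeptideIon,
    rng: np.random.Generator,
    params: SimParams,
    ledger: MassLedger | None = None,
    implant: str | None = None,
    precursor_intensity: float = 1.0e5,
) -> Spectrum:
    """A noisy acquired spectrum of ``ion``; ``implant`` optionally adds an
    unexpected N-terminal modification (shifting the precursor and the whole
    b series) that only an open search can recover."""
    ledger = ledger or default_ledger()
    delta = 0.0 if implant is None else ledger.modification_delta(implant)
    frags = fragment_ladder(ion, ledger)
    n = len(ion.sequence)
    mz_list, int_list = [], []
    for f in frags:
        base = 100.0 * np.exp(-0.5 * ((f.index - n / 2) / (n / 3.0)) ** 2)
        w = (params.y_over_b if f.kind == "y" else 1.0) / f.charge
        # an N-terminal implant rides on every b ion
        shift = delta / f.charge if f.kind == "b" else 0.0
        mz_list.append(f.mz + shift)
        int_list.append(base * w)
    mz = np.array(mz_list)
    inten = np.array(int_list)
    if params.noise_sigma > 0:
        inten = inten * np.exp(rng.normal(0.0, params.noise_sigma, size=len(inten)))
    n_chaff = int(round(params.chaff_peak_fraction * len(mz)))
    if n_chaff:
        lo, hi = 100.0, max(float(mz.max()) + 50.0, 500.0)
        chaff_mz = rng.uniform(lo, hi, size=n_chaff)
        chaff_int = rng.uniform(0.0, 0.1 * float(inten.max()), size=n_chaff)
        mz = np.concatenate([mz, chaff_mz])
        inten = np.concatenate([inten, chaff_int])
    theo_mz = ion.precursor_mz(ledger) + delta / ion.charge
    ppm_err = rng.normal(0.0, params.precursor_ppm_sigma)
    precursor_mz = theo_mz * (1.0 + ppm_err * 1e-6)
    return Spectrum(
        mz,
        inten,
        precursor_mz=precursor_mz,
        charge=ion.charge,
        metadata={"precursor_intensity": float(precursor_intensity)},
    )


def chaff_spectrum(
    rng: np.random.Generator, params: SimParams, precursor_intensity: float
) -> Spectrum:
    """A spectrum from nothing in the library: random peaks, random precursor."""
    n = int(rng.integers(20, 60))
    mz = rng.uniform(120.0, 1400.0, size=n)
    inten = rng.uniform(1.0, 100.0, size=n)
    charge = int(rng.integers(2, 4))
    precursor_mz = rng.uniform(350.0, 1500.0)
    return Spectrum(
        mz, inten, precursor_mz=precursor_mz, charge=charge,
        metadata={"precursor_intensity": float(precursor_intensity)},
    )


# -- fraction runs -----------------------------------------------------------

# log-linear MW -> fraction calibration anchored on the keratin bands:
# ~59 kDa (type II) migrates to F6, ~49 kDa (type I) to F7
_ANCHORS = ((np.log10(59_000.0), 6.0), (np.log10(49_000.0), 7.0))
_MAP_B = (_ANCHORS[1][1] - _ANCHORS[0][1]) / (_ANCHORS[1][0] - _ANCHORS[0][0])
_MAP_A = _ANCHORS[0][1] - _MAP_B * _ANCHORS[0][0]


def mw_to_fraction(mw_da: float) -> float:
    """Gel fraction center (1..10, clipped) for a protein molecular weight."""
    return float(np.clip(_MAP_A + _MAP_B * np.log10(mw_da), 1.0, 10.0))


def _fraction_weights(center: float, sigma: float, smear: float) -> np.ndarray:
    f = np.arange(1, 11, dtype=float)
    g = np.exp(-0.5 * ((f - center) / sigma) ** 2)
    g /= g.sum()
    return (1.0 - smear) * g + smear / 10.0


@dataclass
class Simulation:
    """Everything one simulated experiment produced."""

    params: SimParams
    proteins: list[ProteinRecord]
    sites: list[VariantSite]
    pairs: list[GVPPair]
    classes: dict[str, str]
    library: list[LibraryEntry]
    runs: dict[str, list[Spectrum]]  # fraction id -> query spectra
    manifest: GroundTruthManifest

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from pyteomics import fasta as _fasta

        _fasta.write(
            [(f"{p.accession} GN={p.gene}", p.sequence) for p in self.proteins],
            str(out / "proteome.fasta"),
            file_mode="w",
        )
        write_variant_sites(self.sites, out / "variant_sites.tsv")
        write_msp(self.library, out / "library.msp")
        for fraction, spectra in self.runs.items():
            write_mgf(spectra, out / f"{fraction}.mgf")
        self.manifest.write(out / "manifest.json")


def simulate_fraction_runs(
    params: SimParams | None = None,
    ledger: MassLedger | None = None,
    combined: bool = False,
) -> Simulation:
    """Simulate the full experiment: proteome, library, F1..F10 runs, manifest.

    With ``combined=True`` a single run labeled "combined" is produced by
    pooling all fraction content and applying the same spectra-per-run cap,
    which suppresses low-abundance ions exactly as a one-shot analysis does.
    """
    params = params or SimParams()
    params.validate()
    ledger = ledger or default_ledger()
    rng = np.random.default_rng(params.seed)
    proteins, sites, pairs, classes = make_proteome(params)
    site_by_gene = {s.gene: s for s in sites}
    pair_by_gene = {p.gene: p for p in pairs}

    # --- emission universe: (gene, peptide sequence, allele, gvp name) -----
    emission: list[tuple[str, str, str | None, str | None, float]] = []
    library_index: dict[str, LibraryEntry] = {}
    abundances: dict[str, float] = {}
    for prot in proteins:
        abundances[prot.gene] = 10.0 ** rng.normal(
            params.abundance_log10_mean, params.abundance_log10_sigma
        )
        peptides = {
            p.sequence
            for p in digest(
                prot.sequence, max_missed=0,
                min_len=params.min_len, max_len=params.max_len,
            )
        }
        pair = pair_by_gene.get(prot.gene)
        var_seq = nonvar_seq = None
        if pair is not None:
            var_seq = pair.variant_peptide.sequence
            nonvar_seq = (
                pair.nonvariant_peptide.sequence if pair.nonvariant_peptide else None
            )
            peptides.discard(var_seq)
            peptides.add(var_seq)
            if nonvar_seq:
                peptides.add(nonvar_seq)
        for seq in sorted(peptides):
            allele = None
            gvp = None
            share = 1.0
            if pair is not None and seq == var_seq:
                allele = pair.site.alt_aa
                gvp = name_gvp(prot.gene, pair.site, allele)
                share = params.allele_ratio
            elif pair is not None and seq == nonvar_seq and pair.symmetric:
                # the nonvariant backbone of an asymmetric pair is a
                # different peptide, not an allelic form; it is emitted as an
                # ordinary peptide without a GVP annotation
                allele = pair.site.ref_aa
                gvp = name_gvp(prot.gene, pair.site, allele)
                share = 1.0 - params.allele_ratio
            elif pair is not None and pair.nonvariant_peptide is not None:
                # peptides overlapping the site exist once per allele; all
                # other peptides come from both alleles (share 1)
                pass
            eff = 10.0 ** rng.normal(0.0, params.peptide_eff_log10_sigma)
            emission.append((prot.gene, seq, allele, gvp, share * eff))

    # --- library: canonical ion per emitted peptide ------------------------
    for gene, seq, allele, gvp, _w in emission:
        ion = peptide_ion(seq, ledger)
        if ion.notation in library_index:
            continue
        entry = LibraryEntry(
            ion,
            theoretical_spectrum(ion, ledger, y_over_b=params.y_over_b),
            annotations={"Gene": gene, **({"GVP": gvp} if gvp else {})},
        )
        library_index[ion.notation] = entry
    library = list(library_index.values())

    # --- per-run emission ---------------------------------------------------
    # fractionated mode: each run sees a protein's Gaussian+smear share;
    # combined mode: one run sees each ion once, diluted by pooling
    manifest = GroundTruthManifest()
    if combined:
        run_ids = ["combined"]
    else:
        run_ids = [f"F{i}" for i in range(1, 11)]
    raw_runs: dict[str, list[tuple[float, Spectrum, dict]]] = {
        r: [] for r in run_ids
    }
    spike_names = sorted(params.mod_spike_rates)
    protein_by_gene = {p.gene: p for p in proteins}
    for gene, seq, allele, gvp, eff in emission:
        center = mw_to_fraction(
            len(protein_by_gene[gene].sequence) * _MEAN_RESIDUE_DA
        )
        if combined:
            weights = [1.0 / params.combined_dilution]
        else:
            weights = _fraction_weights(
                center, params.fraction_sigma, params.smear_weight
            )
        ion = peptide_ion(seq, ledger)
        for run_id, w in zip(run_ids, weights):
            intensity = abundances[gene] * eff * w
            intensity *= np.exp(rng.normal(0.0, params.noise_sigma))
            if intensity < params.intensity_floor:
                continue
            spec = simulate_spectrum(
                ion, rng, params, ledger, precursor_intensity=intensity
            )
            record = {
                "origin": "peptide",
                "ion": ion.notation,
                "gene": gene,
                "gvp": gvp,
                "allele": allele,
                "implant": None,
                "fraction": run_id,
                "intended_intensity": float(intensity),
            }
            raw_runs[run_id].append((intensity, spec, record))
            for name in spike_names:
                if rng.random() < params.mod_spike_rates[name]:
                    sub_int = intensity * 10.0 ** rng.normal(-0.7, 0.3)
                    mspec = simulate_spectrum(
                        ion, rng, params, ledger,
                        implant=name, precursor_intensity=sub_int,
                    )
                    mrec = dict(record, implant=name,
                                intended_intensity=float(sub_int))
                    raw_runs[run_id].append((sub_int, mspec, mrec))

    # --- chaff -------------------------------------------------------------
    for run_id in run_ids:
        n_real = len(raw_runs[run_id])
        n_chaff = int(round(
            params.chaff_fraction / max(1e-9, 1 - params.chaff_fraction) * n_real
        ))
        for _ in range(n_chaff):
            intensity = 10.0 ** rng.normal(4.5, 0.4)
            spec = chaff_spectrum(rng, params, intensity)
            record = {
                "origin": "chaff", "ion": None, "gene": None, "gvp": None,
                "allele": None, "implant": None, "fraction": run_id,
                "intended_intensity": float(intensity),
            }
            raw_runs[run_id].append((intensity, spec, record))

    # --- DDA cap + titles --------------------------------------------------
    runs: dict[str, list[Spectrum]] = {}
    for run_id in run_ids:
        items = sorted(raw_runs[run_id], key=lambda t: -t[0])
        items = items[: params.spectra_per_run_cap]
        runs[run_id] = _finalize_run(run_id, items, manifest)

    return Simulation(
        params, proteins, sites, pairs, classes, library, runs, manifest
    )


def _finalize_run(run_id, items, manifest):
    spectra = []
    for k, (intensity, spec, record) in enumerate(items):
        title = f"{run_id} scan={k} " + (record["ion"] or "chaff")
        spec.metadata["title"] = title
        record = dict(record, spectrum_title=title, run=run_id)
        manifest.add(**record)
        spectra.append(spec)
    return spectra
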