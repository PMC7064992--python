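"""Open (DeltaMass) search, DeltaMass clustering, annotation and mimic flags."""

import numpy as np
import pytest

from gvpscan.chem_masses import ppm_window
from gvpscan.hybrid_search import (
    HybridHit,
    annotate_delta,
    classify_ions,
    deltamass_table,
    hybrid_match,
    hybrid_search,
)
from gvpscan.library_search import SearchParams, match_factor
from gvpscan.spectra_io import LibraryEntry, PeptideIon, Spectrum
from gvpscan.synthetic_data import (
    SimParams,
    chaff_spectrum,
    peptide_ion,
    simulate_spectrum,
    theoretical_spectrum,
)


def _entry(seq="HLQLAIR", charge=2):
    ion = PeptideIon(seq, charge)
    return LibraryEntry(ion, theoretical_spectrum(ion), {"Gene": "KRT99"})


class TestHybridMatch:
    def test_identical_spectrum_zero_delta(self, params):
        e = _entry()
        hit = hybrid_match(e.spectrum, e, params)
        assert hit.match_factor == 999
        assert hit.delta_mass == pytest.approx(0.0, abs=1e-9)
        assert hit.shifted_matched == 0

    def test_zero_delta_reduces_to_regular_match_factor(self, params, rng):
        e = _entry("DLNMDSVAEIK")
        q = simulate_spectrum(e.ion, rng, SimParams(precursor_ppm_sigma=0.0))
        hit = hybrid_match(q, e, params)
        mf, _ = match_factor(q, e.spectrum, params)
        assert hit.match_factor == mf

    @pytest.mark.parametrize("mod,delta", [("Acetyl", 42.010565), ("Methyl", 14.015650)])
    def test_implanted_nterm_shift_recovered(self, params, rng, ledger, mod, delta):
        e = _entry("SAMPLEPTIDEK")
        q = simulate_spectrum(
            e.ion, rng, SimParams(noise_sigma=0.0, chaff_peak_fraction=0.0,
                                  precursor_ppm_sigma=0.0),
            implant=mod,
        )
        hit = hybrid_match(q, e, params)
        assert hit.delta_mass == pytest.approx(delta, abs=1e-4)
        assert hit.shifted_matched > 0
        assert hit.match_factor >= 990  # all peaks recovered via the shift

    def test_suffix_shift_exhaustive_positions(self, params, ledger):
        # single-site modification anywhere on a 12-mer: shift the y ions
        # C-terminal of the site by hand and check full recovery
        e = _entry("AGLKESTFDVNR")
        delta = 42.010565
        n = len(e.ion.sequence)
        from gvpscan.fragments import fragment_ladder

        frags = fragment_ladder(e.ion, ledger)
        for site in range(1, n + 1):
            mz = []
            for f in frags:
                # mod at `site` rides on y_i when site within last i residues
                shifted = (f.kind == "y" and site > n - f.index) or (
                    f.kind == "b" and site <= f.index
                )
                mz.append(f.mz + (delta / f.charge if shifted else 0.0))
            q = Spectrum(
                np.array(mz),
                np.ones(len(mz)),
                e.spectrum.precursor_mz + delta / e.ion.charge,
                e.ion.charge,
            )
            hit = hybrid_match(q, e, params)
            assert hit.delta_mass == pytest.approx(delta, abs=1e-6)
            assert hit.direct_matched + hit.shifted_matched >= len(frags) * 0.9

    def test_artifact_mass_shift_on_seven_mer(self, params, rng):
        # acetaldehyde-like +26.0186 Da offset against the unmodified entry
        e = _entry("HLQLAIR")
        base = theoretical_spectrum(e.ion)
        q = Spectrum(
            base.mz + 26.0186,  # every fragment carries the adduct
            base.intensity,
            base.precursor_mz + 26.0186 / 2,
            2,
        )
        hits = hybrid_search(q, [e], params, open_window=200.0)
        assert hits and hits[0].delta_mass == pytest.approx(26.0186, abs=1e-3)

    def test_open_window_excludes_far_entries(self, params):
        e = _entry()
        q = Spectrum(
            e.spectrum.mz, e.spectrum.intensity,
            e.spectrum.precursor_mz + 150.0 / e.ion.charge, e.ion.charge,
        )
        assert hybrid_search(q, [e], params, open_window=200.0)
        assert not hybrid_search(q, [e], params, open_window=100.0)


def _hits_with_deltas(deltas):
    e = _entry()
    return [
        HybridHit(query_id=f"q{i}", entry=e, match_factor=900, delta_mass=d)
        for i, d in enumerate(deltas)
    ]


class TestDeltaMassTable:
    def test_implanted_ratio_recovered(self):
        hits = _hits_with_deltas([42.011] * 75 + [14.016] * 25)
        clusters, hist = deltamass_table(hits, n=5)
        assert [c.representative for c in clusters[:2]] == [42.011, 14.016]
        assert clusters[0].percent == pytest.approx(75.0)
        assert clusters[1].percent == pytest.approx(25.0)
        assert hist["count"].sum() == 100

    def test_all_zero_deltas_single_cluster(self):
        clusters, _ = deltamass_table(_hits_with_deltas([0.0] * 10))
        assert len(clusters) == 1
        assert clusters[0].representative == 0.0
        assert clusters[0].percent == 100.0

    def test_cluster_width_absorbs_jitter(self, rng):
        deltas = 42.0106 + rng.normal(0, 0.002, size=50)
        clusters, _ = deltamass_table(_hits_with_deltas(list(deltas)), cluster_width=0.01)
        assert clusters[0].count == 50


class TestAnnotateDelta:
    def test_acetaldehyde_vs_his_tyr_ambiguity(self, ledger):
        ann = annotate_delta(26.0186, tol=0.02, precursor_mass=875.54, ledger=ledger)
        assert ann.best == "Acetaldehyde"
        assert abs(dict((c[0], c[2]) for c in ann.candidates)["Acetaldehyde"] - 0.0030) < 5e-4
        assert any(s.label == "H->Y" for s in ann.mimic_warnings)

    def test_tight_tolerance_drops_candidate(self, ledger):
        ann = annotate_delta(26.0186, tol=0.0029, precursor_mass=875.54, ledger=ledger)
        assert all(c[0] != "Acetaldehyde" for c in ann.candidates)

    def test_without_precursor_no_mimic_check(self, ledger):
        ann = annotate_delta(26.0186, tol=0.02, ledger=ledger)
        assert ann.mimic_warnings == ()

    def test_zero_delta_is_unmodified(self, ledger):
        ann = annotate_delta(0.0, tol=0.02, ledger=ledger)
        assert ann.best == "unmodified"
        assert ann.mimic_warnings == ()

    def test_composite_formyl_acetyl(self, ledger):
        ann = annotate_delta(70.007, tol=0.02, precursor_mass=1500.0, ledger=ledger)
        assert "Formyl + Acetyl" in [c[0] for c in ann.candidates]

    def test_registered_values_self_annotate_on_top(self, ledger):
        for name in ledger.modifications:
            theo = ledger.modification_delta(name)
            if abs(theo) < 0.005:
                continue
            ann = annotate_delta(theo, tol=0.02, ledger=ledger)
            top_diff = ann.candidates[0][2]
            tied = [c[0] for c in ann.candidates if c[2] <= top_diff + 1e-12]
            assert name in tied, name

    def test_mimics_never_exceed_precursor_window(self, ledger):
        pmass = 1200.0
        ann = annotate_delta(14.0157, tol=0.05, precursor_mass=pmass, ledger=ledger)
        win = ppm_window(pmass, 20.0)
        assert all(abs(s.delta - 14.0157) <= win for s in ann.mimic_warnings)


class TestClassifyIons:
    def test_partition_is_exhaustive_and_disjoint(self, rng):
        entries = []
        for i in range(25):
            seq = "".join(rng.choice(list("ADEFGHILMNQSTVWY"), size=9)) + "R"
            entries.append(_entry(seq))
        sp = SimParams(seed=3)
        queries = []
        for i in range(30):
            e = entries[int(rng.integers(0, len(entries)))]
            queries.append(simulate_spectrum(e.ion, rng, sp))
        for i in range(8):
            e = entries[int(rng.integers(0, len(entries)))]
            queries.append(simulate_spectrum(e.ion, rng, sp, implant="Acetyl"))
        for i in range(10):
            queries.append(chaff_spectrum(rng, sp, 1e4))
        for i, q in enumerate(queries):
            q.metadata["title"] = f"q{i}"
        result = classify_ions(queries, entries, open_window=200.0)
        f = result.fractions
        assert sum(f.values()) == pytest.approx(1.0)
        n = len(result.identified) + len(result.hybrid_identified) + len(
            result.not_identified
        )
        assert n == len(queries)
        # chaff cannot be identified; implants need the open search
        assert len(result.not_identified) >= 8
        assert len(result.hybrid_identified) >= 4
        assert set(result.table["class"]) <= {
            "identified", "hybrid_identified", "not_identified"
        }
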