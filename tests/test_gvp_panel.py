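"""Panel assembly: tier rules, fraction profiles, run comparison, mimics."""

import numpy as np
import pytest

from gvpscan.gvp_panel import (
    FRACTIONS,
    FractionRun,
    IonObservation,
    assemble_panel,
    compare_runs,
    fraction_profile,
    panel_to_frame,
)
from gvpscan.hybrid_search import HybridHit
from gvpscan.spectra_io import LibraryEntry, PeptideIon
from gvpscan.synthetic_data import theoretical_spectrum
from gvpscan.variant_digest import GVPPair, ProteinRecord, TrypticPeptide, VariantSite, gvp_pair


def obs(gvp, intensity, mf=900, gene="KRT33A", seq="QVVSSSEQLQSYQAEIIELR"):
    return IonObservation(
        ion_id=f"{seq}/3_0", gvp=gvp, gene=gene, intensity=intensity,
        match_factor=mf, q_value=0.0, sequence=seq,
    )


def run(fraction, observations):
    return FractionRun(fraction, observations)


@pytest.fixture()
def pair():
    prot = ProteinRecord("KRT33A", "SYN|K33A", "MAAAKQVVSSSEQLQSYQAEIIELRGGGK")
    return gvp_pair(prot, VariantSite("KRT33A", 19, "A", "V"))


@pytest.fixture()
def asym_pair():
    seq = "MSSSSK" + "TYVIAASTMSVCSSDVGH" + "AAAAAK"
    prot = ProteinRecord("KRTAP10-8", "SYN|KAP", seq)
    return gvp_pair(prot, VariantSite("KRTAP10-8", 24, "H", "R"))


class TestFractionProfile:
    def test_single_nonzero(self):
        runs = [run("F6", [obs("X Y_Z", 50.0)])]
        profile, amax = fraction_profile("X Y_Z", runs)
        assert amax == "F6"
        assert profile[5] == 50.0 and profile.sum() == 50.0

    def test_all_zero_flagged_absent(self):
        profile, amax = fraction_profile("X Y_Z", [run("F3", [])])
        assert amax is None and not profile.any()

    def test_tie_goes_to_lower_fraction(self):
        runs = [run("F4", [obs("X", 10.0)]), run("F8", [obs("X", 10.0)])]
        assert fraction_profile("X", runs)[1] == "F4"

    def test_most_abundant_form_measures_ion(self):
        runs = [run("F2", [obs("X", 10.0), obs("X", 30.0)])]
        profile, _ = fraction_profile("X", runs)
        assert profile[1] == 30.0

    def test_requires_runs(self):
        with pytest.raises(ValueError):
            fraction_profile("X", [])


def _runs_for(pair, v_fracs, n_fracs, v_int=100.0, n_int=90.0, mf=900):
    vname = f"{pair.gene} {pair.site.label}_{pair.site.alt_aa}"
    nname = f"{pair.gene} {pair.site.label}_{pair.site.ref_aa}"
    runs = []
    for f in FRACTIONS:
        o = []
        if f in v_fracs:
            o.append(obs(vname, v_int, mf=mf, gene=pair.gene,
                         seq=pair.variant_peptide.sequence))
        if f in n_fracs and pair.nonvariant_peptide is not None:
            o.append(obs(nname, n_int, mf=mf, gene=pair.gene,
                         seq=pair.nonvariant_peptide.sequence))
        # a second peptide so the >=2-peptides protein rule is satisfied
        o.append(obs(None, 40.0, gene=pair.gene, seq="LLDLDSIIAEVK"))
        runs.append(run(f, o))
    return runs


class TestTiers:
    def test_co_migrating_alleles_paired_consistent(self, pair):
        rows = assemble_panel(_runs_for(pair, {"F7", "F8"}, {"F7"}), [pair])
        assert rows[0].tier == "paired_consistent"
        assert rows[0].variant_argmax in ("F7", "F8")
        assert rows[0].protein_supported

    def test_distant_maxima_only_paired(self, pair):
        rows = assemble_panel(_runs_for(pair, {"F2", "F3"}, {"F7", "F8"}), [pair])
        assert rows[0].tier == "paired"

    def test_asymmetric_without_nonvariant(self, asym_pair):
        rows = assemble_panel(
            _runs_for(asym_pair, {"F9", "F10"}, set()), [asym_pair]
        )
        assert rows[0].tier == "variant_only_asymmetric"

    def test_symmetric_without_nonvariant(self, pair):
        rows = assemble_panel(_runs_for(pair, {"F6", "F7"}, set()), [pair])
        assert rows[0].tier == "variant_only"

    def test_low_match_factor_demotes(self, pair):
        rows = assemble_panel(
            _runs_for(pair, {"F7", "F8"}, {"F7"}, mf=450), [pair], mf_floor=600
        )
        assert rows[0].tier == "low_confidence"

    def test_single_fraction_singleton_demotes(self, pair):
        vname = f"{pair.gene} {pair.site.label}_{pair.site.alt_aa}"
        runs = [run("F5", [obs(vname, 10.0, gene=pair.gene,
                               seq=pair.variant_peptide.sequence)])]
        rows = assemble_panel(runs, [pair])
        assert rows[0].tier == "low_confidence"
        assert not rows[0].detected

    def test_absent_site_is_low_confidence(self, pair):
        rows = assemble_panel([run("F1", [])], [pair])
        assert rows[0].tier == "low_confidence"
        assert rows[0].variant_argmax is None

    def test_mass_difference_matches_substitution_delta(self, pair, ledger):
        dm = ledger.peptide_mass(pair.variant_peptide.sequence) - ledger.peptide_mass(
            pair.nonvariant_peptide.sequence
        )
        assert dm == pytest.approx(
            ledger.substitution_delta(pair.site.ref_aa, pair.site.alt_aa), abs=1e-5
        )


class TestMimicWarnings:
    def test_coeluting_deltamass_flags_substitution(self, pair, ledger):
        # His->Tyr is +26.0044; an acetaldehyde artifact at +26.0157 on a
        # small precursor is outside 20 ppm, but a matching shift is flagged
        hy_pair_prot = ProteinRecord("HG", "A", "MSSSSKHLQLAIRAAAAAK")
        hy = gvp_pair(hy_pair_prot, VariantSite("HG", 7, "H", "Y"))
        ion = PeptideIon("HLQLAIR", 2)
        entry = LibraryEntry(ion, theoretical_spectrum(ion), {"Gene": "HG"})
        hit = HybridHit(
            query_id="q", entry=entry, match_factor=705,
            delta_mass=26.0186,
        )
        runs = _runs_for(hy, {"F5", "F6"}, {"F5"})
        rows = assemble_panel(runs, [hy], hybrid_hits=[hit])
        assert rows[0].mimic_warnings
        assert "H->Y" in rows[0].mimic_warnings[0]

    def test_unrelated_deltamass_not_flagged(self, pair):
        ion = PeptideIon("HLQLAIR", 2)
        entry = LibraryEntry(ion, theoretical_spectrum(ion), {"Gene": "X"})
        hit = HybridHit(query_id="q", entry=entry, match_factor=705,
                        delta_mass=57.0215)
        rows = assemble_panel(
            _runs_for(pair, {"F7"}, {"F7"}), [pair], hybrid_hits=[hit]
        )
        assert rows[0].mimic_warnings == ()


class TestCompareRuns:
    def test_identical_panels_identical_rows(self, pair):
        rows = assemble_panel(_runs_for(pair, {"F7", "F8"}, {"F7"}), [pair])
        m = compare_runs({"r1": rows, "r2": rows})
        assert (m.loc["r1"] == m.loc["r2"]).all()

    def test_missing_site_leaves_cell_empty(self, pair):
        present = assemble_panel(_runs_for(pair, {"F7", "F8"}, {"F7"}), [pair])
        absent = assemble_panel([run("F1", [])], [pair])
        m = compare_runs({"with": present, "without": absent})
        col = present[0].variant_name
        assert m.loc["with", col] == "X"
        assert m.loc["without", col] == ""

    def test_mismatched_universe_rejected(self, pair, asym_pair):
        a = assemble_panel(_runs_for(pair, {"F7"}, {"F7"}), [pair])
        b = assemble_panel(_runs_for(asym_pair, {"F9"}, set()), [asym_pair])
        with pytest.raises(ValueError, match="universe"):
            compare_runs({"a": a, "b": b})


def test_panel_frame_columns(pair):
    rows = assemble_panel(_runs_for(pair, {"F7", "F8"}, {"F7"}), [pair])
    df = panel_to_frame(rows)
    assert {"gene", "site", "tier", "variant_argmax", "protein_supported"} <= set(
        df.columns
    )
    assert df.loc[0, "symmetric"]
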