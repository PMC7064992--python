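"""Tryptic digestion against an exhaustive substring oracle, and GVP pairing."""

import numpy as np
import pytest

from gvpscan.chem_masses import default_ledger
from gvpscan.variant_digest import (
    GVPPair,
    ProteinRecord,
    VariantSite,
    digest,
    gvp_pair,
    name_gvp,
    read_proteome,
    read_variant_sites,
    write_variant_sites,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_digest(seq, max_missed, min_len, max_len, proline_rule):
    """Independent oracle: test every substring for tryptic validity."""
    def is_cut(i):  # cut between i-1 and i (0-based)
        if i == 0 or i == len(seq):
            return True
        if seq[i - 1] not in "KR":
            return False
        if proline_rule and seq[i] == "P":
            return False
        return True

    out = set()
    for start in range(len(seq)):
        for end in range(start + 1, len(seq) + 1):
            if not (is_cut(start) and is_cut(end)):
                continue
            internal = sum(1 for i in range(start + 1, end) if is_cut(i))
            if internal <= max_missed and min_len <= end - start <= max_len:
                out.add((seq[start:end], start + 1, end, internal))
    return out


class TestDigest:
    def test_printed_example(self):
        peps = digest("GASPKLYRPWTRAK", max_missed=0, min_len=6, max_len=50)
        assert [p.sequence for p in peps] == ["LYRPWTR"]

    def test_no_cleavage_sites_gives_whole_sequence(self):
        peps = digest("GASELW", max_missed=0, min_len=1, max_len=50)
        assert [p.sequence for p in peps] == ["GASELW"]

    def test_zero_missed_peptides_partition_protein(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list(AA), size=40))
            peps = digest(seq, max_missed=0, min_len=1, max_len=1000)
            assert "".join(p.sequence for p in peps) == seq

    def test_missed_cleavage_peptides_concatenate_zero_missed(self):
        seq = "AAKBBRCCKDDR".replace("B", "S")
        zero = digest(seq, max_missed=0, min_len=1, max_len=100)
        multi = digest(seq, max_missed=2, min_len=1, max_len=100)
        zero_by_start = {p.start: p for p in zero}
        for p in multi:
            parts = []
            pos = p.start
            while pos <= p.end:
                z = zero_by_start[pos]
                parts.append(z.sequence)
                pos = z.end + 1
            assert "".join(parts) == p.sequence
            assert len(parts) == p.missed_cleavages + 1

    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    @pytest.mark.parametrize("proline_rule", [True, False])
    def test_matches_exhaustive_oracle(self, rng, max_missed, proline_rule):
        for _ in range(60):
            n = int(rng.integers(1, 31))
            seq = "".join(rng.choice(list(AA), size=n))
            got = {
                (p.sequence, p.start, p.end, p.missed_cleavages)
                for p in digest(
                    seq, max_missed=max_missed, min_len=2, max_len=20,
                    proline_rule=proline_rule,
                )
            }
            assert got == oracle_digest(seq, max_missed, 2, 20, proline_rule)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest("")


class TestGvpPair:
    TOY = ProteinRecord("TOY", "SYN|TOY", "MAAAKQVVSSSEQLQSYQAEIIELRGGGK")

    def test_symmetric_pair_sequences(self):
        pair = gvp_pair(self.TOY, VariantSite("TOY", 19, "A", "V"))
        assert pair.variant_peptide.sequence == "QVVSSSEQLQSYQVEIIELR"
        assert pair.nonvariant_peptide.sequence == "QVVSSSEQLQSYQAEIIELR"
        assert pair.symmetric

    def test_symmetric_mass_difference_is_substitution_delta(self, ledger):
        pair = gvp_pair(self.TOY, VariantSite("TOY", 19, "A", "V"), ledger=ledger)
        dm = ledger.peptide_mass(pair.variant_peptide.sequence) - ledger.peptide_mass(
            pair.nonvariant_peptide.sequence
        )
        assert dm == pytest.approx(ledger.substitution_delta("A", "V"), abs=1e-5)

    def test_arg_to_gln_abolishes_cleavage(self):
        # ref ...K G[R]SEADSDK... ; R->Q removes the cut after position 7
        seq = "MAAAKG" + "R" + "SEADSDKNATILELR" + "SSSSSK"
        prot = ProteinRecord("DSP", "SYN|DSP", seq)
        pair = gvp_pair(prot, VariantSite("DSP", 7, "R", "Q"))
        assert not pair.symmetric
        assert "Q" in pair.variant_peptide.sequence
        assert pair.variant_peptide.start <= 7 <= pair.variant_peptide.end

    def test_new_arg_creates_cleavage_site(self):
        # H->R inside a long peptide splits it: variant ends at the new R
        seq = "MSSSSK" + "TYVIAASTMSVCSSDVGH" + "AAAAAK"
        prot = ProteinRecord("KAP", "SYN|KAP", seq)
        pair = gvp_pair(prot, VariantSite("KAP", 24, "H", "R"))
        assert not pair.symmetric
        assert pair.variant_peptide.sequence.endswith("R")
        assert pair.variant_peptide.sequence != pair.nonvariant_peptide.sequence

    def test_ref_mismatch_raises(self):
        with pytest.raises(ValueError, match="expected ref"):
            gvp_pair(self.TOY, VariantSite("TOY", 19, "S", "V"))

    def test_random_symmetric_pairs_respect_mass_invariant(self, rng, ledger):
        # random proteins, random non-K/R substitutions
        checked = 0
        while checked < 15:
            seq = "".join(rng.choice(list(AA), size=60))
            pos = int(rng.integers(5, 55))
            ref = seq[pos - 1]
            if ref in "KRP":
                continue
            alt = str(rng.choice([a for a in AA if a not in ("K", "R", "P", ref)]))
            try:
                pair = gvp_pair(
                    ProteinRecord("G1", "A1", seq),
                    VariantSite("G1", pos, ref, alt),
                    ledger=ledger,
                )
            except ValueError:
                continue
            if pair.symmetric:
                dm = ledger.peptide_mass(
                    pair.variant_peptide.sequence
                ) - ledger.peptide_mass(pair.nonvariant_peptide.sequence)
                assert dm == pytest.approx(
                    ledger.substitution_delta(ref, alt), abs=1e-5
                )
                checked += 1


class TestNaming:
    @pytest.mark.parametrize(
        "gene,site,obs,expected",
        [
            ("KRT33A", VariantSite("KRT33A", 270, "A", "V"), "V", "KRT33A A270V_V"),
            ("KRT33A", VariantSite("KRT33A", 270, "A", "V"), "A", "KRT33A A270V_A"),
            ("DSP", VariantSite("DSP", 1738, "R", "Q"), "Q", "DSP R1738Q_Q"),
        ],
    )
    def test_panel_names(self, gene, site, obs, expected):
        assert name_gvp(gene, site, obs) == expected

    def test_non_allele_rejected(self):
        with pytest.raises(ValueError):
            name_gvp("KRT33A", VariantSite("KRT33A", 270, "A", "V"), "G")


def test_fasta_and_site_table_io(tmp_path):
    fasta = tmp_path / "prot.fasta"
    fasta.write_text(">SYN|P1 GN=KRT99\nMAAAKQVVSSSEQK\n>P2 description\nGGGKLLLR\n")
    prots = read_proteome(fasta)
    assert [p.gene for p in prots] == ["KRT99", "P2"]
    assert prots[0].sequence == "MAAAKQVVSSSEQK"

    sites = [VariantSite("KRT99", 7, "V", "L")]
    path = tmp_path / "sites.tsv"
    write_variant_sites(sites, path)
    assert read_variant_sites(path) == sites
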