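"""In-silico tryptic digestion and variant/nonvariant peptide-pair generation.

A genetically variant peptide (GVP) is a tryptic peptide carrying a single
amino-acid substitution.  Its nonvariant counterpart carries the reference
residue — and is a *different* tryptic backbone whenever the substitution
creates or destroys a K/R cleavage site, which is why each pair records a
``symmetric`` flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from pyteomics import fasta as _fasta

from .chem_masses import MassLedger, default_ledger

__all__ = [
    "ProteinRecord",
    "VariantSite",
    "TrypticPeptide",
    "GVPPair",
    "digest",
    "gvp_pair",
    "name_gvp",
    "read_proteome",
    "read_variant_sites",
    "pairs_to_frame",
]

_STANDARD_AA = set("GASPVTCLINDQKEMHFRYW")


@dataclass(frozen=True)
class ProteinRecord:
    gene: str
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _STANDARD_AA
        if bad:
            raise ValueError(
                f"protein {self.gene}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class VariantSite:
    """One substitution site, e.g. KRT33A A270V (ref A, position 270, alt V)."""

    gene: str
    position: int  # 1-based residue index in the protein
    ref_aa: str
    alt_aa: str

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class TrypticPeptide:
    sequence: str
    start: int  # 1-based inclusive protein coordinates
    end: int
    missed_cleavages: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GVPPair:
    """A variant tryptic peptide with its nonvariant counterpart (if any)."""

    site: VariantSite
    gene: str
    variant_peptide: TrypticPeptide
    nonvariant_peptide: TrypticPeptide | None
    symmetric: bool


def digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    proline_rule: bool = True,
) -> list[TrypticPeptide]:
    """Tryptic digestion: cleave after K/R (not before P), allow missed cleavages.

    The length filter is applied last; coordinates are 1-based inclusive on
    the input sequence.  Peptides longer than 50 or shorter than 6 residues
    fall outside the search space and are dropped by default.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = cleavage_sites(sequence, proline_rule=proline_rule)
    # boundaries of zero-missed fragments: [0, *cuts, len]
    bounds = [0] + cuts + [len(sequence)]
    peptides = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for j in range(i, min(i + max_missed + 1, nfrag)):
            start, end = bounds[i], bounds[j + 1]
            pep = sequence[start:end]
            if min_len <= len(pep) <= max_len:
                peptides.append(
                    TrypticPeptide(pep, start + 1, end, missed_cleavages=j - i)
                )
    return peptides


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based cut points (cut between i-1 and i) after K/R, suppressed before P."""
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def _covering_peptide(
    peptides: list[TrypticPeptide], position: int
) -> TrypticPeptide | None:
    """Peptide covering a 1-based position; fewest missed cleavages, then
    shortest, then leftmost — a deterministic choice."""
    covering = [p for p in peptides if p.start <= position <= p.end]
    if not covering:
        return None
    return min(covering, key=lambda p: (p.missed_cleavages, len(p), p.start))


def gvp_pair(
    protein: ProteinRecord,
    site: VariantSite,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    proline_rule: bool = True,
    ledger: MassLedger | None = None,
) -> GVPPair:
    """Build the variant/nonvariant peptide pair for one substitution site.

    Both alleles are digested; the peptide covering the site is selected in
    each.  The pair is symmetric when both backbones are identical apart from
    the substituted residue — guaranteed to fail when the substitution
    touches a K/R cleavage site and the cleavage pattern differs.
    """
    seq = protein.sequence
    if not 1 <= site.position <= len(seq):
        raise ValueError(
            f"{protein.gene} {site.label}: position outside 1..{len(seq)}"
        )
    if seq[site.position - 1] != site.ref_aa:
        raise ValueError(
            f"{protein.gene} {site.label}: sequence has "
            f"{seq[site.position - 1]!r} at position {site.position}, "
            f"expected ref {site.ref_aa!r}"
        )
    alt_seq = seq[: site.position - 1] + site.alt_aa + seq[site.position :]
    kw = dict(
        max_missed=max_missed, min_len=min_len, max_len=max_len,
        proline_rule=proline_rule,
    )
    var_pep = _covering_peptide(digest(alt_seq, **kw), site.position)
    ref_pep = _covering_peptide(digest(seq, **kw), site.position)
    if var_pep is None:
        raise ValueError(
            f"{protein.gene} {site.label}: no allowed tryptic peptide covers "
            f"the variant site"
        )
    symmetric = (
        ref_pep is not None
        and ref_pep.start == var_pep.start
        and ref_pep.end == var_pep.end
        and _differ_only_at(ref_pep.sequence, var_pep.sequence,
                            site.position - var_pep.start)
    )
    if symmetric and ledger is not None:
        dm = ledger.peptide_mass(var_pep.sequence) - ledger.peptide_mass(
            ref_pep.sequence
        )
        expected = ledger.substitution_delta(site.ref_aa, site.alt_aa)
        assert abs(dm - expected) <= 1e-5
    return GVPPair(site, protein.gene, var_pep, ref_pep, symmetric)


def _differ_only_at(a: str, b: str, idx: int) -> bool:
    if len(a) != len(b):
        return False
    return all(x == y for i, (x, y) in enumerate(zip(a, b)) if i != idx)


def name_gvp(gene: str, site: VariantSite, observed_aa: str) -> str:
    """Panel name of an observed allele, e.g. ``"KRT33A A270V_V"``."""
    if observed_aa not in (site.ref_aa, site.alt_aa):
        raise ValueError(
            f"{observed_aa!r} is neither allele of {gene} {site.label}"
        )
    return f"{gene} {site.label}_{observed_aa}"


# -- I/O ---------------------------------------------------------------------

_GN_TOKEN_RE = re.compile(r"GN=(\S+)")


def read_proteome(path, gene_regex: str | None = None) -> list[ProteinRecord]:
    """Read a FASTA proteome; the gene name is parsed from the header.

    By default the ``GN=...`` token is used when present, else the first
    whitespace-delimited token; a custom regex (first non-empty group wins)
    can be supplied for other header conventions.
    """
    pattern = re.compile(gene_regex) if gene_regex else None
    records = []
    with _fasta.read(str(path)) as reader:
        for header, seq in reader:
            accession = header.split()[0]
            if pattern is not None:
                m = pattern.search(header)
                gene = next(
                    (g for g in (m.groups() if m else ()) if g), accession
                )
            else:
                m = _GN_TOKEN_RE.search(header)
                gene = m.group(1) if m else accession
            records.append(ProteinRecord(gene, accession, seq.upper()))
    return records


def read_variant_sites(path) -> list[VariantSite]:
    """Variant-site table: TSV with columns gene, position, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "ref": str, "alt": str})
    required = {"gene", "position", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"variant table needs columns {sorted(required)}")
    return [
        VariantSite(r.gene, int(r.position), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]


def write_variant_sites(sites: list[VariantSite], path) -> None:
    pd.DataFrame(
        [
            {"gene": s.gene, "position": s.position, "ref": s.ref_aa, "alt": s.alt_aa}
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def pairs_to_frame(pairs: list[GVPPair]) -> pd.DataFrame:
    """Long-format table of GVP pairs for TSV export."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "gene": p.gene,
                "site": p.site.label,
                "variant_peptide": p.variant_peptide.sequence,
                "nonvariant_peptide": (
                    p.nonvariant_peptide.sequence if p.nonvariant_peptide else ""
                ),
                "symmetric": p.symmetric,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "site", "variant_peptide", "nonvariant_peptide", "symmetric"],
    )
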