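# gvpscan

Identification of **genetically variant peptides (GVPs)** — tryptic peptides
carrying a single amino-acid substitution, the protein-level trace of a
nonsynonymous SNP — from shotgun proteomics data, as used in forensic hair
proteomics. Hair shaft keratins survive where DNA does not, and a panel of
GVP detections (e.g. `KRT33A A270V_V`) can help differentiate individuals.

The package implements the full desk-side analysis chain around a peptide
spectral library:

- **Mass ledger** (`chem_masses`): monoisotopic masses of elements, residues
  and named modification deltas built from elemental compositions (CAM
  +57.021464, acetyl +42.010565, acetaldehyde +26.015650, …), the ¹³C
  isotope-offset axis, and all 380 residue-substitution deltas.
- **Variant digestion** (`variant_digest`): in-silico tryptic digestion
  (cleave after K/R, not before P, configurable missed cleavages, 6–50
  residue window) and variant/nonvariant peptide-pair construction. When a
  substitution creates or destroys a K/R cleavage site the two allelic forms
  are *different* tryptic backbones; such pairs are flagged asymmetric.
- **Library search** (`library_search`): NIST-style match factor
  `MF = round(999 · cosθ)` between √-intensity-weighted peak vectors under a
  20 ppm precursor / 50 ppm fragment tolerance.
- **Open ("hybrid") search** (`hybrid_search`): drops the precursor filter
  up to ±200 Da and matches fragments at nominal *or* DeltaMass-shifted
  positions, where DeltaMass = query neutral mass − library peptide mass.
  Recurring DeltaMass values are clustered, annotated against the ledger,
  and checked for **GVP mimics** — artifacts whose mass shift falls within
  the precursor tolerance of a substitution delta (N-terminal acetaldehyde
  +26.0157 vs His→Tyr +26.0044 is the canonical trap).
- **Target-decoy FDR** (`fdr_decoy`): reversed-sequence decoys (C-terminal
  residue fixed), q-values from `FDR(s) = #decoy≥s / max(1, #target≥s)`,
  acceptance at 1 % by default.
- **Panel reports** (`gvp_panel`): per-site evidence across ten gel
  fractions F1–F10 with intensity profiles, argmax fraction, confidence
  tiers (`paired_consistent` > `paired` > `variant_only_asymmetric` >
  `variant_only` > `low_confidence`), mimic warnings and a ≥2-peptides
  protein support check.
- **Synthetic data** (`synthetic_data`): a seeded generator producing
  keratin-like proteomes in four molecular-weight classes, heterozygous
  variant sites, HCD b/y spectra with noise/chaff/modification spikes, and
  gel-fraction intensity profiles — with a ground-truth manifest, so every
  stage of the pipeline is verifiable offline.

## Worked example

Generate a synthetic ten-fraction experiment, search one fraction, and build
the GVP panel:

```bash
gvpscan simulate --seed 1 --out demo
# 20 proteins, 17 variant sites, 761 library entries, 5495 spectra -> demo

gvpscan search --library demo/library.msp --queries demo/F7.mgf --out demo/hits_F7.tsv
# 530 identifications at q<=0.01 -> demo/hits_F7.tsv

gvpscan panel --runs demo/F1.mgf ... --runs demo/F10.mgf \
    --library demo/library.msp --proteome demo/proteome.fasta \
    --gvp-sites demo/variant_sites.tsv --out demo/panel.tsv
# 17 detected GVP sites -> demo/panel.tsv
```

The panel table pairs each variant with its nonvariant form and reports
where on the gel each peaks:

```
gene  site                    tier variant_argmax nonvariant_argmax  best_match_factor
KTA1  S53I       paired_consistent             F7                F7                968
KTA2 C361R variant_only_asymmetric             F7                 -                976
KTB7 V351T       paired_consistent             F6                F6                973
```

`KTA1 S53I` is a symmetric site: both allelic peptides co-migrate (argmax
F7, a type-I-keratin-like protein) and pair up at high match factors.
`KTA2 C361R` is asymmetric — the new arginine creates a tryptic cleavage
site, so the nonvariant counterpart is a different peptide and its absence
is structurally expected rather than suspicious. Type-II-like proteins peak
in F6, large proteins in F1–F2, small ones in F9–F10.

The same library commands are available programmatically
(`gvpscan.search`, `gvpscan.hybrid_search`, `gvpscan.assemble_panel`, …);
see `docs/methods.md` for the model details and parameter meanings.

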