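# Methods

This note documents the models and numerical choices behind `gvpscan`, what
the synthetic-data generator does and does not emulate, and the limits of
what the test suite demonstrates.

## Mass ledger

All masses are monoisotopic. Elemental masses are standard CODATA/AME
values to ≥6 decimals; residue masses are derived from elemental
compositions, and every named modification is registered by its *net*
elemental formula (possibly signed, e.g. Gln→pyro-Glu = N⁻¹H⁻³), so a delta
can never drift from its composition. Composite entries
("Formyl + Acetyl", "Deamidation + CAM") are signed sums of base entries;
some frequency-table rows mix adduct chemistry with isotope misassignment
("Sodiated + 2C-13", "Desulfurization + CAM + DTT" ≡ DTT − S); their
decompositions are recorded as given without asserting a mechanism.

Isotope misassignment offsets (k × 1.00335483 Da, k ∈ −2…+5) are modeled as
a separate axis rather than modifications: they arise from picking the wrong
isotopolog peak, not from chemistry.

Substitution deltas cover all 380 ordered residue pairs. I↔L (delta exactly
0) is excluded from mimic reports and from the generator's implanted sites:
the pair is indistinguishable by mass, so it can neither be detected nor
mimicked informatively.

A ledger self-consistency tolerance of 1e-5 Da is used when comparing a
delta against published values; published tables are rounded independently
per row, and one composite row ("Add-Cys + CAM") differs from the
composition-derived value by 5e-6 Da for exactly that reason.

## Digestion and variant pairs

Trypsin model: cleave after K or R, suppressed before proline (Keil rule;
the rule is on by default and configurable because it changes peptide sets
materially). Peptides with more than 2 missed cleavages, shorter than 6 or
longer than 50 residues are outside the search space. The peptide covering
a variant site is chosen by fewest missed cleavages, then shortest, then
leftmost — a deterministic tie-break.

A pair is *symmetric* when both allelic digests yield the same backbone
differing only at the substituted residue; its mass difference then equals
the ledger substitution delta to ≤1e-5 Da (asserted at construction). When
the substitution touches a K/R site the cleavage patterns differ and the
nonvariant "counterpart" is a different peptide with its own release
kinetics; the panel treats its absence as structurally expected
(`variant_only_asymmetric`), and the generator does not annotate such
backbone peptides as allelic forms. Variant positions are interpreted on
the supplied sequence as-is; no initiator-methionine handling is applied,
since numbering conventions vary between sources.

## Match factor and search

The match factor is `round(999 · cosθ)` between weighted peak vectors with
weights `intensity^p · mz^q` (defaults p = 0.5, q = 0, unit-normalized).
Peak matching is greedy nearest-neighbor within the fragment ppm window
(ties to the smaller m/z difference), one-to-one. The exact internals of
production library-search engines are not public; this formulation
reproduces the 0–999 scale, is invariant under uniform intensity scaling,
symmetric, and oracle-checkable, and the exponents are exposed in
`SearchParams`. Candidate filtering uses a 20 ppm precursor window and a
charge match (charge states are distinct peptide ions).

The open search computes DeltaMass = query neutral mass − library neutral
mass (window ±200 Da, covering every ledger entry with margin) and lets
each query peak match a library peak at its nominal position or shifted by
DeltaMass at fragment charge 1; direct and shifted candidates compete in a
single greedy assignment, so DeltaMass = 0 reduces exactly to the regular
score. The single-shift model corresponds to one modification site per
peptide; multi-site shifts are out of scope. Shift candidates are skipped
when |DeltaMass| is inside the fragment tolerance (indistinguishable from
direct matching).

DeltaMass values are clustered on a 3-decimal grid: the mode bin seeds a
cluster and absorbs members within ±0.01 Da (default), annotation proposes
ledger entries, two-entry composites and isotope offsets within ±0.02 Da
(published observed-vs-theoretical gaps reach ~0.008 Da, so ±0.02 gives
2× margin). Mimic warnings list substitutions whose delta lies within the
**20 ppm precursor window** of the observed DeltaMass — the condition under
which an artifact is indistinguishable from a variant by precursor mass.

## Target-decoy FDR

Decoys reverse the sequence keeping the C-terminal residue (preserving
precursor mass, terminal K/R statistics and composition); modifications
travel with their residues; collisions with target sequences are reshuffled
under a fixed seed, and length-≤2 entries are skipped. Decoy spectra are
theoretical b/y ladders carrying the target's intensity-vs-rank profile.
Search runs against the concatenated target+decoy library;
`FDR(s) = #decoy≥s / max(1, #target≥s)`, q-values are the monotonized FDR
(ties share the value of the last hit at that score), and the threshold is
the smallest score with q ≤ α (α = 0.01 default). FDR is estimated per
search mode (regular and hybrid separately). The estimator uses the plain
decoy count without the +1 correction; on the labeled benchmark this is
mildly anticonservative (realized rates ~1.0–1.6 % at the 1 % threshold)
but within the binomial band at the benchmark size used (≥2000 PSMs).

The calibration benchmark generates false PSMs as spectra of *shuffled*
library peptides (C-terminal residue kept): the shuffle preserves the
precursor mass, so every false query competes against its source entry and
that entry's decoy on equal terms, making false-target and decoy scores
exchangeable by construction.

## Panel assembly

Abundance proxy: the precursor intensity recorded with the assigned MS/MS
spectrum (summed matched fragment intensity when absent). The direct
measure would be the MS1 chromatographic peak area, which requires profile
MS1 data outside this package's scope; only ratios and ranks are interpreted.
Per fraction, an ion is measured by its most abundant observed form.

Tier rules: pairing requires a nonvariant observation; `paired_consistent`
additionally requires the two argmax fractions within ±1 (bands span about
two adjacent slices). Demotions to `low_confidence`: best variant MF below
a configurable floor (default 600 — published confident identifications sit
around 700–950, so the floor is deliberately permissive), or a single
observation in a single gel fraction *without* nonvariant corroboration — a
co-migrating nonvariant form is itself strong evidence, so paired sites are
exempt from the singleton rule. Heterozygosity is never inferred: a
homozygous source legitimately lacks the nonvariant form, so `variant_only`
is a report, not an error.

Protein-level support applies the ≥2 distinct peptides rule per gene over
all accepted identifications.

## Synthetic experiment

The generator emulates a gel-fractionated hair-shaft-like experiment:

- **Proteome**: random sequences at vertebrate-average composition with
  K+R ≈ 11 % in four MW classes — type-I-keratin-like (420–470 aa), type-II
  (490–590 aa), large (2300–2700 aa), small (140–260 aa); default counts
  6/6/2/6. Real keratin sequences can be supplied as FASTA instead.
- **Variant sites**: one per protein with probability 0.7 (≈14 sites per
  experiment, matching a realistic single-donor panel), 20 % touching K/R
  sites so asymmetric pairs occur; all sites heterozygous at allele ratio
  0.5. Sites are validated through the pair constructor and resampled until
  the intended symmetry class is realized.
- **Spectra**: b/y ladders for fragment charges 1..max(1, z−1), y-series
  weighted 2× over b, a smooth positional intensity profile, log-normal
  multiplicative noise (σ_ln = 0.3), 30 % chaff peaks ≤10 % of base peak,
  3 ppm precursor error. Library entries are the noise-free ladders.
- **Gel model**: fraction center = log-linear in MW, anchored at 59 kDa→F6
  and 49 kDa→F7 (the type-II/type-I bands), clipped to [1, 10]; per-protein
  Gaussian width 0.6 fractions plus an 8 % uniform smear standing in for
  cross-linked material. Protein abundance 10^N(6.3, 0.3) (arbitrary
  units), peptide release efficiency 10^N(0, 0.25), detection floor 4e4.
- **Artifacts**: per emitted spectrum, N-terminal modification spikes at
  rates mirroring their relative open-search frequencies (acetyl 6 %,
  acetaldehyde 3.5 %, methyl 3 %, formyl 2 %, carbamyl 1.5 %); 20 % of each
  run is pure chaff.
- **Acquisition**: a data-dependent cap of 1000 spectra per run, taken
  top-down by precursor intensity. Fractionated runs sit below the cap —
  which is the point of fractionating. A *combined* run models pooling all
  fractions into one injection at fixed load: each ion appears once at
  1/10 of its total intensity, so low-abundance ions fall below the
  detection floor and whole sites are lost relative to per-fraction
  analysis.

One seed determines everything; identical parameters give byte-identical
output files.

What the generator does **not** emulate: retention-time structure and
chromatographic co-elution, isotope envelopes (beyond the ledger's isotope
offset axis), correlated noise between fractions, real keratin sequence
homology (shared peptides between paralogs), and ion-suppression physics
beyond the cap/dilution model. Passing tests therefore demonstrate the
correctness of the identification and panel logic under controlled
conditions, not performance on real LC-MS/MS data.

## Problem sizes used in tests and the acceptance script

Digestion-oracle equivalence uses 500 random sequences of length ≤30
(exhaustive substring enumeration as the oracle). Scoring self-consistency
uses 1000 synthetic spectra. The FDR benchmark uses 2400 true + 2000 false
queries (≥2000 scored PSMs). Panel recovery runs three replicate seeds of
the default experiment (~15 sites, ~5500 spectra, ten fractions each) for
both fractionated and combined modes, mirroring triplicate experiments;
the open-search artifact ranking is computed over all ten fractions of one
replicate. These sizes give stable statistics while keeping a full run in
the minutes range on one CPU.

## Known limitations

- Match factors are not numerically comparable to any specific production
  engine's scores; only their ordering and scale behavior are designed.
- The hybrid search does not localize the modification site; shifted
  matching is evidence of *a* shift, and annotation is by precursor delta.
- The panel's confidence tiers are explicit, configurable rules, not a
  claim of equivalence to any published evidence-weighing procedure.
- Open-search DeltaMass shifts are applied at fragment charge 1; shifted
  fragments at higher charge states are not matched.
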