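# Methods

## Scope and data model

The package analyses transcript-space variants: each library is a set of
biallelic single-nucleotide variants (SNVs) on a shared reference
transcriptome, with 1-based positions and a per-variant read depth.
Transcripts are sense-strand sequences, so all coding analysis runs on the
forward strand only.  The unit of inference is the library; the study
design is a 3-caste × 3-population grid of nine libraries.

## Variant isolation and depth filtering

`read_snvs` keeps VCF alleles whose REF and ALT are both single ACGT
bases.  Indels, MNVs, symbolic and spanning-deletion alleles are dropped;
multi-allelic rows are decomposed so every single-base ALT becomes its own
record (conserving alleles; a strict mode drops such rows instead).  Depth
comes from the sample FORMAT `DP`, falling back to INFO `DP`, else 0.
Duplicate (transcript, pos, alt) triples keep the last record read, with a
warning.

The depth filter retains records with depth **strictly greater than** the
threshold (default 10).  The strictness and threshold are flags; the
strict reading matches the "high-quality (depth > 10)" convention for this
kind of data.  No false-discovery-rate computation is attached to the
depth filter: a depth cutoff has no well-defined FDR without a calibration
model, so none is claimed.

## Mutational catalogues

SBS classes are pyrimidine-referenced: a change whose REF is a purine is
reverse-complemented (flanks swapped and complemented) before formatting,
giving six substitution types and, with the 5′/3′ flanking bases read from
the reference transcript strand, 96 trinucleotide classes in the COSMIC
ordering.  Flank context is taken from the reference, not read evidence.
Records at transcript ends (no flank) are excluded from SBS-96 but kept in
SBS-6; records whose REF disagrees with the reference base are excluded
and tallied, never recoded.  Both exclusion tallies are reported so
catalogue totals always reconcile with the input record count.  A
purine-lead rendering of the class labels is available as an output
option.

## ORFs and dN/dS

The longest open reading frame per transcript is the longest ATG→stop span
over the three forward frames (first in-frame stop closes an ORF; ties go
to the smaller start).  Site counts follow the approximate Nei–Gojobori
convention: for every codon, each of the nine single-base changes is
classified against the standard genetic code; synonymous and nonsynonymous
changes contribute 1/3 site each, and stop-creating changes contribute to
neither (their mass is tracked separately so per-codon totals of 3
reconcile).  The terminal stop codon is excluded from counting, and SNVs
inside it are classed noncoding.

Each SNV is classified independently against the reference codon (no
haplotype phasing).  Within a library, substitution and site counts are
pooled over all transcripts with an ORF — per-transcript ratios are
undefined whenever a transcript lacks synonymous hits, which at realistic
densities is the majority, so pooling is the default and a per-transcript
mode is provided for sensitivity analysis.  Proportions are corrected for
multiple hits with the Jukes–Cantor distance d = −(3/4)·ln(1 − 4p/3),
defined for p < 3/4 (saturation raises an explicit error).  dN/dS = d_N/d_S,
reported as undefined (not an error) when d_S = 0.  Stop-gain and
noncoding SNVs and SNVs on ORF-less transcripts are excluded from p_S/p_N
and reported in side tallies.  When pooling across libraries (e.g. a
caste's three libraries), counts are summed and each library contributes
its own per-site opportunity, i.e. site totals scale with the number of
libraries pooled.

## Group statistics

SNV counts are compared with the tie-corrected Kruskal–Wallis H test and
Dunn's pairwise post-hoc on mean ranks (z statistics with the tie term
Σ(t³−t)/(12(N−1))).  The post-hoc adjustment defaults to
Benjamini–Hochberg, with none/Bonferroni/Holm available — the choice
matters little at three pairwise comparisons, and only inequality
statements are typically reported at this design size.  ts/tv and dN/dS
use classical one-way ANOVA (between/within decomposition) with Tukey's
HSD for dN/dS.  Degenerate inputs are values, not errors: a fully constant
response reports an undefined F with p = 1; zero within-group variance
with distinct means reports F = ∞, p = 0.  With n = 3 libraries per group
these tests are low-powered by construction; no minimum-n refusal is made
beyond the mathematical contracts.

## Synthetic-study generator

The generator emulates what the upstream read-processing pipeline hands to
this package (reference FASTA + per-library VCFs + metadata), not the
reads themselves.

**Reference.**  Each transcript is 5′UTR + ATG + k inner sense codons +
stop + 3′UTR, with bases drawn i.i.d. at the configured GC content (UTRs
may contain starts and stops — this exercises the ORF finder) and the
embedded ORF verified by re-scan to be the transcript's longest.
Defaults: 300 transcripts, 100–300 inner codons, 20–100 nt UTRs, GC 0.45 —
a desk-scale stand-in for a ~30 K-transcript assembly, sized so that a
full nine-library analysis runs in seconds while keeping per-library
substitution counts in the thousands.

**Variants.**  A planted variant is a (position, alternative base) pair.
The base measure is uniform over transcript positions, with the
alternative base carrying transition probability r/(1+r) for ts/tv target
r (default 1.7, the ratio typical of transcriptome SNV data) and
transversions split evenly.  Selection effects multiply the odds of every
*nonsynonymous* change: a global multiplier (`nonsyn_enrichment`), a
soldier-×-subset multiplier (`soldier_nonsyn_enrichment`), and a per-library
mean-one lognormal factor (`library_effect_sd`, default 0.08) that models
between-library overdispersion — real replicate libraries differ by more
than counting noise, and without this term any between-caste contrast,
however small, becomes formally significant at large variant counts.
Exactly `variants_per_library` (default 30,000) distinct sites are drawn
by sequential weighted sampling without replacement (Gumbel top-k over the
per-site total change weight); with all multipliers at one this reduces
exactly to uniform placement.  Depths are negative-binomial (mean 40,
dispersion 5), a right-skewed model consistent with a 10–100-dominated
depth profile.  The caste-associated subset is a random ⌈f·n⌉ transcripts
(default f = 0.05, between the ~1–2% of a real caste-associated gene list
and the statistical power desk scale requires).  An optional per-population
count multiplier emulates population-level count differences; by default
populations differ only by their labels.

Every planted variant carries a ground-truth class
(synonymous/nonsynonymous/stopgain/noncoding) and ts/tv label produced by
the same classification core the estimator uses, so recovery is exactly
testable.  A single master seed drives everything; per-library streams are
derived by stable (SHA-256) hashing of the library id, so adding a library
never perturbs the others, and identical config + seed yields
byte-identical files.

**Calibration.**  `calibrate_config` solves the two enrichment multipliers
so the *expected* pooled dN/dS equals requested targets (defaults: 1.7
background, 4.3 in the soldier subset).  The expectation is computed in
closed form from the generated reference: per-site inclusion
probabilities under the weighted without-replacement draw are approximated
by the Hájek form π_i = 1 − exp(−t·z_i) (t chosen so Σπ = n), expected
class counts follow directly, and the resulting pooled ratio is strictly
increasing in the nonsynonymous odds, so each multiplier is a 1-D root
find.  No simulation output is consulted.

**What the generator does not model** — and hence what passing tests do
not establish about real data: read-level error, mapping and calling
artefacts, allele-frequency structure and diploid genotypes, indels/MNVs,
linkage between nearby variants, transcript-expression-dependent coverage,
and any real phylogenetic or demographic signal.  Recovery results show
the estimator is correct under its own model, not that the biological
effect sizes are realistic.

## Numerical and design notes

- Coordinates are 1-based inclusive everywhere (VCF/FASTA convention).
- NG86 site counts are accumulated as integer change counts divided by 3
  once, so "fractions of thirds" are exact to machine precision.
- The ts/tv ratio is an explicit `None` when a library has no
  transversions; dN/dS is `None` when d_S = 0.
- Report SDs use the sample (n−1) convention, flagged in the run manifest.
- Reports contain no timestamps, so identical config + seed reproduces
  every report file bit for bit; `run` in simulate mode writes the study
  files first and then ingests them through the same file-reading path as
  real data, which is why a later ingest of those files is exactly
  round-trippable.
- The planted soldier-subset enrichment necessarily leaks a small
  (~3% at the default subset fraction) elevation into soldier
  whole-transcriptome dN/dS; with the default overdispersion this stays
  within between-library noise, so the whole-transcriptome caste ANOVA is
  expected non-significant, though an unlucky seed can cross nominal
  significance.
- Known limitations: no codon-model maximum-likelihood dN/dS, no
  ts/tv-weighted (modified) site counting, no pairwise-alignment path
  averaging (inputs are variants against a single reference, not sequence
  pairs), and no multiple-testing control across measures.

## Configuration file

`castevar run --config` accepts a flat YAML mapping of the
`PipelineConfig` fields (`mode`, `out_dir`, `reference`, `vcf_dir`,
`metadata`, `subset`, `min_depth`, `strict_depth`, `dnds_mode`,
`adjustment`, `seed`) plus a nested `simulation:` mapping (or
`simulation_`-prefixed keys) of `SimulationConfig` fields.  Exit codes:
0 success, 2 configuration error, 3 data-consistency error.
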