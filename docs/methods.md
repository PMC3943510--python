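# Methods

## The problem

The HM450K bead array measures DNA methylation at ~485k CpGs through
hybridization of 50-mer probes to bisulfite-converted DNA. Bisulfite
treatment converts unmethylated C to T, so probes hybridize a
reduced-complexity genome; together with repeats, SNPs and INDELs under the
probe body, this makes a subset of probes report signal unrelated to
methylation. `probeqc` annotates those genomic factors, quantifies each
category's noise against whole-genome bisulfite sequencing (WGBS), and
applies a keep/discard workflow in which factors that demonstrably do not
inflate noise are rescued rather than dropped.

## Coordinates and footprint geometry

Manifest positions are 1-based forward-strand positions of the C of the
interrogated CpG; all internal intervals are 0-based half-open; BED input is
0-based half-open; VCF input is 1-based. With `c = cpg_pos − 1` the
footprint convention (`"illumina"`, the only built-in; exposed as a config
enum because it is fixed by array chemistry rather than by the filtering
method) is:

| chemistry | strand | footprint | rationale |
|---|---|---|---|
| I  | + | `[c, c+50)`    | probe 3′ terminus pairs with the C |
| II | + | `[c+1, c+51)`  | single-base extension reads the C |
| I  | − | `[c−48, c+2)`  | mirror image; the reverse-strand C sits at `c+1` |
| II | − | `[c−49, c+1)`  | mirror image |

Every footprint has length 50 and contains or abuts the CpG dinucleotide
`[c, c+2)`. SNP offsets are strand-oriented: offset 0 is the interrogated C
on the probe's strand, offset 1 the paired G, larger offsets run into the
probe body. A SNP at the type II extension position is the CpG-C itself and
is handled by the CpG-site flags, not as a body SNP.

## Bisulfite-space mapping

The mapper is methylation-blind and strand-symmetric: both the C→T-converted
forward text and the C→T-converted reverse complement of each chromosome are
searched. Probe letters map to allowed-character sets — non-CpG `C` → `{T}`,
CpG-context `C` → `{C,T}`, the type II degenerate base `R` → `{A,G}`, others
to themselves; genomic `N` matches nothing. Matching is exact by default
(`max_mismatch = 0`): the product is a uniqueness verdict, not an aligner,
and exact matching is deterministic and oracle-checkable. A mismatch-tolerant
scan (vectorized per-position mismatch counting) exists for sensitivity
analyses; hit counts are monotone in `max_mismatch`. For speed the exact
scanner prefilters with the query's longest wildcard-free literal run and
verifies candidate windows position-by-position; a regex scan is the fallback
when that run is shorter than 8 bases. Hit locations are capped at 16 per
probe; counts are always exact.

## SNP classification and the bisulfite rescue

A SNP is *bisulfite-okay* when its allele set is exactly {C,T} (alleles
normalized to the forward strand) and the base immediately 3′ is not G: such
a position reads as T after conversion whichever allele is present, so the
probe cannot feel it. At a chromosome end the downstream base is undefined
and the SNP is conservatively not okay. Body-SNP counts are
`effective = total − bisokay`; a probe whose body SNPs are all bisulfite-okay
has effective 0 and is never discarded for body SNPs. INDELs spanning the
CpG dinucleotide set both the INDEL and the CpG-site flags. Multi-allelic
VCF rows are split into biallelic records before classification.
Heterozygosity strata default to edges (0, 0.1, 0.2, 0.3, 0.4, 0.5), last
bin closed, with an "unknown" stratum for SNPs lacking an average-heterozygosity
annotation.

## WGBS pairing and noise statistics

WGBS sites (score 0–100, coverage) are kept at coverage ≥ 5 and matched to
the probe's forward-strand C position exactly; no merging of the symmetric
reverse-strand measurement (a coverage-weighted merge could be added, but
single-base matching is the default behaviour). β_wgbs = score/100;
differences are array − WGBS. Per category the package reports the unique
probe count, median |Δβ| (even-length medians are midpoint means), Pearson r
over (β_wgbs, β_array), and a two-sided Wilcoxon rank-sum p of the
category's |Δβ| against the high-quality background (no multiple-testing
correction, matching raw-p reporting; one-sided mode is available). The
rank-sum test enumerates the exact null when both n ≤ 8 without ties and
otherwise uses the tie- and continuity-corrected normal approximation (via
scipy). The 2-D density matrix bins both betas at window 0.02 into a 50×50
grid with a closed last bin so β = 1.0 is countable. Probes with
|Δβ| > 0.3 (strictly) are *unknown-factor* probes; without a WGBS pairing
the flag is unevaluable and never fires. Per-probe standard deviations use
the n−1 denominator and require ≥ 2 non-missing values; keep-vs-discard SD
comparisons test the full distributions and report density summaries
restricted to SD ≥ 0.10.

## Decision workflow

Reason codes accumulate in workflow order (MULTIMAP, REPEAT, INDEL,
SNP_AT_CPG, body SNPs, UNKNOWN_FACTOR) rather than short-circuiting, because
the unique-category accounting with its "multiple factors" row is not
derivable from first-fired-reason records. The default config discards
multimap, repeat, CpG-SNP, effective type I body-SNP and unknown-factor
probes; INDEL and type II body-SNP probes are kept. Presets: `population`
additionally drops INDEL probes; `cell_line` keeps CpG-SNP probes
(appropriate for genetically homogeneous material); `conservative` drops
every factor and disables the bisulfite-okay rescue, so its discard set is a
superset of the default's. Genotype overrides: a CpG-SNP probe homozygous
reference at both dinucleotide positions is rescued (positions without an
annotated SNP count as reference); homozygous alternate at either position
forces discard; heterozygous or missing calls change nothing. Rescued-by
classes (GENOTYPE, BIS_OKAY, TYPE_II_TOLERANT, INDEL_TOLERANT,
CONFIG_TOLERANT, in precedence order) partition every flagged-but-kept
probe so that kept = high-quality + rescued holds exactly, overall and per
chemistry. High-quality means: no factor flag and not unknown-flagged.

## Synthetic world

The generator emulates the statistical structure of real array-vs-WGBS
comparisons at toy scale, with one global seed and per-track labelled
sub-seeds (adding a track never perturbs the others; identical seeds give
byte-identical files).

* Genome: uniform random A/C/G/T chromosomes (default 4 × 100 kb) with a
  planted CpG at each probe anchor; probes occupy exclusive 110-bp slots so
  planted factors never bleed into neighbours.
* Probes are genuine genomic 50-mers on their declared strand (reverse
  complemented for −), with `R` at the G of each internal CpG for type II;
  every designed probe verifies "consistent" against the genome.
* Multi-mapping probes are created by copying their footprint into a
  probe-free decoy zone. Category plantings (repeat intervals, INDELs,
  CpG-site SNPs, body SNPs, bisulfite-okay SNPs) are placed inside the
  owning footprint only.
* True betas ~ Beta(0.3, 0.3) (bimodal, concentrating density at (0,0) and
  (1,1)). WGBS is digital: coverage ~ Poisson(30), methylated reads ~
  Binomial(coverage, β), score = round(100·m/cov). The array is analog:
  clamp(β + N(0, sd)) with sd = 0.05 background plus per-category extras
  (+0.10 repeats, +0.05 multimap) — the simplest models that reproduce the
  analog-vs-digital background error between the platforms.
* CpG-SNP probes receive a genotype (hom-ref/het/hom-alt at 0.25/0.5/0.25);
  homozygous-alternate probes collapse to an array beta near 0.02, het
  probes to half their true beta.
* Unknown-factor probes get a ±0.45 array offset (toward the interior of
  [0,1]) so |Δβ| robustly exceeds 0.3. The expected unknown flag in the
  ground truth is computed from the exact betas written to disk (sample_01
  against score/100), so coincidental threshold crossings in other
  categories are part of the recorded truth, not a mismatch.

What a green test does *not* establish: the world has no realistic genome
composition (no CpG islands, no repeat families with internal structure, no
linkage among variants, no batch effects, no probe-affinity biases), so
green end-to-end tests certify the bookkeeping and the statistical
machinery, not performance on hg19-scale data.

Array betas are rounded to 6 decimals at generation so the in-memory matrix
equals the CSV on disk bit-for-bit; this keeps threshold comparisons
(|Δβ| > 0.3) identical between the generator's ground truth and a pipeline
run that re-reads the files.

## Numerical conventions and edge cases

* Interval overlap is half-open everywhere; one shared base counts, abutment
  does not.
* Duplicate WGBS rows at one position keep the higher-coverage row (warned).
* Pearson r requires n ≥ 3 and nonzero variance; degenerate categories
  report NaN instead of failing the whole summary.
* Empty categories report n = 0 with NaN statistics; regions with zero
  probes report NaN removal fractions (undefined, not 0).
* Annotation exports are sorted by probe id and byte-deterministic; the
  reader round-trips them losslessly.
* Unknown chromosomes in a manifest are carried through with
  genome-dependent flags unevaluable, never dropped silently.

## Known limitations

* The mapper is exact-match by default; a probe uniquely placeable only by
  a gapped or mismatch-tolerant aligner is reported as unmappable/multimapped
  accordingly. Genome-scale multimap counts from production aligners are
  therefore not comparable.
* Average heterozygosity is the only population signal carried; no
  population-specific allele frequencies or phasing.
* Figure-level plotting is out of scope; every statistic is emitted as a
  table a plotting layer can consume.
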