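# probeqc

Quality annotation and filtering of Illumina HumanMethylation450 (HM450K)
methylation-array probes.

A substantial fraction of HM450K probes report something other than
methylation: their 50-mer hybridizes more than one locus of the
reduced-complexity *bisulfite genome* (every unmethylated C reads as T),
overlaps a repeat, carries SNPs or INDELs that perturb hybridization, or
disagrees grossly with whole-genome bisulfite sequencing (WGBS) for no
annotated reason. `probeqc` annotates each probe for these genomic factors,
compares array beta values against WGBS beta values, and applies a
configurable keep/discard workflow with principled rescues — so that studies
filter the probes that are actually noisy instead of discarding every
flagged probe.

## What it computes

For each probe (id, Infinium chemistry I/II, CpG position, strand, 50-mer):

1. **Multi-mapping** — the probe sequence is rendered into bisulfite space
   (non-CpG `C`→`T`; CpG-context `C` matches `{C,T}`; the type II degenerate
   base `R` matches `{A,G}`) and counted against both C→T-converted strand
   texts of the genome. More than one exact hit ⇒ ambiguous.
2. **Repeats / INDELs** — half-open interval overlap of the 50-bp footprint
   with a RepeatMasker-style BED track and VCF INDEL spans.
3. **SNPs** — every footprint SNP gets a strand-oriented offset from the
   interrogated C; SNPs at the CpG dinucleotide are flagged separately.
   A C↔T SNP whose downstream base is not G is invisible after bisulfite
   conversion (*bisulfite-okay*) and never counts against the probe.
4. **WGBS concordance** — array betas are paired with WGBS betas
   (β = score/100, coverage ≥ 5) at the interrogated C; |Δβ| > 0.3 with no
   flagged explanation marks an *unknown-factor* probe. Per category the
   package reports n, median |Δβ|, Pearson r, and a two-sided Wilcoxon
   rank-sum p against the high-quality background (probes with no flags).
5. **Filtering** — discard multimapped, repeat-overlapping, CpG-SNP and
   unknown-factor probes; keep INDEL probes, bisulfite-okay SNP probes and
   type II body-SNP probes (rescues). Presets: `default`, `population`
   (drop INDELs), `cell_line` (keep CpG-SNP probes), `conservative`
   (drop everything, no rescues). Accounting tables report any-overlap
   counts, unique-category counts with a multiple-factors row, rescue
   decompositions, and per-region removal fractions, with the identities
   kept + discarded = total and kept = high-quality + rescued enforced.

A seeded synthetic-data module generates a toy genome plus every input file
(manifest, FASTA, VCF, BED, bedGraph, beta matrix) with known ground-truth
labels, so the whole pipeline is testable offline.

## Worked example

```bash
probeqc simulate --seed 11 --n-probes 600 --out fx/
probeqc annotate --manifest fx/manifest.csv --genome fx/genome.fa \
                 --snps fx/variants.vcf --repeats fx/repeats.bed --out flags.csv
probeqc compare-wgbs --manifest fx/manifest.csv --wgbs fx/wgbs.bedgraph \
                     --betas fx/betas.csv --out pairs.tsv
probeqc filter --flags flags.csv --pairs pairs.tsv --preset default --out annotations.csv
probeqc summarize --annotations annotations.csv --style unique
```

which prints (on the seed-11 fixture):

```
annotated 600 probes (60 multimapped, 0 unmappable) -> flags.csv
paired 600 probes (0 unmatched) -> pairs.tsv
252 kept / 348 discarded -> annotations.csv
```

followed by the unique-category table:

```
          type_i  type_ii  total  kept_type_i  kept_type_ii  kept_total
multimap      19       41     60            0             0           0
repeat        26       48     74            0             0           0
indel         13       47     60           13            47          60
snp_at_cpg    18       46     64            0             0           0
body_snp_1    54      106    160           20           106         126
body_snp_2plus 25      35     60            0            35          35
unknown       12       37     49            0             0           0
multiple_factors 16    26     42            0             0           0
high_quality   9       22     31            9            22          31
total        192      408    600           42           210         252
```

Reading it: the 60 planted multimappers, all repeat-overlapping and all
CpG-SNP probes are discarded; all 60 INDEL-only probes are kept; in the
body-SNP rows every type II probe is kept (the chemistry tolerates body
SNPs) while type I probes survive only when their SNPs are bisulfite-okay —
and kept (252) equals high-quality (31) plus rescued (221) overall and per
chemistry.

The same operations are available as a library (`import probeqc`); see
`docs/methods.md` for the model and the numerical conventions.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a seeded fixture, runs the full pipeline (bisulfite mapping →
annotation → WGBS pairing → filtering → accounting), verifies the verdicts
against the generator's independent label oracle, and writes the results
JSON.
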