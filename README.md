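# grburden

Compute per-individual weighted **genetic risk burden (GRB)** scores from
VCF genotypes and compare them across populations, together with
allele-frequency-spectrum analyses (rare-variant proportions, fixed
alleles, frequency densities) and a reciprocal-tail negative-selection
test. A synthetic multi-population cohort generator (Balding–Nichols
differentiation, Hardy–Weinberg genotypes) makes the whole pipeline
testable with no downloads.

For an annotated variant subset of size N with positive per-allele effect
sizes β and effect-allele counts c (0/1/2), the score is

```
GRB_j = N * (Σ_i c_ij β_i) / (Σ_i β_i)
```

which lives on the 0..2N allele-count scale and reduces to the plain
allele count when all weights are equal. Missing genotypes are handled by
per-individual weight renormalization.

## Layout

| module | role |
|---|---|
| `grburden.annotations_io` | annotation table / sample panel / VCF readers; dosage orientation to the effect allele |
| `grburden.grb_core` | weighted and unweighted scores; ancestral/derived and deleteriousness stratification |
| `grburden.population_stats` | Welch group comparisons, risk-allele frequencies, rare/fixed classification, selection test, paired strata contrasts, frequency spectra |
| `grburden.synthetic_data` | Balding–Nichols cohort simulator with ground-truth files |
| `grburden.cli` | `grburden` command-line interface |

## CLI

```sh
# write a synthetic cohort (VCF + panel + annotations + truth tables)
grburden simulate --outdir sim --n-variants 59 \
    --populations POPA:SUPA:500:0.08,POPB:SUPB:500:0.02 --seed 1

# per-individual scores for the five variant strata
grburden score --vcf sim/cohort.vcf --panel sim/panel.tsv \
    --annotations sim/annotations.tsv --outdir out --reference SUPA

# all group-level comparison tables
grburden compare --vcf sim/cohort.vcf --panel sim/panel.tsv \
    --annotations sim/annotations.tsv --outdir out \
    --reference SUPA --grouping super_population

# or both at once; options may also come from a YAML file
grburden all --config run.yaml --outdir out
```

Exit codes: 0 success, 2 config error, 3 input-format error, 4 analysis
error. Every run writes a `manifest.json` with input checksums and
parameters; reruns with identical inputs and seed are byte-identical.

## Input formats

* **Annotation table** (TSV, header): `rsid chrom pos effect_allele
  other_allele beta allele_state cadd_phred`; `beta` > 0 is the magnitude
  of the lowering effect, `allele_state` ∈ {ancestral, derived}.
* **Sample panel**: whitespace- or tab-delimited with columns `sample pop
  super_pop` and optional `gender`.
* **VCF 4.x** with GT fields; variants are matched by chrom+pos and
  allele-checked against the annotation (literal comparison, no strand
  flipping); multi-allelic records are usable iff REF plus one ALT equals
  the annotation allele pair.

## Real-cohort run and acceptance report

The published analysis uses the phase-3 release of the 1000 Genomes
Project (2504 samples, 26 populations; https://www.internationalgenome.org/)
and a 59-variant annotation table. To reproduce it:

1. download the phase-3 autosome VCFs and the
   `integrated_call_samples_v3.20130502.ALL.panel` file;
2. slice the 59 annotated sites into one VCF, e.g.
   `bcftools view -R positions.tsv ALL.chr*.vcf.gz` and concatenate;
3. place `genotypes.vcf`, `samples.panel` and `annotations.tsv` in one
   directory.

Then:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json \
    --data-dir /path/to/data     # or export GRB_REAL_DATA_DIR
```

Without `--data-dir` the script still succeeds but writes an empty report,
since none of the target quantities can be computed offline.
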