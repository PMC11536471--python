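# chipdyn

Longitudinal clonal-hematopoiesis dynamics from targeted sequencing.

Clonal hematopoiesis of indeterminate potential (CHIP) is the presence of a
somatic driver mutation — most often in *DNMT3A*, *TET2* or *JAK2* — in blood
at a variant allele fraction (VAF) of at least 2%, without a hematologic
malignancy. When an individual is sampled at two timepoints, the change in a
clone's VAF measures how fast that clone is out-competing normal
hematopoiesis. `chipdyn` is a pipeline for exactly this analysis:

1. **Call/filter** — ingest Mutect2-style somatic VCFs over a 22-gene CHIP
   panel (~44 kb of targeted territory), recompute VAF = AD/DP, and apply
   the CHIP filters: total depth ≥ 100, alt-supporting reads ≥ 3, VAF ≥ 2%.
2. **Pair** — track each mutation across the two draws. A mutation passing
   filters at only one timepoint gets the other timepoint's VAF rescued
   from any sub-threshold call with ≥ 3 alt reads, or imputed at 0.001
   (the assay's lower detection limit).
3. **Dynamics** — estimate each clone's *clonal fitness* CF, the annual
   proportional growth rate under a deterministic exponential model:

   ```
   VAF₂ = VAF₁ · (1 + CF)^T        ⇒        CF = (VAF₂ / VAF₁)^(1/T) − 1
   ```

   with T the years between draws. The cohort's bottom 10% of clones by
   |CF| are classified *stagnant*; the rest are *expansion* (CF > 0) or
   *reduction* (CF < 0). Two-mutation individuals are called **sub-clonal**
   (one mutation nested in the other's clone) when both clones share a
   trajectory class and their within-class z-scores differ by < 0.6,
   otherwise **distinct**.
4. **Report** — per-gene mean growth rates (with a single-mutation
   sensitivity analysis), a driver-gene co-occurrence χ² test against a
   prevalence-product null (analytic and permutation p-values), and
   gene-adjusted covariate association models for CHIP expansion rate.

Because the biobank data this kind of study uses is access-restricted, the
package ships a ground-truthed **synthetic cohort generator** that emulates
the relevant statistics — skewed driver-gene frequencies, gene-specific
exponential growth, 66/26/8% mutation-count mix, Poisson×binomial
sequencing noise at ~1725–2000× depth, and nested/distinct two-clone
architectures — so every stage is testable end to end against known truth.

## Worked example

Simulate a 101-individual cohort and run the full pipeline:

```bash
chipdyn simulate --seed 17 --n 101 --out-dir fixtures/
cat > run.yaml <<EOF
vcf: fixtures/cohort.vcf
metadata: fixtures/metadata.tsv
out_dir: out/
seed: 17
EOF
chipdyn run --config run.yaml
```

The run prints its stage counts:

```
{"architecture_calls": 32, "calls_read": 306, "calls_retained": 292,
 "clone_pairs": 152, "clones": 152, "distinct": 19, "expansion": 100,
 "panel_genes": 22, "panel_target_bp": 43400, "reduction": 36,
 "stagnant": 16, "sub_clone": 13}
```

i.e. 306 per-sample calls survive ingestion, 292 pass the CHIP filters,
and they pair into 152 clones. The bottom-10% rule labels 16 clones
stagnant (the implied cutoff, |CF| < 0.027/yr, is logged), 100 expand and
36 shrink; of the 32 two-mutation individuals, 13 are called sub-clonal
and 19 distinct. `out/gene_summary.tsv` then ranks driver genes by mean
growth rate:

```
gene    n_clones  mean_cf  n_expansion  n_reduction  n_stagnant
JAK2    17        0.276    16           0            1
PPM1D   15        0.154    13           1            1
TET2    17        0.065    9            4            4
DNMT3A  79        0.060    50           22           7
```

*JAK2* clones grow fastest (≈28%/yr in this realization) and *DNMT3A*
slowest — the generator's gene-fitness ordering, recovered from noisy
reads. `out/cooccurrence.json` holds the χ² test (here χ² = 60.1,
permutation p = 0.31: this cohort was simulated with independent gene
draws, so no co-occurrence structure is expected), and
`out/associations.tsv` the gene-adjusted covariate models.

Each stage is also available separately (`chipdyn call`, `dynamics`,
`report`, `simulate`), and everything is importable:

```python
import chipdyn
cf = chipdyn.compute_growth_rate(vaf1=0.02, vaf2=0.08, dt_years=2)  # 1.0
```

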