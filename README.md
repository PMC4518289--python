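# heritkit

Estimating how much of the variation in a polygenic trait is captured by
common genetic variants — and *where in the genome* that signal lives — is
a standard task in quantitative genetics, but assembling the pieces
(genotype QC, kinship estimation, annotation-aware variance partitioning,
restricted maximum likelihood, twin models) usually means stitching
together several external tools.  heritkit implements that whole analysis
as one tested Python library, exercised end to end on synthetic cohorts
with known ground truth.  It was built around the quantitative-genetic
analysis of regional cortical surface area — GRM-based SNP heritability per
brain region, variance partitioned by genic and evolutionary-conservation
annotation, and a classical twin comparison — but every stage is generic.

## The model

For a phenotype vector *y* over *n* unrelated subjects, fixed effects *X*
and genetic relationship matrices *G<sub>c</sub>* built from standardized
SNP dosages,

    y = Xb + Σ_c g_c + e,      V = Σ_c G_c σ²_c + I σ²_e,

fitted by average-information REML.  SNP heritability is
*h²<sub>c</sub> = σ²<sub>c</sub> / (Σσ² + σ²<sub>e</sub>)*, tested against
zero with a boundary-mixture likelihood ratio (½χ²₀ + ½χ²₁).  Partitions
come from genic annotation (gene spans ± 20 kb flanks) or from a median
split of LD-weighted conservation scores
*s̃<sub>i</sub> = Σ<sub>j</sub> r²<sub>ij</sub> s<sub>j</sub> /
Σ<sub>j</sub> r²<sub>ij</sub>*.  Twin heritability uses the ACE
decomposition (rMZ = a² + c², rDZ = ½a² + c²) fitted by direct maximum
likelihood, with Falconer moment estimates alongside.  See
`docs/methods.md` for the full account.

## Worked example

Simulate a cohort (800 subjects × 2000 SNPs, total h² = 0.45 split 0.30
genic / 0.15 intergenic), estimate overall and partitioned SNP
heritability, then compare with a twin sample:

```python
import numpy as np
from heritkit import (SimulationConfig, simulate_genotypes, simulate_annotation,
                      simulate_phenotype, estimate_h2, build_partition,
                      simulate_twins, fit_ace, twin_correlations, falconer)

cfg = SimulationConfig(n_subjects=800, n_snps=2000, seed=42)
geno = simulate_genotypes(cfg)
annot = simulate_annotation(geno.snp_map, cfg)
pheno = simulate_phenotype(geno, annot.track, cfg)

report = estimate_h2(geno, pheno.phenotype, n_pcs=10)
print(report.to_frame().round(4).to_string(index=False))

part = build_partition(annot.track)
part_report = estimate_h2(geno, pheno.phenotype, partition=part, n_pcs=10)
print(part_report.to_frame().round(4).to_string(index=False))

twins = simulate_twins(cfg)
r_mz, r_dz = twin_correlations(twins)
ace = fit_ace(twins)
print(f"rMZ={r_mz:.3f} rDZ={r_dz:.3f}")
print(f"ACE: a2={ace.a2:.3f} c2={ace.c2:.3f} e2={ace.e2:.3f}")
print("Falconer:", tuple(round(v, 3) for v in falconer(r_mz, r_dz)))
```

Output:

```
component  sigma2     se   prop  prop_se    loglik     lrt   p
  genetic  0.5047 0.0899 0.4615   0.0699 -405.8252 42.0913 0.0
 residual  0.5890 0.0716 0.5385   0.0699 -405.8252     NaN NaN
 component  sigma2     se   prop  prop_se   loglik     lrt      p
intergenic  0.1351 0.0532 0.1238   0.0474 -402.947  8.5085 0.0018
     genic  0.3628 0.0686 0.3326   0.0547 -402.947 42.8604 0.0000
  residual  0.5931 0.0706 0.5436   0.0689 -402.947     NaN    NaN
rMZ=0.633 rDZ=0.281
ACE: a2=0.625 c2=0.000 e2=0.375
Falconer: (0.702, -0.07, 0.367)
```

Reading this: all SNPs jointly explain an estimated 46% of phenotypic
variance (truth 0.45; s.e. 0.07), strongly nonzero by the boundary-mixture
LRT.  The two-component fit attributes 0.33 to genic and 0.12 to
intergenic SNPs (truths 0.30 / 0.15) — the genic enrichment planted in the
simulation is recovered.  The twin sample gives correlations near the ACE
truth (0.62 / 0.31), an ML a² of 0.63 with no shared-environment
component, and Falconer moments scattered around the same values (the raw
moment c² may go negative; it is deliberately untruncated).

## Command line

```bash
heritkit simulate --config sim.yaml --out data/ --seed 7
heritkit qc    --bfile data/simulated --out data/clean
heritkit grm   --bfile data/clean --out data/all
heritkit pca   --grm data/all --out data/pcs.txt --k 10
heritkit annotate --bfile data/clean --genes data/genes.bed --out data/partition.tsv
heritkit reml  --bfile data/clean --pheno data/phenotype.txt \
               --partition data/partition.tsv --out data/fit.tsv
heritkit twin  --pairs data/twins.tsv
heritkit run-all --config pipeline.yaml --out results/ --seed 7
```

`run-all` executes simulate/ingest → QC → GRM → relatedness pruning (both
0.025 and 0.1 thresholds side by side) → PCA → annotation → REML per
phenotype per mode, writing `.hsq`-style tables, a summary with
significance stars, and a provenance log with content hashes; reruns with
the same seed are byte-identical.

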