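# resistrank

Cross-cohort rank-product meta-analysis of immunotherapy responder vs
non-responder transcriptomes, with the downstream immune-context statistics
and Hill-equation dose-response fitting used to characterize the top hits.

## Who this is for

Tumor-immunology groups comparing pretreatment expression profiles of
tumors that did or did not respond to immune checkpoint blockade (ICB)
often hold several small, heterogeneous cohorts — different species,
platforms and response definitions — and want to know which genes are
*consistently* upregulated in non-responders. Effect sizes are not
comparable across such cohorts, but fold-change *ranks* are. This package
implements that rank-based meta-analysis as a tested, reusable pipeline,
together with a synthetic-data module that emulates the multi-cohort design
with known ground truth, so every stage can be validated at desk scale.

## The statistics

**Rank product.** Within each of k comparisons, genes are ranked by
log2 fold change (non-responder mean − responder mean; rank 1 = most
upregulated in non-responders, average ranks on ties). For gene *g* the
statistic is the geometric mean of relative ranks

```
rho_g = ( prod_i  r_{g,i} / n_i ) ^ (1/k)
```

Small `rho_g` means consistent upregulation in non-responders. Its null
distribution (independent uniform ranks) is computed three ways: exact
enumeration (`rp_pvalue_exact`, the reference for small problems), a
continuity-corrected Gamma(k, 1) tail approximation (`rp_pvalue_gamma`,
the production route, certified against enumeration), and seeded
Monte-Carlo permutation. P-values get Benjamini–Hochberg adjustment; in
parallel, per-cohort one-tailed p-values from an empirical-Bayes moderated
t-test (variance shrinkage toward a prior `s0²` with prior df `d0`
estimated by digamma/trigamma moment matching) are combined with Fisher's
method, `X = −2 Σ ln p_i ~ χ²(2k)`. Results are finally filtered to a
metabolic gene set (GMT) and re-ranked.

**Downstream.** `immunectx` scores gene signatures (mean z-score),
median-dichotomizes cohorts into e.g. macrophage-high/CD8-low vs
macrophage-low/CD8-high strata with a pooled t-test between them,
correlates per-cell-type mean expression across datasets, and computes
dot-plot summaries. `dosefit` reduces Fura-2 calcium traces to
ionomycin-normalized peak responses and fits
`y = baseline + Emax·c^h / (EC50^h + c^h)` by multi-start least squares
with EC50 on the log scale, including potency-ratio comparisons with
confidence intervals.

## Worked example

```python
import resistrank as rr

# four cohorts of 1,321 metabolic genes, 10 responders vs 10 non-responders,
# one gene truly up in non-responders by 3 log2 units in every cohort
cfg = rr.SimConfig(n_genes=1321, n_studies=4, noise_sd=1.0,
                   spikes={"gene_0001": 3.0}, metabolic_fraction=1.0, seed=1)
studies, truth = rr.simulate_cohorts(cfg)
result, manifest = rr.run_meta(studies, metabolic=truth.metabolic_genes)
top = result.iloc[0]
print(result.index[0], int(top["meta_rank"]), float(top["rho"]),
      float(top["p_adj"]), float(top["p_fisher"]))
```

prints

```
gene_0001 1 0.0007570022710068131 1.639410552910489e-09 1.6024639686006804e-53
```

The spiked gene is recovered at meta-rank 1: it held fold-change rank 1 in
all four cohorts (`rho = 1/1321`), its BH-adjusted rank-product p-value is
1.6 × 10⁻⁹ (well below the 10⁻⁴ significance convention for such screens),
and Fisher's one-sided combination of the per-cohort moderated-t p-values
agrees. The same pipeline is available from the shell:

```
resistrank simulate --outdir sim --seed 1
resistrank meta --studies manifest.yaml --metabolic sim/metabolic.gmt --out meta.tsv
resistrank fitdose --data dose_response.tsv --out fit.json
```

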