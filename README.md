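# senescape

Quantifying the burden of cellular senescence in brain tissue, for
researchers analysing single-nucleus RNA-seq and imaging mass cytometry
(IMC) from Alzheimer's disease (AD) and control (NDC) cohorts.

Senescent cells — durably growth-arrested, stress-induced, and
secretory — accumulate in the ageing brain and are suspected
contributors to AD pathology, particularly in microglia near β-amyloid
plaques.  `senescape` implements the full quantification chain:

- **Gene-set scoring** per nucleus: rank-based AUC enrichment
  (AUC = Σᵢ y(i) / Σᵢ min(i, k) over the top 5% of ranked genes, where
  y(i) counts set genes at rank ≤ i) and a bin-matched control module
  score (mean set expression minus matched-bin control genes).
- **Senescent-nucleus calling** by a robust outlier rule: senescent if
  score > median + 3·(1.4826·MAD) within the cell type.
- **Group statistics**: Wilcoxon rank-sum contrasts of per-sample
  senescent proportions with the rank-biserial effect size
  r = P(x>y) − P(x<y) and bootstrap CI; Pearson regression against
  amyloid load; BH-FDR adjustment.
- **Age modelling**: the linear-plateau fit y = a + b·min(age, c) with
  a profiled breakpoint c and an F-test against an age-free null.
- **Meta-analysis**: Hedges' g per dataset on per-donor mean scores,
  pooled with DerSimonian–Laird random effects (tau², I², direction
  counts).
- **IMC spatial analysis**: 1% QC trimming, marker positivity (fixed /
  quantile / Otsu), cluster-level senescent proportions, and
  peri-plaque classification (cells within 10 µm of a plaque boundary).
- **Synthetic data** with planted ground truth for every stage, so the
  whole chain is testable end to end.

## Worked example

```python
from senescape import (ExpressionSimConfig, simulate_expression,
                       score_cells, call_senescent, sample_proportions)
from senescape.stats import contrast_proportions

dataset, gene_sets, truth = simulate_expression(ExpressionSimConfig(seed=1))
scores = score_cells(dataset, gene_sets, method="auc", seed=1)
calls = call_senescent(scores, dataset.cell_meta, group_by="cell_type")
props = sample_proportions(calls, dataset.cell_meta)
effects = contrast_proportions(props, truth.attrs["sample_meta"], seed=1)
print(effects[effects.cell_type == "Micro"]
      [["p_value", "rank_biserial", "ci_low", "ci_high"]])
```

prints

```
    p_value  rank_biserial  ci_low  ci_high
3  0.000899            1.0     1.0      1.0
```

— the synthetic cohort plants a senescent microglial fraction of 0.25
in AD vs 0.05 in NDC, and the pipeline recovers a complete separation
of the two arms' per-donor proportions (rank-biserial 1.0) with an
exact rank-sum p < 0.001.  On the same cohort the calls themselves
track the planted truth closely (AD 0.263 called vs 0.266 planted,
NDC 0.034 vs 0.034; `analysis/02_score_and_call.py`).

The numbered scripts under `analysis/` walk the full study:
simulation (`01`), scoring and calling (`02`), AD-vs-NDC contrasts and
the amyloid regression (`03`), the age-plateau fit (`04`), the
14-dataset meta-analysis (`05`), and the IMC peri-plaque contrast
(`06`).  Each writes its tables under `results/analysis/`.  The same
stages are exposed as a CLI (`senescape simulate|score|call|compare|
agefit|meta|spatial|run`); `senescape run --config run.yaml --outdir
out/` executes everything from one config with byte-reproducible
outputs.

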