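# tmakit

Analysis toolkit for tissue-microarray (TMA) marker data: batch correction,
per-marker distribution modelling, survival screening and correlation-network
inference, as a scriptable Python library with a matching `tmakit` CLI.

TMA studies measure protein expression for a modest panel of markers
(typically 4–16) across ~100 tumour samples, as continuous AQUA scores or
semi-continuous/categorical quickscores, usually with clinical follow-up
attached. tmakit covers the desk workflow for such grids:

* **Import** — markers as columns, samples as rows; replicates are columns
  with identical names, `*Batch` carries the TMA block, `*cov…` columns are
  covariates; CSV/TSV/XLSX in, with validation and discrepancy reports.
* **Batch correction** — parametric empirical-Bayes location/scale
  adjustment (per-batch additive effects γ and multiplicative effects δ,
  shrunk across markers with normal / inverse-gamma priors), adapted to
  sparse TMA grids by pairwise-complete estimation plus automatic screening
  of columns that cannot support per-batch estimates.
* **Distribution exploration** — adaptive-bandwidth kernel density
  estimates (Abramson's square-root law over a Silverman pilot) and
  univariate Gaussian mixtures fitted by EM, with the number of patient
  groups selected by BIC = −2 log L + (3K−1) ln n and samples assigned to
  the maximum-responsibility component.
* **Survival** — Kaplan–Meier product-limit curves and the Mantel-Cox
  log-rank test, screened across markers under mixture / tertile /
  categorical stratification with Benjamini–Hochberg FDR.
* **Networks** — Spearman (exact permutation null, AS 89 Edgeworth, or
  Student-t significance depending on n and ties), Pearson, or mutual
  information with a permutation null; Benjamini–Yekutieli (recommended),
  BH or Bonferroni adjustment; thresholded graphs exported as GraphML.
* **Synthetic cohorts** — a Gaussian-copula generator with exact mixture
  marginals, planted correlation blocks, batch effects, group-dependent
  exponential hazards and calibrated censoring, so every stage is testable
  against known ground truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Generate a synthetic 128-patient, 9-marker cohort (marker M1 is bimodal
with a 3× hazard ratio between its expression groups; the second TMA block
carries a planted batch effect), then run the full workflow:

```sh
tmakit simulate --seed 17 --out demo
tmakit combat   --in demo/grid.csv --out demo/corrected.csv --report demo/removals.json
tmakit mixture  --in demo/corrected.csv --marker M1 --kmax 3 --seed 17 --out demo/m1.json
tmakit survival --grid demo/corrected.csv --surv demo/surv.csv --mode mixture --seed 17 --out demo/survival.json
tmakit network  --grid demo/corrected.csv --method spearman --alpha 0.05 --adjust by --out demo/net.graphml --edges demo/edges.csv
```

The mixture step prints

```
M1: K=2, BIC=518.07
```

and writes the fitted model: two groups with means 1.45 (34% of patients,
"M1 low") and 5.83 (66%, "M1 high") — recovering the generating mixture
(means 1 and 5 before the batch shift, 30/70 weights). The survival screen
prints one line per testable marker, sorted by FDR-adjusted p:

```
M1: chi2=31.885 df=1 p=1.636e-08 FDR p=4.908e-08
M3: chi2=4.955 df=1 p=0.02601 FDR p=0.03902
M5: chi2=0.033 df=1 p=0.8566 FDR p=0.8566
```

The planted prognostic marker M1 dominates; M3 (correlated ρ = 0.6 with M1
by construction) inherits a weaker association; unimodal markers are
reported as skipped because mixture groups are undefined for them (use
`--mode tertile` to test those). The network step prints

```
6 significant edge(s) at BY p<=0.05; 5 component(s)
```

recovering the two planted three-marker correlation blocks {M1,M2,M3} and
{M4,M5,M6} plus three isolated null markers. `demo/edges.csv` holds the
full unthresholded edge table with per-edge statistics, p-values and the
significance regime used.

The same workflow is available programmatically (`tmakit.io`,
`tmakit.batch`, `tmakit.distribution`, `tmakit.survival`,
`tmakit.network`, `tmakit.synthetic`), and `tmakit run --config cfg.json`
executes the whole pipeline with a manifest recording versions, seeds and
input checksums.

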