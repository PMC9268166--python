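# lipochemo

Chemometric lipophilicity profiling for small-molecule series, built
around a 27-compound panel of anticancer sulfonamide derivatives whose
lipophilicity was measured both computationally (seven logP estimators)
and chromatographically (five reversed-phase / biomimetic HPLC indices).

The package answers the practical question such panels raise: *which
lipophilicity measure should you trust for this chemical series?*  It
provides:

- **Chromatographic-index transforms** — the linear calibrations
  `logk_IAM = 0.045·CHI_IAM + 0.42` (immobilized-artificial-membrane
  column) and `CHI logD = 0.0525·CHI_C18 − 1.467` (C18 column), plus the
  consensus logP (mean of five in-silico predictions).
- **Sum of ranking differences (SRD)** — for each measure, the city-block
  distance between its compound ranking and a row-average consensus
  ranking; validated by CRRN (the exact or Monte-Carlo null distribution
  of SRD under random rankings), 7-fold cross-validation, and pairwise
  Wilcoxon matched-pair grouping.
- **PCA and Ward/Euclidean cluster analysis** of the standardized
  measures.
- **GA-PLS QSRR/QSAR modelling** — genetic-algorithm selection of five
  descriptors feeding a three-latent-variable PLS regression, with the
  full external-validation battery (R², Q²loo, RMSE_CV, Q²F1, Q²F2, Q²F3,
  RMSEP, CCC), y-randomization, and a leverage applicability domain
  (Williams plot, h* = 3(p+1)/n_train).
- **Synthetic-data generators** with known ground truth (informative
  descriptor subsets; measure families that are noisy affine transforms
  of one latent lipophilicity scale) so every method is testable without
  proprietary descriptor software.

## Worked example

```python
from lipochemo import dataset, srd

panel = dataset.lipophilicity_panel()          # 27 compounds x 12 measures
res = srd.SRDAnalysis(panel, crrn_method="monte_carlo",
                      n_draws=1_000_000, seed=1).fit()
print(res.summary())
```

```
Sum of ranking differences (row-average reference)
  objects: 27   measures: 12

  measure                SRD     SRD%
  Consensus LogP        57.0    15.66
  WLogP                 74.0    20.33
  Silicos-IT LogP       76.0    20.88
  XLogP3                78.0    21.43
  MLogP                 86.0    23.63
  iLogP                117.0    32.14
  logk_IAM             129.0    35.44
  KOWWIN LogP          130.0    35.71
  logkw_C8             136.0    37.36
  logkw_CN             161.0    44.23
  CHI_logD             164.0    45.05
  logkw_Ph             164.0    45.05

  CRRN null (random rankings): 5%=192, 25%=222, 50%=244, 75%=264, 95%=292, mean=242.6
```

Reading this: the consensus logP ranks the 27 compounds most like the
all-measure consensus (smallest SRD), the in-silico estimators cluster
nearest the reference, and the CN/Ph/C18-derived chromatographic indices
sit furthest — yet *every* measure falls far below the 5% point of the
random-ranking null (SRD 192), so all are informative rather than random.
Among chromatographic indices, logk_IAM comes closest to the consensus.

The full analysis — transform audit, correlations, PCA, clustering, SRD
with CRRN and cross-validation, and a GA-PLS demonstration on synthetic
descriptors — runs as one command and writes a CSV/JSON report bundle:

```sh
lipochemo run --out results_dir --seed 1
```

A GA-PLS model on your own descriptor matrix (CSV with an endpoint
column):

```sh
lipochemo gapls --descriptors descriptors.csv --endpoint pIC50 --seed 1
```

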