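# mnshape

Reconstruction of **complex radiation exposure scenarios** — partial-body
shielding and neutron + photon mixtures — from the *shape* of
micronuclei-per-binucleated-cell count distributions measured by the
cytokinesis-block micronucleus (CBMN) assay.

After a large-scale radiological incident (e.g. an improvised nuclear
device), triage needs more than a single dose number: shielded, partial-body
exposures and high-RBE neutron components change treatment decisions. Both
leave a statistical fingerprint in the MN/cell count distribution even when
mean MN yields are identical: partial-body exposure turns Poisson counts
into a two-component Poisson mixture, and neutron tracks produce compound-
Poisson counts — both overdispersed, with heavy upper tails.

`mnshape` is aimed at biodosimetry researchers and method developers. It
provides:

* **Shape statistics** (`mnshape.features`) — ten per-sample predictors of
  the MN/cell histogram: `ln n`, `ln M`, `ln V`, the log dispersion index
  `ln(V/M)`, `ln(1+f_0)`, `ln(1+f_3)`, the squared-scaled Fisher dispersion
  statistic `ln[((1/√(2n))[(n−1)V/M − n])²]`, signed-log excess kurtosis and
  skewness, and the per-cell maximized log-likelihood gap between a
  geometric and a Poisson fit, `(LLexp − LLPois)/n`.
* **Classification and dose reconstruction** (`mnshape.models`) — repeated
  stratified half-split evaluation of per-outcome random forests, gradient
  boosting and logistic regression, with ROC AUC / R² repeat ranges,
  Spearman correlation matrices, and backward-elimination predictor
  reduction.
* **Neutron RBE estimation** — `PhotonEquivalentDoseFitter` scans candidate
  RBE values, regressing the photon-equivalent dose
  `D_photon + RBE · D_neutron` on the shape predictors; the RBE with the
  highest mean test R² is the best fit.
* **A synthetic-data generator** (`mnshape.synth`) — Poisson / Poisson-
  mixture / compound-Poisson samples with dose-dependent cell attrition and
  inter-sample jitter, emulating two study designs: homogeneous 0–8 Gy gamma
  vs. 1:1 blood mixtures (96 samples), and x rays vs. neutron+photon
  mixtures (40 pooled dose combinations).
* **Sample-table plumbing** (`mnshape.data`) — a canonical CSV schema for
  per-sample MN histograms plus exposure metadata, validation, and pooling
  by dose combination.

Transformers and estimators follow scikit-learn conventions
(`fit`/`transform`/`predict`, `get_params`, trailing-underscore fitted
attributes) and compose with sklearn pipelines.

## Worked example

```bash
mnshape simulate --scenario B --seed 5 --out samples.csv
mnshape features --in samples.csv --dataset B --out features.csv
mnshape evaluate --features features.csv --dataset B --model rf \
    --repeats 20 --seed 2 --report report.json
mnshape rbe-fit --features features.csv --grid 1:8:0.25 --repeats 16 \
    --seed 3 --report rbe.json
```

or, in Python:

```python
from mnshape import SynthConfig, generate_dataset_B, repeat_evaluate, fit_rbe
from mnshape.pipeline import build_table

table = build_table(generate_dataset_B(SynthConfig(), seed=5), "B")
res = repeat_evaluate(table, "rf", ["mix_index", "neutron_index"],
                      n_repeats=20, seed=2)
for name, s in res.summaries.items():
    print(name, s.metric, round(s.mean, 3), (round(s.min, 3), round(s.max, 3)))
rbe = fit_rbe(table, n_repeats=16, seed=3)
print("best RBE", round(rbe.best_rbe, 2))
```

On the default synthetic design this prints (your exact numbers depend on
the seeds):

```
mix_index auc 1.0 (1.0, 1.0)
neutron_index auc 0.988 (0.929, 1.0)
best RBE 4.4
```

`mix_index` AUC is the probability that a sample with ≥10% neutron
contribution outscores a pure-photon sample under the forest's score — here
the mixture is detected almost perfectly from distribution shape alone.
`neutron_index` is the analogous readout for detecting ≥0.5 Gy of neutrons,
and the best-fit RBE recovers the generator's damage-rate ratio (4.0).
Synthetic data is cleaner than real blood, so these figures are upper bounds
on assay performance, not estimates of it.

The full pipeline (`mnshape run --dataset A --out outdir` or
`mnshape replicate --in samples.csv ...` for an existing canonical CSV)
writes features, evaluation JSON, Spearman matrices, per-sample prediction
CSVs and a manifest that reproduces the run byte-for-byte.

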