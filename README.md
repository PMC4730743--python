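# clonofit

Statistical analysis of clonogenic (colony-formation) survival data.

Colony formation assays measure the fraction of single cells that retain
the capacity to grow into colonies (≥ 50 cells) after ionizing
irradiation. A panel experiment observes several cell lines at a common
dose grid (typically 0–10 Gy) in 3–4 independent replicates, and the
analyst wants (i) per-line dose-response parameters, (ii) a defensible
choice among candidate regression models, and (iii) panel-level summaries
that classify lines as radioresistant or radiosensitive and score them
quantitatively. `clonofit` provides all three for radiobiologists and
biostatisticians working with such panels.

## Models

**Linear-quadratic (LQ) regression** on the log scale, without intercept:

    ln SF = α·D + β·D², ε ~ N(0, σ²)

`α` (per Gy) and `β` (per Gy²) weight single-track and two-track
lethal damage; their quotient α/β (Gy) is the dose at which both terms
contribute equally and is the field's traditional radiosensitivity
summary (delta-method standard errors included).

**Constrained log-logistic regression** on the raw SF scale:

    SF = φ₁ + (1 − φ₁) / (1 + exp{φ₃[ln D − ln φ₂]})^φ₄ + ε

with SF(0) = 1 by construction. `φ₁` is the surviving fraction at
infinite dose, `φ₂` the midpoint dose (the median effective dose ED50
when φ₁ = 0, φ₄ = 1), `φ₃` a slope factor, `φ₄` an asymmetry parameter.
Fixing φ₄ = 1, then φ₁ = 0, then φ₃ = 1 gives a nested 4-/3-/2-/1-
parameter family (plus a 3-parameter Weibull comparator). A family
member is fitted jointly across the panel — per-line mean parameters,
one shared error variance — and members are ranked by

    AIC = 2(p + 1) − 2 ln L,

with a lack-of-fit F-test against the saturated cell-means ANOVA model.

**Panel summaries.** The cell-line × dose matrix of mean surviving
fractions (percent) feeds (a) Euclidean-distance Ward clustering with
silhouette validation — the best cut of the dendrogram classifies
resistant vs. sensitive lines — and (b) correlation-matrix PCA, whose
first component (all loadings positive) is a weighted radioresistance
score per line, correlated in turn with the fitted parameters.

A seeded synthetic module generates panels with the same design
(9 lines in two groups, doses 0–10 Gy, 3–4 replicates, SF-scale noise
0.075) from LQ or log-logistic truth curves, down to raw Poisson colony
counts.

## Worked example

```python
import clonofit as cf

ds = cf.paper_like_panel(0)                 # 9-line synthetic panel
sel = cf.select_models(ds, ["ll4", "ll3", "ll2", "ll1"],
                       prefer_free_asymptote=True, seed=0)
print(sel.as_frame())
```

```
model      loglik  n_params         aic  sigma_hat
  ll3  290.656403        28 -525.312805   0.056150
  ll2  281.114180        19 -524.228361   0.057483
  ll4  295.915307        37 -517.830614   0.056192
  ll1  131.873671        10 -243.747343   0.123404
```

The three-parameter member wins on AIC (−525.3; `n_params` counts the
9 × 3 per-line parameters plus the shared variance), and its residual
standard error 0.056 on the SF scale is an order of magnitude below the
pooled LQ value on the log scale (0.572 here) — the sigmoid tracks the
raw survival curve far more closely than the log-scale polynomial.
Continuing,

```python
ll3 = next(e.fit for e in sel.entries if e.spec_name == "ll3")
cf.lack_of_fit_test(ll3, ds)        # F = 0.914, p = 0.611: no lack of fit
{c: round(cf.effective_dose(p, 0.5), 2) for c, p in ll3.params.items()}
```

gives per-line ED50 values of 1.24–1.43 Gy for the three sensitive lines
and 2.51–2.74 Gy for the six resistant ones. Clustering and PCA recover
the same structure:

```python
X = cf.mean_sf_matrix(ds)
D = cf.euclidean_distances(X)
sol = cf.best_cut(cf.agglomerate(D))        # k = 2, true groups recovered
cf.silhouette(D, sol).average               # 0.74: a clear classification
scores = cf.radioresistance_scores(cf.panel_pca(X))
```

The first-PC scores range from −2.69 (most sensitive line) to +2.47
(most resistant), ordering the panel by radioresistance over the whole
dose range.

The same pipeline is available from the shell:

```sh
clonofit simulate --seed 0 --out panel.csv
clonofit report --input panel.csv --seed 0 --out report.json
```

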