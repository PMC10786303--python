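# synchwave

Wavelet analysis of **spatial synchrony** — the tendency of an ecological
variable to fluctuate in step across separated sites — and of the drivers
that cause it. The package was built around a cross-ecosystem
resource-subsidy question: giant-kelp detritus (*wrack*) is deposited on
sandy beaches in amounts that rise and fall together across beaches, and
that synchrony propagates up the beach food web to the shorebirds that
forage there. The same machinery applies to any small set of sites observed
on a common monthly grid.

## What it computes

For an N-site × T-month matrix `x_n(t)` the package forms continuous Morlet
wavelet transforms `W_n(t, σ)` (timescale σ in months equals the period of
maximal response) and from them:

- **Wavelet mean field (WMF)** — the across-site average of
  power-normalized transforms; `|WMF|²` measures synchrony at each time and
  timescale.
- **Wavelet phasor mean field (WPMF)** — the across-site average of unit
  phasors `W/|W|`, in [0, 1]; significance comes from the null of N
  independent uniform phasors (the (1−α) quantile of `|mean phasor|` over
  1,000 random draws).
- **Spatial wavelet coherence** — for two variables,
  `⟨conj(w̃x) · w̃y⟩` averaged over sites, valid times and a timescale band
  (2–8, 8–16, 16–60 months by default). Magnitude ≤ 1 measures association;
  the argument φ, in fractions of π, is the temporal offset (negative ⇒ the
  response lags the driver). Significance uses Fourier-surrogate drivers
  with phases shared across sites, evaluated either by brute force ("slow")
  or by an exact frequency-domain linearization ("fast").
- **Wavelet linear models (WLM)** — per-timescale complex least-squares
  regression of the response field on coherent driver fields, with the
  exact decomposition
  `S_mod = Σ_j ⟨|M_j|²⟩ + Σ_{j<k} ⟨2 Re(M_j conj(M_k))⟩`
  splitting model-predicted synchrony into per-driver contributions and
  signed pairwise interaction terms, and `S_mod / S_obs` the fraction of
  observed synchrony explained.
- **The cascade pipeline** — aggregation of raw survey tables, wave-series
  first-differencing, driver screening at P < 0.1 with a local/regional
  kelp tiebreak, per-band wrack models, and shorebird models with wrack and
  air temperature as predictors.
- **A synthetic-data generator** — seeded site×month datasets with known
  Moran (shared-driver) structure, mechanistic wrack formation and a lagged
  consumer, so every stage can be tested against ground truth.

## Worked example

```python
from synchwave import (CascadeConfig, CascadeScenario,
                       generate_cascade_scenario, run_cascade)

variables, truth = generate_cascade_scenario(CascadeScenario(seed=42))
report = run_cascade(variables, CascadeConfig(n_surr=1000, seed=7))
d = report.to_dict()

for r in d["wrack_screening"]["rows"]:
    if r["band"] == "8-16":
        print(f"{r['driver']:14s} p={r['p_value']:.3f} "
              f"phi={r['phi']:+.2f} selected={r['selected']}")
m = d["wrack_models"]["8-16"]
print("sync explained:", round(m["sync_explained"], 3))
bc = d["bird_coherence"]["8-16"]
print(f"birds~wrack: p={bc['p_value']:.4f} phi={bc['phi_fractions_of_pi']:.3f}")
```

prints

```
kelp_local     p=0.095 phi=+0.06 selected=False
kelp_regional  p=0.004 phi=-0.12 selected=True
waves          p=0.027 phi=-0.19 selected=True
width          p=0.126 phi=+0.04 selected=False
sync explained: 0.89
birds~wrack: p=0.0010 phi=-0.167
```

Reading this: in the annual (8–16 month) band, the regional kelp analog is
coherent with wrack (p = 0.004) and is selected over the local analog
(p = 0.095, and only the lower-p kelp scale enters the model); the
wave-change analog is also selected. The two selected drivers explain 89%
of time-averaged wrack synchrony in the band. Shorebird abundance is
strongly coherent with wrack (p = 0.001) at a phase of −0.167 fractions of
π — exactly the −2·ℓ/12 signature of the generator's ℓ = 1 month
consumer lag at the 12-month timescale.

The same stages are scriptable from a shell (`synchwave simulate`,
`transform`, `meanfield`, `coherence`, `wlm`, `cascade`); see
`synchwave --help`.

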