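# mastsecr

Spatially explicit capture–recapture (SECR) analysis of density and
space use in cyclic small-mammal populations — built for studies that
live-trap rodents on grids across the boom (first summer after a tree
mast year, FSA) and bust (second summer, SSA) phases of a
masting-driven population cycle, and ask whether the relationship
between population density and home-range size differs between phases.

It is aimed at field ecologists with standard trap-layout and
capture-history tables (a secr-style TSV dialect) and at methodologists
who want a self-contained, simulation-validated multi-catch SECR
likelihood in Python.

## The model

Each animal holds an unobserved activity centre `x`; centres follow a
homogeneous Poisson process with intensity `D` (animals/ha).  A trap at
distance `d` from the centre accrues per-night detection hazard

    h(d) = λ0 · exp(−d² / (2σ²)),

and with several multi-catch traps competing the animal enters trap
`k` with probability `(h_k/H)(1 − e^{−H})`, `H = Σ h_k`, or escapes
with probability `e^{−H}`.  Integrating the unknown centres over a
buffered habitat mask gives the full Poisson likelihood

    log L = −D·a(θ) + n·log D + Σ_i log[c Σ_m Pr(ω_i|x_m)] − log n!,

maximised to estimate `D`, the spatial scale of detection `σ` (a
model-based index of home-range size), `λ0`, and optionally a global
behavioural response `b` (change in `λ0` after first capture).
Candidate structures (each parameter constant or session-specific) are
ranked by AICc with Akaike weights.  The derived overlap index
`k = σ√D/100` and `S95 = 6πk²` (individuals within one 95% home range)
quantify home-range overlap, and a second stage of linear mixed models
(random intercept per site, Wald Type II tests) asks whether density
and space use — and the density–space-use relationship itself — differ
between mast phases and sexes.  A synthetic-data module simulates the
whole design from the same detection model.

## Worked example

Simulate one 5-night session on an 8×8 grid of traps 10 m apart, with
25 animals/ha, σ = 12 m and λ0 = 0.5, then re-estimate the parameters:

```python
import numpy as np
import mastsecr as m

rng = np.random.default_rng(11)
traps = m.TrapArray.grid(8, 8, 10.0)
params = m.DetectionParams(lambda0=0.5, sigma=12.0)
session, centers = m.simulate_session(
    25.0, params, traps, K=5, buffer_sim=150.0, rng=rng)

res = m.SecrModel([session], traps).fit()
print(res.summary())
```

```
SECR fit (Poisson likelihood, half-normal multi-catch)
  structure : lambda0~(.), D~(.), sigma~(.)
  sessions  : 1   individuals: 30
  mask      : 660 points, 6.60 ha (buffer 100 m, spacing 10 m)
  logLik    : -426.606   parameters: 3   converged: True

session parameter  estimate  se_log
    all         D   21.7403  0.1936
    all     sigma   11.8266  0.0720
    all   lambda0    0.4389  0.1945
```

Thirty animals were detected; the estimates 21.7 animals/ha and
σ = 11.8 m sit within one standard error (log scale) of the generating
25/ha and 12 m.  The derived overlap statistics:

```python
D_hat, s_hat = 21.7403, 11.8266
k = m.k_index(D_hat, s_hat)       # 0.551
m.s95(k)                          # 5.73 individuals per 95% home range
```

A `k` near 0.55 and roughly 5–6 individuals sharing each home range is
what a post-mast peak population looks like; crash-phase populations
run nearer `k ≈ 0.3` and `S95 ≈ 2–3`.

The whole chain — candidate-model fitting per site and sex, AICc
tables, overlap statistics, and the two mixed models — runs from the
shell:

```sh
mastsecr simulate --seed 1 --out data/
mastsecr pipeline --traps data/traps.tsv --captures data/captures.tsv \
                  --config data/config.yaml --out analysis/
```

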