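# Methods

## The estimation problem

Live-trapping a small-mammal population on a grid yields spatial capture
histories: which animals were caught, in which traps, on which nights.
Spatially explicit capture–recapture (SECR) turns these into joint
estimates of population density `D` (animals/ha) and the spatial scale
of detection `σ` (metres).  Each animal is assumed to hold a fixed but
unobserved activity centre `x`; the chance of entering a trap decays
with the distance between the centre and the trap.  Because `σ` indexes
how far an animal ranges from its centre, it serves as a model-based
measure of home-range size, and the pair `(D, σ)` lets one ask how space
use responds to density — here, across the peak (first summer after a
beech mast autumn, FSA) and crash (second summer, SSA) phases of a
masting-driven population cycle.

## Detection model

Detection follows a half-normal hazard

    h(d) = λ0 · exp(−d² / (2σ²)),

where `λ0` is the per-occasion cumulative hazard of entering a trap
placed exactly at the activity centre.  `λ0` is treated as a hazard, not
a probability.  This is a deliberate design choice: with several traps
competing for one animal, per-trap probabilities cannot be combined
coherently, whereas hazards add.  For a multi-catch trap array the
per-occasion outcome is an exact multinomial (competing risks):

    H(x)    = Σ_k h_k(x)
    p_k(x)  = (h_k / H) · (1 − e^{−H})    (caught in trap k)
    p_0(x)  = e^{−H}                      (not caught)

An optional global behavioural response multiplies `λ0` by `b` from the
occasion *after* an animal's first capture within a session (`b > 1`
trap-happy, `b < 1` trap-shy); it resets between sessions because
sessions are modelled as independent populations.  The probability of
being detected at least once in `K` occasions uses the naive `λ0`
throughout — every occasion before a first capture is by definition
naive — giving `p·(x) = 1 − e^{−K·H(x)}`.

## Likelihood

Activity centres follow a homogeneous Poisson process with intensity
`D` over the plane.  The likelihood integrates the unobserved centres
over a habitat mask: a regular grid of points (default spacing 10 m,
equal to the trap spacing) clipped to within a 100-m buffer of the
nearest trap, each point representing a cell of area `c` hectares.  The
full (Poisson-n) session log-likelihood is

    log L = −D·a(θ) + n·log D + Σ_i log[ c Σ_m Pr(ω_i | x_m) ] − log n!

with `a(θ) = c Σ_m p·(x_m)` the effective sampling area and
`Pr(ω_i|x)` the product over occasions of the multinomial terms above,
with behavioural switching.  The `−log n!` constant is kept so
log-likelihoods are comparable across model structures.

Across sessions, each of `D`, `σ` and `λ0` may be shared ("constant")
or session-specific ("by-session"); `b` is always a single global
parameter when present.  Sites are fitted independently, which is
exactly equivalent to a joint model in which every parameter is
site-specific, and keeps each optimisation small.

Numerics: all parameters are log-transformed; optimisation is L-BFGS-B
with an analytic gradient (verified against finite differences) and an
objective tolerance of 1e−12; starting values are `D = n /` mask area,
`σ` = half the mean displacement between successive captures of the
same animal (falling back to half the trap spacing when no such
recaptures exist), `λ0 = 0.3`, `b = 1`.  Richer structures are
warm-started from the all-constant fit when ranked together.  Wald
standard errors come from the inverse observed information
(central-difference Hessian of the analytic gradient); confidence
intervals are computed on the log scale and exponentiated, so lower
bounds are positive.  Kernel sums that underflow at extreme trial
parameter values during line search are floored at 1e−290 to keep the
objective finite; the floored cells contribute nothing at any relevant
parameter value.

## Model selection

The default candidate set crosses `D` (constant/by-session) × `σ`
(constant/by-session) × `λ0` in three flavours (constant, by-session,
constant plus behavioural response), giving 12 models.  A fourth `λ0`
flavour (by-session plus behavioural) is expressible and can be added
through a user-supplied spec list; the 12-model default is one reading
of a design whose published description is ambiguous between 8, 12 and
16 crossings.  Ranking uses AICc with `n` = the number of distinct
individuals detected (standard SECR practice), Akaike weights
`w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2)`, and evidence ratios `w_i/w_j`.
Models whose `n ≤ K+1` are excluded from ranking with a logged warning.
AICc ties break toward fewer parameters, then enumeration order.

## Overlap statistics

With `D` in animals/ha and `σ` in metres, the home-range overlap index
is defined here as

    k = σ·√D / 100,

dimensionless because √(animals/ha) = √animals / 100 m.  Constant `k`
forces `σ ∝ D^{−1/2}` — a log-log slope of exactly −0.5 — so a phase
difference in `k` appears as an intercept shift in the log σ versus
log D relation.  `S95 = 6πk²` estimates how many individuals occur
within one animal's 95% home range.  Phase-level `S95` is reported both
ways the averaging order allows — `6π·(mean k)²` and the mean of
per-session `6πk²` — because the two differ by a Jensen gap whenever
`k` varies within a phase and published values do not always state
which convention was used.

## The mixed-model stage

Session-specific estimates `(D̂, σ̂)` per site, month and sex become rows
of a space-use table and feed two Gaussian linear mixed models with a
random intercept per site, fitted by maximum likelihood (not REML, so
likelihoods are comparable across fixed-effect structures):

* density model: `log D̂ ~ mast × sex + month`
* sigma model:  `log σ̂ ~ (log D̂ + mast + sex)² two-way + month`

SSA and female are the reference levels, so the `mast` coefficient
reads as the FSA offset.  Month enters as a centred numeric covariate
(June = 6 … September = 9, centred at 7.5); the density model includes
it for symmetry with the sigma model.  Whether month should be numeric
or categorical is a genuinely open design point; numeric-centred was
chosen as the minimal covariate adjustment.

Fixed effects are screened with Wald Type II chi-square tests: the
term's coefficient block is tested in the model containing every other
term except the higher-order interactions containing it, using that
model's ML covariance.  On balanced orthogonal designs this reproduces
the sequential (Type I) statistic exactly, and under a null mast effect
its rejection rate calibrates to the nominal 5% level (checked by
simulation in the test suite).  When the site variance is estimated
exactly at the zero boundary the ML mixed fit coincides with OLS; the
implementation falls back to an OLS fit with ML-scaled covariance and
flags the boundary rather than failing.

First-stage estimation uncertainty in `(D̂, σ̂)` is ignored by the second
stage — point estimates enter at face value.  This understates
second-stage standard errors and attenuates the fitted log D slope
toward zero (classical errors-in-variables dilution); the simulation
tests show the recovered slope averaging ≈ −0.46 against the generating
−0.5 for exactly this reason.

## Synthetic data

The generator inverts the fitted model, so simulator and likelihood
validate each other end to end.  One session: `N ~ Poisson(D × area)`
centres uniform on the trap bounding box padded by `buffer_sim`
(default 150 m, beyond the 100-m analysis buffer so edge animals are
representable; truth densities refer to this padded region); per
occasion each animal is caught with probability `1 − e^{−H}` and
allocated to a trap with probability proportional to its half-normal
kernel, with behavioural switching after the first capture; only
detected animals appear in the output.

The mast-cycle scenario emulates the study design: 8 sites, 8×8 grids
at 10-m spacing, 5-night sessions, June–September over four years
alternating FSA/SSA.  Per site × session × sex, density is drawn from a
lognormal moment-matched to the phase- and sex-specific mean and SD on
the natural scale (FSA 27.68 ± 17.61 male / 22.36 ± 15.89 female;
SSA 6.37 ± 5.95 / 5.26 ± 5.33 animals/ha — positivity plus the large
dispersions make the lognormal the natural choice), and `σ` is tied to
density through the phase–sex overlap index (`k` = 0.58/0.54 FSA,
0.37/0.30 SSA) via `σ = 100k/√D`.  No `λ0` or behavioural magnitude is
published for this system; the defaults `λ0 = 0.5`, `b = 1` (with a
trap-happy preset `b = 1.5`) are artifact choices picked to reproduce
the published magnitudes of `k`, density, and per-session sample sizes.

What the generator does *not* emulate: within-session movement of
activity centres, kin-structured spatial clustering, open-population
turnover between months, trap saturation, and inter-site distance
effects.  Passing tests therefore demonstrate internal consistency of
the estimator and pipeline under the stated model, not robustness to
these violations.

## Problem sizes in the test suite

The simulation-based tests use deliberately scaled problem sizes chosen
to keep Monte-Carlo margins comfortable: parameter recovery uses 100
single-session fits on the full 8×8/100-m design at 10-m mask spacing;
structure recovery uses 50 replicates of six sessions ranked over the
12-model grid at 25-m mask spacing (mask coarseness shifts all
candidates alike and leaves the ranking informative), with the
behavioural effect set to `b = 2`, a realistic magnitude for strongly
trap-happy mice in baited live traps and large enough to be
identifiable at ~120 individuals per replicate; the mixed-model
recovery uses 20 replicates of a 4-site, 2-year, 4-month scenario at
15-m mask spacing, dropping sessions with fewer than three detected
individuals (session-specific parameters are not usefully estimable
below that).

## Known limitations

* Homogeneous density only; no density surfaces or covariates on `D`.
* Multi-catch likelihood applied to traps that physically hold one or
  two animals; this misspecification is known to leave `D` and `σ`
  nearly unbiased but is not corrected.
* No errors-in-variables treatment of the two-stage pipeline (see
  above).
* Wald (not profile) intervals; with few detected animals the log-scale
  Wald interval can be poorly calibrated.
* Closed-population sessions; animals recaptured in later months are
  treated as new detections in that month's session.
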