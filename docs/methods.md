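# Methods

## Coupled binding equilibria

The sensor protein is modelled with sequential macroscopic (Adair)
association constants: `logK = (logK₁ … logKₙ)` in log₁₀ M⁻¹, cumulative
products `βᵢ = Π_{j≤i} 10^logKⱼ`, occupancy
`ν(x) = Σ i βᵢ xⁱ / (1 + Σ βᵢ xⁱ)`. Macroscopic constants describe the
i-th binding event regardless of which site fills; site-specific
(microscopic) models are out of scope. Because the βᵢ are cumulative
products, the polynomial is *not* invariant under permutation of the
stepwise constants; fits therefore report constants in the order the
optimizer resolves them, and only the apparent affinity
`K_d^app = 10^(−mean logKᵢ)` (the geometric mean of stepwise K_d's) is
permutation-invariant. Occupancy is evaluated with a log-sum-exp
factoring so extreme β·xⁱ terms cannot overflow.

Titrations are performed against 1 mM Mg²⁺ background; the fitted
constants are Mg²⁺-background-conditional, as such assays convention­ally
report them. Mg²⁺ is not modelled as a competing ligand.

**Free-Ca²⁺ solver.** `f(x) = x + Q·x/(K_d+x) + P·ν(x) − Ca_total` is
strictly increasing on `[0, Ca_total]`, so the root is unique. Brent's
method is used with `xtol` scaled to `1e-16·Ca_total` (micromolar
problems converge to machine precision rather than to a fixed absolute
floor); the result is verified against the balance at 1e-10 relative and
a diagnostic error is raised otherwise.

**Chelator.** 5,5′Br₂-BAPTA is a one-site chromophoric chelator whose
263-nm absorbance falls on Ca²⁺ binding. Its K_d is buffer-dependent and
is configurable; the default 2.3 µM is a literature calibration value for
this ionic-strength regime, not a value fitted here. The default optical
endpoints (0.55 → 0.15 AU) describe a ~25 µM chelator solution in a 1-cm
cuvette. Residual Ca²⁺ after buffer decalcification (0.15–0.7 µM in
practice) can be modelled as an additive offset `ca0`, default 0,
optionally fitted.

**Titration fit.** Nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) in log-constant space with each logK bounded in
[2, 10] — positivity is enforced and the objective is better conditioned
than in linear K. By default the optical endpoints are fitted jointly
with the constants, because the observed extrema of a noisy series
underestimate the true asymptotes; fixed-endpoint fitting is available.
Eight jittered restarts of the logK initialisation (seeded, ±1 log unit)
guard against local minima of the three-site model; the best-RSS solution
is kept. Standard errors are Gauss-Newton approximations from
`(JᵀJ)⁻¹·s²` at the optimum. Replicate-level aggregation
(`aggregate_replicate_fits`) averages per-replicate constants and reports
their standard deviation, matching how such assays are tabulated.
Normalised coordinates follow the assay convention
`x = Ca_total/(Q + n·P)`, `y = (A − A_min)/(A_max − A_min)` with the
observed extrema as default endpoints.

## Cyclase regulation

Activity curves use the four-parameter Hill form with free top and bottom
plateaus (measured curves plateau above zero at saturating Ca²⁺):
decreasing in free Ca²⁺ for inhibition (midpoint IC₅₀), increasing in
activator concentration for activation (EC₅₀). Fitting is done in linear
dose space so the zero/near-zero dose participates; the midpoint is
multi-started log-spaced across the dose range. Orientation is sanity-
checked with a Spearman trend before fitting; opposing data are returned
flagged, never silently fitted. Activity units are caller-defined and all
fitted quantities are equivariant under unit rescaling (half-point and h
invariant; plateaus scale). `X-fold = (GC_max − GC_min)/GC_min` with
GC_min > 0 required. Condition comparisons default to Welch's
unequal-variance two-tailed t-test; zero-variance/equal-mean input
returns t=0, p=1 with a `degenerate` flag.

## Thermal denaturation

Two-state model with sloping linear baselines,

    θ(T) = [(b_n + k_n·T) + (b_u + k_u·T)·K(T)] / [1 + K(T)],
    K(T) = exp(−ΔG_nu(T)/RT),
    ΔG_nu(T) = ΔH(1 − T/T_m) + ΔC_p(T − T_m − T·ln(T/T_m)),

with T in Kelvin internally, R = 8.314 J/(mol·K), and the *stability*
sign convention: ΔG_nu > 0 below T_m for ΔH > 0 (unfolding is
unfavourable for a stable protein); the opposite (folding) convention is
available via `stability_convention=False`. ΔC_p is fixed at 0 by default
— it is weakly identifiable from a single melt — and fitting it is
opt-in. Baselines are initialised from linear fits to the first/last 20%
of points and T_m from the steepest-gradient temperature, with extra
starts at and beyond the window edge so incomplete melts are still
optimised. A fitted midpoint above the scanned window is reported as
"T_m > window max" (`in_window=False`) rather than forced inside —
Ca²⁺-loaded EF-hand sensors typically do not complete their transition by
96 °C — and a trace indistinguishable from a straight line is flagged as
having no transition. Percent unfolding `|θ(96)−θ(20)|/|θ(20)|·100` and
the ion-induced change `|θ₂₂₂^ion−θ₂₂₂^ref|/|θ₂₂₂^ref|·100` are reported
as magnitudes, since ratios of negative ellipticities are tabulated as
positive percentages.

## Hydrodynamics

`D_c = (V_e − V_v)/(V_t − V_v)` with the default column geometry
V_t = 25 mL, V_v = 8 mL (a Superose-12-class analytical column). MW
calibration is ordinary least squares of log₁₀(MW/kDa) on D_c over
user-supplied or synthetic standards (no published standard set is
bundled); queries far outside the standards' range warn. DLS summaries
are the mean ± s.e.m. of the first 30 diameter measurements; the mean
count rate series is exported with a centred moving average only — its
slow oscillations are treated descriptively, with no periodicity
estimation.

## Synthetic data

Each generator is a pure function of (truth parameters, protocol, seed).
Protocol defaults mirror the assays: titrations add Ca²⁺ in 3 µM steps
from 0 into 25 µM chelator + 20 µM protein; inhibition curves use 12
log-spaced doses spanning 19 nM–1 mM; activation curves 8 linear doses
over 0–10 µM including the zero baseline; melts 77 points over 20–96 °C.
Noise defaults — 1% of optical span (absolute) for titrations, 5%
proportional for activity, 2% of trace span for melts — were chosen to
match the visual scatter of typical published panels of these assays.
Melt generation defaults to ΔH = 300 kJ/mol, ΔC_p = 0 and baselines
giving a ~−20 mdeg native trace relaxing to ~−15 mdeg, i.e. ~30% signal
loss over the scan. The activation generator's default cooperativity is
h = 2 (the characterised activation data set is summarised by its EC₅₀
only, and GC activation by GCAP1 is cooperative with h near 2); EC₅₀
recovery is insensitive to this choice within the fitted range.

The generators emulate measurement noise only: no instrument drift,
photobleaching, scan-rate hysteresis, baseline wander or dilution series
artefacts. Passing recovery tests therefore demonstrates estimator
correctness and statistical calibration under idealised Gaussian noise,
not robustness to every systematic error of real traces. Dilution during
stepwise additions is treated as negligible by default (an optional
per-point volume correction exists in the protocol design space but the
generators do not exercise it).

## Recovery experiments (acceptance script)

`scripts/acceptance.py` runs, per seed, 100 replicate simulate-and-fit
cycles for each assay — a problem size that makes the medians stable to
well under the comparison tolerances while completing in seconds — and
reports median fitted IC₅₀ and h (Ca²⁺ inhibition at truth 0.52 µM /
1.77, plateaus 4.9/1.0 giving X-fold 3.9), median EC₅₀ (activation at
truth 1.6 µM, h = 2), and median T_m (melts at truth 48.1 °C, the
apo-state midpoint of the N104H variant). Replicate seeds derive
deterministically from `--seed`.

## Known limitations

- Macroscopic constants only; no site assignment or microscopic coupling.
- The chelator K_d is taken as known; errors in it propagate into logK.
- Single-melt fits cannot separate ΔC_p from baselines; fixed 0 default.
- Hill fits with few doses and free plateaus can trade h against the
  plateaus at high noise; medians across replicates remain calibrated.
- SEC apparent MWs depend entirely on the supplied calibration standards.
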