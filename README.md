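# casensor

Biophysical characterisation toolkit for EF-hand Ca²⁺ sensor proteins,
built around the assay chain used to study disease-associated variants of
GCAP1 (guanylate cyclase-activating protein 1), the neuronal calcium
sensor that switches retinal guanylate cyclase (GC) between cGMP synthesis
and inhibition as intracellular Ca²⁺ falls and rises during the
photoresponse. It is aimed at protein biochemists who run these assays —
chelator-competition Ca²⁺ titrations, GC reconstitution activity curves,
CD thermal melts, analytical SEC and DLS — and want a reproducible,
scriptable analysis with synthetic-data generators for validation.

## What it computes

**Ca²⁺ binding (chelator competition).** A sequential n-site macroscopic
(Adair) model with stepwise association constants `K₁…Kₙ` (stored as
log₁₀) defines the binding polynomial `Z(x) = 1 + Σᵢ βᵢ xⁱ`,
`βᵢ = Π_{j≤i} Kⱼ`, and mean occupancy `ν(x) = Σᵢ i βᵢ xⁱ / Z(x)`.
Titrating total Ca²⁺ into a mixture of protein and the chromophoric
chelator 5,5′Br₂-BAPTA (absorbance at 263 nm drops on Ca²⁺ binding)
couples the two equilibria through the mass balance

    Ca_total = x + Q·x/(K_d + x) + P·ν(x),

which `solve_free_ca` inverts exactly (bracketed root search, mass balance
conserved to 1e-10 relative). `fit_binding_constants` recovers the logKᵢ
from the absorbance trace by nonlinear least squares against this forward
model, and the apparent affinity is the geometric mean of the stepwise
dissociation constants, `K_d^app = 10^(−mean(logKᵢ))`.

**GC regulation.** Four-parameter Hill fits of cyclase activity, either
decreasing in free Ca²⁺ (IC₅₀, cooperativity h) or increasing in activator
concentration (EC₅₀); the dynamic range is
`X-fold = (GC_max − GC_min)/GC_min`, and condition comparisons use a
two-tailed (Welch) t-test.

**Thermal stability.** Two-state unfolding fits of CD melting traces
(ellipticity at 222 nm) with sloping native/unfolded baselines and the
Gibbs–Helmholtz stability curve
`ΔG_nu(T) = ΔH(1 − T/T_m) + ΔC_p(T − T_m − T·ln(T/T_m))`; melts that do
not reach their midpoint inside the scanned window are flagged
("T_m > window max") rather than forced. Spectral descriptors
(θ₂₂₂/θ₂₀₈, ion-induced Δθ/θ, % unfolding) are computed from far-UV traces.

**Hydrodynamics.** SEC distribution coefficient
`D_c = (V_e − V_v)/(V_t − V_v)`, apparent MW from a log₁₀(MW)-vs-D_c
calibration, oligomer ratio versus the monomer MW, and DLS diameter
summaries (mean ± s.e.m. of the first 30 measurements).

**Synthetic data.** Seeded generators emulate every assay series from
known truth parameters with configurable Gaussian noise, so the whole
pipeline is testable without wet-lab data; `PRESETS` carries the
characterised parameter sets of the WT and N104H GCAP1 variants.

## Worked example

```python
import casensor as cs

# apparent Ca2+ affinity from fitted macroscopic constants
print(cs.kd_apparent([5.92, 4.70, 4.23]) * 1e6)   # 11.22018454301963 (µM)
print(cs.kd_apparent([7.07, 5.55]) * 1e6)         # 0.48977881936844564 (µM)

# simulate a competition titration from the N104H preset and re-fit it
model = cs.SequentialBindingModel(cs.PRESETS["N104H"]["logK"])
series = cs.gen_titration(model, p_total=20e-6, q_total=25e-6, n_points=40)
fit = cs.fit_binding_constants(series, cs.DEFAULT_CHELATOR, n_sites=3)
print(fit.logK)        # (5.92, 4.70, 4.23) to ~1e-12 on noise-free data
print(fit.kd_app*1e6)  # 11.220184543017107 (µM)
```

The first two numbers are the apparent dissociation constants implied by
the tabulated binding constants of the N104H variant (11.2 µM, a ~20-fold
affinity loss) and the wild type (0.49 µM). The round trip shows that the
fitter recovers the generating constants from a clean synthetic titration.

From the shell:

```bash
casensor simulate ca_inhibition --noise-sigma 0.05 --seed 3 --out-dir demo
#    N104H        IC50 = 0.4892 uM
#    N104H           h = 1.692
#    N104H      X-fold = 3.94
```

i.e. one noisy (5%) simulated Ca²⁺-inhibition curve generated from the
N104H preset (true IC₅₀ 0.52 µM, h 1.77, X-fold 3.9) and fitted back.
Other subcommands: `simulate`, `fit-titration`, `fit-gc`, `fit-melt`,
`sec`, `report` (YAML-configured; exit codes 0 OK, 2 input error, 3
non-convergence).

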