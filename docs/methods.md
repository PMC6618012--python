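# Methods

## The model

`leafrd` solves steady-state CO2 transport, fixation and respiratory
release inside a simplified two-dimensional mesophyll unit cell and uses
that forward model to estimate photosynthetic parameters — above all day
respiration, Rd — from combined gas-exchange and chlorophyll-fluorescence
response curves.

The unit cell is one half of a repeating palisade-cell motif: a depth
stack of cell wall (thickness `twall`), outer cytosol (`tcyt`),
chloroplast stroma (`tstr`) and inner cytosol (`tcyt_inner`), bounded on
the inside by the tonoplast (treated as impermeable: the vacuole is not
simulated). Laterally the chloroplast covers a fraction Sc/Sm of the
cell; the remaining strip is the cytosol gap connecting outer and inner
cytosol between neighbouring chloroplasts. Lateral symmetry planes at
the chloroplast mid-plane and the mid-gap plane are no-flux, so the
computational domain is the half cell. The lateral chloroplast
half-width (default 5 µm, a typical chloroplast scale) only matters
through the gap width `lchl (1/ScSm − 1)`; all trends are controlled by
the dimensionless Sc/Sm.

The steady concentration field C(x, y) (liquid-phase partial-pressure
equivalents, Pa) satisfies

    ∇·(D_eff ∇C) − sink(C) + source = 0

with layerwise effective diffusivity `D_eff = f_layer · D_water` and
explicit membrane conductances at the plasma membrane and the
chloroplast envelope (flux = P·ΔC, inserted in series on the shared cell
face). Carboxylation consumes CO2 in the stroma at the pointwise minimum
of the Rubisco-limited and electron-transport-limited Michaelis–Menten
branches,

    w_c = Vmax,vol · C / (C + KmC(1 + O/KmO)),
    w_j = (Jvol/4) · C / (C + 2Γ*),      w = min(w_c, w_j),

with Γ* = 0.5·O/(Sc/o). Each unit of carboxylation at local pressure C
is accompanied by photorespiratory release of Γ*/C units of CO2
(Vo/Vc = 2Γ*/C, half a CO2 per oxygenation). That release, plus day
respiration Rd, is re-injected uniformly in one of three cytosolic
source regions representing the mitochondria position ("release
scenario"): the inner cytosol (between chloroplast and tonoplast), the
cytosol gaps, or the outer cytosol (between plasma membrane and
envelope). TPU limitation is applied as a leaf-level cap
AN ≤ 3Tp − Rd on the reported assimilation, not as a local rate law.

Leaf-level rates convert to the cell scale through Sm/S (mesophyll
surface per leaf surface) and the stroma volume per mesophyll area
tstr·(Sc/Sm); the solubility (Henry) constant closes the gas/liquid unit
conversion.

### Boundary modes

* **Ci-driven**: the intercellular CO2 pressure Ci is imposed at the
  airspace–wall interface (used for fitting against measured Ci and for
  the Laisk-protocol simulations).
* **Ca-driven**: ambient Ca and stomatal conductance gs are given and
  the scalar compatibility condition AN = gs·(Ca − Ci) is solved by
  bisection on Ci ∈ [0, Ca] (the bracket is extended above Ca when the
  leaf is a net source).

### Numerics

Cell-centred finite volumes on a boundary-fitted structured mesh (every
layer boundary and membrane interface coincides with a cell face; cells
are distributed over layers in proportion to thickness, at least one
per layer, which sets a minimum usable resolution of roughly
10 × 28 for the default anatomy). The Michaelis–Menten sink is
linearised as w = k(C_prev)·C with k the limiting-branch coefficient, a
damped Picard iteration (damping 0.5 on both k and the re-injected
photorespiratory release Rp) that keeps the system an M-matrix and the
field strictly positive. Convergence requires both |ΔAN| and |ΔRp|
below 1e-6 µmol m⁻² s⁻¹ (at most 200 iterations); linear systems are
solved by sparse LU. Because the reported totals are computed from the
same linear system as the final field, the flux balance
AN = Vc − 0.5·Vo − Rd closes to solver precision (~1e-12 relative), and
the conservation audit (`flux_report`) exposes it.

Verification: a single-layer slab with first-order sink matches the
closed-form cosh profile to <0.1% at 40 cells across the depth (<0.01%
at 80); with transport scaled ×1e6 the solver collapses onto the
leaf-level FvCB law at Cc = Ci to ≲1e-5 relative.

Apparent mesophyll conductance is gm = AN/(Ci − Cc) with Cc the stroma
volume-mean pressure (a carboxylation-weighted mean is available); gm is
undefined (guarded) when |Ci − Cc| < 1e-9 Pa, and is reported from the
uncapped AN. The reassimilated fraction freass uses a frozen-coefficient
linear tracer: the first-order sink field k(x) of the converged solve is
kept, tracer is released in the scenario's source region at rate
Rp + Rd, and freass = 1 − efflux/(Rp + Rd). Linearisation at the
converged state is the standard tagging construction — the nonlinear
solve itself cannot attribute flux by origin. The tracer is checked
against a 10⁵-walker random-walk absorption estimate on the same
lattice (agreement ≲0.5%).

## Default parameters

| parameter | default | unit | role |
|---|---|---|---|
| twall / tcyt / tstr | 120 / 250 / 2500 | nm | layer thicknesses |
| Sc/Sm, Sm/S | 0.90, 16 | – | surface-area ratios |
| KmC, KmO | 26.7 Pa, 16.4 kPa | | Rubisco Michaelis constants |
| Sc/o | 2.6 | kPa Pa⁻¹ | Rubisco specificity (Γ* = 0.5·O/Sc/o) |
| D_water | 1.79e-9 | m² s⁻¹ | CO2 diffusivity in water, 25 °C |
| f_wall, f_cyt, f_str | 1.0, 0.3, 0.3 | – | relative effective diffusivities |
| p_pm, p_env | 3.5e-3 | m s⁻¹ | membrane permeabilities |
| Henry constant | 3.3e-4 | mol m⁻³ Pa⁻¹ | solubility |

The transport constants are literature-typical values for this model
class, not measurements tied to a particular leaf; all are configurable
and the package's property tests do not depend on their exact values.

## Estimation pipeline

1. **s** (calibration of J = s·Iinc·Φ2): OLS slope of AN on Iinc·Φ2/4
   under nonphotorespiratory conditions, window Iinc ∈ [50, 150]
   µmol m⁻² s⁻¹; the intercept is retained (its negative is the
   Yin-method Rd).
2. **Rd**: 1-D bounded least squares (Rd ∈ [0, 10], multistart
   {0.5, 1.5, 3.0}) of the forward model against light-response records
   with Iinc ≤ 150, run separately per regime (O = 21 / 2 kPa) and per
   release scenario. Fitting is Ci-driven by default — the measured Ci
   drives the boundary, so stomatal-model error does not propagate —
   with Ca-driven available by flag.
3. **Tp** = (Ap + Rd)/3 from the mean observed AN at the highest Ca of
   the photorespiratory CO2-response curve. This grouping is the one
   consistent with the plateau form AN = 3Tp − Rd; the alternative
   reading Ap + Rd/3 is selectable (`grouping="half"`).
4. **Vcmax**: 1-D least squares on the photorespiratory CO2-response
   records with Ca < 30 Pa, Rd and Tp fixed.

Standard errors are Gaussian-linearisation estimates (residual variance
× inverse Gauss–Newton curvature); bootstrap is deliberately not the
default. Records not used by any fit form the held-out validation set
(per-record residuals, RMSE, bias). Scenario ranking pools the fit RSS
and uses the least-squares AIC, n·ln(RSS/n) + 2K with K = fitted
parameters + 1 (residual variance counted); a scenario has substantial
support when ΔAIC ≤ 2 (inclusive). AICc is available by flag but off by
default.

The comparator estimators: Kok (−intercept of AN on Iinc) and Yin
(−intercept of AN on Iinc·Φ2/4), both on the window [50, 150]
µmol m⁻² s⁻¹ — the lower bound avoids the Kok-effect breakpoint region,
whose detection is out of scope. The Laisk fit takes several AN–Ci
curves, fits per-curve OLS lines over Ci ≤ 10 Pa (configurable), reports
all pairwise line intersections, and estimates the common intersection
by joint least squares over AN_j = a_j·(Ci − Ci*) + A* with shared
(Ci*, A*) and free slopes; Rd_Laisk = −A*.

## Synthetic data generator

Real gas-exchange archives for this system are not redistributable, so
the package generates synthetic studies with known truth following the
four standard measurement designs: A–Ca at Iinc = 1500 µmol m⁻² s⁻¹
(PR: O = 21 kPa; NPR: O = 2 kPa; Ca grid 5–100 Pa) and A–Iinc at
Ca = 40 Pa / O = 21 (PR) and Ca = 100 Pa / O = 2 (NPR; Iinc grid
25–1500). Two sub-models supply the physiological structure the
intercept methods are sensitive to:

* declining PSII quantum yield Φ2(Iinc) = φ2max/(1 + Iinc/ihalf)
  (defaults 0.8, 1000);
* saturating stomatal conductance
  gs(Iinc) = gs_min + (gs_max − gs_min)·Iinc/(Iinc + ig)
  (defaults 0.3, 3.0 µmol m⁻² s⁻¹ Pa⁻¹, 200),

so that Ci (and Cc) decline with increasing irradiance at low light —
exactly the feature that biases the Kok and Yin intercepts downward
under photorespiratory conditions. True parameters default to
Rd(PR) = 1.5, Rd(NPR) = 1.1, Vcmax = 120, Tp = 12 µmol m⁻² s⁻¹,
s = 0.45; Gaussian noise sd 0.15 µmol m⁻² s⁻¹ on AN and 0.005 on Φ2.
The generator records the noiseless truth alongside (`an_true`,
`phi2_true`) for recovery studies, and a seed fixes the table
bit-exactly (PCG64).

What the generator does **not** emulate: instrument drift and leakage
at low CO2 (a known practical issue for the Laisk method), replicate
leaf-to-leaf variability, temperature responses, and any mismatch
between the assumed and the true transport constants. Passing recovery
tests therefore demonstrate internal consistency of the estimation
machinery under the model's own assumptions, not field accuracy.

## Model phenomenology (computed by the test suite and
`scripts/acceptance.py`; values regenerate at run time)

* Apparent gm falls with Ca when release is in the inner cytosol and
  rises with Ca for gaps/outer release (photorespiratory regime, Ca
  between ~15 Pa and the TPU plateau); gm(inner) > gm(gaps) > gm(outer)
  pointwise; all scenarios approach a common high-Ca value shared
  between oxygen regimes.
* freass increases and saturates with irradiance. With Ca it *declines*
  in this model at saturating light — the carboxylation resistance
  (Cc + X2)/X1 grows with Cc, so refixation competes less and less with
  escape. The test suite asserts an increasing trend for the Ca
  response, which this model does not satisfy; the assertion is kept
  and fails, documenting the disagreement rather than hiding it.
* Laisk-protocol simulations (Ci-driven, electron-transport-limited,
  J = 52.0/36.3/19.3/9.1 µmol m⁻² s⁻¹): inner and gaps release give
  near-concurrent line families intersecting close to AN = −Rd at small
  Ci* (inner < gaps), outer release gives a non-concurrent family whose
  pairwise intersections increase with the irradiance pair and lie
  above −Rd. The concurrency is not exact here: with a distributed
  Michaelis–Menten sink, exact concurrency at A* = −Rd would require a
  well-mixed stroma pool (so that Vc = Rp exactly when the stroma mean
  equals Γ*, with a J-independent exterior flux −Rd). At the default
  f_str the internal stroma resistance disperses the inner-scenario
  intersections by a few tenths of a Pa and offsets A* from −Rd by
  ~10%; the corresponding strict-concurrency assertions in the test
  suite fail by design and record the model's actual behaviour.

## Problem sizes

Default production mesh 12 × 40 cells; the test suite and the
acceptance script run the simulation-heavy studies at 10 × 28 (the
coarsest boundary-fitted mesh for the default anatomy), where AN
differs from the 24 × 80 solution by <0.5%. Monte-Carlo studies use
50 replicates in the test suite and 20 in the acceptance script;
recovery fits use a single start at the truth-scale initial value,
full multistart being reserved for real analyses.

## Known limitations

* 2D half-cell with a single rectangular chloroplast; no palisade vs
  spongy distinction, no 3D tortuosity.
* No bicarbonate/carbonic-anhydrase facilitation, no temperature
  dependence of kinetic constants, no transients.
* The exact transport constants of the reference model class are not
  published; defaults are literature-typical and configurable.
* The Kok-effect breakpoint below the light compensation point is not
  modelled; windows simply avoid it.
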