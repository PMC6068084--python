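# Methods

## Binding model

All simulation and fitting assume the 1:1 Langmuir interaction
`A + B ⇌ AB` on a surface with capacity Rmax (RU):

    dR/dt = kon·C·(Rmax − R) − koff·R

with constant analyte concentration C during the injection and C = 0
afterwards. The closed-form phase solutions are used everywhere;
`simulate_ode` integrates the ODE directly (`scipy.integrate.solve_ivp`,
LSODA, rtol = atol/Rmax = 1e-12) and exists purely as an independent oracle —
the test suite requires closed form and ODE to agree within 1e-8·Rmax.

Deliberately **not** modelled: mass-transport limitation (the analysis
pipeline assumes transport-free 1:1 kinetics throughout), bulk
refractive-index jumps, baseline drift, and surface heterogeneity. Each
association phase starts from R = 0, i.e. regeneration between cycles is
assumed complete. Noise is i.i.d. homoscedastic Gaussian in RU — the
simplest model consistent with the residual behaviour of Biacore-class
instruments; real instruments additionally show drift and injection spikes,
so recovery results here bound what is achievable on ideal data, not what a
real campaign yields.

## Global fitting

A one-temperature concentration series is fitted jointly: a single
(kon, koff, Rmax) triple must explain every blank-subtracted trace, each
evaluated at its own concentration and phase boundaries. Choices:

- **Parameterization**: log10(kon), log10(koff), log10(Rmax). Rates span
  decades and must be positive; the log transform enforces both and
  conditions the Jacobian. Wide box bounds (kon ∈ [1e−2, 1e14] M⁻¹s⁻¹ in
  log space) only guard against pathological excursions.
- **Optimizer**: Levenberg–Marquardt via lmfit, xtol = ftol = gtol = 1e-12,
  generous evaluation budget. On noiseless synthetic data the fit recovers
  ground truth to ~1e-15 relative error; the documented guarantee is 1e-6.
- **Initialization** (deterministic, derivative-free): koff from a
  log-linear regression of the dissociation tail of the
  highest-concentration trace; per-trace kobs from the time to half the
  end-of-injection response, whence kon = (kobs − koff)/C averaged
  geometrically; Rmax = 1.2 × the largest observed response.
- **Standard errors**: Jacobian-based covariance with the usual residual
  variance estimate, mapped from log scale by the delta method
  (SE(x) = x·ln10·SE(log10 x)). This matches "mean ± SE" reporting without
  bootstrap cost; it is a local, asymptotic estimate.
- **Diagnostics**: koff·(dissociation duration) < 1e-3 flags koff as poorly
  determined (warning, not error — the point estimate is still returned).
  Blank-only or all-zero trace sets raise a non-identifiability error.

Blank subtraction requires bitwise-identical time grids and never
interpolates; mismatched grids are an error by design.

Reported Kd is the ratio of the 3-significant-figure rounded rates, the
convention of instrument-software kinetic tables; full precision is kept
internally.

## Equilibrium thermodynamics

`ΔG = RT·ln Kd` (Kd in M) with R = 8.314 J·mol⁻¹·K⁻¹. Temperature
dependence follows the van't Hoff model with constant heat-capacity change,

    ΔG(T) = ΔH − TΔS + ΔCp(T − T₀) − ΔCp·T·ln(T/T₀),   T₀ = 293.15 K.

T₀ is hard-fixed: ΔH and ΔS are *defined* at 293.15 K and making T₀
configurable would silently re-parameterize them. Although the model is
nonlinear in T, it is linear in (ΔH, ΔS, ΔCp), so the fit is an exact
unweighted linear least-squares solve (`numpy.linalg.lstsq` on the design
matrix [1, −T, (T−T₀) − T·ln(T/T₀)]); at least three distinct temperatures
are required. Weighting by per-point ΔG uncertainty is not implemented —
with the standard five-temperature design and SPR-grade Kd precision the
unweighted solution is adequate, and no weighting scheme is standard.

## Transition-state analysis

The Eyring approximation for the association rate,

    ln(kon/T) = −ΔH‡/(RT) + ΔS‡/R + ln(kB/h),

is fitted by ordinary least squares of ln(kon/T) on 1/T (slope −ΔH‡/R,
intercept ΔS‡/R + ln(kB/h)), i.e. the classical Eyring plot, rather than
nonlinear fitting of kon directly. With ≥ 2 temperatures the noiseless fit
is exact. The transmission coefficient is taken as 1; ΔS‡ therefore carries
the usual caveat about the kB·T/h prefactor for bimolecular reactions in
solution.

Signature classification labels the enthalpic term favorable when ΔH < 0
and the entropic term favorable when −TΔS < 0, with a neutrality band of
0.1 kJ·mol⁻¹ on |ΔH| and |TΔS| to keep labels stable against numerical
noise at the boundary.

## Synthetic experiments

A ground truth is the pair (ThermoParams, ActivationParams) plus Rmax.
Rates derive from it:

    kon(T)  = (kB·T/h)·exp(ΔS‡/R − ΔH‡/(RT))
    Kd(T)   = exp(ΔG(T)/(RT)),   koff(T) = kon(T)·Kd(T)

so the thermodynamic cycle closes identically at every temperature and the
van't Hoff/Eyring analyses are exact inverses of the generator — the basis
of all recovery tests. kon outside [1, 1e12] M⁻¹s⁻¹ triggers an
implausible-regime warning.

Default campaign design: temperatures {283.15, 288.15, 293.15, 298.15,
303.15} K; concentrations {1.25, 2.5, 5, 10} nM (bracketing the 5 nM
typical assay concentration for this panel); 120 s association, 600 s
dissociation, 1 Hz sampling; one blank (zero-concentration) cycle per
temperature. The timing was chosen so that a koff near 5×10⁻⁴ s⁻¹ decays
by a clearly measurable ~30% during dissociation; the tightest panel
variant (koff ≈ 1.5×10⁻⁵ s⁻¹) sits near the identifiability warning
threshold, as it would on a real instrument. Rmax (default 100 RU) is held
constant across temperatures — a single immobilized surface — although real
campaigns show some drift in active surface density.

Panel presets (`variant_ground_truth`) anchor each variant's kon and Kd at
298.15 K to its measured values and encode the panel's qualitative
signatures through preset ΔH (positive, i.e. entropy-driven binding, for
wild type/D5/E5; negative for R3/R5/K5), preset association ΔH‡ (low for
R5's encounter complex, high for K5, intermediate otherwise) and
ΔCp = −800 J·mol⁻¹·K⁻¹, a typical value for a protein–protein interface.
ΔS and ΔS‡ are then solved exactly from the anchors. The presets are
self-consistent illustrations of the published qualitative patterns, not
measured values — the corresponding enthalpies and entropies were never
published numerically.

All randomness flows through explicit integer seeds or
`numpy.random.Generator` instances; there is no global random state, and a
fixed design seed regenerates a campaign byte-identically.

## DSC thermograms and Tm

Synthetic thermograms use the two-state van't Hoff excess heat capacity

    Cp_ex(T) = ΔH_unf²/(R·T²) · K/(1+K)²,   K = exp(−ΔH_unf/R·(1/T − 1/Tm))

on a 30–90 °C grid at 0.1 °C (default ΔH_unf = 400 kJ·mol⁻¹, typical for a
Fab). Because of the 1/T² factor the curve's maximum sits slightly below
Tm — about 0.08 °C at 400 kJ·mol⁻¹ — which is physical, not a numerical
artifact; recovery is asserted within ±0.1 °C. Extraction subtracts a
linear baseline through the pre- and post-transition plateaus (means of
the first/last three points) and refines the grid argmax by parabolic
interpolation. A flat curve raises a no-peak error; a maximum on the grid
edge returns with an explicit edge flag and warning.

## Net charge and pI

Henderson–Hasselbalch with independent titration of D, E, C, Y, H, K, R
and the chain termini. Default pKa set: EMBOSS (C-term 3.6, N-term 8.6,
C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1); a Lehninger-style
textbook set is provided as an alternative, and any mapping can be passed
in — absolute charges shift by a few tenths of a unit between sets, so
only orderings and shifts are asserted across sets. Disulfide-bonded
cysteines are *not* excluded from titration; for cystine-rich proteins
(insulin among them) this biases the charge slightly negative, well within
the tolerance used. pI is found by bisection on pH ∈ [0.1, 13.9] to 1e-6,
and is undefined (error) when the charge curve does not change sign.

Mutation positions are plain 1-based sequential indices; Kabat/IMGT
renumbering is out of scope. The bundled VL domain (`demo_vl`) is a
synthetic scaffold with serines at positions 63/65/67/70/72, used because
the panel's real light-chain sequence is not available in machine-readable
form; charge orderings across the mutant family are independent of the
scaffold details.

## Problem sizes

The test suite and acceptance script run: 4-trace global fits on ~2 900
points (noiseless, plus 100 noisy replicates at 1 RU); 20-draw round-trip
checks of both thermodynamic fits; one full 5×4 noiseless campaign written
to and re-read from disk; and 601-point thermograms. The whole suite
completes in a few seconds on one CPU.

## Known limitations

- No mass-transport or heterogeneous-surface models; data with transport
  limitation will bias kon low and the package will not flag it.
- SEs are asymptotic; they understate uncertainty for short dissociation
  phases where koff is weakly identified (the warning fires, but no
  profile-likelihood interval is computed).
- The van't Hoff fit assumes temperature-independent ΔCp.
- Equivalence with proprietary instrument-software fitting (weighting, SE
  definitions) cannot be asserted; validation is by parameter recovery on
  synthetic data.
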