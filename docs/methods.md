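# Methods

## The three-state unfolding model

`pahunfold` analyzes equilibrium unfolding of a protein whose denaturation
shows two resolved transitions, modelled as three macroscopic states in
equilibrium, native ⇌ intermediate ⇌ unfolded (N ⇌ I ⇌ U). The observable —
here tryptophan fluorescence intensity at a fixed emission wavelength — is a
population-weighted sum of three state signals, each assumed linear in the
perturbation variable x (urea concentration D, or temperature T):

    F(x) = fN·(FN0 + mN·x) + fI·(FI0 + mI·x) + fU·(FU0 + mU·x)

with Boltzmann populations

    fN : fI : fU  =  1 : e^(−ΔG1/RT) : e^(−(ΔG1+ΔG2)/RT).

For chemical denaturation the two free energies follow the linear
extrapolation method (LEM):

    ΔG1 = m1·(Um1 − D),    ΔG2 = m2·(Um2 − D),

where Um is the mid-transition denaturant concentration of a transition and
m its free-energy slope (kcal·mol⁻¹·M⁻¹, proportional to the surface area
newly exposed). For thermal denaturation each transition follows the
Gibbs–Helmholtz expression

    ΔG(T) = ΔH·(1 − T/Tm) + ΔCp·[T − Tm − T·ln(T/Tm)],

zero at the mid-denaturation temperature Tm by construction.

Assumptions worth keeping in mind: the model is a *macroscopic* description —
no subunit dissociation, association or aggregation enters the equilibrium
explicitly, although for an oligomer those processes certainly occur. The
fitted parameters are therefore apparent quantities. ΔCp is fixed at zero by
default in thermal fits (it is floatable via `FitConfig.fixed`/`bounds`)
because optical melting curves rarely constrain it; with ΔCp = 0 the
transition temperatures are the robust quantities and the enthalpies should
be read as van't Hoff slopes at Tm.

### Numerical evaluation

Populations are computed in log space (log-sum-exp) and renormalized once,
so the three fractions sum to 1 to ≤10⁻¹² and remain finite for arbitrarily
large |ΔG|/RT — the optimizer is free to probe extreme parameter values
without overflowing. R is fixed at 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹ and not
configurable, to make unit mixing impossible. Temperatures are Kelvin
internally and Celsius at every file/report boundary (offset 273.15).
Chemical equilibria are evaluated at 298.15 K by default (samples
equilibrated at 25 °C).

## Individual and global fitting

`fit_global` pools replicate curves into one least-squares problem where the
thermodynamic parameters (Um/m or Tm/ΔH) are shared across curves and the
three linear baselines are free per curve. This matches the standard
practice of reporting a single apparent parameter set per construction and
concentration from two or three replicate curves; `fit_individual` is the
one-curve special case.

Starting values are data-driven (`initial_guess`): transition midpoints from
the two largest extrema of a smoothed first derivative of y(x) (with a
significance check — a real transition must stand well above the typical
derivative magnitude — and a tercile fallback, flagged, for featureless
data); edge baselines from linear fits to the outer 15% of points; the
intermediate baseline from the plateau between the midpoints; steepness (m
or ΔH) from the derivative peak's half-height width via the two-state
relation that a transition spans ≈4.4 RT between its 10% and 90% points.

Minimization is Levenberg–Marquardt (lmfit), restarted from 8 seeded ±20%
perturbations of the guess because overlapping two-transition fits have
local minima; the best converged restart wins, and identical configuration
plus seed reproduces the result bit-for-bit. The second midpoint is
parameterized as first midpoint plus a positive gap, which prevents
transition swapping. Default bounds keep the optimizer in physically
sensible basins: midpoints within the observed x-range ±10%, m ∈ (0, 20]
kcal·mol⁻¹·M⁻¹, ΔH ∈ (0, 500] kcal·mol⁻¹. Standard errors come from
lmfit's scaled covariance (inverse Gauss–Newton normal matrix at the
optimum); `bootstrap_stderr` offers a residual bootstrap (default 200
resamples) when the curvature approximation is in doubt. Unweighted least
squares is used throughout; fluorescence noise is approximately homoscedastic
across a curve.

`population_curve` converts a converged fit into per-x species fractions —
the computation behind statements like "at 5.4 M urea the protein is ~90%
in the intermediate state".

## DSC processing

The DSC pipeline enforces its order through provenance flags: buffer
subtraction (linear interpolation of the buffer scan onto the sample grid),
molar normalization (division by subunit moles in the cell, µM × mL ×
10⁻⁹ mol), then analysis. Transition temperatures come from the smoothed
first derivative of the thermogram: maxima are located where the derivative
crosses zero from + to − (sub-grid position by linear interpolation of the
derivative), candidates below 5% prominence of the global maximum are
suppressed, and detections closer than the smoothing window (default 1.5 K,
matched to ~0.1 K point spacing at 1 K·min⁻¹ scan rate) are merged.

Deconvolution fits the sum of two *independent* two-state van't Hoff peaks
plus a linear residual baseline:

    Cp_exc(T) = s·ΔHvH²·f(1−f)/(R·T²),   f = K/(1+K),
    K = exp(−ΔHvH·(1 − T/Tm)/(R·T))

This is the simplest form that reproduces two overlapping calorimetric
peaks; a sequential (coupled) three-state ladder is deliberately not imposed
because irreversible aggregation distorts the high-temperature region and a
rigorous equilibrium model is not warranted there. For the same reason the
fitting window is clipped above the temperature where the signal falls below
25% of the second peak's height on the high-temperature side. The fit is
initialized from the derivative procedure; a `degenerate` flag marks fits
where the data do not actually support two transitions (an amplitude scale
below 0.05, or the two fitted Tm within 1 K). Note the Cp_exc maximum sits
slightly *below* Tm (by <0.1 K for ΔHvH ≥ 80 kcal·mol⁻¹), so derivative
detection and deconvolution agree only to that physical offset.

## Spectral descriptors

Emission maxima are read from a 5 nm moving-average-smoothed spectrum with
quadratic refinement through the three points around the discrete maximum;
a maximum on the range edge is returned flagged rather than refined.
Spectral shift is the signed difference of two maxima (positive = red
shift); the intensity ratio I355/I337 is linearly interpolated and scale
invariant. Typical tryptophan benchmarks: ~330 nm buried, ~355 nm fully
solvent exposed.

## Hydrodynamic summaries

Observed sedimentation coefficients are standardized to water at 20 °C,

    s20,w = s_obs · (η_solvent/η_w20) · (1 − v̄ρ_w20)/(1 − v̄ρ_solvent),

with ρ_w20 = 0.99823 g·mL⁻¹ and η_w20 = 1.002 mPa·s fixed. Solvent density
and viscosity for urea buffers are *inputs* (tabulated externally, as is
usual practice); only pure-water defaults ship with the package. The
frictional ratio is f/f0 = R_s/R_0 with the Stokes radius implied by s20,w
and the anhydrous-sphere radius from M and v̄ (default 0.73 mL·g⁻¹,
overridable). c(s) distributions are consumed, never computed: windows are
integrated by the trapezoidal rule with interpolated edges, fractions
normalized by the full-range integral, and each window's s reported as the
signal-weighted mean.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline reads, deterministic under
a seed, with the generating truth carried in metadata (and in a `.meta.json`
sidecar through file round trips). Named presets encode the published
apparent parameters of the two constructions (full-length tetramer PAHt and
catalytic-domain dimer PAHd): four urea parameter sets, four thermal Tm
pairs, two DSC Tm pairs, emission maxima, and native c(s) fractions.

Quantities the source experiments never printed are fixed plausible
constants, documented as invented: fluorescence baselines (PAHt native
100 a.u. rising to 190 in the first transition, ≈+90%; PAHd 100→120,
≈+20%; declining thermal native baselines reproducing the unspecific
thermal quenching of fluorescence), thermal ΔH (80 and 120 kcal·mol⁻¹),
DSC ΔHvH (100 and 150 kcal·mol⁻¹), c(s) peak widths. Default noise is
i.i.d. Gaussian at 1% of the native-to-intermediate amplitude — chosen so
that fitted parameter uncertainties come out on the order of the published
ones — except for c(s) distributions, which get 0.2% of peak height
because a regularized c(s) inversion output is smooth, not pointwise noisy
(and clipping larger symmetric noise at zero would bias integral fractions).

What passing recovery tests on these data shows: the estimation machinery
returns the truth it was fed, at realistic noise, including baseline/
thermodynamics trade-offs. What it cannot show: robustness to the real
data's pathologies — aggregation-distorted baselines, partially irreversible
transitions, correlated instrument drift — none of which the generator
emulates. Parameters recovered from real curves remain apparent quantities.

## Problem sizes and determinism

Recovery checks use three 40-point replicate urea curves (0–7.8 M) or three
71-point thermal curves (20–90 °C at 1 °C), 701-point DSC grids (0.1 °C),
and 8 multistart restarts — sizes chosen to mirror the source experiments'
sampling. One caveat from the simulation study: the second urea midpoint of
the PAHt 8 µM parameter set (Um2 = 6.38 M, m2 = 1.21) lies close to the
7.8 M solubility limit, so its sampling error under these conditions is
intrinsically ~0.085 M; expectations tighter than ±0.1 M on that single
parameter are not reliably met at 1% noise, while all other midpoints are
recovered an order of magnitude more precisely. All randomness flows from
explicit integer seeds; repeated runs are bit-identical.
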