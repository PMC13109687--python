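# Methods

This note records the models, conventions, and design choices behind the
package, and what its synthetic-data validations do and do not demonstrate.

## Units and constants

Distances in Å, energies in kcal/mol, concentrations in nM unless a function
documents otherwise (the depletion-isotherm fitter is unit-agnostic;
the study's weak-site data are in µM). k_B = 0.0019872041 kcal/mol/K.
Neither the simulations nor the assays pin an exact temperature beyond
"room temperature", so every thermodynamic function takes a temperature
argument with a default of 298.15 K.

## Synthetic free-energy landscape

The generator's landscape is defined through its Boltzmann density rather
than through an energy expression: the unbiased density is the sum of

1. a broad quartic-exponential open basin, exp(−((x−x_open)/w)⁴), centred at
   25 Å (w = 6 Å; the quartic gives a wide flat-bottomed basin whose tails
   die fast enough not to contaminate the closed region);
2. a narrow Gaussian closed well at 2.5 Å whose *amplitude* is
   exp(−ΔG_closed/kT) — +15 kcal/mol above the open floor without metal,
   9 kcal/mol below it with metal (sd 0.10 Å: the metal-chelated state is
   tightly confined);
3. a constant floor exp(−E_barrier/kT) (default 18 kcal/mol) that caps the
   barrier plateau between the basins.

W(x) = −kT·ln(density), anchored to zero at its minimum. Because the
landmark energies enter as amplitudes, they are exact by construction, and
the two profiles coincide above ~5 Å exactly as the study's landscapes do.
With the default widths, Boltzmann integration splits at d = 4 Å gives
ΔG₀ ≈ +17.2 and ΔG_M ≈ −6.8 kcal/mol; the well depth default (9 kcal/mol)
was set from ΔG_M ≈ −depth + kT·ln(σ_open_eff/σ_closed) so the metal-state
stabilization lands in the regime the linkage analysis operates in.

The closed-well sd of 0.10 Å keeps the well's energy profile contained
inside x < 3 Å, which is what makes the basin split robust to the cutoff
choice (d ∈ {3, 4, 5} Å moves ΔG_M by < 0.05 kcal/mol); the package still
always emits the three-cutoff sensitivity triplet.

## Umbrella-window sampling

Windows are drawn by inverse-CDF sampling of the exact biased density
exp(−[W(x) + k(x−c)²/2]/kT) on an internal grid refined to a quarter of
min(PMF grid step, σ_bias/5), where σ_bias = √(kT/k). The refinement keeps
the piecewise-uniform density implied by a piecewise-linear CDF from
distorting either the window variance (≪1%) or a χ²
goodness-of-fit at n = 10⁵ against the analytic biased density. Samples are
independent draws — deliberately so, since the estimators downstream assume
independent counts; correlated MD data would need decorrelation upstream,
which is out of scope.

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

## WHAM

Standard self-consistent WHAM with Picard iteration: bin counts n_ij on a
uniform grid, bias b_ij evaluated at bin centres, window free energies
pinned by F₁ = 0, convergence when max|ΔF_i| ≤ 10⁻⁷ kcal/mol (cap 10⁵
iterations). Unsampled bins are masked (NaN), excluded from anchoring and
from all downstream integrals. No statistical-inefficiency weighting is
applied (independent-draw inputs, see above). Zero-overlap adjacent pairs
trigger a warning up front, and failure to converge is reported on the
solution object, never raised silently.

Bin-width choice matters more than is commonly appreciated for stiff
springs: evaluating the bias at the bin centre biases W when the bias varies
strongly across a bin, so the bin width should be well below
σ_bias (0.069 Å for the study's 125 kcal/mol/Å² spring). The reader/writer
default is 0.1 Å; the validation runs use 0.05 Å, and with 125 kcal/mol/Å²
springs the residual binning bias is visible in the recovery RMSE if the
width is pushed back to 0.1 Å.

The cross-implementation check solves the identical estimator by L-BFGS
minimization of the WHAM negative log-likelihood with its analytic gradient
(an independent numerical route to the same fixed point) and demands per-bin
agreement within 0.05 kcal/mol.

Validation problem sizes: profile recovery uses the study's window protocol
(125 kcal/mol/Å², 0.2 Å spacing) over 2–12 Å at 2000 samples/window against
a known quadratic profile (RMSE target 0.25 kcal/mol on bins with ≥ 50
counts); the end-to-end K_app recovery uses a softer 20 kcal/mol/Å² spring
at 0.3 Å spacing over the full 2–37.8 Å range with 16 000 samples/window —
spring, spacing and sample count chosen by a precision analysis so the
accumulated window-to-window statistical error in ΔG_M stays well below
kT·ln(1.25), the 25% K_app agreement target.

## Basin free energies and linkage

Both Boltzmann integrals are evaluated by trapezoidal quadrature entirely
in the log domain (segment-wise log-sum-exp), so +16 kcal/mol features
cannot overflow and a vanishing integral surfaces as an explicit error
rather than ±∞. The cutoff d is inserted as an interpolated node shared by
both integrals; the formal upper limit ∞ is truncated at the grid maximum —
a convention, consistent with the sampled range. Interior masked bins are
bridged by linear interpolation; masked edges shrink the range. On the
synthetic landscape's 0.05 Å grid the quadrature error from the narrow well
is ~0.01 kcal/mol (checked against a 2·10⁶-node oracle); the 10⁻³ kcal/mol
agreement targets apply to smooth flat/harmonic profiles where trapezoid
error is negligible.

The linkage relations K_app = e^(ΔG_M/kT)·K_open,
ΔG_M = kT·ln(K_app/K_open) and K_closed = K_open·e^((ΔG_M−ΔG_0)/kT) are
evaluated exactly. K_open is an input (the study uses the 933 nM single-Bpy
value for the double mutant, treating both single sites as equivalent for
simplicity); the package takes it as a parameter rather than hard-coding
that assumption.

## Competition and isotherm fitting

Speciation treats every ligand class as an independent 1:1 site (one Bpy₂Ni
site per protein, 1:1 chelator:metal; an optional weak nonspecific class
with a site count models the secondary binding seen at metal excess). Free
metal solves m + Σ S_s·m/(K_s+m) = M_total; the left side is increasing and
concave, so [0, M_total] brackets the unique root and Newton from the upper
end converges monotonically inside the bracket — verified against an
independent scalar root-finder to 10⁻⁶ relative (it agrees to ~10⁻¹⁵), with
mass balance asserted to 10⁻¹⁰ relative.

The fluorescence model is linear in its response coefficients, and free +
bound chelator is conserved, so only two nuisances per replicate are
identifiable (intercept, slope on free chelator). The global fit therefore
profiles the shared Kd on a log₁₀ grid plus bounded Brent refinement, with
the nuisances solved exactly by linear regression at every candidate Kd —
no iterative multi-parameter optimizer, hence no convergence failures; a fit
pinned at the Kd bounds is flagged instead. The chelator Kd is fixed during
competition fits (calibrated first from a direct, protein-free titration),
mirroring the two-step assay procedure. The chelator's own Kd for Ni(II) is
not published; the synthetic default is 100 nM at 500 nM chelator and
500 nM protein, 16 titration points to 2.5 µM total metal — conditions under
which a ~40 nM protein site is well identified.

Uncertainty comes from a seeded residual bootstrap (replicate resampling
available) with percentile intervals; the bootstrap refits warm-start from
the point estimate with an automatic fallback to the full scan if the
optimum hits the narrowed bracket. Titration noise is homoscedastic
Gaussian (the study does not characterize assay noise); "2% noise" in the
validation means an sd of 2% of the clean curve's dynamic range. Coverage
of the 95% CI is checked over 200 simulated assays (150 bootstrap draws
each) with an ≥88% acceptance floor — percentile intervals on 48-point fits
are expected to undercover slightly, not to be exact.

The weak-binding isotherm fit uses the exact single-site depletion
quadratic f = (P+M+K−√((P+M+K)²−4PM))/(2P) on pre-extracted fraction-bound
values; how fractions are obtained from spectra is upstream of this
package.

## FRET and conformer analysis

Förster-law routines are exact algebra (E = 1/(1+(r/R₀)⁶) and its inverse);
the measured-efficiency estimator is donor quenching, E = 1 − F_DA/F_D,
appropriate for a dark-quencher acceptor and left uncorrected for labeling
efficiency. Site screening is ordinary least squares of candidate pair
distance on the switching coordinate with a positive-slope suitability
verdict — the package reports predicted-vs-measured quantities and leaves
biological interpretation to the user.

Conformer classification defaults to a two-component Gaussian mixture (EM,
three initializations, seeded) because no threshold distance is given for
the near/distant triad states; a fixed-cut threshold method is available
for reproducibility. A mixture whose components end up closer than twice
the smaller component sd, or with a component weight under 2%, is flagged
degenerate and falls back to a threshold at the sample mean (single-mode
data typically fit as two components ~1.5 sd apart; genuinely bimodal data
separate by several). Histograms use a fixed 0.2 Å bin width and conserve
counts exactly.

## What the synthetic validations do and do not show

The generators emulate the *structure* of the study's data — landmark
basin geometry, harmonic-bias sampling, quench-competition curves, bimodal
triad distances — with independent noise and known truth. Passing the
closed-loop tests shows the estimators are correct and calibrated on data
satisfying their assumptions. It does not show that real MD frames are
uncorrelated, that real assay noise is homoscedastic Gaussian, or that the
study's specific numerical values (ΔG₀ = +16.5, ΔG_M = −7.6 kcal/mol,
Kd = 41.5 nM, etc.) are recoverable without the original trajectories and
raw titrations — those require the study's data and are out of scope.

## Known limitations

- 1-D WHAM only; no MBAR primary estimator, no bootstrap error bars on the
  PMF itself (the per-bin kT/√count estimate is a counting heuristic).
- The without-metal window spacing of the original protocol is not fully
  specified in the source material; the generator exposes spacing as a
  parameter instead of guessing.
- Inner-filter/photobleaching corrections, spectral unmixing, dye-linker
  and κ² orientation effects are not modeled.
- No structure/trajectory parsing: all modules consume scalar series.
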