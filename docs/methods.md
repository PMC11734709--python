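# Methods

`scatterkin` models femtosecond time-resolved gas-phase x-ray scattering of
a photoexcited molecular sample and inverts it: given a percent-difference
scattering map %ΔI(q, t), it recovers the rate constants of a first-order
photochemical network, the species-associated difference patterns S_α(q),
and the optical excitation fraction γ. The built-in system is the 200-nm
photofragmentation of 1,2-dithiane (DT, C4H8S2), a six-membered ring with a
disulfide bond.

## Observable and forward model

The experiment measures, at momentum transfer q and pump-probe delay t,

    %ΔI(q, t) = 100 · [I_on(q, t) − I_off(q)] / I_off(q),

with I_off the scattering of the unexcited sample. For a dilute gas of
independent scatterers this separates into kinetics and structure:

    %ΔI(q, t) = γ Σ_α S_α(q) F_α(t),

where F_α(t) is the relative population of species α, S_α(q) its
percent-difference pattern against the ground-state reactant, and γ the
fraction of molecules the pump excites. Everything in the package is built
around this separable model: the generator composes it, the fit inverts it.

## Scattering (independent atom model)

Rotationally averaged elastic scattering of a rigid structure follows the
Debye equation, I(q) = Σ_ij f_i f_j sin(q r_ij)/(q r_ij), with
Cromer–Mann four-Gaussian atomic form factors (f(0) = Z within 0.1%).
Consequences used throughout: I(0) = (ΣZ)², which fixes the absolute scale
of every pattern by electron counting, and dissociation produces a negative
percent-difference lobe at low q because well-separated fragments lose the
inter-fragment interference (fragment mixtures are summed incoherently).
Electronic effects — bonding density, excited-state density changes,
inelastic/Compton background — are outside the IAM; the percent-difference
observable cancels static backgrounds to first order. One direct modelling
consequence: a vertically excited molecule, whose nuclei have not yet
moved, scatters identically to the ground state under the IAM, so the
excited reactant DT* carries an exactly zero difference pattern.

Built-in structures are assembled from standard covalent parameters
(C–C 1.53 Å, C–S 1.82 Å, S–S 2.06 Å, S=S 1.89 Å, tetrahedral CH2, ring
closure by constrained least squares on a chair template). They are
geometric stand-ins adequate for percent-level difference patterns, not
quantum-chemistry optimizations. The ring-opened biradical is kept compact
(S···S 3.3 Å): the carbon backbone confines the sulfur radicals, and its
difference pattern is weak, consistent with a transient that remains
structurally close to the reactant. Hydrogens are nearly invisible to x-ray
scattering, so the H-transfer variants (x, y, z ∈ {0, 1}) of the fragment
channels give near-identical patterns; the default is no transfer.

Vibrationally hot species are represented by geometry pools:
`ensemble_pattern` averages per-frame Debye patterns (weighted), which
damps interference oscillations while leaving I(0) fixed. The built-in
`toy_thermal_pool` applies i.i.d. Gaussian Cartesian displacements
(default 0.05 Å, 100 frames for hot DT) — a geometric stand-in with no
mode structure, correlation, or anharmonicity; externally computed pools
(e.g. molecular-dynamics frames) load through the multi-frame XYZ reader.

## Kinetics

The reaction scheme is a linear first-order network: DT* branches with k1
(ring opening to the biradical), k3 (prompt one-sulfur channel FA-1) and
k4 (prompt two-sulfur channel FB); the biradical and vibrationally hot
cyclic DT equilibrate via k2/k−2; slow ground-state drains k5 (FA-1→FA-2),
k6 (DT_hot→FB) and k7 (biradical→FA-2) complete the fragmentation. The
symbol-to-edge mapping of the three drains is configurable; the default
best reproduces the ~36/64 three-body/two-body product split (the exact
mapping is a modelling choice, and the asymptotic FB fraction computed from
the reference rates is 0.617).

Populations solve dP/dt = A P by eigen-decomposition; the Gaussian
instrument response (default FWHM 238 fs) enters by convolving each
exponential mode analytically (exponentially-modified-Gaussian form,
evaluated with the scaled complementary error function for stability).
Populations are normalized to the eventually-excited subpopulation: after
the IRF has passed they sum to 1 (tested to 1e-6). Near-degenerate spectra
(eigenvector condition number > 1e8) fall back to matrix exponentials plus
Gauss–Legendre quadrature over the IRF support, which matches the analytic
route to ~1e-9. Asymptotic product fractions come from the absorbing-state
analysis of the embedded jump chain (a small linear solve), with trapped
species reported by name.

Reference rate constants (defaults of the generator): k1 = 4.23,
k2 = 0.95, k−2 = 0.31, k3 = 2.86, k4 = 2.85 (×10¹² s⁻¹), k5 = 0.0158,
k6 = 0.0025, k7 = 0.0022 (×10¹² s⁻¹); γ = 4.5%.

## Global fit: variable projection with a theory-informed pattern prior

The model is linear in the patterns, so the fit uses variable projection:
an outer bounded nonlinear search (scipy `least_squares`, trf) over the
log-rates (optionally t0, IRF width, and log-γ) with the patterns solved
exactly per q by weighted linear least squares at every step. Multi-start
restarts draw initial rates log-uniformly within per-rate windows; reported
parameters are mean ± SD over restarts that reached the global cost level
(restarts in distinctly worse local minima, or pinned at a bound, are
excluded and the reason recorded per restart).

Two structural facts about the separable model shape the estimator:

1. **Gauge freedoms.** With fully free patterns, the fitted map depends on
   the rate constants only through the span of the population time-courses,
   and that span is fixed by the rate-matrix spectrum alone. The network
   has one fewer nonzero temporal mode than species (both terminal products
   share the zero eigenvalue), so the individual branching ratios k1:k3:k4,
   the k2/k−2 split, and the drain assignment are *exactly* unidentifiable
   from the map if every species' pattern is free — distinct rate sets fit
   noiseless data to machine precision. This is a property of the model,
   not of any optimizer.

2. **Electron-count determinism.** The absolute magnitude of each species'
   pattern is not arbitrary: under the IAM it is fixed by the candidate
   structure's electron count and geometry. The estimator encodes this as
   a per-(group, q) Gaussian prior pulling each coefficient toward
   γ·S_theory(q), implemented as pseudo-measurements added to the inner
   normal equations. γ itself is a fit parameter, pinned by the prior's
   absolute scale — this is also what breaks the γ-vs-pattern scale
   degeneracy (γ → cγ, S → S/c), which the forward model satisfies exactly.

The prior weight defaults to the equivalent of 10 extra measurements per
(group, q) at the mean data weight: enough to pin the gauge directions
(which carry zero data curvature, so even a weak prior settles them at the
theory-consistent point) while contributing ~10% of one delay-scan's weight
to the data-constrained directions. The DT* pattern is pinned to exactly
zero (see IAM section) rather than extracted. The biradical and hot-DT are
fitted as separate pattern groups by default: their pattern *difference*
carries the sub-picosecond equilibration transient that identifies k2 and
k−2 (with one merged pattern, the pair's internal exchange is nearly
invisible). The raw design for separate groups is singular — the
collinearity warning fires by construction — and the prior is what makes
the inner solve well-posed. A merged biradical+DT_hot group remains
available for presentation-style extractions.

Per-rate search windows (fast channels 0.02–2 ps, exchange 0.1–20 ps,
drains 0.01–10 ns) encode the timescale hierarchy the scheme postulates;
without them, eigenvalue-role permutations between network positions
produce duplicate global optima.

γ can also be estimated after the fact by `estimate_gamma`, the weighted
least-squares scale factor between extracted γ·S and IAM theory over
anchor groups (default: the terminal products); with the prior-based fit
the two routes agree.

## Anisotropy channel

A linearly polarized pump photoselects by cos², imprinting
I = S0(q) + S2(q)·P2(cos θ_q) on the difference signal, with θ_q the angle
between the scattering vector and the pump polarization. The module renders
flat-detector images from the exact pixel geometry (q = (4π/λ)sin(Θ/2);
the scattering vector tilts out of the detector plane by Θ/2, so a pixel on
the polarization axis has θ_q = Θ/2 exactly and a perpendicular pixel
exactly 90°), applies the Thomson polarization factor of the x-polarized
probe, and inverts by per-q-bin weighted regression on [1, P2] with
normal-equation standard errors. Bins with too few pixels or no angular
contrast are flagged rather than filled. Rendering can evaluate the
patterns on the decomposition's own q-bin centres; on that shared
discretization the zero-noise round trip is exact (machine precision),
whereas smooth rendering leaves an O(bin-width²) binning bias (~3e-3 at the
default geometry). Only P0/P2 are modelled (one-photon excitation); the
kinetic analysis itself consumes the isotropic component.

## Synthetic data and what passing tests show

`generate_map` composes the full forward model — IAM difference patterns of
every species (hot DT via the thermal ensemble), IRF-convolved populations,
the separable sum, homoscedastic Gaussian noise (default 0.1 percentage
points; an optional q-dependent σ profile emulates detector noise growth) —
with all randomness derived from one seed (bit-identical maps per seed).
The default grids are q ∈ [0.5, 4.5] Å⁻¹ (60 points) and 80 delays from
−0.5 ps to 3 ns, linear to 1 ps and log-spaced beyond.

The generator emulates: the separable kinetics-times-structure observable,
the finite cross-correlation, percent-difference normalization, and
per-point Gaussian noise. It does **not** emulate: detector tiling and
calibration artefacts, timing jitter, shot-noise heteroscedasticity,
excited-state electron-density corrections, or coherent wave-packet
motion. Parameter-recovery results therefore demonstrate the estimator's
correctness and statistical efficiency under the stated conditions, not
robustness to those systematic effects.

The recovery benchmark (`recovery_experiment`, also behind
`scripts/acceptance.py`) generates maps for seeds 1–10 at 0.1-point noise,
fits each with 20 restarts, and reports across-seed means. Typical output:
1/k1 ≈ 239 fs (generating 240 fs), γ ≈ 4.50%, 1/k2 ≈ 1.05 ps, 1/k5 ≈ 69 ps
(generating 63 ps — the FA-1 drain has per-seed likelihood scatter of
roughly ±20% at this noise level, the widest of the headline parameters).
The whole benchmark runs in about half a minute on one core.

## Numerical choices and limitations

- Degenerate Debye terms (r_ij = 0) use the sinc → 1 limit; q = 0 is exact.
- The chair-ring builder solves a small constrained least squares
  (bond lengths hard, angles and chair torsions soft); results are
  deterministic and cached.
- Inner linear solves run on batched normal equations with a pinv fallback
  for singular designs; covariances come from the (prior-regularized)
  normal matrix.
- Outer optimizer tolerances are tight (1e-12) so noiseless recovery is
  limited by conditioning, not termination.
- Restart aggregation excludes non-converged, bound-pinned, and
  local-minimum restarts (cost above the best by >0.01%); exclusions are
  recorded per restart.
- Known limitations: the pattern prior biases extracted patterns toward the
  supplied candidates when the data are weak (by design); t0/IRF fitting is
  available but frozen by default; error bars are restart SDs, not
  posterior widths — for sloppy directions they understate the statistical
  uncertainty.
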