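# Methods

## The problem

Time-domain FLIM-FRET measures protein-protein interaction by the
quenching of a donor fluorophore's fluorescence lifetime.  The
conventional readout — the amplitude-weighted mean lifetime
τ_m = Σᵢ αᵢτᵢ / Σᵢ αᵢ of a free multi-exponential fit — conflates two
distinct quantities: *how many* donors sit in FRET-competent complexes,
and *how efficiently* each of them transfers energy.  The same τ_m can
come from many weakly-coupled complexes or few tightly-coupled ones.

The pattern-constrained analysis implemented here separates them.  The
donor-only decay is first calibrated as a fixed "pattern" of 1-3
exponential components (lifetimes τⱼ and relative amplitudes αⱼ; for a
fluorescent protein like mVenus it is bi-exponential, roughly 3 ns with
amplitude ≈ 0.9 plus 1-2 ns with amplitude ≈ 0.1).  A FRET sample is
then fitted with the per-photon arrival density

    p(t) ∝ (1 − B) · Σⱼ αⱼ e^(−t/τⱼ)  +  B · e^(−t/τ_FRET),
    τ_FRET = (1 − E) · τ_ref,

where only three shape parameters are free: **BINDING** B (the relative
pre-exponential amplitude of the FRET component — the fraction of donors
in complexes, the affinity proxy), the **FRET efficiency** E (proximity/
orientation proxy), and a time-uniform background fraction.  The donor
lifetimes and their amplitude ratio never move.

## Estimation

* **Loss.** Poisson maximum likelihood on binned counts, minimized as the
  Poisson deviance (C statistic); TCSPC shot noise is Poisson, and
  weighted least squares with variance max(counts, 1) is kept behind a
  `loss="wls"` flag as a cross-check.  The overall scale is profiled out
  analytically: with the shape normalized to 1 the scale MLE is exactly
  the photon total, so only (B, E, background) are searched.
* **Bounds.** B ∈ [−0.5, 1]: donor-only data legitimately produce small
  negative apparent BINDING (scatter around zero), so the lower bound
  must admit it; −0.5 is wide enough for that without letting the model
  invert into a negative-amplitude mimic.  E ∈ [0.10, 0.80]: below ~10%
  efficiency the FRET component is indistinguishable from the donor
  mixture, above ~80% it compresses into the first bins; outside these
  limits the parameter is unidentifiable in practice and pins to a bound
  (reported via `hit_bound`).
* **Optimizer.** A 5×5 coarse grid over (B, E) ranks starting points; the
  best three are refined by bounded L-BFGS-B (ftol 1e-9, iteration cap
  2000) and the lowest deviance wins.  Multi-start matters: for no-FRET
  data the misfit surface holds efficiency-at-bound local optima.  On
  simulated instances the optimizer agrees with an exhaustive (B, E) grid
  search at step 0.005 to within the grid step (the acceptance script
  re-measures this).
* **Reference lifetime.** τ_ref defaults to the amplitude-weighted mean
  lifetime of the pattern — the one single number consistent with how
  the pattern itself is summarized; the slowest component is available
  via `tau_ref_mode="longest"`.  E and τ_FRET are one parameter; results
  record both.
* **IRF handling.** With no instrument response supplied, histograms are
  tail-fitted from their peak channel, with the model's time axis
  re-originated there.  With a Gaussian or empirical IRF the model is
  reconvolved: components are integrated analytically on a 4× oversampled
  grid, convolved with the discretized IRF, and summed back to the
  acquisition bins (exact analytic bin integration in the no-IRF case
  avoids midpoint bias at short lifetimes).  Periodic-excitation
  wrap-around is not modeled; a warning fires when the window is shorter
  than 3× the longest lifetime.

## Cut-off semantics

When fitted BINDING is below 10%, essentially no photons inform the FRET
component and the efficiency estimate piles up at its bounds.  Such
efficiencies are reported numerically but flagged `valid_efficiency =
False`, and every downstream statistic (summary tables, group tests on
efficiency) uses only flagged-valid results.  The comparison is strict:
"below 10%" excludes, exactly 10% is kept.  The cut-off is a parameter
(default 0.10) and re-applicable via `apply_fret_cutoff`.

## Comparison analyses

* **Mono-exponential donor** (`MonoDonorFitter` / `fit_mono_donor`): the
  donor is collapsed to one fixed lifetime and the same three-parameter
  fit is run.  The default collapse is the pattern's principal (slowest)
  component — the convention of fixing the donor at its published
  mono-exponential lifetime — because that is the regime in which the
  conventional analysis misreads the secondary short donor component as
  FRET: on bi-exponential donor-only simulations the collapse yields
  BINDING ≈ the secondary amplitude (≈ 10% for the default pattern)
  instead of ≈ 0.  Two alternatives are selectable: the
  intensity-weighted mean (what a free mono-exponential calibration
  would converge to; inflation ≈ 6% on the same data) and the
  amplitude-weighted mean.  The amplitude-weighted collapse is *not* the
  default because its maximum-likelihood solution on multi-exponential
  donors is a negative-amplitude difference of near-equal exponentials
  (B ≈ −0.3) — a fit no conventional software reports, and the opposite
  of the documented false-positive failure mode.
* **Average lifetime** (`fit_average_lifetime`): the conventional free
  1-2 component fit summarized by τ_m, for side-by-side comparison with
  the legacy readout.

## Donor-pattern calibration

`MultiExponentialFitter` fits 1-3 free components plus background by the
same Poisson MLE (lifetime bounds [0.05, 10] ns, log-spaced lifetime
starts around the empirical mean arrival time, two starts for n ≥ 2).
Fits whose lifetimes collapse within 5% of each other raise a
degenerate-fit error advising fewer components.  Per-batch patterns are
pooled by `aggregate_patterns` as photon-weighted, rank-matched means.

A caveat the tests document: free bi-exponential decomposition with a
*free background* is ill-conditioned — the background level trades
against the slow lifetime along a flat likelihood valley, so at 10⁶
photons the short component can wander (e.g. to ~1.9 ns) even though the
deviance is genuinely lower there than at the generating values.  On
background-free decays the decomposition recovers the generating
components to ~2-3%.  Practical calibration should use high photon
counts and, where the setup's background is known, fix it.

## The simulator

`SimulationSpec`/`simulate_histogram` draw shot-noise histograms from
exactly the forward model the fits use: default 12.5 ns window in 250
bins of 50 ps (an 80 MHz TCSPC configuration), default donor pattern
3.0 ns/1.2 ns with amplitudes 0.9/0.1, 2% time-uniform background,
multinomial sampling (photon total conserved exactly; independent
Poisson per bin as an alternative).  Scenes
(`SceneSpec`/`simulate_flim_image`) compose elliptical nuclei with
concentric "nucleolus" carve-outs (labelled with the negative nucleus
label, i.e. excluded), optional bright short-lifetime "plastid" spots,
and uniform background counts; a ground-truth table accompanies every
scene.  All randomness flows through seeded `numpy` generators;
per-nucleus streams derive from `SeedSequence([seed, label])` so each
ROI is independently reproducible.

What the simulator does *not* emulate: instrument dead time,
afterpulsing and pile-up; excitation wrap-around; day-to-day drift of
the true donor pattern; detector IRF asymmetry; spatial PSF blur between
neighbouring structures.  Passing tests therefore demonstrate
correctness of the estimator and workflow logic under the stated noise
model, not robustness to every instrumental artefact of real recordings.

Photon-budget defaults (10⁵-10⁶ pooled photons per ROI for the
well-expressed regime, 10³-10⁴ for a low-count regime behind a
`min_photons` override) bracket typical transient-expression vs
stable-line count levels.

## Image workflow

The "fast lifetime" map is the per-pixel intensity-weighted mean photon
arrival time minus an origin (default: the bin of the image-summed
histogram maximum, an IRF-peak proxy); zero-photon pixels are NaN, and no
truncation correction is applied — it is a display and filtering
estimator, not a calibrated lifetime.  `exclude_low_lifetime_pixels`
flips ROI pixels whose fast lifetime falls below a threshold (default
use-case: ~1 ns, rejecting plastid-like autofluorescence) to the
excluded (negative) label, and `pool_roi` sums the remaining pixels of
one label into a single histogram for fitting — ROI-pooled fitting, not
pixel-wise maps, because per-pixel counts are far too low for a
three-parameter fit.  For the exclusion to catch a contaminating spot,
the spot must dominate its pixels' photon budget; the mixed-pixel fast
lifetime is the photon-weighted mean of the components.

## Group statistics

Multi-group comparison is the Kruskal-Wallis omnibus test
(tie-corrected H, chi-squared p) followed by a *protected* Fisher's-LSD
post hoc on the rank means (Conover's procedure: pairwise |R̄ᵢ − R̄ⱼ|
against t₁₋α/₂,N₋k · √(S²(N−1−H)/(N−k)(1/nᵢ+1/nⱼ)); no pairwise testing
unless the omnibus p < α, default α = 0.05).  No additional
multiple-testing correction is applied beyond the protection step — LSD
is the stated criterion — though a Bonferroni-style switch could be
layered on by callers.  The compact letter display is built from the
maximal cliques of the "not significantly different" graph, which makes
the display provably consistent with the pairwise matrix in both
directions (groups share a letter iff not significantly different);
cliques are sorted for deterministic lettering.

Paired acceptor-photobleaching comparisons use the Wilcoxon signed-rank
test on per-ROI BINDING deltas (exact null for n ≤ 25, one-sided "drop"
alternative by default; all-zero deltas degenerate to p = 1).  The
BINDING-vs-acceptor-level relation is summarized by Spearman rank
correlation (Pearson selectable) of BINDING against acceptor-channel
photon counts carried as per-ROI metadata.

## Numerical choices and degenerate inputs

* Expected-count floor 1e-12 guards the Poisson likelihood against
  zero/negative rates (negative densities can arise transiently for
  B < 0); clipping is flagged as model-invalidity.
* Bins are half-open [t₀, t₁), 0-based, (row, col) image convention.
* Summary statistics use the n−1 sample SD, SE = SD/√n; groups with no
  valid efficiencies report absent (NaN) efficiency columns, never 0.
* All-identical pooled samples short-circuit Kruskal-Wallis to H = 0,
  p = 1 (scipy would reject the degenerate case).
* Batch fitting isolates per-ROI failures as non-converged NaN results
  rather than aborting the batch.

## Known limitations

* The mean arrival time of the model is *not* monotone in E over the
  full [0.10, 0.80] range: the FRET component's photon share scales with
  B·τ_FRET, so past a turnover (E ≈ 0.53 for B = 0.3 with the default
  pattern) stronger quenching removes photons faster than it shifts
  them earlier.  This is physics, not a defect, but it is why
  weak-binding/low-efficiency corners are hard.
* In the weak-FRET corner (E ≈ 0.2, where τ_FRET is close to the donor
  mean) B and E trade off along a likelihood valley; at 10⁶ photons the
  Cramér-Rao bound alone implies sd(B) ≈ 0.04 regardless of estimator.
  Estimates there are honest but noisy, and the E ≥ 0.10 bound induces
  a positive bias in B when noise pushes Ê onto the bound.
* Problem sizes in the test suite and acceptance script (50 null
  replicates at 5·10⁵ photons, 10 seeds per recovery cell at 10⁶, 64×64
  scenes) were chosen as the smallest sets that give stable Monte-Carlo
  estimates of the quantities being checked.
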