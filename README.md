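# opaflim

Pattern-constrained FLIM-FRET analysis for multi-exponential donors.

Time-domain FLIM-FRET quantifies protein-protein interaction through the
quenching of a donor fluorophore's lifetime, but the conventional
readout — the amplitude-weighted mean lifetime τ_m of a free
multi-exponential fit — cannot distinguish *many weakly coupled*
complexes from *few tightly coupled* ones.  `opaflim` implements a
pattern-constrained fit that separates the two: the donor-only decay is
calibrated once as a fixed pattern of components (τⱼ, αⱼ), and each FRET
sample is fitted with

    p(t) ∝ (1 − B) Σⱼ αⱼ e^(−t/τⱼ) + B e^(−t/τ_FRET),   τ_FRET = (1 − E) τ_ref

by Poisson maximum likelihood, yielding

* **BINDING** `B` — the relative amplitude of the FRET component, the
  fraction of donors in FRET-competent complexes (affinity proxy),
  fitted on [−0.5, 1] (donor-only samples scatter around 0, including
  small negative values);
* **FRET efficiency** `E = 1 − τ_FRET/τ_ref` — the proximity/orientation
  proxy, fitted on [0.10, 0.80]; when `B < 10%` the efficiency is
  unidentifiable and flagged invalid (strict "below": exactly 10% is
  kept).

The package is written for microscopists and image analysts working with
TCSPC FLIM data of cells (the motivating use-case is nuclei of plant
cells expressing fluorescent-protein fusions).  It covers the whole
desk-side workflow: donor-pattern calibration, ROI pooling with
nucleolus/low-lifetime exclusion rules, the constrained fit with cut-off
semantics, two legacy comparison analyses (mono-exponential-donor fit
and free average-lifetime fit), group statistics (Kruskal-Wallis with
protected Fisher's-LSD letters, bleach-pair tests, acceptor
correlation), and a TCSPC/FLIM simulator with known ground truth so that
every step is testable without instrument data.

## Worked example

```python
import opaflim as op

# 1. calibrate the donor pattern from donor-only recordings
donor_fits = []
for seed in (1, 2, 3):
    h = op.simulate_histogram(op.SimulationSpec(
        binding=0.0, efficiency=0.0, n_photons=2_000_000, seed=seed))
    donor_fits.append(op.fit_multiexp(h, n_components=2))
pattern = op.aggregate_patterns(donor_fits)
print(pattern.lifetimes_ns, pattern.amplitudes, pattern.mean_lifetime_ns)

# 2. fit a FRET sample against the fixed pattern
fret = op.simulate_histogram(op.SimulationSpec(
    binding=0.30, efficiency=0.40, n_photons=1_000_000, seed=10))
r = op.fit_opa(fret, pattern, roi_id="nucleus-1")
print(f"BINDING = {100*r.binding_hat:.1f}%  E = {100*r.efficiency_hat:.1f}%  "
      f"tau_FRET = {r.tau_fret_ns:.2f} ns")

# 3. a donor-only control falls under the cut-off
donor = op.simulate_histogram(op.SimulationSpec(
    binding=0.0, efficiency=0.0, n_photons=1_000_000, seed=11))
rd = op.fit_opa(donor, pattern, roi_id="donor-only-1")
print(f"donor-only BINDING = {100*rd.binding_hat:.1f}%  "
      f"valid_efficiency = {rd.valid_efficiency}")
```

prints

```
[3.017 1.306] [0.885 0.115] 2.821
BINDING = 30.1%  E = 39.5%  tau_FRET = 1.71 ns
donor-only BINDING = -2.8%  valid_efficiency = False
```

The calibrated pattern recovers the generating 3.0/1.2 ns donor
(amplitudes 0.9/0.1, τ_m = 2.82 ns); the FRET sample's ground truth was
B = 30%, E = 40%; the donor-only control lands within the expected
−10…10% BINDING band and its (meaningless) efficiency is suppressed by
the cut-off.

The fitters are scikit-learn-style estimators, so the same fit reads

```python
est = op.OPAFitter(pattern=pattern).fit(fret)
est.binding_, est.efficiency_, est.valid_efficiency_
```

and composes with `clone`/`get_params`/`set_params`.

## Command line

```
opaflim simulate  --config scene.json --out fixtures/ --seed 1
opaflim calibrate --donor-dir donor_csvs/ --components 2 --out pattern.json
opaflim fit       --hist rois/ --pattern pattern.json --model opa --out results.json
opaflim image-fit --stack stack.tif --mask mask.tif --pattern pattern.json \
                  --exclude-below-ns 1.0 --out results.json
opaflim stats     --results results.json --groups groups.csv --out report.json
```

Histograms travel as `time_ns,counts` CSV, image stacks as multi-page
TIFF (one page per time bin), ROI masks as signed-integer TIFF
(0 background, +k nucleus, −k excluded sub-region of nucleus k),
patterns and results as JSON (results also as a flat CSV).

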