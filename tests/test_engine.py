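import numpy as np
import pytest
from sklearn.base import clone

from opaflim import (
    DonorPattern,
    MonoDonorFitter,
    OPAFitter,
    SimulationSpec,
    apply_fret_cutoff,
    batch_fit,
    fit_average_lifetime,
    fit_mono_donor,
    fit_opa,
    simulate_histogram,
)
from opaflim.exceptions import InvalidInputError, LowPhotonsError


class TestFitOPA:
    def test_recovers_binding_and_efficiency(self, pattern, fret_hist):
        r = fit_opa(fret_hist, pattern)
        assert r.converged
        assert r.binding_hat == pytest.approx(0.3, abs=0.03)
        assert r.efficiency_hat == pytest.approx(0.4, abs=0.05)
        assert r.background_hat == pytest.approx(0.02, abs=0.02)

    def test_tau_fret_consistent_with_efficiency(self, pattern, fret_hist):
        r = fit_opa(fret_hist, pattern)
        assert r.tau_fret_ns == pytest.approx(
            (1 - r.efficiency_hat) * r.tau_ref_ns, abs=1e-9
        )

    def test_donor_only_binding_near_zero(self, pattern, donor_hist):
        r = fit_opa(donor_hist, pattern)
        assert abs(r.binding_hat) < 0.10
        assert not r.valid_efficiency

    def test_donor_only_efficiency_pins_to_bound(self, pattern, donor_hist):
        """Without FRET photons the efficiency is unidentifiable and sits at
        a limit of its allowed range, flagged via hit_bound."""
        r = fit_opa(donor_hist, pattern)
        assert not r.valid_efficiency  # cut-off suppresses the estimate

    def test_likelihood_at_fit_beats_truth(self, pattern, fret_hist):
        """Sanity of optimization: the fitted deviance cannot exceed the
        deviance at the generating parameters."""
        from opaflim.calibration import poisson_deviance, _tail_view
        from opaflim.decay import IRF
        from opaflim.engine import _ConstrainedModel

        r = fit_opa(fret_hist, pattern)
        counts, grid = _tail_view(fret_hist)
        total = counts.sum()
        m = _ConstrainedModel(pattern, IRF.none(), grid)

        def dev(b, e, bg):
            p = (1 - bg) * m.shape(b, e) + bg / grid.n_bins
            return poisson_deviance(counts, total * p)

        assert dev(r.binding_hat, r.efficiency_hat, r.background_hat) <= (
            dev(0.3, 0.4, 0.02) + 1e-6
        )

    def test_low_photon_histogram_rejected_or_warned(self, pattern):
        h = simulate_histogram(
            SimulationSpec(binding=0.3, efficiency=0.4, n_photons=2_000, seed=1)
        )
        with pytest.raises(LowPhotonsError):
            fit_opa(h, pattern)
        with pytest.warns(UserWarning, match="photons"):
            r = fit_opa(h, pattern, min_photons=10_000, low_photons="warn")
        # n_photons counts the fitted (tail) range, which starts at the
        # empirical peak bin
        assert 0 < r.n_photons <= 2_000

    def test_accuracy_improves_with_photons(self, pattern):
        """Monte-Carlo bias and RMSE of (B, E) shrink as photons grow."""
        rmse_b, rmse_e = [], []
        for n in (10_000, 100_000, 1_000_000):
            eb, ee = [], []
            for seed in range(8):
                h = simulate_histogram(
                    SimulationSpec(binding=0.3, efficiency=0.4,
                                   n_photons=n, seed=300 + seed)
                )
                r = fit_opa(h, pattern, min_photons=1_000)
                eb.append(r.binding_hat - 0.3)
                ee.append(r.efficiency_hat - 0.4)
            rmse_b.append(np.sqrt(np.mean(np.square(eb))))
            rmse_e.append(np.sqrt(np.mean(np.square(ee))))
        assert rmse_b[0] > rmse_b[1] > rmse_b[2]
        assert rmse_e[0] > rmse_e[1] > rmse_e[2]

    def test_optimizer_matches_grid_search(self, pattern):
        """Bounded optimizer lands on the brute-force (B, E) grid optimum."""
        from opaflim.calibration import poisson_deviance, _tail_view
        from opaflim.decay import IRF
        from opaflim.engine import _ConstrainedModel

        for seed in (50, 51):
            h = simulate_histogram(
                SimulationSpec(binding=0.25, efficiency=0.5,
                               n_photons=200_000, seed=seed)
            )
            r = fit_opa(h, pattern, fix_background=0.02)
            counts, grid = _tail_view(h)
            total = counts.sum()
            m = _ConstrainedModel(pattern, IRF.none(), grid)
            bs = np.arange(-0.5, 1.0001, 0.005)
            es = np.arange(0.10, 0.8001, 0.005)
            fret = np.stack([m.fret_vector(e) for e in es])
            pat = m._pattern_vec
            best = (np.inf, None)
            for b in bs:
                shapes = (1 - b) * pat + b * fret
                shapes = np.clip(shapes, 1e-12, None)
                shapes /= shapes.sum(axis=1, keepdims=True)
                lam = total * (0.98 * shapes + 0.02 / grid.n_bins)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dev = 2 * np.sum(
                        lam - counts
                        + np.where(counts > 0,
                                   counts * np.log(np.maximum(counts, 1) / lam), 0),
                        axis=1,
                    )
                j = int(np.argmin(dev))
                if dev[j] < best[0]:
                    best = (dev[j], (b, es[j]))
            gb, ge = best[1]
            assert abs(r.binding_hat - gb) <= 0.01
            assert abs(r.efficiency_hat - ge) <= 0.01


class TestCutoff:
    def _result(self, binding, pattern, donor_hist):
        r = fit_opa(donor_hist, pattern)
        from dataclasses import replace

        return replace(r, binding_hat=binding)

    @pytest.mark.parametrize(
        "binding, valid", [(0.05, False), (0.10, True), (0.30, True)]
    )
    def test_strictly_below_excludes(self, binding, valid, pattern, donor_hist):
        r = apply_fret_cutoff(self._result(binding, pattern, donor_hist))
        assert r.valid_efficiency is valid

    def test_cutoff_out_of_range_rejected(self, pattern, donor_hist):
        r = self._result(0.2, pattern, donor_hist)
        with pytest.raises(InvalidInputError):
            apply_fret_cutoff(r, cutoff=1.5)


class TestMonoDonor:
    def test_inflates_binding_on_biexp_donor(self, donor_fit_pairs):
        """The mono-donor assumption misreads the short donor component as
        FRET, so paired BINDING exceeds the pattern fit on every replicate."""
        opa, mono = donor_fit_pairs
        assert np.all(mono > opa)
        assert mono.mean() > 0.05

    def test_inflation_crosses_cutoff_more_often(self, donor_fit_pairs):
        opa, mono = donor_fit_pairs
        assert (mono > 0.10).mean() > (opa > 0.10).mean()

    def test_true_mono_donor_stays_near_zero(self):
        mono_pattern = DonorPattern.from_values([3.0], [1.0])
        hits = []
        for seed in range(10):
            h = simulate_histogram(
                SimulationSpec(pattern=mono_pattern, binding=0.0, efficiency=0.0,
                               n_photons=500_000, seed=seed)
            )
            r = fit_mono_donor(h, mono_pattern)
            hits.append(abs(r.binding_hat) < 0.10)
        assert np.mean(hits) >= 0.9

    def test_single_component_pattern_contract_identical(self, donor_hist):
        """fit_opa on a one-component pattern and fit_mono_donor agree
        bit-for-bit (same bounds, same model) apart from the model tag."""
        mono_pattern = DonorPattern.from_values([2.82], [1.0])
        a = fit_opa(donor_hist, mono_pattern)
        b = fit_mono_donor(donor_hist, mono_pattern)
        assert a.binding_hat == b.binding_hat
        assert a.efficiency_hat == b.efficiency_hat
        assert a.background_hat == b.background_hat
        assert (a.model, b.model) == ("opa", "mono-donor")


class TestAverageLifetime:
    def test_donor_only_mean_lifetime(self, donor_hist):
        tau_m, fit = fit_average_lifetime(donor_hist)
        assert tau_m == pytest.approx(2.82, rel=0.02)

    def test_fret_lowers_mean_lifetime(self, pattern):
        taus_d, taus_f = [], []
        for seed in range(5):
            hd = simulate_histogram(
                SimulationSpec(binding=0.0, efficiency=0.0,
                               n_photons=500_000, seed=600 + seed)
            )
            hf = simulate_histogram(
                SimulationSpec(binding=0.3, efficiency=0.4,
                               n_photons=500_000, seed=700 + seed)
            )
            taus_d.append(fit_average_lifetime(hd)[0])
            taus_f.append(fit_average_lifetime(hf)[0])
        assert np.all(np.array(taus_f) < np.array(taus_d))

    def test_fret_mean_lifetime_matches_closed_form(self, pattern, fret_hist):
        tau_m, _ = fit_average_lifetime(fret_hist)
        # amplitude-weighted mean over the three generating components
        tau_f = (1 - 0.4) * pattern.mean_lifetime_ns
        amps = np.append(0.7 * pattern.amplitudes, 0.3)
        taus = np.append(pattern.lifetimes_ns, tau_f)
        closed_form = np.dot(amps, taus) / amps.sum()
        assert tau_m == pytest.approx(closed_form, rel=0.05)

    def test_three_components_rejected(self, donor_hist):
        with pytest.raises(InvalidInputError):
            fit_average_lifetime(donor_hist, n_components=3)


class TestBatchFit:
    def test_empty_list_rejected(self, pattern):
        with pytest.raises(InvalidInputError):
            batch_fit([], pattern)

    def test_order_preserved_and_failures_isolated(self, pattern):
        good1 = simulate_histogram(
            SimulationSpec(binding=0.3, efficiency=0.4, n_photons=100_000, seed=1)
        )
        tiny = simulate_histogram(
            SimulationSpec(binding=0.3, efficiency=0.4, n_photons=500, seed=2)
        )
        good2 = simulate_histogram(
            SimulationSpec(binding=0.0, efficiency=0.0, n_photons=100_000, seed=3)
        )
        with pytest.warns(UserWarning, match="failed"):
            results = batch_fit(
                [("a", good1), ("b", tiny), ("c", good2)], pattern
            )
        assert [r.roi_id for r in results] == ["a", "b", "c"]
        assert results[0].converged and results[2].converged
        assert not results[1].converged
        assert np.isnan(results[1].binding_hat)

    def test_acceptor_photons_carried_through(self, pattern):
        h = simulate_histogram(
            SimulationSpec(binding=0.3, efficiency=0.4, n_photons=100_000, seed=4)
        )
        results = batch_fit([("roi", h, 5_000)], pattern)
        assert results[0].acceptor_photons == 5_000


class TestSklearnIntegration:
    def test_get_set_params_and_clone(self, pattern):
        est = OPAFitter(pattern=pattern, cutoff=0.15)
        params = est.get_params()
        assert params["cutoff"] == 0.15
        est2 = clone(est)
        assert est2.get_params()["cutoff"] == 0.15
        est2.set_params(cutoff=0.05)
        assert est2.cutoff == 0.05

    def test_mono_fitter_clone_keeps_convention(self, pattern):
        est = clone(MonoDonorFitter(pattern=pattern, mono_lifetime="weighted_mean"))
        assert est.mono_lifetime == "weighted_mean"

    def test_fitted_attributes_have_trailing_underscore(self, pattern, fret_hist):
        est = OPAFitter(pattern=pattern).fit(fret_hist)
        for attr in ("binding_", "efficiency_", "tau_fret_ns_", "converged_"):
            assert hasattr(est, attr)
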