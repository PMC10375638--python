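"""Donor-pattern calibration: free multi-exponential decay fits.

The donor-only decay of a fluorophore such as mVenus is bi-exponential
(roughly 3 ns and 1-2 ns components).  This module estimates those
lifetimes and relative amplitudes from donor-only histograms by Poisson
maximum likelihood and freezes them into the fixed `DonorPattern` the
pattern-constrained FRET fit uses.

`MultiExponentialFitter` is the estimator class; `fit_multiexp`,
`make_pattern` and `aggregate_patterns` are the functional surface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import __version__
from .decay import (
    DENSITY_FLOOR,
    IRF,
    BinGrid,
    DecayComponent,
    DonorPattern,
    _decay_shape,
)
from .exceptions import DegenerateFitError, InvalidInputError, LowPhotonsError
from .imageio import TCSPCHistogram

__all__ = [
    "CalibrationFit",
    "MultiExponentialFitter",
    "fit_multiexp",
    "make_pattern",
    "aggregate_patterns",
    "save_pattern",
    "load_pattern",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Result of a free multi-exponential fit to a donor-only histogram."""

    components: tuple[DecayComponent, ...]  # sorted by descending lifetime,
    # amplitudes normalized to sum 1
    background_fraction: float
    fit_statistic: float  # reduced Poisson deviance
    n_photons: int
    converged: bool

    @property
    def mean_lifetime_ns(self) -> float:
        taus = np.array([c.lifetime_ns for c in self.components])
        amps = np.array([c.amplitude for c in self.components])
        return float(np.dot(amps, taus) / amps.sum())


def poisson_deviance(counts: np.ndarray, expected: np.ndarray) -> float:
    """Poisson deviance (C statistic): ``2 sum(lam - c + c ln(c/lam))``."""
    lam = np.clip(expected, DENSITY_FLOOR, None)
    dev = lam - counts
    nz = counts > 0
    dev[nz] += counts[nz] * np.log(counts[nz] / lam[nz])
    return 2.0 * float(dev.sum())


def wls_chi2(counts: np.ndarray, expected: np.ndarray) -> float:
    """Neyman weighted least squares with variance ``max(counts, 1)``."""
    return float(((counts - expected) ** 2 / np.maximum(counts, 1)).sum())


def _tail_view(hist: TCSPCHistogram) -> tuple[np.ndarray, BinGrid]:
    """Sub-histogram from the count maximum onward, re-origined at its start.

    Without an IRF the decay is tail-fitted from the peak channel; the
    model's time axis is measured from the first fitted bin.
    """
    start = int(np.argmax(hist.counts))
    counts = hist.counts[start:].astype(float)
    grid = BinGrid(
        bin_width_ns=hist.grid.bin_width_ns,
        n_bins=len(counts),
        origin_ns=0.0,
    )
    return counts, grid


class MultiExponentialFitter(BaseEstimator):
    """Free multi-exponential decay fit by bounded Poisson maximum likelihood.

    Fits 1-3 lifetimes, their relative amplitudes and a time-uniform
    background fraction to a TCSPC histogram.  With an IRF the model is
    reconvolved; without one the histogram is tail-fitted from its peak
    channel.

    Parameters
    ----------
    n_components : int
        Number of exponential components (1-3).
    irf : IRF or None
        Instrument response; None means tail fitting.
    min_photons : int
        Histograms with fewer photons are rejected.
    lifetime_bounds_ns : tuple
        Box bounds for every lifetime.
    loss : str
        ``"poisson"`` (deviance, default) or ``"wls"`` for a
        weighted-least-squares cross-check.

    Attributes (after fit)
    ----------------------
    components_ : tuple of DecayComponent, descending lifetime, amplitudes sum 1
    background_ : fitted background fraction
    fit_statistic_ : reduced Poisson deviance
    n_photons_ : photons in the fitted range
    converged_ : False if the optimizer hit its cap or a lifetime bound
    """

    def __init__(
        self,
        n_components: int = 2,
        irf: IRF | None = None,
        min_photons: int = 10_000,
        lifetime_bounds_ns: tuple[float, float] = (0.05, 10.0),
        max_background: float = 0.5,
        loss: str = "poisson",
        max_iter: int = 2000,
        tol: float = 1e-9,
    ) -> None:
        self.n_components = n_components
        self.irf = irf
        self.min_photons = min_photons
        self.lifetime_bounds_ns = lifetime_bounds_ns
        self.max_background = max_background
        self.loss = loss
        self.max_iter = max_iter
        self.tol = tol

    # -- internals ---------------------------------------------------------

    def _objective_factory(self, counts, grid, irf_eff):
        n = self.n_components
        total = counts.sum()
        nbins = len(counts)
        loss_fn = poisson_deviance if self.loss == "poisson" else wls_chi2

        def objective(x: np.ndarray) -> float:
            taus = x[:n]
            amps = np.concatenate([[1.0], 10.0 ** x[n : 2 * n - 1]])
            bg = x[-1]
            shape = _decay_shape(taus, amps, irf_eff, grid)
            shape = np.clip(shape, DENSITY_FLOOR, None)
            shape = shape / shape.sum()
            p = (1.0 - bg) * shape + bg / nbins
            return loss_fn(counts, total * p)

        return objective

    def _starts(self, counts, grid) -> list[np.ndarray]:
        n = self.n_components
        centers = grid.centers_ns
        mean_t = float(np.dot(counts, centers) / counts.sum())
        lo, hi = self.lifetime_bounds_ns
        starts = []
        for spread in (2.0, 4.0):
            taus = np.geomspace(
                np.clip(mean_t * spread, lo * 1.5, hi / 1.5),
                np.clip(mean_t / spread, lo * 1.5, hi / 1.5),
                n,
            )
            x0 = np.concatenate([taus, np.zeros(n - 1), [0.01]])
            starts.append(x0)
        return starts if n > 1 else starts[:1]

    # -- public API --------------------------------------------------------

    def fit(self, hist: TCSPCHistogram) -> "MultiExponentialFitter":
        if self.n_components not in (1, 2, 3):
            raise InvalidInputError("n_components must be 1, 2 or 3")
        if hist.total_photons < self.min_photons:
            raise LowPhotonsError(
                f"histogram has {hist.total_photons} photons, below the "
                f"configured minimum of {self.min_photons}"
            )
        irf = self.irf if self.irf is not None else IRF.none()
        if irf.kind == "none":
            counts, grid = _tail_view(hist)
        else:
            counts, grid = hist.counts.astype(float), hist.grid

        n = self.n_components
        objective = self._objective_factory(counts, grid, irf)
        lo, hi = self.lifetime_bounds_ns
        bounds = [(lo, hi)] * n + [(-4.0, 4.0)] * (n - 1) + [(0.0, self.max_background)]

        best = None
        for x0 in self._starts(counts, grid):
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": self.tol},
            )
            if best is None or res.fun < best.fun:
                best = res

        taus = np.asarray(best.x[:n], dtype=float)
        amps = np.concatenate([[1.0], 10.0 ** best.x[n : 2 * n - 1]])
        amps = amps / amps.sum()
        order = np.argsort(taus)[::-1]
        taus, amps = taus[order], amps[order]

        for a, b in zip(taus, taus[1:]):
            if abs(a - b) / a < 0.05:
                raise DegenerateFitError(
                    f"fitted lifetimes {a:.3f} and {b:.3f} ns lie within 5% of "
                    "each other; refit with fewer components"
                )

        eps = 1e-6 * (hi - lo)
        at_bound = bool(np.any(taus <= lo + eps) or np.any(taus >= hi - eps))
        iter_cap = best.nit >= self.max_iter

        self.components_ = tuple(
            DecayComponent(float(t), float(a)) for t, a in zip(taus, amps)
        )
        self.background_ = float(best.x[-1])
        dof = max(len(counts) - len(best.x), 1)
        self.fit_statistic_ = poisson_deviance(
            counts,
            counts.sum()
            * self._normalized_model(taus, amps, self.background_, grid, irf),
        ) / dof
        self.n_photons_ = int(counts.sum())
        self.converged_ = bool(best.success) and not at_bound and not iter_cap
        return self

    def _normalized_model(self, taus, amps, bg, grid, irf) -> np.ndarray:
        shape = _decay_shape(np.asarray(taus), np.asarray(amps), irf, grid)
        shape = np.clip(shape, DENSITY_FLOOR, None)
        shape = shape / shape.sum()
        return (1.0 - bg) * shape + bg / grid.n_bins

    def result(self) -> CalibrationFit:
        return CalibrationFit(
            components=self.components_,
            background_fraction=self.background_,
            fit_statistic=self.fit_statistic_,
            n_photons=self.n_photons_,
            converged=self.converged_,
        )


def fit_multiexp(
    hist: TCSPCHistogram,
    n_components: int = 2,
    irf: IRF | None = None,
    **options,
) -> CalibrationFit:
    """Fit a free 1-3 component decay model; see `MultiExponentialFitter`."""
    return MultiExponentialFitter(
        n_components=n_components, irf=irf, **options
    ).fit(hist).result()


def make_pattern(fit: CalibrationFit, source_note: str | None = None) -> DonorPattern:
    """Freeze a converged calibration fit into a donor pattern."""
    if not fit.converged:
        raise InvalidInputError("refusing to build a pattern from a non-converged fit")
    note = source_note or (
        f"calibrated from {fit.n_photons} photons, "
        f"reduced deviance {fit.fit_statistic:.3f}"
    )
    return DonorPattern.from_values(
        [c.lifetime_ns for c in fit.components],
        [c.amplitude for c in fit.components],
        source_note=note,
    )


def aggregate_patterns(fits: list[CalibrationFit]) -> DonorPattern:
    """Photon-weighted, rank-matched average of several calibration fits.

    All fits must be converged and share the component count; components
    are matched by descending-lifetime rank.  Used to pool many donor-only
    nuclei of one construct into a single batch pattern.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise InvalidInputError("need at least one converged fit")
    n = len(usable[0].components)
    if any(len(f.components) != n for f in usable):
        raise InvalidInputError("all fits must have the same number of components")
    w = np.array([f.n_photons for f in usable], dtype=float)
    w = w / w.sum()
    taus = np.array([[c.lifetime_ns for c in f.components] for f in usable])
    amps = np.array([[c.amplitude for c in f.components] for f in usable])
    mean_taus = w @ taus
    mean_amps = w @ amps
    return DonorPattern.from_values(
        mean_taus,
        mean_amps,
        source_note=f"aggregate of {len(usable)} calibration fits",
    )


def save_pattern(pattern: DonorPattern, path) -> None:
    payload = {
        "lifetimes_ns": pattern.lifetimes_ns.tolist(),
        "amplitudes": pattern.amplitudes.tolist(),
        "source": pattern.source_note,
        "created_by": f"opaflim {__version__}",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_pattern(path) -> DonorPattern:
    with open(path) as fh:
        payload = json.load(fh)
    return DonorPattern.from_values(
        payload["lifetimes_ns"], payload["amplitudes"], payload.get("source", str(path))
    )
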