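"""Closed-form TCSPC decay mathematics.

Multi-exponential intensity models, amplitude-weighted lifetimes, FRET
efficiency/lifetime conversions, instrument-response convolution and
expected-photon-count generation.  Everything downstream (simulator,
calibration, the pattern-constrained fit) builds on the forward model
defined here.

The model
---------
A fluorophore population with decay components ``(tau_j, alpha_j)`` emits
photons with arrival-time density ``sum_j alpha_j exp(-t / tau_j)`` after
the excitation pulse.  With a fraction ``B`` (BINDING) of donors engaged in
FRET, a third component with lifetime ``tau_FRET = (1 - E) * tau_ref``
joins the fixed donor pattern:

    p(t)  propto  (1 - B) * sum_j alpha_j exp(-t / tau_j)
                  + B * exp(-t / tau_FRET)

``E`` is the FRET efficiency and ``tau_ref`` the reference donor lifetime,
by default the amplitude-weighted mean lifetime of the pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "DecayComponent",
    "DonorPattern",
    "IRF",
    "BinGrid",
    "amplitude_weighted_lifetime",
    "intensity_weighted_lifetime",
    "fret_efficiency",
    "fret_lifetime",
    "amplitude_to_photon_fraction",
    "expected_counts",
]

#: numerical floor applied to expected densities so a Poisson likelihood
#: never sees a zero or negative rate
DENSITY_FLOOR = 1e-12

#: oversampling factor used when a model must be convolved with an IRF
_OVERSAMPLE = 4


@dataclass(frozen=True)
class DecayComponent:
    """One exponential decay component: lifetime (ns) and pre-exponential amplitude."""

    lifetime_ns: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.lifetime_ns > 0:
            raise InvalidInputError(
                f"lifetime_ns must be positive, got {self.lifetime_ns}"
            )


@dataclass(frozen=True)
class DonorPattern:
    """The fixed donor-only decay pattern: 1-3 components with normalized amplitudes.

    Amplitudes must sum to 1 (within 1e-9) and lifetimes must be strictly
    decreasing.  Use :meth:`from_values` to build a pattern from raw,
    unnormalized amplitudes.
    """

    components: tuple[DecayComponent, ...]
    source_note: str = ""

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not 1 <= len(comps) <= 3:
            raise InvalidInputError(
                f"a donor pattern has 1-3 components, got {len(comps)}"
            )
        amps = np.array([c.amplitude for c in comps], dtype=float)
        if np.any(amps < 0) or np.any(amps > 1):
            raise InvalidInputError("pattern amplitudes must lie in [0, 1]")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise InvalidInputError(
                f"pattern amplitudes must sum to 1 (got {amps.sum()!r}); "
                "use DonorPattern.from_values to normalize"
            )
        taus = [c.lifetime_ns for c in comps]
        if any(t1 <= t2 for t1, t2 in zip(taus, taus[1:])):
            raise InvalidInputError(
                f"pattern lifetimes must be strictly decreasing, got {taus}"
            )

    @classmethod
    def from_values(
        cls,
        lifetimes_ns: Sequence[float],
        amplitudes: Sequence[float],
        source_note: str = "",
    ) -> "DonorPattern":
        """Build a pattern from lifetimes and (possibly unnormalized) amplitudes."""
        amps = np.asarray(amplitudes, dtype=float)
        total = amps.sum()
        if total <= 0:
            raise InvalidInputError("amplitudes must have a positive sum")
        order = np.argsort(lifetimes_ns)[::-1]
        comps = tuple(
            DecayComponent(float(lifetimes_ns[i]), float(amps[i] / total))
            for i in order
        )
        return cls(components=comps, source_note=source_note)

    @property
    def lifetimes_ns(self) -> np.ndarray:
        return np.array([c.lifetime_ns for c in self.components])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def mean_lifetime_ns(self) -> float:
        """Amplitude-weighted mean lifetime of the pattern."""
        return amplitude_weighted_lifetime(self.components)

    def tau_ref(self, mode: str = "weighted_mean") -> float:
        """Reference donor lifetime used in efficiency conversions.

        ``weighted_mean`` (default) uses the amplitude-weighted mean
        lifetime; ``longest`` uses the slowest component.
        """
        if mode == "weighted_mean":
            return self.mean_lifetime_ns
        if mode == "longest":
            return float(self.lifetimes_ns[0])
        raise InvalidInputError(f"unknown tau_ref mode {mode!r}")


@dataclass(frozen=True)
class IRF:
    """Instrument response function: gaussian, empirical histogram, or none."""

    kind: str = "none"
    center_ns: float = 0.0
    fwhm_ns: float | None = None
    histogram: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "empirical", "none"):
            raise InvalidInputError(f"unknown IRF kind {self.kind!r}")
        if self.kind == "gaussian":
            if self.fwhm_ns is None or not self.fwhm_ns > 0:
                raise InvalidInputError("gaussian IRF requires fwhm_ns > 0")
        if self.kind == "empirical":
            if self.histogram is None:
                raise InvalidInputError("empirical IRF requires a histogram")
            h = np.asarray(self.histogram, dtype=float)
            if np.any(h < 0) or h.sum() <= 0:
                raise InvalidInputError(
                    "empirical IRF histogram must be nonnegative with positive sum"
                )
            object.__setattr__(self, "histogram", h / h.sum())

    @classmethod
    def none(cls) -> "IRF":
        return cls(kind="none")

    @classmethod
    def gaussian(cls, center_ns: float, fwhm_ns: float) -> "IRF":
        return cls(kind="gaussian", center_ns=center_ns, fwhm_ns=fwhm_ns)

    @classmethod
    def empirical(cls, histogram: np.ndarray) -> "IRF":
        return cls(kind="empirical", histogram=np.asarray(histogram, dtype=float))


@dataclass(frozen=True)
class BinGrid:
    """Uniform TCSPC time binning: bin width (ns), number of bins, origin (ns)."""

    bin_width_ns: float
    n_bins: int
    origin_ns: float = 0.0

    def __post_init__(self) -> None:
        if not self.bin_width_ns > 0:
            raise InvalidInputError("bin_width_ns must be positive")
        if not (isinstance(self.n_bins, (int, np.integer)) and self.n_bins >= 1):
            raise InvalidInputError("n_bins must be a positive integer")

    @property
    def window_ns(self) -> float:
        return self.bin_width_ns * self.n_bins

    @property
    def edges_ns(self) -> np.ndarray:
        """Bin edges, length n_bins + 1; bins are half-open [t0, t1)."""
        return self.origin_ns + self.bin_width_ns * np.arange(self.n_bins + 1)

    @property
    def centers_ns(self) -> np.ndarray:
        return self.origin_ns + self.bin_width_ns * (np.arange(self.n_bins) + 0.5)


def _components_of(obj: Iterable[DecayComponent] | DonorPattern) -> list[DecayComponent]:
    if isinstance(obj, DonorPattern):
        return list(obj.components)
    return list(obj)


def amplitude_weighted_lifetime(
    components: Iterable[DecayComponent] | DonorPattern,
) -> float:
    """Amplitude-weighted mean lifetime ``tau_m = sum(a_i tau_i) / sum(a_i)``.

    Equals the single lifetime for a one-component list; invariant under
    rescaling all amplitudes by a common positive factor.
    """
    comps = _components_of(components)
    if not comps:
        raise InvalidInputError("component list is empty")
    taus = np.array([c.lifetime_ns for c in comps])
    amps = np.array([c.amplitude for c in comps])
    total = amps.sum()
    if total <= 0:
        raise InvalidInputError("amplitude sum must be positive")
    return float(np.dot(amps, taus) / total)


def intensity_weighted_lifetime(
    components: Iterable[DecayComponent] | DonorPattern,
) -> float:
    """Intensity-weighted mean lifetime ``sum(a_i tau_i^2) / sum(a_i tau_i)``.

    Each component's detected-photon share is ``a_i tau_i``, so this is the
    mean lifetime *per photon* — and therefore the lifetime a
    mono-exponential maximum-likelihood fit recovers from multi-exponential
    data in the large-photon, long-window limit.
    """
    comps = _components_of(components)
    if not comps:
        raise InvalidInputError("component list is empty")
    taus = np.array([c.lifetime_ns for c in comps])
    amps = np.array([c.amplitude for c in comps])
    denom = np.dot(amps, taus)
    if denom <= 0:
        raise InvalidInputError("amplitude sum must be positive")
    return float(np.dot(amps, taus**2) / denom)


def fret_efficiency(tau_fret_ns: float, tau_ref_ns: float) -> float:
    """FRET efficiency ``E = 1 - tau_FRET / tau_ref``.

    May return a negative value when the "FRET" lifetime exceeds the
    reference; the caller decides whether that is meaningful.
    """
    if not (tau_fret_ns > 0 and tau_ref_ns > 0):
        raise InvalidInputError("lifetimes must be positive")
    return 1.0 - tau_fret_ns / tau_ref_ns


def fret_lifetime(tau_ref_ns: float, efficiency: float) -> float:
    """Quenched lifetime ``tau_FRET = (1 - E) * tau_ref``; inverse of fret_efficiency."""
    if not tau_ref_ns > 0:
        raise InvalidInputError("tau_ref_ns must be positive")
    if efficiency >= 1:
        raise InvalidInputError("efficiency must be < 1")
    return (1.0 - efficiency) * tau_ref_ns


def amplitude_to_photon_fraction(
    binding: float, pattern: DonorPattern, tau_fret_ns: float
) -> float:
    """Convert the amplitude fraction B into the detected-photon (area) fraction.

    Each component's integrated intensity is ``alpha * tau``, so the FRET
    component collects ``B tau_F / (B tau_F + (1 - B) tau_m)`` of the
    photons, with ``tau_m`` the pattern's amplitude-weighted lifetime.
    """
    if not 0 <= binding <= 1:
        raise InvalidInputError(
            "binding must lie in [0, 1]; a negative amplitude fraction has no "
            "photon-fraction interpretation"
        )
    if not tau_fret_ns > 0:
        raise InvalidInputError("tau_fret_ns must be positive")
    tau_m = pattern.mean_lifetime_ns
    num = binding * tau_fret_ns
    return float(num / (num + (1.0 - binding) * tau_m))


# ---------------------------------------------------------------------------
# forward model


def _bin_integrals(
    lifetimes: np.ndarray, amplitudes: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Exact per-bin integral of ``sum_j a_j exp(-t/tau_j)`` from local time 0.

    ``edges`` are measured from the decay origin.  Components with negative
    amplitude (an unconstrained B during fitting) are handled by linearity.
    """
    t = np.clip(edges, 0.0, None)
    # integral over [t0, t1) of a * exp(-t/tau) dt = a * tau * (e^-t0/tau - e^-t1/tau)
    ex = np.exp(-t[None, :] / lifetimes[:, None])
    per_comp = (amplitudes * lifetimes)[:, None] * (ex[:, :-1] - ex[:, 1:])
    return per_comp.sum(axis=0)


def _irf_weights(irf: IRF, grid: BinGrid, n_fine: int, fine_width: float) -> np.ndarray:
    """Mass of the IRF in each fine bin of the oversampled grid, normalized."""
    edges = grid.origin_ns + fine_width * np.arange(n_fine + 1)
    if irf.kind == "gaussian":
        from scipy.stats import norm

        sigma = irf.fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        cdf = norm.cdf(edges, loc=irf.center_ns, scale=sigma)
        w = np.diff(cdf)
    elif irf.kind == "empirical":
        h = np.asarray(irf.histogram, dtype=float)
        if len(h) != grid.n_bins:
            raise InvalidInputError(
                "empirical IRF histogram length must match the bin grid"
            )
        # spread each coarse bin's mass evenly over its fine sub-bins
        w = np.repeat(h / _OVERSAMPLE, _OVERSAMPLE)[:n_fine]
    else:  # pragma: no cover - callers dispatch before reaching here
        raise InvalidInputError("no IRF weights for kind='none'")
    total = w.sum()
    if total <= 0:
        raise InvalidInputError("IRF carries no mass inside the time window")
    return w / total


def _decay_shape(
    lifetimes: np.ndarray,
    amplitudes: np.ndarray,
    irf: IRF,
    grid: BinGrid,
) -> np.ndarray:
    """Unnormalized per-bin decay signal, IRF-convolved when one is given."""
    if irf.kind == "none":
        edges = grid.edges_ns - grid.origin_ns
        return _bin_integrals(lifetimes, amplitudes, edges)
    n_fine = grid.n_bins * _OVERSAMPLE
    fine_width = grid.bin_width_ns / _OVERSAMPLE
    fine_edges = fine_width * np.arange(n_fine + 1)
    decay = _bin_integrals(lifetimes, amplitudes, fine_edges)
    weights = _irf_weights(irf, grid, n_fine, fine_width)
    conv = np.convolve(weights, decay)[:n_fine]
    return conv.reshape(grid.n_bins, _OVERSAMPLE).sum(axis=1)


def expected_counts(
    pattern: DonorPattern,
    binding: float,
    efficiency: float,
    background_fraction: float,
    irf: IRF,
    grid: BinGrid,
    total_photons: float,
    tau_ref_mode: str = "weighted_mean",
    return_validity: bool = False,
) -> np.ndarray | tuple[np.ndarray, bool]:
    """Expected photon counts per bin for the pattern-constrained model.

    The per-photon density is the donor pattern scaled by ``1 - binding``
    plus a FRET component of amplitude ``binding`` at lifetime
    ``(1 - efficiency) * tau_ref``, convolved with the IRF, bin-integrated,
    mixed with a time-uniform background at ``background_fraction`` of the
    photons, and scaled so the vector sums to ``total_photons``.

    Parameters
    ----------
    binding : float
        Amplitude fraction of the FRET component.  Values below 0 (apparent
        negative BINDING from a fit) are accepted; any resulting negative
        bin density is clipped at a 1e-12 floor and, when
        ``return_validity`` is set, flagged.
    efficiency : float
        FRET efficiency in ``[0, 1)``.
    return_validity : bool
        When true, return ``(counts, model_valid)`` where ``model_valid``
        is False if clipping occurred.
    """
    if not 0 <= efficiency < 1:
        raise InvalidInputError("efficiency must lie in [0, 1)")
    if not 0 <= background_fraction < 1:
        raise InvalidInputError("background_fraction must lie in [0, 1)")
    if not total_photons > 0:
        raise InvalidInputError("total_photons must be positive")
    taus = pattern.lifetimes_ns
    if grid.bin_width_ns > taus.min():
        warnings.warn(
            "bin width exceeds the smallest pattern lifetime; the grid is too "
            "coarse to resolve the fast component",
            stacklevel=2,
        )
    if grid.window_ns < 3.0 * taus.max():
        warnings.warn(
            "time window is shorter than 3x the longest pattern lifetime; the "
            "decay is substantially truncated",
            stacklevel=2,
        )

    tau_ref = pattern.tau_ref(tau_ref_mode)
    tau_f = fret_lifetime(tau_ref, efficiency)
    lifetimes = np.append(taus, tau_f)
    amplitudes = np.append((1.0 - binding) * pattern.amplitudes, binding)

    shape = _decay_shape(lifetimes, amplitudes, irf, grid)
    clipped = bool(np.any(shape < 0))
    shape = np.clip(shape, DENSITY_FLOOR, None)
    shape = shape / shape.sum()

    per_photon = (1.0 - background_fraction) * shape + background_fraction / grid.n_bins
    counts = per_photon * total_photons
    if return_validity:
        return counts, not clipped
    return counts
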