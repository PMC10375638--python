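"""Synthetic TCSPC and FLIM data with known ground truth.

The simulator draws photon arrival histograms from the same forward model
the fits use (bi-exponential donor pattern plus an optional FRET component,
IRF convolution, time-uniform background) with shot noise, and composes
whole FLIM scenes: elliptical nuclei with carved-out nucleoli, short-lived
"plastid" spots and background counts, together with a per-nucleus
ground-truth table.

Defaults emulate a typical 80 MHz TCSPC recording (12.5 ns window, 250
bins of 50 ps) and a donor with a ~3 ns major and ~1.2 ns minor lifetime
component (amplitudes 0.9 / 0.1).

All randomness flows through `numpy.random.Generator` instances derived
from the spec seed; per-nucleus streams are spawned from
``SeedSequence([seed, label])`` so each ROI is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .decay import IRF, BinGrid, DonorPattern, expected_counts
from .exceptions import InvalidInputError
from .imageio import FLIMImage, ROIMask, TCSPCHistogram

__all__ = [
    "default_donor_pattern",
    "default_grid",
    "SimulationSpec",
    "NucleusSpec",
    "PlastidSpot",
    "SceneSpec",
    "simulate_histogram",
    "simulate_bleach_pair",
    "simulate_flim_image",
]


def default_donor_pattern() -> DonorPattern:
    """Bi-exponential donor: 3.0 ns (amplitude 0.9) + 1.2 ns (amplitude 0.1)."""
    return DonorPattern.from_values(
        [3.0, 1.2], [0.9, 0.1], source_note="default bi-exponential donor"
    )


def default_grid() -> BinGrid:
    """12.5 ns window in 250 bins of 50 ps (80 MHz repetition rate)."""
    return BinGrid(bin_width_ns=0.05, n_bins=250, origin_ns=0.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters for one simulated histogram."""

    pattern: DonorPattern = field(default_factory=default_donor_pattern)
    binding: float = 0.0
    efficiency: float = 0.0
    background_fraction: float = 0.02
    irf: IRF = field(default_factory=IRF.none)
    grid: BinGrid = field(default_factory=default_grid)
    n_photons: int = 500_000
    seed: int = 0
    sampling: str = "multinomial"

    def __post_init__(self) -> None:
        if not 0 <= self.binding <= 1:
            raise InvalidInputError(
                "simulated binding must lie in [0, 1]; negative BINDING is a "
                "fit artefact, never a ground truth"
            )
        if self.binding > 0:
            if not 0.10 <= self.efficiency <= 0.80:
                raise InvalidInputError(
                    "efficiency must lie in [0.10, 0.80] when binding > 0 "
                    "(the fit limits)"
                )
        elif self.efficiency != 0:
            raise InvalidInputError("efficiency must be 0 when binding is 0")
        if not 0 <= self.background_fraction < 1:
            raise InvalidInputError("background_fraction must lie in [0, 1)")
        if not self.n_photons > 0:
            raise InvalidInputError("n_photons must be positive")
        if self.sampling not in ("multinomial", "poisson"):
            raise InvalidInputError(f"unknown sampling mode {self.sampling!r}")

    def bin_probabilities(self) -> np.ndarray:
        """Per-bin photon probabilities of the noiseless model."""
        # efficiency=0 with binding=0 degenerates to the pure pattern; the
        # FRET component then has zero amplitude and any lifetime works
        expected = expected_counts(
            self.pattern,
            self.binding,
            self.efficiency if self.binding > 0 else 0.5,
            self.background_fraction,
            self.irf,
            self.grid,
            total_photons=1.0,
        )
        return expected / expected.sum()


def _sample(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    p = spec.bin_probabilities()
    if spec.sampling == "multinomial":
        return rng.multinomial(spec.n_photons, p)
    return rng.poisson(spec.n_photons * p)


def simulate_histogram(spec: SimulationSpec) -> TCSPCHistogram:
    """Draw one shot-noise histogram from the spec's ground-truth model.

    ``multinomial`` sampling conserves the photon total exactly; ``poisson``
    draws each bin independently at its expectation.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _sample(spec, rng)
    src = (
        f"simulated B={spec.binding} E={spec.efficiency} "
        f"bg={spec.background_fraction} seed={spec.seed}"
    )
    return TCSPCHistogram(grid=spec.grid, counts=counts, source=src)


def _derived_seed(seed: int, *keys: int) -> int:
    state = np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(1)
    return int(state[0] % (2**31))


def simulate_bleach_pair(spec: SimulationSpec) -> tuple[TCSPCHistogram, TCSPCHistogram]:
    """Simulate an acceptor-photobleaching pair for one ROI.

    The pre-bleach member follows ``spec``; the post-bleach member is
    re-simulated with ``binding = 0`` (bleaching the acceptor abolishes
    FRET) from the same pattern and photon budget, with a fresh seed
    derived from the spec seed.
    """
    if not spec.binding > 0:
        raise InvalidInputError("bleach pairs require binding > 0 before the bleach")
    before = simulate_histogram(spec)
    after_spec = replace(
        spec, binding=0.0, efficiency=0.0, seed=_derived_seed(spec.seed, 0xB1EAC)
    )
    after = simulate_histogram(after_spec)
    return before, after


# ---------------------------------------------------------------------------
# FLIM scenes


@dataclass(frozen=True)
class NucleusSpec:
    """One elliptical nucleus: center (row, col), radii (ry, rx), truth and density."""

    center: tuple[float, float]
    radii: tuple[float, float]
    binding: float
    efficiency: float
    photon_density: float  # mean photons per pixel


@dataclass(frozen=True)
class PlastidSpot:
    """A small round spot with a short mono-exponential lifetime."""

    center: tuple[float, float]
    radius: float
    lifetime_ns: float
    photon_density: float


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and ground truth of a simulated FLIM field of view."""

    image_shape: tuple[int, int]
    nuclei: tuple[NucleusSpec, ...]
    nucleolus_fraction: float = 0.3
    plastid_spots: tuple[PlastidSpot, ...] = ()
    background_density: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        object.__setattr__(self, "plastid_spots", tuple(self.plastid_spots))
        if not 0 <= self.nucleolus_fraction < 1:
            raise InvalidInputError("nucleolus_fraction must lie in [0, 1)")


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _validate_scene(scene: SceneSpec) -> list[np.ndarray]:
    shape = scene.image_shape
    footprints = []
    for nuc in scene.nuclei:
        cy, cx = nuc.center
        ry, rx = nuc.radii
        if cy - ry < 0 or cy + ry >= shape[0] or cx - rx < 0 or cx + rx >= shape[1]:
            raise InvalidInputError(f"nucleus at {nuc.center} extends outside the image")
        footprints.append(_ellipse_mask(shape, nuc.center, nuc.radii))
    for a in range(len(footprints)):
        for b in range(a + 1, len(footprints)):
            if np.any(footprints[a] & footprints[b]):
                raise InvalidInputError(f"nuclei {a + 1} and {b + 1} overlap")
    for spot in scene.plastid_spots:
        cy, cx = spot.center
        r = spot.radius
        if cy - r < 0 or cy + r >= shape[0] or cx - r < 0 or cx + r >= shape[1]:
            raise InvalidInputError(f"plastid spot at {spot.center} outside the image")
    return footprints


def simulate_flim_image(
    scene: SceneSpec, defaults: SimulationSpec
) -> tuple[FLIMImage, ROIMask, pd.DataFrame]:
    """Simulate a FLIM stack, its ROI mask and a ground-truth table.

    Each nucleus ``k`` (1-based) receives label ``k``; its central
    nucleolus ellipse (radius scaled by ``nucleolus_fraction``) is labelled
    ``-k`` (excluded).  Plastid spots and background add photons to the
    image but never appear in the mask.  Returns
    ``(image, mask, ground_truth)`` where the table holds per-nucleus
    binding, efficiency and sampled photon totals (included pixels only).
    """
    footprints = _validate_scene(scene)
    shape = scene.image_shape
    grid = defaults.grid
    n_bins = grid.n_bins
    counts = np.zeros((*shape, n_bins), dtype=np.int64)
    labels = np.zeros(shape, dtype=np.int32)

    truth_rows = []
    for k, (nuc, fp) in enumerate(zip(scene.nuclei, footprints), start=1):
        spec_k = replace(
            defaults,
            binding=nuc.binding,
            efficiency=nuc.efficiency,
        )
        p = spec_k.bin_probabilities()
        rng = np.random.default_rng(np.random.SeedSequence([defaults.seed, k]))
        idx = np.argwhere(fp)
        pix = rng.poisson(nuc.photon_density * p, size=(len(idx), n_bins))
        counts[idx[:, 0], idx[:, 1]] += pix
        labels[fp] = k
        nucleolus = _ellipse_mask(
            shape,
            nuc.center,
            (
                max(scene.nucleolus_fraction * nuc.radii[0], 1e-9),
                max(scene.nucleolus_fraction * nuc.radii[1], 1e-9),
            ),
        ) if scene.nucleolus_fraction > 0 else np.zeros(shape, dtype=bool)
        labels[nucleolus & fp] = -k
        included = labels == k
        truth_rows.append(
            {
                "label": k,
                "binding": nuc.binding,
                "efficiency": nuc.efficiency,
                "n_pixels": int(included.sum()),
                # filled after plastids/background are added
                "photons_included": 0,
            }
        )

    for i, spot in enumerate(scene.plastid_spots):
        rng = np.random.default_rng(
            np.random.SeedSequence([defaults.seed, 1_000_000 + i])
        )
        fp = _ellipse_mask(shape, spot.center, (spot.radius, spot.radius))
        t0, t1 = grid.edges_ns[:-1] - grid.origin_ns, grid.edges_ns[1:] - grid.origin_ns
        mass = np.exp(-np.clip(t0, 0, None) / spot.lifetime_ns) - np.exp(
            -np.clip(t1, 0, None) / spot.lifetime_ns
        )
        p = mass / mass.sum()
        idx = np.argwhere(fp)
        counts[idx[:, 0], idx[:, 1]] += rng.poisson(
            spot.photon_density * p, size=(len(idx), n_bins)
        )

    if scene.background_density > 0:
        rng = np.random.default_rng(np.random.SeedSequence([defaults.seed, 0]))
        lam = scene.background_density / n_bins
        counts += rng.poisson(lam, size=counts.shape)

    for row in truth_rows:
        included = labels == row["label"]
        row["photons_included"] = int(counts[included].sum())

    image = FLIMImage(grid=grid, counts=counts, metadata={"seed": defaults.seed})
    mask = ROIMask(labels=labels)
    return image, mask, pd.DataFrame(truth_rows)
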