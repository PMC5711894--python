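"""Ground-truthed synthetic FLIM data: granule phantoms -> TCSPC photon stacks.

The generator emulates confocal TCSPC acquisitions of mucin granules loaded
with a viscosity-sensitive molecular rotor.  A scene phantom places circular
granules in a frame; each granule carries one true viscosity drawn from a
named population preset:

``nonCF``
    a single normal population, mean 521 cP, sd 60 cP — healthy cells show one
    granule-viscosity population centred near 520 cP;
``CF``
    a two-component mixture, 70% at 164 cP (sd 40) and 30% at 501 cP (sd 60) —
    cystic-fibrosis cells show a dominant low-viscosity population plus a
    smaller one matching the healthy value;
``nonrotor_control``
    every granule gets one fixed lifetime regardless of viscosity, emulating
    the viscosity-insensitive control dye.

Viscosities become lifetimes through the forward Forster-Hoffmann calibration,
and each pixel's photon-count histogram is an IRF-convolved single-exponential
decay with independent Poisson counts per time bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._kernels import bin_fractions
from .rotor_calibration import CalibrationCurve, default_calibration

__all__ = [
    "OpticalConfig",
    "GranuleSpec",
    "ScenePhantom",
    "TCSPCImage",
    "GroundTruth",
    "PlacementError",
    "PRESETS",
    "make_phantom",
    "render_tcspc",
    "default_dataset",
]


class PlacementError(RuntimeError):
    """Frame too crowded to place the requested granules."""


@dataclass(frozen=True)
class OpticalConfig:
    """TCSPC acquisition window and instrument response.

    Defaults: 256 bins x 0.1953125 ns = 50 ns window, matching a 20 MHz
    excitation repetition rate; Gaussian IRF of 0.2 ns FWHM centred 1 ns into
    the window.
    """

    n_time_bins: int = 256
    bin_width: float = 50.0 / 256.0  # ns
    rep_period: float = 50.0  # ns (20 MHz)
    irf_fwhm: float = 0.2  # ns
    irf_center: float = 1.0  # ns
    excitation_rate_label: str = "20 MHz"

    def __post_init__(self):
        if self.n_time_bins <= 0 or self.bin_width <= 0 or self.rep_period <= 0:
            raise ValueError("optics parameters must be positive")
        if self.irf_fwhm < 0 or self.irf_center < 0:
            raise ValueError("IRF parameters must be nonnegative")
        if self.n_time_bins * self.bin_width > self.rep_period * (1 + 1e-9):
            raise ValueError("acquisition window exceeds the repetition period")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_time_bins + 1) * self.bin_width

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width


@dataclass(frozen=True)
class GranuleSpec:
    center: Tuple[float, float]  # (row, col), 0-based pixel coordinates
    radius: float  # px
    true_viscosity: float  # cP
    cluster_id: Optional[int] = None

    def __post_init__(self):
        if self.radius < 1.0:
            raise ValueError("granule radius must be >= 1 px")
        if self.true_viscosity <= 0:
            raise ValueError("true viscosity must be positive")


@dataclass(frozen=True)
class ScenePhantom:
    height: int
    width: int
    granules: Tuple[GranuleSpec, ...]
    background_viscosity: float = 40.0  # cP
    background_intensity_fraction: float = 0.05
    preset_name: str = "custom"

    def __post_init__(self):
        if not 0.0 <= self.background_intensity_fraction < 1.0:
            raise ValueError("background_intensity_fraction must be in [0, 1)")


@dataclass
class TCSPCImage:
    """Time-binned photon-count stack, axes (time bin, row, col)."""

    counts: np.ndarray  # nonnegative integers
    optics: OpticalConfig
    seed: Optional[int] = None

    def __post_init__(self):
        if self.counts.ndim != 3:
            raise ValueError("counts must be a (time, row, col) stack")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")

    @property
    def intensity(self) -> np.ndarray:
        """Total counts per pixel (sum over time bins)."""
        return self.counts.sum(axis=0)


@dataclass
class GroundTruth:
    viscosity_map: np.ndarray  # cP per pixel
    lifetime_map: np.ndarray  # ns per pixel
    granule_label_map: np.ndarray  # 0 background, 1..n granule ids
    granules: Tuple[GranuleSpec, ...]


# population presets: list of (mean cP, sd cP, weight)
PRESETS: Dict[str, List[Tuple[float, float, float]]] = {
    "nonCF": [(521.0, 60.0, 1.0)],
    "CF": [(164.0, 40.0, 0.7), (501.0, 60.0, 0.3)],
}
NONROTOR_LIFETIME_NS = 3.5  # fixed lifetime of the viscosity-insensitive dye

# granule radii: lognormal, median 4 px, sigma_log 0.3, clipped to >= 3 px so
# rasterised disks stay comfortably above the circularity threshold
_RADIUS_LOG_MEDIAN = np.log(4.0)
_RADIUS_LOG_SIGMA = 0.3
_RADIUS_MIN = 3.0
_RADIUS_MAX = 10.0

CLUSTER_PROBABILITY = 0.25  # chance a granule is placed beside an existing one


def _draw_viscosities(
    components: Sequence[Tuple[float, float, float]], n: int, rng: np.random.Generator
) -> np.ndarray:
    means, sds, weights = (np.array(c) for c in zip(*components))
    weights = weights / weights.sum()
    comp = rng.choice(len(means), size=n, p=weights)
    vals = rng.normal(means[comp], sds[comp])
    # populations are physical viscosities: resample the rare negative draw
    bad = vals <= 1.0
    while np.any(bad):
        comp_b = rng.choice(len(means), size=int(bad.sum()), p=weights)
        vals[bad] = rng.normal(means[comp_b], sds[comp_b])
        bad = vals <= 1.0
    return vals


def make_phantom(
    preset: Union[str, Sequence[Tuple[float, float, float]]],
    n_granules: int,
    frame: Tuple[int, int] = (128, 128),
    seed: int = 0,
    cluster_probability: float = CLUSTER_PROBABILITY,
    background_viscosity: float = 40.0,
    background_intensity_fraction: float = 0.05,
    calibration: Optional[CalibrationCurve] = None,
) -> Tuple[ScenePhantom, GroundTruth]:
    """Place ``n_granules`` non-overlapping disks and assign true viscosities.

    ``preset`` is one of ``"nonCF"``, ``"CF"``, ``"nonrotor_control"`` or an
    explicit list of ``(mean_cP, sd_cP, weight)`` mixture components.  With
    probability ``cluster_probability`` a granule is placed near-tangent
    (1.2-1.6 px boundary gap) to an existing granule and shares its
    ``cluster_id``; all other granules keep >= 2 px clearance so independent
    disks never touch.  Identical seeds give identical phantoms.
    """
    if n_granules < 1:
        raise ValueError("n_granules must be >= 1")
    height, width = int(frame[0]), int(frame[1])
    rng = np.random.default_rng(seed)

    if isinstance(preset, str):
        preset_name = preset
        if preset == "nonrotor_control":
            components = PRESETS["nonCF"]
        elif preset in PRESETS:
            components = PRESETS[preset]
        else:
            raise ValueError(f"unknown preset {preset!r}")
    else:
        preset_name = "custom"
        components = list(preset)

    radii = np.clip(
        rng.lognormal(_RADIUS_LOG_MEDIAN, _RADIUS_LOG_SIGMA, size=n_granules),
        _RADIUS_MIN,
        _RADIUS_MAX,
    )
    # large disks first: packing succeeds far more often and stays deterministic
    radii = np.sort(radii)[::-1].copy()
    if 2 * radii.max() + 4 > min(height, width):
        raise PlacementError("frame smaller than the largest requested granule")
    viscosities = _draw_viscosities(components, n_granules, rng)

    centers: List[Tuple[float, float]] = []
    cluster_ids: List[Optional[int]] = []
    next_cluster = 1
    # coarse spatial hash so placement stays near-linear in n_granules
    cell = 2.0 * _RADIUS_MAX + 4.0
    buckets: Dict[Tuple[int, int], List[int]] = {}

    def _bucket(r0: float, c0: float) -> Tuple[int, int]:
        return (int(r0 // cell), int(c0 // cell))

    def _register(idx: int):
        buckets.setdefault(_bucket(*centers[idx]), []).append(idx)

    def _clear_of_others(r0: float, c0: float, rad: float, skip: Optional[int]) -> bool:
        br, bc = _bucket(r0, c0)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for j in buckets.get((br + dr, bc + dc), ()):
                    if j == skip:
                        continue
                    rj, cj = centers[j]
                    if np.hypot(r0 - rj, c0 - cj) < rad + radii[j] + 2.0:
                        return False
        return True

    for i in range(n_granules):
        rad = radii[i]
        placed = False
        as_companion = len(centers) > 0 and rng.random() < cluster_probability
        if as_companion:
            host = int(rng.integers(len(centers)))
            for _ in range(60):
                theta = rng.uniform(0.0, 2.0 * np.pi)
                gap = rng.uniform(1.2, 1.6)
                dist = rad + radii[host] + gap
                r0 = centers[host][0] + dist * np.sin(theta)
                c0 = centers[host][1] + dist * np.cos(theta)
                if not (rad + 1 <= r0 <= height - rad - 2 and rad + 1 <= c0 <= width - rad - 2):
                    continue
                if _clear_of_others(r0, c0, rad, skip=host):
                    centers.append((r0, c0))
                    _register(len(centers) - 1)
                    if cluster_ids[host] is None:
                        cluster_ids[host] = next_cluster
                        next_cluster += 1
                    cluster_ids.append(cluster_ids[host])
                    placed = True
                    break
        if not placed:
            # crowded frames: after exhausting retries, shrink the disk a
            # little (at most 3 times, never below the minimum radius)
            for _ in range(4):
                for _ in range(400):
                    r0 = rng.uniform(rad + 1, height - rad - 2)
                    c0 = rng.uniform(rad + 1, width - rad - 2)
                    if _clear_of_others(r0, c0, rad, skip=None):
                        radii[i] = rad
                        centers.append((r0, c0))
                        _register(len(centers) - 1)
                        cluster_ids.append(None)
                        placed = True
                        break
                if placed or rad <= _RADIUS_MIN:
                    break
                rad = max(rad * 0.8, _RADIUS_MIN)
        if not placed:
            raise PlacementError(
                f"could not place granule {i + 1}/{n_granules} in a {height}x{width} frame"
            )

    granules = tuple(
        GranuleSpec(center=centers[i], radius=float(radii[i]),
                    true_viscosity=float(viscosities[i]), cluster_id=cluster_ids[i])
        for i in range(n_granules)
    )
    phantom = ScenePhantom(
        height=height,
        width=width,
        granules=granules,
        background_viscosity=background_viscosity,
        background_intensity_fraction=background_intensity_fraction,
        preset_name=preset_name,
    )

    curve = calibration if calibration is not None else default_calibration()
    visc_map = np.full((height, width), background_viscosity, dtype=float)
    label_map = np.zeros((height, width), dtype=np.int32)
    yy, xx = np.mgrid[0:height, 0:width]
    for gid, g in enumerate(granules, start=1):
        inside = (yy - g.center[0]) ** 2 + (xx - g.center[1]) ** 2 <= g.radius**2
        visc_map[inside] = g.true_viscosity
        label_map[inside] = gid
    if preset_name == "nonrotor_control":
        lifetime_map = np.full((height, width), NONROTOR_LIFETIME_NS, dtype=float)
    else:
        lifetime_map = curve.lifetime(visc_map)
    truth = GroundTruth(
        viscosity_map=visc_map,
        lifetime_map=lifetime_map,
        granule_label_map=label_map,
        granules=granules,
    )
    return phantom, truth


def render_tcspc(
    phantom: ScenePhantom,
    truth: GroundTruth,
    optics: OpticalConfig = OpticalConfig(),
    photons_per_granule_pixel: float = 500.0,
    calibration: Optional[CalibrationCurve] = None,
    seed: int = 0,
) -> TCSPCImage:
    """Render a phantom into a Poisson photon-count stack.

    Every granule pixel's expected decay is a single exponential at the
    pixel's ground-truth lifetime convolved with the Gaussian IRF, binned into
    the acquisition window and normalised so the expected total counts per
    granule pixel equal ``photons_per_granule_pixel``.  Background pixels get
    ``background_intensity_fraction`` of that budget at the background
    lifetime.  Counts are independent Poisson draws per bin; identical seeds
    give bit-identical stacks.
    """
    if photons_per_granule_pixel < 0:
        raise ValueError("photon budget must be nonnegative")
    if np.any(truth.lifetime_map <= 0):
        raise ValueError("ground-truth lifetimes must be positive")
    rng = np.random.default_rng(seed)
    edges = optics.bin_edges
    h, w = truth.lifetime_map.shape
    expected = np.zeros((optics.n_time_bins, h, w), dtype=float)

    budget_map = np.where(
        truth.granule_label_map > 0,
        photons_per_granule_pixel,
        photons_per_granule_pixel * phantom.background_intensity_fraction,
    )
    # granules are internally homogeneous, so only a handful of distinct
    # lifetimes occur per image; render one decay profile per unique value
    for tau in np.unique(truth.lifetime_map):
        frac = bin_fractions(edges, float(tau), optics.irf_center, optics.irf_fwhm)
        total = frac.sum()
        if total <= 0:
            raise ValueError(f"lifetime {tau} ns leaves no photons in the window")
        prob = frac / total
        sel = truth.lifetime_map == tau
        expected[:, sel] = prob[:, None] * budget_map[sel][None, :]

    counts = rng.poisson(expected).astype(np.int32)
    return TCSPCImage(counts=counts, optics=optics, seed=int(seed))


def default_dataset(
    group: str,
    n_images: int = 12,
    seed: int = 0,
    frame: Tuple[int, int] = (128, 128),
    n_granules_per_image: int = 50,
    photons_per_granule_pixel: float = 500.0,
    optics: OpticalConfig = OpticalConfig(),
    calibration: Optional[CalibrationCurve] = None,
) -> List[Tuple[TCSPCImage, GroundTruth]]:
    """Simulate ``n_images`` independent acquisitions of one study group.

    Defaults mirror one analysed image set: 12 images per group, each a
    128x128 frame holding 60 granules at 500 photons per granule pixel.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=(n_images, 2))
    out = []
    for i in range(n_images):
        phantom, truth = make_phantom(
            group,
            n_granules=n_granules_per_image,
            frame=frame,
            seed=int(sub_seeds[i, 0]),
            calibration=calibration,
        )
        img = render_tcspc(
            phantom,
            truth,
            optics=optics,
            photons_per_granule_pixel=photons_per_granule_pixel,
            calibration=calibration,
            seed=int(sub_seeds[i, 1]),
        )
        out.append((img, truth))
    return out
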