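"""Synthetic ground-truth generators for every analysis stage.

Because the microscopy behind the quantifications is not publicly
deposited, validation here is parameter recovery on simulated data: each
generator returns its inputs as an explicit :class:`GroundTruth` record, and
the downstream metrics are judged by how well they recover those values.

Generators and what they emulate
--------------------------------
``simulate_cell_image``
    A cytosolic cell (disk or polygon plateau over a darker background)
    containing diffraction-limited puncta, modelled as isotropic Gaussian
    spots, under an optional two-stage camera noise model (Poisson shot
    noise on expected counts, then additive Gaussian read noise).
``simulate_coloc_pair``
    Two channels sharing a controllable fraction of puncta positions, for
    Pearson colocalization.
``simulate_recruitment_series``
    Per-cell bait/prey TIRF intensity time courses around a dimerizer
    addition: baseline * (1 + (fold-1) * ramp), where the ramp rises
    linearly after the event and saturates exactly at ``rise_time`` — so a
    noise-free series recovers its fold change exactly.
``simulate_tracks``
    A persistent (correlated) random walk at fixed speed: the heading turns
    by wrapped-Gaussian increments with variance 2*dt/persistence_time, and
    an optional chemotactic bias mixes a fixed axis direction into each
    step without changing the step length.
``simulate_growth``
    Exponential cell growth, n0 * 2^(t / doubling_time).

All generators are pure functions of (params, seed): the same call is
bit-identical. Per-cell random sub-streams are spawned deterministically
from the single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .errors import InvalidParamsError
from .image_metrics import RecruitmentSeries
from .images import FluorescenceImage, RoiMask, polygon_mask


@dataclass
class GroundTruth:
    """Record of the generating parameters of one simulated dataset."""

    kind: str
    n_puncta: int | None = None
    puncta_centers: list | None = None
    coloc_fraction: float | None = None
    bait_fold: float | None = None
    prey_fold: float | None = None
    speed_um_min: float | None = None
    persistence_min: float | None = None
    bias: float | None = None
    axis: tuple[float, float] | None = None
    doubling_time_h: float | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


@dataclass
class ImageSimParams:
    """Parameters of one simulated cell image.

    The cytosol region is either a disk (``center`` in (x, y) pixel
    coordinates plus ``radius``) or a polygon (vertex list); intensities are
    in arbitrary units. Inside the region the expected intensity is
    ``background + cytosol_level``; outside it is ``background``. Each
    punctum adds an isotropic Gaussian of peak ``puncta_amplitude`` and
    width ``puncta_sigma`` (pixels), centred uniformly inside the region.
    """

    shape: tuple[int, int] = (256, 256)
    center: tuple[float, float] | None = None
    radius: float | None = 100.0
    polygon: Sequence[tuple[float, float]] | None = None
    background: float = 10.0
    cytosol_level: float = 100.0
    n_puncta: int = 30
    puncta_amplitude: float = 300.0
    puncta_sigma: float = 1.5
    shot_noise: bool = True
    read_noise_sigma: float = 2.0
    roi_margin: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0 or self.cytosol_level < 0 or self.puncta_amplitude < 0:
            raise InvalidParamsError("levels and amplitudes must be >= 0")
        if self.n_puncta < 0:
            raise InvalidParamsError("n_puncta must be >= 0")
        if self.puncta_sigma <= 0:
            raise InvalidParamsError("puncta_sigma must be positive")
        if self.read_noise_sigma < 0:
            raise InvalidParamsError("read_noise_sigma must be >= 0")
        if self.polygon is None:
            if self.radius is None or self.radius <= 0:
                raise InvalidParamsError("disk region needs a positive radius")
            if self.center is None:
                self.center = (self.shape[1] / 2, self.shape[0] / 2)
            if self.puncta_sigma >= self.radius:
                raise InvalidParamsError("puncta radius must be smaller than the region")

    def region_mask(self) -> RoiMask:
        """The full cytosol region (the plateau painted into the image)."""
        if self.polygon is not None:
            return polygon_mask(self.polygon, self.shape, role="cytosol")
        yy, xx = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        cx, cy = self.center
        return RoiMask((xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius**2, role="cytosol")

    def roi_mask(self) -> RoiMask:
        """Interior cytosolic ROI, eroded by ``roi_margin`` pixels.

        Emulates a hand-drawn ROI that stays clear of the cell edge, where
        intensity fluctuation from the plasma membrane would otherwise leak
        into the puncta index.
        """
        if self.roi_margin <= 0:
            return self.region_mask()
        if self.polygon is not None:
            import scipy.ndimage as _ndi

            eroded = _ndi.binary_erosion(
                self.region_mask().data, iterations=int(self.roi_margin)
            )
            return RoiMask(eroded, role="cytosol")
        yy, xx = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        cx, cy = self.center
        r = max(self.radius - self.roi_margin, 1.0)
        return RoiMask((xx - cx) ** 2 + (yy - cy) ** 2 <= r**2, role="cytosol")


def _draw_centers(params: ImageSimParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform puncta centres inside the cytosol region, as (x, y) pairs."""
    if n == 0:
        return np.empty((0, 2))
    if params.polygon is None:
        # polar sampling with sqrt radius => uniform over the disk; keep the
        # full Gaussian kernel inside by shrinking the admissible radius
        r_max = max(params.radius - params.puncta_sigma, params.radius * 0.5)
        r = r_max * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        cx, cy = params.center
        return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
    mask = params.region_mask().data
    inside = np.argwhere(mask)
    if len(inside) == 0:
        raise InvalidParamsError("polygon region rasterizes to an empty mask")
    idx = rng.integers(0, len(inside), size=n)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    return inside[idx][:, ::-1] + jitter  # (row, col) -> (x, y)


def _add_gaussians(expected: np.ndarray, centers: np.ndarray, amp: float, sigma: float) -> None:
    """Accumulate isotropic Gaussian spots in place (evaluated on 6-sigma tiles)."""
    h, w = expected.shape
    half = max(int(np.ceil(6 * sigma)), 2)
    for cx, cy in centers:
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        expected[y0:y1, x0:x1] += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
        )


def _apply_noise(expected: np.ndarray, params: ImageSimParams, rng: np.random.Generator) -> np.ndarray:
    img = expected
    if params.shot_noise:
        img = rng.poisson(expected).astype(float)
    if params.read_noise_sigma > 0:
        img = img + rng.normal(0.0, params.read_noise_sigma, size=expected.shape)
    return np.clip(img, 0.0, None)


def simulate_cell_image(params: ImageSimParams) -> tuple[FluorescenceImage, RoiMask, GroundTruth]:
    """Simulate one cell image with puncta; returns image, cytosol mask, truth."""
    rng = np.random.default_rng(params.seed)
    region = params.region_mask()
    expected = np.full(params.shape, float(params.background))
    expected[region.data] += params.cytosol_level
    centers = _draw_centers(params, params.n_puncta, rng)
    _add_gaussians(expected, centers, params.puncta_amplitude, params.puncta_sigma)
    image = FluorescenceImage(_apply_noise(expected, params, rng), channel="sim")
    mask = params.roi_mask()
    truth = GroundTruth(
        kind="cell_image",
        n_puncta=params.n_puncta,
        puncta_centers=[list(map(float, c)) for c in centers],
        seed=params.seed,
        params={"amplitude": params.puncta_amplitude, "sigma": params.puncta_sigma},
    )
    return image, mask, truth


def simulate_coloc_pair(
    colocalized_fraction: float, params: ImageSimParams
) -> tuple[FluorescenceImage, FluorescenceImage, RoiMask, GroundTruth]:
    """Two-channel image pair sharing a stated fraction of puncta positions.

    Channel 2 reuses ``round(fraction * n)`` of channel 1's puncta centres
    and draws the remainder independently; noise is independent per channel.
    """
    if not (0.0 <= colocalized_fraction <= 1.0):
        raise InvalidParamsError("colocalized_fraction must be in [0, 1]")
    ss = np.random.SeedSequence(params.seed)
    rng_pos, rng_noise1, rng_noise2 = (np.random.default_rng(s) for s in ss.spawn(3))
    region = params.region_mask()
    n = params.n_puncta
    n_shared = int(round(colocalized_fraction * n))
    c1 = _draw_centers(params, n, rng_pos)
    extra = _draw_centers(params, n - n_shared, rng_pos)
    c2 = np.vstack([c1[:n_shared], extra]) if n else c1

    images = []
    for centers, rng_noise in ((c1, rng_noise1), (c2, rng_noise2)):
        expected = np.full(params.shape, float(params.background))
        expected[region.data] += params.cytosol_level
        _add_gaussians(expected, centers, params.puncta_amplitude, params.puncta_sigma)
        images.append(FluorescenceImage(_apply_noise(expected, params, rng_noise)))
    truth = GroundTruth(
        kind="coloc_pair",
        n_puncta=n,
        coloc_fraction=float(colocalized_fraction),
        seed=params.seed,
    )
    return images[0], images[1], params.roi_mask(), truth


def simulate_recruitment_series(
    bait_fold: float,
    prey_fold: float,
    rise_time: float = 5.0,
    frames_pre: int = 5,
    frames_post: int = 20,
    noise_sigma: float = 0.0,
    n_cells: int = 1,
    seed: int = 0,
    interval_min: float = 1.0,
    baseline_level: float = 100.0,
) -> tuple[list[RecruitmentSeries], GroundTruth]:
    """Per-cell bait/prey courses around a dimerization event.

    Each channel follows ``baseline * (1 + (fold - 1) * S(t))`` plus
    Gaussian noise, where S(t) = 0 before the event and rises linearly to
    exactly 1 over ``rise_time`` minutes after it. The event frame index is
    ``frames_pre`` (the first frame at/after dimerizer addition).
    """
    if bait_fold <= 0 or prey_fold <= 0:
        raise InvalidParamsError("fold changes must be positive")
    if frames_pre < 1 or frames_post < 1:
        raise InvalidParamsError("need >= 1 frame before and after the event")
    if rise_time <= 0 or interval_min <= 0 or baseline_level <= 0:
        raise InvalidParamsError("rise_time, interval and baseline must be positive")
    if noise_sigma < 0 or n_cells < 1:
        raise InvalidParamsError("noise_sigma >= 0 and n_cells >= 1 required")

    n = frames_pre + frames_post
    t = np.arange(n) * interval_min
    ramp = np.clip((t - t[frames_pre]) / rise_time, 0.0, 1.0)
    ss = np.random.SeedSequence(seed)
    cells = []
    for i, child in enumerate(ss.spawn(n_cells)):
        rng = np.random.default_rng(child)
        bait = baseline_level * (1 + (bait_fold - 1) * ramp)
        prey = baseline_level * (1 + (prey_fold - 1) * ramp)
        if noise_sigma > 0:
            bait = np.clip(bait + rng.normal(0, noise_sigma, n), 0, None)
            prey = np.clip(prey + rng.normal(0, noise_sigma, n), 0, None)
        cells.append(
            RecruitmentSeries(t, bait, prey, event_frame=frames_pre, cell_id=f"cell{i:03d}")
        )
    truth = GroundTruth(kind="recruitment", bait_fold=bait_fold, prey_fold=prey_fold, seed=seed)
    return cells, truth


@dataclass
class TrackSimParams:
    """Parameters of a persistent biased random-walk track ensemble.

    ``persistence_min`` is the directional persistence time: heading
    increments are wrapped-Gaussian with variance 2*interval/persistence
    (``inf`` gives perfectly straight tracks). ``bias`` in [0, 1] mixes the
    unit ``axis`` vector into each step direction (convex combination,
    renormalized) without changing the step length, so bias moves the
    forward migration index but not the speed.
    """

    n_cells: int = 100
    speed_um_min: float = 0.5
    persistence_min: float = 30.0
    bias: float = 0.0
    axis: tuple[float, float] = (0.0, 1.0)
    interval_min: float = 10.0
    duration_min: float = 960.0
    noise_sigma_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParamsError("n_cells must be >= 1")
        if self.speed_um_min < 0 or self.noise_sigma_um < 0:
            raise InvalidParamsError("speed and noise must be >= 0")
        if self.persistence_min <= 0:
            raise InvalidParamsError("persistence_min must be positive (inf allowed)")
        if not (0.0 <= self.bias <= 1.0):
            raise InvalidParamsError("bias must be in [0, 1]")
        if self.interval_min <= 0:
            raise InvalidParamsError("interval must be positive")
        if self.duration_min < self.interval_min:
            raise InvalidParamsError("duration must be >= one interval")
        norm = math.hypot(*self.axis)
        if norm == 0:
            raise InvalidParamsError("axis must be non-zero")
        self.axis = (self.axis[0] / norm, self.axis[1] / norm)

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_min / self.interval_min)) + 1


def _simulate_one_track(params: TrackSimParams, rng: np.random.Generator) -> np.ndarray:
    n_steps = params.n_frames - 1
    if math.isinf(params.persistence_min):
        sigma_theta = 0.0
    else:
        sigma_theta = math.sqrt(2.0 * params.interval_min / params.persistence_min)
    turns = rng.normal(0.0, sigma_theta, n_steps - 1) if sigma_theta > 0 else np.zeros(n_steps - 1)
    theta = rng.uniform(0, 2 * np.pi) + np.concatenate([[0.0], np.cumsum(turns)])
    u = np.column_stack([np.cos(theta), np.sin(theta)])
    b = params.bias
    if b > 0:
        mix = (1 - b) * u + b * np.asarray(params.axis)
        norms = np.linalg.norm(mix, axis=1)
        ok = norms > 1e-12
        u = np.where(ok[:, None], mix / np.where(ok, norms, 1.0)[:, None], u)
    steps = params.speed_um_min * params.interval_min * u
    pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if params.noise_sigma_um > 0:
        pos = pos + rng.normal(0.0, params.noise_sigma_um, size=pos.shape)
    return pos


def simulate_tracks(params: TrackSimParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an ensemble of tracks as a TrackMate-style table.

    Returns a DataFrame with columns TRACK_ID, FRAME, POSITION_X, POSITION_Y
    (µm) and POSITION_T (min), one row per cell per frame.
    """
    ss = np.random.SeedSequence(params.seed)
    frames = np.arange(params.n_frames)
    rows = []
    for cell, child in enumerate(ss.spawn(params.n_cells)):
        pos = _simulate_one_track(params, np.random.default_rng(child))
        rows.append(
            pd.DataFrame(
                {
                    "TRACK_ID": cell,
                    "FRAME": frames,
                    "POSITION_X": pos[:, 0],
                    "POSITION_Y": pos[:, 1],
                    "POSITION_T": frames * params.interval_min,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(
        kind="tracks",
        speed_um_min=params.speed_um_min,
        persistence_min=params.persistence_min,
        bias=params.bias,
        axis=params.axis,
        seed=params.seed,
    )
    return table, truth


def expected_step_projection(bias: float) -> float:
    """Expected projection of a unit step on the bias axis, heading uniform.

    With the convex-combination bias model and a uniformly distributed
    heading angle theta, the mean projection of the renormalized step
    direction on the axis is the quadrature

        p(b) = (1/2pi) \\int [ (1-b) cos(theta) + b ]
                       / sqrt((1-b)^2 + b^2 + 2 b (1-b) cos(theta)) dtheta.

    For noise-free, fixed-speed walks whose heading has relaxed to its
    uniform stationary distribution this is also the expected forward
    migration index, since the path length is deterministic.
    """
    if not (0.0 <= bias <= 1.0):
        raise InvalidParamsError("bias must be in [0, 1]")
    if bias == 0.0:
        return 0.0
    if bias == 1.0:
        return 1.0
    b = bias

    def integrand(th: float) -> float:
        num = (1 - b) * math.cos(th) + b
        den = math.sqrt((1 - b) ** 2 + b**2 + 2 * b * (1 - b) * math.cos(th))
        if den < 1e-12:  # removable singularity at b = 0.5, th = pi
            return 0.0
        return num / den

    val, _ = quad(integrand, 0.0, 2.0 * math.pi, limit=200)
    return val / (2.0 * math.pi)


def simulate_growth(n0: float, doubling_time: float, elapsed: float) -> float:
    """Exponential growth: n0 * 2^(elapsed / doubling_time)."""
    if n0 <= 0 or doubling_time <= 0:
        raise InvalidParamsError("n0 and doubling_time must be positive")
    if elapsed < 0:
        raise InvalidParamsError("elapsed time must be >= 0")
    return n0 * 2.0 ** (elapsed / doubling_time)
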