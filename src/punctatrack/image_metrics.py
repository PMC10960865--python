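"""Per-image and per-time-series scalar measurements.

The central quantity is the *puncta index*, a texture statistic scoring the
abundance of diffraction-limited vesicles in a cytosolic region: the raw
image is divided, pixel by pixel, by its median-filtered version, and the
dispersion of that ratio image over the cytosolic ROI is reported. A flat
cytosol gives a ratio image of exactly 1 everywhere (index 0); bright puncta
survive the division as localized excursions above 1 and inflate the index.
Two variants are supported: the sample standard deviation of the ratio values
(``sd``, 5x5 window default, spinning-disk data) and the moment skewness of
their histogram (``skewness``, 10x10 window default, laser-scanning data).

The module also implements Pearson colocalization over an ROI, the
co-recruitment index (CI) of a chemically-inducible dimerization TIRF assay
with its 30% bait gate, a cytosolic-depletion translocation index, focal-
adhesion enrichment, t=0 normalization of time courses, and background-
subtracted cytosolic uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy import stats as sps

from .errors import (
    DegenerateBaselineError,
    DegenerateInputError,
    InsufficientRoiError,
    InvalidParamsError,
    UndefinedCorrelationError,
)
from .images import FluorescenceImage, RoiMask

#: filtered pixels below this fraction of the image maximum are clamped
#: before division, so dark pixels cannot produce infinities in the ratio
DIVISION_FLOOR_FRACTION = 1e-6

#: bait fold-change gate of the co-recruitment assay: cells whose bait
#: signal rose by less than 30% after the dimerizer are excluded
DEFAULT_BAIT_GATE = 1.30

DEFAULT_WINDOW = {"sd": 5, "skewness": 10}


def _median_filter(data: np.ndarray, window: int) -> np.ndarray:
    """Square median filter with reflect padding.

    For even windows the anchor is the upper-left pixel of the central
    2x2 block, i.e. the window spans offsets ``-(w//2 - 1) .. w//2`` around
    the output pixel. scipy's default even-window anchor is the lower-right
    pixel of that block, hence the origin shift.
    """
    origin = -1 if window % 2 == 0 else 0
    return ndi.median_filter(data, size=window, mode="reflect", origin=origin)


def median_ratio_image(image: FluorescenceImage, window: int = 5) -> FluorescenceImage:
    """Divide the raw image by its median-filtered version, elementwise.

    The result is scale invariant: multiplying the input by any c > 0 leaves
    the ratio image unchanged, because the median filter is scale
    equivariant and c cancels in the division.
    """
    if window < 3:
        raise InvalidParamsError(f"window must be >= 3, got {window}")
    data = image.data
    if min(data.shape) <= window:
        raise InvalidParamsError(
            f"image shape {data.shape} too small for a {window}x{window} median filter"
        )
    peak = float(data.max())
    if peak <= 0:
        raise DegenerateInputError("all-zero image: median ratio undefined")
    filtered = _median_filter(data, window)
    floor = DIVISION_FLOOR_FRACTION * peak
    ratio = data / np.maximum(filtered, floor)
    return FluorescenceImage(ratio, image.pixel_size_um, image.channel)


@dataclass
class PunctaIndexResult:
    """Puncta (endocytosis) index of one cell.

    ``value`` is dimensionless: >= 0 for the ``sd`` variant, unbounded for
    the ``skewness`` variant. ``n_pixels`` is the number of ROI pixels the
    statistic was computed over.
    """

    value: float
    variant: str
    window: int
    n_pixels: int

    def __post_init__(self) -> None:
        if self.variant == "sd" and self.value < 0:
            raise InvalidParamsError("sd-variant index cannot be negative")


def puncta_index(
    image: FluorescenceImage,
    cytosol: RoiMask,
    window: int | None = None,
    variant: str = "sd",
) -> PunctaIndexResult:
    """Puncta index over a cytosolic ROI.

    ``sd``: sample standard deviation (n-1 denominator) of the median-ratio
    values over the masked pixels. ``skewness``: biased moment skewness
    g1 = m3 / m2^1.5 of the same values.
    """
    if variant not in DEFAULT_WINDOW:
        raise InvalidParamsError(f"variant must be 'sd' or 'skewness', got {variant!r}")
    if window is None:
        window = DEFAULT_WINDOW[variant]
    cytosol.check_congruent(image)
    n = cytosol.n_pixels
    if n <= window * window:
        raise InsufficientRoiError(
            f"ROI has {n} pixels, need more than the {window}x{window} filter area"
        )
    ratio = median_ratio_image(image, window).data[cytosol.data]
    if variant == "sd":
        value = float(np.std(ratio, ddof=1))
    else:
        value = float(sps.skew(ratio, bias=True))
    return PunctaIndexResult(value=value, variant=variant, window=window, n_pixels=n)


def pearson_colocalization(
    ch1: FluorescenceImage, ch2: FluorescenceImage, mask: RoiMask
) -> float:
    """Pearson product-moment correlation of two channels over an ROI."""
    mask.check_congruent(ch1)
    mask.check_congruent(ch2)
    if mask.n_pixels < 2:
        raise InsufficientRoiError("need at least 2 masked pixels for a correlation")
    a = ch1.data[mask.data]
    b = ch2.data[mask.data]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in a channel over the mask")
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class RecruitmentSeries:
    """Per-cell bait/prey intensity time course around a dimerization event.

    ``event_frame`` is the index of the first frame at/after dimerizer
    addition; frames strictly before it form the baseline. ``background``
    holds one scalar per channel (bait, prey), subtracted before fold
    changes are formed; subtracted intensities clip at 0.
    """

    time_min: np.ndarray
    bait: np.ndarray
    prey: np.ndarray
    event_frame: int
    background: tuple[float, float] = (0.0, 0.0)
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.bait = np.asarray(self.bait, dtype=float)
        self.prey = np.asarray(self.prey, dtype=float)
        n = len(self.time_min)
        if len(self.bait) != n or len(self.prey) != n:
            raise InvalidParamsError("time, bait and prey must have equal length")
        if not (1 <= self.event_frame <= n - 1):
            raise InvalidParamsError(
                "need at least one frame before and one at/after the event"
            )

    @property
    def n_frames(self) -> int:
        return len(self.time_min)


@dataclass
class CoRecruitmentResult:
    """Fold changes of one cell in the co-recruitment assay.

    ``ci`` (co-recruitment index) is the prey fold change; it is reported
    for every cell, with ``included`` flagging whether the bait fold change
    passed the gate.
    """

    bait_fold: float
    ci: float
    included: bool
    gate: float = DEFAULT_BAIT_GATE

    def __post_init__(self) -> None:
        if self.bait_fold <= 0 or self.ci <= 0:
            raise InvalidParamsError("fold changes must be positive")


def _window_fold(values: np.ndarray, baseline_idx: np.ndarray, response_idx: np.ndarray,
                 background: float, channel: str) -> float:
    v = np.clip(values - background, 0.0, None)
    base = float(np.mean(v[baseline_idx]))
    if base <= 0:
        raise DegenerateBaselineError(
            f"{channel} baseline mean is {base:g} after background subtraction"
        )
    return float(np.mean(v[response_idx])) / base


def co_recruitment_index(
    series: RecruitmentSeries,
    gate: float = DEFAULT_BAIT_GATE,
    baseline_frames: int | None = None,
    response_frames: int = 3,
) -> CoRecruitmentResult:
    """Co-recruitment index with the bait inclusion gate.

    Fold change per channel = mean over the response window divided by mean
    over the baseline window. The baseline window is all frames strictly
    before the event (or the last ``baseline_frames`` of those); the
    response window is the last ``response_frames`` frames of the series.
    A cell is included iff its bait fold change >= ``gate`` (default 1.30,
    the "at least 30% increase" rule). The prey fold change is the CI and
    is reported regardless, with the flag.
    """
    n = series.n_frames
    base = np.arange(series.event_frame)
    if baseline_frames is not None:
        if baseline_frames < 1:
            raise InvalidParamsError("baseline_frames must be >= 1")
        base = base[-baseline_frames:]
    if not (1 <= response_frames <= n):
        raise InvalidParamsError("response_frames must be in [1, n_frames]")
    resp = np.arange(n - response_frames, n)
    bait_fold = _window_fold(series.bait, base, resp, series.background[0], "bait")
    prey_fold = _window_fold(series.prey, base, resp, series.background[1], "prey")
    return CoRecruitmentResult(
        bait_fold=bait_fold, ci=prey_fold, included=bool(bait_fold >= gate), gate=gate
    )


def translocation_index(cytosolic_means, event_frame: int) -> float:
    """Cytosolic-depletion translocation index in [0, 1].

    1 - mean(post-event)/mean(pre-event): 0 means no translocation, 1 means
    complete cytosolic depletion. Negative raw values (post brighter than
    pre) are clipped to 0 with a warning.
    """
    v = np.asarray(cytosolic_means, dtype=float)
    if not (1 <= event_frame <= len(v) - 1):
        raise InvalidParamsError("event_frame must leave >= 1 frame on each side")
    pre = float(np.mean(v[:event_frame]))
    if pre <= 0:
        raise DegenerateBaselineError(f"pre-event cytosolic mean is {pre:g}")
    raw = 1.0 - float(np.mean(v[event_frame:])) / pre
    if raw < 0:
        warnings.warn(
            f"negative depletion ({raw:.3g}) clipped to 0: cytosol brightened after event",
            stacklevel=2,
        )
    return float(np.clip(raw, 0.0, 1.0))


def fa_enrichment(
    image: FluorescenceImage,
    fa: RoiMask,
    cytosol: RoiMask,
    background: float = 0.0,
) -> float:
    """Focal-adhesion enrichment: mean FA intensity / mean cytosolic intensity.

    A shared scalar background may be subtracted from both regions first.
    The two masks must be non-empty and disjoint.
    """
    fa.check_congruent(image)
    cytosol.check_congruent(image)
    if fa.n_pixels == 0 or cytosol.n_pixels == 0:
        raise InsufficientRoiError("both masks must be non-empty")
    if np.any(fa.data & cytosol.data):
        raise InvalidParamsError("focal-adhesion and cytosol masks overlap")
    cyt = float(np.mean(image.data[cytosol.data])) - background
    if cyt <= 0:
        raise DegenerateBaselineError(f"cytosolic mean is {cyt:g} after subtraction")
    fa_mean = float(np.mean(image.data[fa.data])) - background
    return fa_mean / cyt


def timecourse_normalize(values, t0_index: int = 0) -> np.ndarray:
    """Divide a time course by its value at t=0 (index ``t0_index``)."""
    v = np.asarray(values, dtype=float)
    if not (0 <= t0_index < len(v)):
        raise InvalidParamsError("t0_index out of range")
    ref = v[t0_index]
    if ref <= 0:
        raise DegenerateBaselineError(f"value at t=0 is {ref:g}")
    return v / ref


def cytosolic_uptake(
    image: FluorescenceImage, cell: RoiMask, background: float = 0.0
) -> float:
    """Background-subtracted mean intensity over a cell mask, floored at 0."""
    cell.check_congruent(image)
    if cell.n_pixels == 0:
        raise InsufficientRoiError("cell mask is empty")
    return max(float(np.mean(image.data[cell.data])) - background, 0.0)


def estimate_background(image: FluorescenceImage, cell: RoiMask, bins: int = 256) -> float:
    """Estimate a scalar background as the histogram mode outside the cell mask."""
    cell.check_congruent(image)
    outside = image.data[~cell.data]
    if outside.size == 0:
        raise InsufficientRoiError("cell mask covers the whole image")
    counts, edges = np.histogram(outside, bins=bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))
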