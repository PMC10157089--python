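"""Lateral-flow strip densitometry and biotin-blocking titration analysis.

A lateral-flow immunoassay strip is read out here as a grayscale image:
averaging across the strip width gives a lightness profile along the
chromatographic flow direction, test and control lines appear as peaks
over a rolling-median baseline, and a series of strips run with
increasing free-biotin doses ("microscopy titration") yields a declining
test-line signal whose plateau onset marks saturation of the surface
protein's biotin sites.

Lightness is the mean grayscale of the stored image in [0, 1]; RGB input
is converted with Rec. 601 luma weights.  This is a relative measure —
only ratios and positions along one imaging session are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "StripImage",
    "StripProfile",
    "LinePeak",
    "TitrationSeries",
    "TitrationEndpointResult",
    "read_strip_image",
    "lightness_profile",
    "detect_lines",
    "titration_endpoint",
    "titration_to_proteins",
]

_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class StripImage:
    """Grayscale strip image with physical pixel size.

    ``flow_axis`` names the array axis that runs along the chromatographic
    flow (0 = down rows, 1 = along columns).
    """

    pixels: np.ndarray
    pixel_size: float  # mm per pixel
    flow_axis: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.flow_axis not in (0, 1):
            raise ValueError("flow_axis must be 0 or 1")
        self.pixels = px


@dataclass
class StripProfile:
    """Mean lightness across the strip width at each flow position (mm)."""

    positions: np.ndarray
    lightness: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        lig = np.asarray(self.lightness, dtype=float)
        if pos.ndim != 1 or pos.size != lig.size:
            raise ValueError("positions and lightness must be 1-D and equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.positions = pos
        self.lightness = lig

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.positions, self.lightness)
        ax.set_xlabel("flow position / mm")
        ax.set_ylabel("lightness")
        return ax


@dataclass(frozen=True)
class LinePeak:
    """One detected line: position (mm), height and area above the local
    baseline, and signal-to-noise ratio."""

    position: float
    height: float
    area: float
    snr: float


@dataclass
class TitrationSeries:
    """Test-line signal versus added biotin dose (molecules per bead)."""

    doses: np.ndarray
    signals: np.ndarray
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if d.ndim != 1 or d.size != s.size:
            raise ValueError("doses and signals must be 1-D and equal length")
        if np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise ValueError("doses must be non-negative and strictly increasing")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")
        self.doses = d
        self.signals = s

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.doses, self.signals, "o-")
        ax.set_xlabel("added biotin / molecules per bead")
        ax.set_ylabel("test-line signal")
        return ax


def read_strip_image(path: str, pixel_size: float, flow_axis: int = 1) -> StripImage:
    """Load a PNG/TIFF strip image; 8/16-bit gray or RGB.

    Integer images are scaled by their dtype maximum; RGB is collapsed with
    Rec. 601 luma weights.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _REC601
    return StripImage(np.clip(arr, 0.0, 1.0), pixel_size=pixel_size, flow_axis=flow_axis)


def lightness_profile(image: StripImage) -> StripProfile:
    """Average the image across the strip width at each flow position."""
    width_axis = 1 - image.flow_axis
    profile = image.pixels.mean(axis=width_axis)
    positions = np.arange(profile.size) * image.pixel_size
    return StripProfile(positions, profile)


def detect_lines(
    profile: StripProfile,
    min_snr: float = 3.0,
    expected_line_width_mm: float = 1.0,
) -> list[LinePeak]:
    """Find test/control lines as peaks over a rolling-median baseline.

    The baseline window is 5x the expected line width, which leaves debris
    blobs and the lines themselves out of the baseline.  Peak height is the
    baseline-subtracted profile at the peak; area is the trapezoidal
    integral over the contiguous positive support around the peak; snr is
    height over a robust (MAD-based) noise estimate of the residual.
    Returns peaks with snr >= min_snr sorted by position (possibly empty).
    """
    pos, light = profile.positions, profile.lightness
    if pos.size < 5:
        raise ValueError("profile too short to detect lines (need >= 5 samples)")
    step = float(np.median(np.diff(pos)))
    win = max(3, int(round(5.0 * expected_line_width_mm / step)) | 1)  # odd
    baseline = ndimage.median_filter(light, size=win, mode="nearest")
    resid = light - baseline
    noise = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    noise = max(noise, 1e-12)

    min_dist = max(1, int(round(0.5 * expected_line_width_mm / step)))
    idx, _ = signal.find_peaks(resid, height=min_snr * noise, distance=min_dist)
    peaks: list[LinePeak] = []
    for i in idx:
        lo = i
        while lo > 0 and resid[lo - 1] > 0:
            lo -= 1
        hi = i
        while hi < resid.size - 1 and resid[hi + 1] > 0:
            hi += 1
        area = float(np.trapezoid(resid[lo : hi + 1], pos[lo : hi + 1]))
        peaks.append(
            LinePeak(
                position=float(pos[i]),
                height=float(resid[i]),
                area=area,
                snr=float(resid[i] / noise),
            )
        )
    return sorted(peaks, key=lambda p: p.position)


@dataclass(frozen=True)
class TitrationEndpointResult:
    """Fitted two-segment (declining line + constant plateau) changepoint."""

    endpoint_dose: float
    plateau_level: float
    initial_signal: float  # fitted signal at dose 0
    slope: float
    split_index: int
    sse: float


def _fit_two_segment(doses: np.ndarray, signals: np.ndarray) -> TitrationEndpointResult:
    """Least-squares decline+plateau fit over all split points.

    For each candidate split k the points up to and including k are fitted
    by a straight line and the points from k on by a constant; the split
    with the smallest total squared error wins.  The endpoint is the dose
    where the fitted line meets the plateau level.
    """
    n = doses.size
    best: TitrationEndpointResult | None = None
    for k in range(1, n - 1):
        a, b = np.polyfit(doses[: k + 1], signals[: k + 1], 1)
        level = float(np.mean(signals[k:]))
        pred_line = a * doses[:k] + b
        sse = float(np.sum((signals[:k] - pred_line) ** 2) + np.sum((signals[k:] - level) ** 2))
        if best is None or sse < best.sse - 1e-15:
            if a < 0:
                endpoint = (level - b) / a
                endpoint = float(np.clip(endpoint, doses[0], doses[-1]))
            else:
                endpoint = float(doses[k])
            best = TitrationEndpointResult(
                endpoint_dose=endpoint,
                plateau_level=level,
                initial_signal=float(b),
                slope=float(a),
                split_index=k,
                sse=sse,
            )
    assert best is not None
    return best


def titration_endpoint(series: TitrationSeries) -> TitrationEndpointResult:
    """Dose at which the test-line signal becomes permanent (plateau onset).

    Blocking the protein's biotin sites with free biotin suppresses bead
    capture at the test line; once every site is blocked, adding more
    biotin changes nothing, and that onset of signal permanence is the
    titration endpoint.  Fitted as a two-segment least-squares changepoint
    (declining segment + constant segment).

    Raises ValueError ("no signal permanence") when the tail of the series
    is still declining beyond the noise floor, i.e. no plateau was reached.
    """
    if series.doses.size < 4:
        raise ValueError("need at least 4 doses to locate an endpoint")
    res = _fit_two_segment(series.doses, series.signals)

    scale = float(np.max(np.abs(series.signals))) or 1.0
    tol = max(3.0 * series.noise_floor, 1e-9 * scale)
    tail = series.signals[res.split_index :]
    if tail.size < 2 or np.max(np.abs(tail - res.plateau_level)) > tol:
        raise ValueError("no signal permanence: series does not reach a plateau")
    return res


def titration_to_proteins(series: TitrationSeries, sites_per_protein: int = 4) -> float:
    """Surface proteins per bead: titration endpoint divided by the number
    of biotin-binding sites per protein (4 for (Neutr)avidin)."""
    if sites_per_protein < 1:
        raise ValueError("sites_per_protein must be >= 1")
    return titration_endpoint(series).endpoint_dose / sites_per_protein
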