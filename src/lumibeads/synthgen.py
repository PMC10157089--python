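"""Seeded synthetic-data generators with analytic ground truth.

Every input the analysis chain consumes can be generated here: Eu3+
5D0->7F_J line spectra (Gaussian bands near 579/593/614/654/701 nm),
mono-exponential decay traces, inner-filter-attenuated dilution series,
lateral-flow strip images with test/control lines and debris, and
biotin-blocking titration series.  Each generator is a pure function of
its seed and returns the analytic truth alongside the sample, so every
downstream module is testable without laboratory data.

Default band areas give a total-to-magnetic-dipole ratio of 27.46, the
ratio at which the radiative-lifetime relation returns 655 us in a KBr
host (n = 1.5598) — i.e. the defaults emulate a thenyl-diketonate-like
emitter with a dominant hypersensitive 7F2 band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import DecayTrace
from .lfia import StripImage, TitrationSeries
from .spectra import BandTable, Spectrum

__all__ = [
    "DEFAULT_BAND_CENTERS",
    "DEFAULT_BAND_AREAS",
    "SpectrumSpec",
    "InnerFilterSpec",
    "DilutionSeries",
    "gen_emission_spectrum",
    "gen_decay_trace",
    "gen_dilution_series",
    "gen_strip_image",
    "gen_titration_series",
]

#: Peak positions (nm) of the 5D0->7F_J lines, J = 0..4.
DEFAULT_BAND_CENTERS = {"F0": 579.0, "F1": 593.0, "F2": 614.0, "F3": 654.0, "F4": 701.0}

#: Relative band areas (F1 = 1) of a strongly hypersensitive emitter;
#: they sum to 27.46 so the default spectrum carries I_tot/I_MD = 27.46.
DEFAULT_BAND_AREAS = {"F0": 0.2, "F1": 1.0, "F2": 24.0, "F3": 0.5, "F4": 1.76}


@dataclass
class SpectrumSpec:
    """Recipe for a synthetic Eu3+ emission spectrum.

    Bands are Gaussians with the requested integrated areas; optional
    additive Gaussian noise is expressed as a fraction of the peak
    intensity.  ``stark_shoulder`` splits the 7F2 band into a main
    component and a smaller Stark component at 617.5 nm, as seen for
    thenyl-substituted complexes.
    """

    band_centers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_CENTERS))
    band_areas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BAND_AREAS))
    band_sigma_nm: float = 2.0
    grid: tuple[float, float, float] = (570.0, 720.0, 0.2)  # start, stop, step
    noise_sd: float = 0.0  # fraction of peak intensity
    stark_shoulder: bool = False
    stark_fraction: float = 0.3  # share of the F2 area moved to 617.5 nm
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.band_areas.values()):
            raise ValueError("band areas must be non-negative")
        if self.band_areas.get("F1", 0.0) <= 0:
            raise ValueError("the magnetic-dipole band F1 must have positive area")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be positive")
        if self.band_sigma_nm <= 0:
            raise ValueError("band_sigma_nm must be positive")


def _gauss(x: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gen_emission_spectrum(spec: SpectrumSpec) -> tuple[Spectrum, BandTable]:
    """Generate a line spectrum and return it with its analytic band table.

    The truth table carries the *requested* (full-Gaussian) areas; on the
    default 0.2 nm grid with sigma = 2 nm the trapezoidal band areas agree
    with these to better than 1e-4 relative.
    """
    start, stop, step = spec.grid
    wl = np.arange(start, stop + 0.5 * step, step)
    sigma = spec.band_sigma_nm
    for name, c in spec.band_centers.items():
        if spec.band_areas.get(name, 0.0) > 0 and not (
            wl[0] <= c - 4 * sigma and c + 4 * sigma <= wl[-1]
        ):
            raise ValueError(f"grid {spec.grid} does not cover band {name} at {c} nm +/- 4 sigma")

    inten = np.zeros_like(wl)
    for name, area in spec.band_areas.items():
        if area <= 0:
            continue
        center = spec.band_centers[name]
        if name == "F2" and spec.stark_shoulder:
            inten += _gauss(wl, center, sigma, area * (1.0 - spec.stark_fraction))
            inten += _gauss(wl, 617.5, sigma, area * spec.stark_fraction)
        else:
            inten += _gauss(wl, center, sigma, area)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        inten = inten + rng.normal(0.0, spec.noise_sd * inten.max(), size=inten.size)
        inten = np.clip(inten, 0.0, None)

    truth = BandTable({k: float(v) for k, v in spec.band_areas.items()})
    return Spectrum(wl, inten, label=f"synthetic seed={spec.seed}"), truth


def gen_decay_trace(
    tau: float,
    amplitude: float = 1000.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    window: tuple[float, float, float] = (0.0, 3000.0, 5.0),
    seed: int = 0,
    poisson: bool = False,
) -> DecayTrace:
    """Sample A*exp(-t/tau) + b on a time window (us) with seeded noise.

    ``noise_sd`` is additive Gaussian noise as a fraction of the peak
    signal; ``poisson`` draws Poisson counts around the model instead.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t0, t1, dt = window
    t = np.arange(t0, t1 + 0.5 * dt, dt)
    y = amplitude * np.exp(-t / tau) + baseline
    rng = np.random.default_rng(seed)
    if poisson:
        y = rng.poisson(np.clip(y, 0.0, None)).astype(float)
    elif noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * y.max(), size=y.size)
    return DecayTrace(t, np.clip(y, 0.0, None), label=f"synthetic tau={tau} seed={seed}")


@dataclass
class InnerFilterSpec:
    """Recipe for an inner-filter-attenuated dilution series.

    Absorbance is linear in concentration with value
    ``absorbance_at_reference`` at the first (highest) concentration; the
    emitted intensity follows the primary inner-filter law
    I = scale * (1 - 10**(-A)).  At high absorbance a tenfold dilution
    costs much less than a factor of ten in signal; in the dilute limit
    the series becomes proportional.
    """

    absorbance_at_reference: float
    concentrations: tuple[float, ...] = (1e-3, 1e-4, 1e-5)  # weight fractions, decreasing
    emission_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.absorbance_at_reference < 0:
            raise ValueError("absorbance must be non-negative")
        c = np.asarray(self.concentrations, dtype=float)
        if np.any(c <= 0) or np.any(np.diff(c) >= 0):
            raise ValueError("concentrations must be positive and strictly decreasing")


@dataclass
class DilutionSeries:
    """Concentrations, model intensities and successive step ratios."""

    concentrations: np.ndarray
    intensities: np.ndarray

    @property
    def step_ratios(self) -> np.ndarray:
        """Intensity ratio of each concentration to the next (more dilute) one."""
        return self.intensities[:-1] / self.intensities[1:]


def gen_dilution_series(spec: InnerFilterSpec) -> DilutionSeries:
    """Evaluate the inner-filter dilution model (deterministic)."""
    c = np.asarray(spec.concentrations, dtype=float)
    absorbance = spec.absorbance_at_reference * c / c[0]
    intensities = spec.emission_scale * (1.0 - 10.0 ** (-absorbance))
    return DilutionSeries(c, intensities)


def gen_strip_image(
    line_positions_mm: tuple[float, ...] = (20.0, 30.0),
    line_heights: tuple[float, ...] = (0.3, 0.2),
    line_sigma_mm: float = 0.3,
    background: float = 0.08,
    debris_count: int = 0,
    debris_height: float = 0.25,
    noise_sd: float = 0.0,
    pixel_size: float = 0.05,  # mm per pixel
    strip_length_mm: float = 40.0,
    strip_width_mm: float = 5.0,
    seed: int = 0,
) -> tuple[StripImage, dict]:
    """Render a luminescent strip: background + line bands + debris + noise.

    Lines are Gaussian bands across the full strip width; debris are
    random bright circular blobs like the agglomerates left behind by
    poorly dispersed beads.  The truth dict records line positions and
    heights, debris coordinates, and a ``lines_overlap`` warning flag when
    two lines sit closer than 3 sigma.
    """
    n_flow = int(round(strip_length_mm / pixel_size))
    n_width = int(round(strip_width_mm / pixel_size))
    x_mm = np.arange(n_flow) * pixel_size

    profile = np.full(n_flow, background)
    for p, h in zip(line_positions_mm, line_heights):
        if not 0.0 <= p <= strip_length_mm:
            raise ValueError(f"line position {p} mm outside strip length {strip_length_mm} mm")
        profile = profile + h * np.exp(-0.5 * ((x_mm - p) / line_sigma_mm) ** 2)
    pixels = np.tile(profile, (n_width, 1))

    rng = np.random.default_rng(seed)
    debris: list[tuple[float, float, float]] = []
    for _ in range(debris_count):
        cx = rng.uniform(0, n_flow - 1)
        cy = rng.uniform(0, n_width - 1)
        r = rng.uniform(2.0, 5.0)  # pixels
        yy, xx = np.ogrid[:n_width, :n_flow]
        pixels = pixels + debris_height * ((xx - cx) ** 2 + (yy - cy) ** 2 <= r**2)
        debris.append((cx * pixel_size, cy * pixel_size, r * pixel_size))
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    sorted_pos = np.sort(np.asarray(line_positions_mm, dtype=float))
    overlap = bool(np.any(np.diff(sorted_pos) < 3.0 * line_sigma_mm)) if sorted_pos.size > 1 else False
    truth = {
        "line_positions_mm": list(map(float, line_positions_mm)),
        "line_heights": list(map(float, line_heights)),
        "line_sigma_mm": line_sigma_mm,
        "background": background,
        "debris_xy_r_mm": debris,
        "lines_overlap": overlap,
    }
    return StripImage(pixels, pixel_size=pixel_size, flow_axis=1), truth


def gen_titration_series(
    sites_per_bead: float = 1000.0,
    sites_per_protein: int = 4,
    dose_grid: np.ndarray | None = None,
    signal0: float = 0.5,
    plateau: float = 0.05,
    noise_sd: float = 0.0,  # fraction of signal0
    seed: int = 0,
) -> tuple[TitrationSeries, dict]:
    """Biotin-blocking titration: signal declines linearly to a plateau.

    The test-line signal is signal0 * max(0, 1 - dose/endpoint) + plateau
    with endpoint = sites_per_protein * sites_per_bead (all protein sites
    blocked), plus seeded Gaussian noise.  The default dose grid spans 0
    to twice the endpoint in 16 steps.
    """
    endpoint = float(sites_per_protein) * float(sites_per_bead)
    if dose_grid is None:
        dose_grid = np.linspace(0.0, 2.0 * endpoint, 17)
    doses = np.asarray(dose_grid, dtype=float)
    clean = signal0 * np.clip(1.0 - doses / endpoint, 0.0, None) + plateau
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * signal0, size=doses.size) if noise_sd > 0 else 0.0
    series = TitrationSeries(doses, clean + noise, noise_floor=noise_sd * signal0)
    truth = {
        "endpoint_dose": endpoint,
        "proteins_per_bead": float(sites_per_bead),
        "signal0": signal0,
        "plateau": plateau,
    }
    return series, truth
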