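"""Corrected emission spectra: I/O, validation and band integration.

The quantity this module ultimately feeds is the total-to-magnetic-dipole
intensity ratio I_tot/I_MD of a Eu3+ emission spectrum.  The 5D0->7F1
transition near 593 nm is magnetic-dipole allowed and its spontaneous
emission rate is essentially independent of the ligand field, so its
integrated intensity serves as an internal standard against which the
whole 5D0 emission is referenced.  Band areas are trapezoidal integrals
on the native wavelength grid; no resampling is performed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRANSITIONS",
    "DEFAULT_WINDOWS",
    "Spectrum",
    "BandWindow",
    "BandTable",
    "SpectrumError",
    "read_spectrum",
    "load_windows",
    "integrate_band",
    "band_areas",
    "absorption_from_reflectance",
]

#: 5D0 -> 7F_J transition labels, J = 0..4.
TRANSITIONS = ("F0", "F1", "F2", "F3", "F4")


class SpectrumError(ValueError):
    """Raised for malformed spectral input or invalid band requests."""


@dataclass(frozen=True)
class BandWindow:
    """Integration window [lo, hi] in nm assigned to one 5D0->7F_J transition."""

    transition: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.transition not in TRANSITIONS:
            raise SpectrumError(
                f"unknown transition {self.transition!r}; expected one of {TRANSITIONS}"
            )
        if not self.lo < self.hi:
            raise SpectrumError(f"window must have lo < hi, got [{self.lo}, {self.hi}]")


#: Default integration windows (nm).  The five emission lines sit near
#: 579 / 593 / 614 / 654 / 701 nm; the windows partition 574-720 nm around
#: those centres and are overridable via ``load_windows`` or a custom set.
DEFAULT_WINDOWS = (
    BandWindow("F0", 574.0, 585.0),
    BandWindow("F1", 585.0, 603.0),
    BandWindow("F2", 603.0, 640.0),
    BandWindow("F3", 640.0, 672.0),
    BandWindow("F4", 672.0, 720.0),
)


@dataclass
class Spectrum:
    """A corrected emission spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Wavelengths in nm, strictly increasing, length >= 2.
    intensities : array-like
        Non-negative corrected emission intensity per nm (arbitrary units).
    medium_refractive_index : float, optional
        Refractive index of the host medium, if known (e.g. 1.5598 for KBr).
    label : str
        Free-text sample label.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    medium_refractive_index: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or inten.ndim != 1 or wl.size != inten.size:
            raise SpectrumError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(inten)):
            raise SpectrumError("spectrum contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing (no duplicates)")
        neg = np.flatnonzero(inten < 0)
        if neg.size:
            raise SpectrumError(
                f"negative intensity {inten[neg[0]]:g} at row {neg[0]} "
                f"(wavelength {wl[neg[0]]:g} nm)"
            )
        if self.medium_refractive_index is not None and self.medium_refractive_index <= 0:
            raise SpectrumError("medium_refractive_index must be positive")
        self.wavelengths = wl
        self.intensities = inten

    def __len__(self) -> int:
        return self.wavelengths.size

    def plot(self, ax=None):
        """Plot intensity vs wavelength; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavelengths, self.intensities, lw=0.8)
        ax.set_xlabel("wavelength / nm")
        ax.set_ylabel("corrected intensity / a.u.")
        if self.label:
            ax.set_title(self.label)
        return ax


@dataclass
class BandTable:
    """Per-transition integrated areas and the totals entering the
    radiative-rate calculation.

    ``i_tot`` is the sum of the listed band areas, ``i_md`` the area of the
    magnetic-dipole (F1) band; ``ratio_tot_md`` is I_tot/I_MD.
    """

    areas: dict[str, float] = field(default_factory=dict)

    @property
    def i_tot(self) -> float:
        return float(sum(self.areas.values()))

    @property
    def i_md(self) -> float:
        return float(self.areas["F1"])

    @property
    def ratio_tot_md(self) -> float:
        md = self.i_md
        if md <= 0:
            raise SpectrumError("I_MD is zero; I_tot/I_MD is undefined")
        return self.i_tot / md


def read_spectrum(
    source: str | TextIO,
    *,
    medium_refractive_index: float | None = None,
    label: str = "",
) -> Spectrum:
    """Read a two-column delimited spectrum (wavelength nm, intensity).

    Accepts a file path, raw text, or an open text stream.  Comma or
    whitespace delimiters; ``#`` starts a comment.  Rows are sorted by
    wavelength before validation.
    """
    df = _read_two_columns(source, what="spectrum")
    df = df.sort_values(df.columns[0], kind="stable")
    return Spectrum(
        df.iloc[:, 0].to_numpy(),
        df.iloc[:, 1].to_numpy(),
        medium_refractive_index=medium_refractive_index,
        label=label,
    )


def _read_two_columns(source: str | TextIO, what: str) -> pd.DataFrame:
    """Shared two-column reader for spectra and decay traces."""
    close = False
    if isinstance(source, str):
        if "\n" in source or "," in source:
            handle: TextIO = io.StringIO(source)  # raw text, not a path
        else:
            handle = open(source)
            close = True
    else:
        handle = source
    try:
        df = pd.read_csv(
            handle, sep=None, engine="python", comment="#", header=None, skip_blank_lines=True
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SpectrumError(f"could not parse {what} input: {exc}") from exc
    finally:
        if close:
            handle.close()
    if df.shape[1] < 2:
        raise SpectrumError(f"{what} input needs two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectrumError(f"non-numeric value {df[col].iloc[row]!r} at row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SpectrumError(f"missing value at row {row}")
        df[col] = coerced
    return df


def load_windows(source: str | TextIO) -> tuple[BandWindow, ...]:
    """Load band windows from a YAML mapping ``{F1: [585, 603], ...}``."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, Mapping):
        raise SpectrumError("window config must be a mapping of transition -> [lo, hi]")
    return tuple(BandWindow(str(k), float(v[0]), float(v[1])) for k, v in raw.items())


def integrate_band(spectrum: Spectrum, window: BandWindow) -> float:
    """Trapezoidal integral of intensity over ``[window.lo, window.hi]``.

    Window edges falling between grid points are handled by linear
    interpolation (the clipped trapezoid), so areas vary continuously with
    the window parameters.  Returns 0.0 when the window does not overlap
    the spectrum support.
    """
    wl, inten = spectrum.wavelengths, spectrum.intensities
    lo = max(window.lo, wl[0])
    hi = min(window.hi, wl[-1])
    if lo >= hi:
        return 0.0
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, wl, inten)], inten[inside], [np.interp(hi, wl, inten)])
    )
    return float(np.trapezoid(ys, xs))


def band_areas(spectrum: Spectrum, windows: Iterable[BandWindow] = DEFAULT_WINDOWS) -> BandTable:
    """Integrate each window and assemble the band table.

    The F1 (magnetic-dipole) window must be present, and its area must be
    non-zero for the I_tot/I_MD ratio to be defined.  Windows must be
    pairwise disjoint so that ``i_tot`` is a sum over distinct bands.
    """
    windows = tuple(windows)
    seen = [w.transition for w in windows]
    if len(set(seen)) != len(seen):
        raise SpectrumError(f"duplicate transitions in window set: {seen}")
    if "F1" not in seen:
        raise SpectrumError("window set must include the magnetic-dipole band F1")
    ordered = sorted(windows, key=lambda w: w.lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.lo < a.hi:
            raise SpectrumError(
                f"windows {a.transition} and {b.transition} overlap ({a.hi} > {b.lo})"
            )
    table = BandTable({w.transition: integrate_band(spectrum, w) for w in windows})
    if table.i_md <= 0:
        raise SpectrumError("F1 band area is zero; I_tot/I_MD is undefined")
    return table


def absorption_from_reflectance(reflectance: float) -> float:
    """Absorption of a powderous sample as 1 - R (diffuse reflectance R in [0, 1])."""
    if not 0.0 <= reflectance <= 1.0:
        raise ValueError(f"reflectance must be in [0, 1], got {reflectance}")
    return 1.0 - reflectance
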