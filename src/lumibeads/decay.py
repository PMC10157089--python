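"""Mono-exponential fitting of luminescence decay traces.

Eu3+ 5D0 emission from beta-diketonate complexes decays on the several-
hundred-microsecond scale and, in a homogeneous host, follows a single
exponential A*exp(-t/tau) + b.  The observed lifetime tau_obs from this
fit enters the intrinsic quantum yield Phi_int = tau_obs / tau_r.

The fit is nonlinear least squares (unweighted by default, optionally
Poisson-weighted), initialised from a log-linear regression on the
baseline-subtracted tail.  ``MonoExponentialDecay`` is the model object;
``fit_monoexponential`` is the one-call convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TextIO

import numpy as np
from scipy.optimize import curve_fit

from .spectra import _read_two_columns

__all__ = [
    "DecayTrace",
    "DecayFitResult",
    "DecayFitError",
    "MonoExponentialDecay",
    "fit_monoexponential",
    "read_decay_trace",
]


class DecayFitError(RuntimeError):
    """Raised when a decay trace cannot be fitted (degenerate input or
    non-convergence); carries the last iterate when one exists."""

    def __init__(self, message: str, last_iterate: dict | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class DecayTrace:
    """Time-resolved luminescence signal.

    times are in microseconds and strictly increasing; the signal is
    non-negative and of the same length (>= 4 points).
    """

    times: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and signal must be 1-D and equal length")
        if t.size < 4:
            raise ValueError("a decay trace needs at least 4 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("trace contains non-finite values")
        if np.any(y < 0):
            raise ValueError("signal must be non-negative")
        self.times = t
        self.signal = y


def read_decay_trace(source: str | TextIO, *, label: str = "") -> DecayTrace:
    """Read a two-column delimited decay trace (time us, signal)."""
    df = _read_two_columns(source, what="decay trace")
    df = df.sort_values(df.columns[0], kind="stable")
    return DecayTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), label=label)


@dataclass
class DecayFitResult:
    """Results of a mono-exponential decay fit.

    tau_obs and its standard error are in microseconds; amplitude and
    baseline are in signal units.  ``rms_residual`` is the root-mean-square
    misfit over the fitted points.
    """

    tau_obs: float
    amplitude: float
    baseline: float
    rms_residual: float
    n_points_used: int
    tau_stderr: float = float("nan")
    fit_start: float = 0.0
    label: str = ""

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.amplitude * np.exp(-(t - self.fit_start) / self.tau_obs) + self.baseline

    def summary(self) -> str:
        lines = [
            "Mono-exponential decay fit" + (f" [{self.label}]" if self.label else ""),
            "-" * 40,
            f"tau_obs      {self.tau_obs:12.4g} us  (+/- {self.tau_stderr:.2g})",
            f"amplitude    {self.amplitude:12.4g}",
            f"baseline     {self.baseline:12.4g}",
            f"rms residual {self.rms_residual:12.4g}",
            f"points used  {self.n_points_used:12d}  (from t = {self.fit_start:g} us)",
        ]
        return "\n".join(lines)

    def plot(self, trace: DecayTrace, ax=None):
        """Overlay the fitted curve on the measured trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(trace.times, trace.signal, ".", ms=3, alpha=0.5, label="data")
        mask = trace.times >= self.fit_start
        ax.plot(trace.times[mask], self.predict(trace.times[mask]), "-", label="fit")
        ax.set_xlabel("time / µs")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


class MonoExponentialDecay:
    """Mono-exponential decay model A*exp(-(t - t0)/tau) + b for a trace.

    Parameters
    ----------
    trace : DecayTrace
    fit_start : float, optional
        Time (us) from which points enter the fit.  Defaults to the time of
        the signal maximum, which skips the excitation-pulse region of
        gated traces.
    fit_baseline : bool
        Fit a constant baseline b (default) or fix it to zero.
    poisson_weights : bool
        Weight residuals by 1/sqrt(y) (counting statistics) instead of
        unweighted least squares.
    """

    def __init__(
        self,
        trace: DecayTrace,
        fit_start: float | None = None,
        fit_baseline: bool = True,
        poisson_weights: bool = False,
    ):
        self.trace = trace
        self.fit_start = (
            float(trace.times[int(np.argmax(trace.signal))]) if fit_start is None else float(fit_start)
        )
        self.fit_baseline = fit_baseline
        self.poisson_weights = poisson_weights

    def fit(self) -> DecayFitResult:
        t_all, y_all = self.trace.times, self.trace.signal
        mask = t_all >= self.fit_start
        t = t_all[mask] - self.fit_start  # shift so amplitude refers to fit_start
        y = y_all[mask]
        if t.size < 4:
            raise DecayFitError(f"fewer than 4 points after fit_start = {self.fit_start:g} us")
        if np.ptp(y) == 0:
            raise DecayFitError("signal is constant; no decay to fit")

        a0, tau0, b0 = self._initial_guess(t, y)
        p0 = [a0, tau0, b0] if self.fit_baseline else [a0, tau0]
        sigma = np.sqrt(np.clip(y, 1.0, None)) if self.poisson_weights else None

        if self.fit_baseline:
            def model(tt, a, tau, b):
                return a * np.exp(-tt / tau) + b
            bounds = ([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
        else:
            def model(tt, a, tau):
                return a * np.exp(-tt / tau)
            bounds = ([0.0, 1e-12], [np.inf, np.inf])

        try:
            popt, pcov = curve_fit(
                model, t, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
            )
        except RuntimeError as exc:
            raise DecayFitError(
                f"mono-exponential fit did not converge: {exc}",
                last_iterate={"p0": p0},
            ) from exc

        a, tau = float(popt[0]), float(popt[1])
        b = float(popt[2]) if self.fit_baseline else 0.0
        if a <= 0 or tau <= 0:
            raise DecayFitError(
                "fit converged to a non-positive amplitude or lifetime",
                last_iterate={"popt": list(map(float, popt))},
            )
        resid = y - model(t, *popt)
        tau_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
        return DecayFitResult(
            tau_obs=tau,
            amplitude=a,
            baseline=b,
            rms_residual=float(np.sqrt(np.mean(resid**2))),
            n_points_used=int(t.size),
            tau_stderr=tau_se,
            fit_start=self.fit_start,
            label=self.trace.label,
        )

    def _initial_guess(self, t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        """Log-linear regression on the baseline-subtracted tail."""
        b0 = float(np.median(y[-max(3, y.size // 10):])) if self.fit_baseline else 0.0
        ysub = y - b0
        peak = float(ysub.max())
        if peak <= 0:
            return max(float(y.max()), 1.0), float(t[-1] - t[0]) / 3 or 1.0, b0
        use = ysub > 0.02 * peak
        if use.sum() < 2:
            use = ysub > 0
        slope, intercept = np.polyfit(t[use], np.log(ysub[use]), 1)
        tau0 = -1.0 / slope if slope < 0 else float(t[-1] - t[0]) / 3
        return float(np.exp(intercept)), float(max(tau0, 1e-9)), b0


def fit_monoexponential(
    trace: DecayTrace,
    fit_start: float | None = None,
    fit_baseline: bool = True,
    poisson_weights: bool = False,
) -> DecayFitResult:
    """Fit A*exp(-t/tau) + b to a trace and return the fitted parameters."""
    return MonoExponentialDecay(
        trace, fit_start=fit_start, fit_baseline=fit_baseline, poisson_weights=poisson_weights
    ).fit()
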