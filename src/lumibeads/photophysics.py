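"""Quantum-yield decomposition of sensitized Eu3+ emission.

For an antenna-sensitized lanthanide emitter the overall quantum yield
factorises as

    Phi_tot = eta_sens * Phi_int,          Phi_int = tau_obs / tau_r,

where Phi_int is the intrinsic quantum yield of the emitting 5D0 level
under direct f-f excitation and eta_sens the ligand-to-metal energy
transfer efficiency.  The radiative lifetime tau_r follows from the
magnetic-dipole-referenced emission spectrum,

    1 / tau_r = A_MD0 * n^3 * (I_tot / I_MD),

with A_MD0 = 14.65 s^-1 the vacuum spontaneous emission rate of the
5D0->7F1 transition, n the refractive index of the medium and
I_tot/I_MD the total-to-magnetic-dipole intensity ratio of the corrected
emission spectrum.

All quantities are fractions internally; percentages appear only in
reports.  Lifetimes are microseconds at the interface and converted to
seconds only inside the radiative-rate arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectra import BandTable, absorption_from_reflectance

__all__ = [
    "A_MD0",
    "RadiativeRateResult",
    "PhotophysicsSummary",
    "radiative_lifetime",
    "intrinsic_qy",
    "sensitization_efficiency",
    "brightness",
    "summarize",
]

#: Vacuum spontaneous emission rate of the Eu3+ 5D0->7F1 transition, s^-1.
A_MD0 = 14.65

#: |eta_sens - 1| slack tolerated before a summary is flagged.
_ETA_TOL = 0.02


@dataclass(frozen=True)
class RadiativeRateResult:
    """Radiative decay rate of the 5D0 level and the derived lifetime."""

    ratio_tot_md: float
    refractive_index: float
    radiative_rate: float  # s^-1
    tau_r: float  # us
    a_md0: float = A_MD0


def radiative_lifetime(ratio_tot_md: float, n: float) -> RadiativeRateResult:
    """Radiative lifetime from the emission-intensity ratio and refractive index.

    Parameters
    ----------
    ratio_tot_md : float
        I_tot/I_MD >= 1 (the total emission contains the MD band).
    n : float
        Refractive index of the medium, >= 1.

    Returns
    -------
    RadiativeRateResult with the rate in s^-1 and tau_r in microseconds.
    """
    if ratio_tot_md < 1.0:
        raise ValueError(f"I_tot/I_MD must be >= 1, got {ratio_tot_md}")
    if n < 1.0:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    rate = A_MD0 * n**3 * ratio_tot_md  # s^-1
    return RadiativeRateResult(
        ratio_tot_md=float(ratio_tot_md),
        refractive_index=float(n),
        radiative_rate=float(rate),
        tau_r=1e6 / rate,
    )


def intrinsic_qy(tau_obs: float, tau_r: float) -> float:
    """Intrinsic quantum yield Phi_int = tau_obs / tau_r (both in us).

    Values above 1 are returned as computed; flagging unphysical results
    is left to :func:`summarize` so the evidence is preserved.
    """
    if tau_obs <= 0 or tau_r <= 0:
        raise ValueError("lifetimes must be positive")
    return tau_obs / tau_r


def sensitization_efficiency(phi_tot: float, phi_int: float) -> float:
    """Ligand-to-metal transfer efficiency eta_sens = Phi_tot / Phi_int.

    ``phi_int`` should be the unrounded intrinsic quantum yield; rounding
    it first can shift the second decimal of eta_sens.
    """
    if not 0.0 <= phi_tot <= 1.0:
        raise ValueError(f"phi_tot must be in [0, 1], got {phi_tot}")
    if phi_int <= 0:
        raise ValueError("phi_int must be positive")
    if phi_int > 1.0 + _ETA_TOL:
        raise ValueError(f"phi_int = {phi_int:.4g} exceeds 1 beyond tolerance")
    return phi_tot / phi_int


def brightness(phi_tot: float, absorption: float) -> float:
    """Brightness of a powderous sample: quantum yield times absorption."""
    for name, v in (("phi_tot", phi_tot), ("absorption", absorption)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return phi_tot * absorption


@dataclass
class PhotophysicsSummary:
    """One label's photophysical bookkeeping (one column of a results table).

    All fractional quantities are stored unrounded; ``to_report`` rounds to
    the customary precisions (Phi_int to integer percent, eta_sens to two
    decimals).
    """

    label: str
    phi_tot: float
    tau_obs: float  # us
    tau_r: float  # us
    phi_int: float
    eta_sens: float
    absorption: float | None = None
    brightness: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_report(self) -> dict:
        rep = {
            "label": self.label,
            "phi_tot_percent": round(self.phi_tot * 100),
            "tau_obs_us": round(self.tau_obs),
            "tau_r_us": round(self.tau_r),
            "phi_int_percent": round(self.phi_int * 100),
            "eta_sens": round(self.eta_sens, 2),
            "flags": list(self.flags),
        }
        if self.absorption is not None:
            rep["absorption"] = round(self.absorption, 2)
        if self.brightness is not None:
            rep["brightness"] = round(self.brightness, 3)
        return rep

    def summary(self) -> str:
        rep = self.to_report()
        lines = [
            f"Photophysics summary [{self.label}]",
            "-" * 40,
            f"Phi_tot      {rep['phi_tot_percent']:>6d} %",
            f"tau_obs      {rep['tau_obs_us']:>6d} us",
            f"tau_r        {rep['tau_r_us']:>6d} us",
            f"Phi_int      {rep['phi_int_percent']:>6d} %",
            f"eta_sens     {rep['eta_sens']:>6.2f}",
        ]
        if self.absorption is not None:
            lines.append(f"absorption   {rep['absorption']:>6.2f}")
        if self.brightness is not None:
            lines.append(f"brightness   {rep['brightness']:>6.3f}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def summarize(
    label: str,
    phi_tot: float,
    tau_obs: float,
    *,
    band_table: BandTable | None = None,
    tau_r: float | None = None,
    n: float | None = None,
    reflectance: float | None = None,
    reference_eta_sens: float | None = None,
) -> PhotophysicsSummary:
    """Assemble the full quantum-yield decomposition for one sample.

    Either ``tau_r`` (us) is given directly, or a ``band_table`` plus the
    refractive index ``n`` from which it is computed.  ``reflectance``
    optionally adds absorption and brightness.  ``reference_eta_sens``
    lets a previously reported value be checked; a mismatch beyond the
    second decimal is flagged, not overwritten.
    """
    if tau_r is None:
        if band_table is None or n is None:
            missing = [nm for nm, v in (("band_table", band_table), ("n", n)) if v is None]
            raise ValueError(f"need tau_r or band_table + n; missing {missing}")
        tau_r = radiative_lifetime(band_table.ratio_tot_md, n).tau_r
    if tau_obs is None or phi_tot is None:
        raise ValueError("phi_tot and tau_obs are required")

    flags: list[str] = []
    phi_int = intrinsic_qy(tau_obs, tau_r)
    if phi_int > 1.0:
        flags.append("unphysical: phi_int > 1 (tau_obs exceeds tau_r)")
        eta = phi_tot / phi_int
    else:
        eta = sensitization_efficiency(phi_tot, phi_int)
    if eta > 1.0 + _ETA_TOL:
        flags.append("unphysical: eta_sens > 1")

    absorp = bright = None
    if reflectance is not None:
        absorp = absorption_from_reflectance(reflectance)
        bright = brightness(phi_tot, absorp)

    if reference_eta_sens is not None and abs(round(eta, 2) - reference_eta_sens) > 0.005:
        flags.append(
            f"eta_sens discrepancy: computed {eta:.4f} (rounds to {round(eta, 2):.2f}) "
            f"vs reported {reference_eta_sens:.2f}"
        )

    return PhotophysicsSummary(
        label=label,
        phi_tot=phi_tot,
        tau_obs=tau_obs,
        tau_r=tau_r,
        phi_int=phi_int,
        eta_sens=eta,
        absorption=absorp,
        brightness=bright,
        flags=flags,
    )
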