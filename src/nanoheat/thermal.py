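"""Slab temperature profiles, relaxation times and Kapitza conductance.

The interfacial thermal conductance (ITC, Kapitza conductance) of the
sheet-water-lipid contact is extracted from pulse-relaxation data: after a
heat pulse, the sheet temperature decays exponentially toward the
environment with time constant tau, and G_K = C / (tau * A) where C is the
sheet heat capacity and A the interface area. In the per-area form used
here, C/A = rho_g * c_g * d, so G_K depends only on intensive sheet
constants and tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats

from .constants import K_B, AMU_KG, NM_PER_PS
from .trajectory import Trajectory

__all__ = [
    "TemperatureSeries",
    "TemperatureProfile",
    "GrapheneSheet",
    "DeltaTCurve",
    "RelaxationFit",
    "slab_temperature_profile",
    "relaxation_time",
    "kapitza_conductance",
    "critical_power",
]


@dataclass
class TemperatureSeries:
    """Temperature of one layer vs time."""

    times: np.ndarray  # ps
    temperature: np.ndarray  # K
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.times.shape != self.temperature.shape:
            raise ValueError("times and temperature must have the same length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.temperature <= 0):
            raise ValueError("temperatures must be positive")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_ps": self.times, "temperature_K": self.temperature})


@dataclass
class TemperatureProfile:
    """Temperature vs position across the stack; NaN marks empty slabs."""

    z_bins: np.ndarray  # nm, bin centers
    temperature: np.ndarray  # K
    averaging_window: float = 1.0  # ps

    def __post_init__(self):
        self.z_bins = np.asarray(self.z_bins, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.z_bins.shape != self.temperature.shape:
            raise ValueError("z_bins and temperature must have the same length")
        occ = np.isfinite(self.temperature)
        if np.any(self.temperature[occ] <= 0):
            raise ValueError("occupied slabs must have positive temperature")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"z_nm": self.z_bins, "temperature_K": self.temperature})


@dataclass
class GrapheneSheet:
    """Graphene sheet constants; heat capacity C = rho_g * c_g * d * A."""

    rho_g: float = 2.265  # g/cm^3
    c_g: float = 2.1  # J/g/K
    d: float = 0.34  # nm, van der Waals thickness
    A: float = 27.55  # nm^2

    def __post_init__(self):
        if min(self.rho_g, self.c_g, self.d, self.A) <= 0:
            raise ValueError("all sheet constants must be positive")

    @property
    def heat_capacity_per_area(self) -> float:
        """rho_g * c_g * d in J m^-2 K^-1."""
        return self.rho_g * 1e3 * self.c_g * 1e3 * self.d * 1e-9

    @property
    def heat_capacity(self) -> float:
        """Total C in J/K."""
        return self.heat_capacity_per_area * self.A * 1e-18


@dataclass
class DeltaTCurve:
    """Lipid-bilayer temperature rise vs heating power density."""

    power: np.ndarray  # GW/m^2
    delta_T: np.ndarray  # K
    stderr: np.ndarray | None = None  # K, across independent runs

    def __post_init__(self):
        self.power = np.asarray(self.power, dtype=float)
        self.delta_T = np.asarray(self.delta_T, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power densities must be >= 0")
        if not np.all(np.isfinite(self.delta_T)):
            raise ValueError("delta_T must be finite")
        order = np.argsort(self.power)
        self.power = self.power[order]
        self.delta_T = self.delta_T[order]
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)[order]


@dataclass
class RelaxationFit:
    """Single-exponential decay fit T(t) = T_env + dT0 * exp(-t/tau)."""

    tau: float  # ps
    tau_stderr: float
    dT0: float  # K
    T_env: float
    rms_residual: float  # K

    def __iter__(self):  # allow tau, diag = relaxation_time(...)
        yield self.tau
        yield self


def slab_temperature_profile(
    traj: Trajectory,
    bin_width: float = 0.1,
    window: tuple | None = None,
    origin: float = 0.0,
    species=None,
) -> TemperatureProfile:
    """Kinetic temperature per z-slab, T = sum m v^2 / (3 N k_B).

    Averaged over the frames whose times fall in `window` (ps). Slabs with
    no particles in any contributing frame are NaN, not zero. Three
    translational degrees of freedom per particle are assumed.
    """
    if traj.velocities is None:
        raise ValueError("trajectory has no velocities")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = traj.select(species)
    frames = np.arange(traj.n_frames)
    if window is not None:
        in_win = (traj.times >= window[0]) & (traj.times <= window[1])
        frames = frames[in_win]
        if len(frames) == 0:
            raise ValueError("averaging window contains no frames")
    z = traj.positions[:, mask, 2] - origin
    m_kg = traj.masses[mask] * AMU_KG
    v2 = (traj.velocities[:, mask, :] * NM_PER_PS) ** 2  # (m/s)^2
    ke = 0.5 * m_kg[None, :, None] * v2  # J per axis
    z_lo = float(z[frames].min())
    n_bins = max(1, int(np.ceil((z[frames].max() - z_lo) / bin_width + 1e-12)))
    esum = np.zeros(n_bins)
    nsum = np.zeros(n_bins)
    for f in frames:
        idx = np.clip(((z[f] - z_lo) / bin_width).astype(int), 0, n_bins - 1)
        esum += np.bincount(idx, weights=ke[f].sum(axis=1), minlength=n_bins)
        nsum += np.bincount(idx, minlength=n_bins)
    temp = np.full(n_bins, np.nan)
    occ = nsum > 0
    temp[occ] = 2.0 * esum[occ] / (3.0 * nsum[occ] * K_B)
    centers = z_lo + (np.arange(n_bins) + 0.5) * bin_width
    win = (
        float(traj.times[frames[-1]] - traj.times[frames[0]])
        if len(frames) > 1
        else 0.0
    )
    return TemperatureProfile(z_bins=centers, temperature=temp, averaging_window=win)


def relaxation_time(series: TemperatureSeries, T_env: float) -> RelaxationFit:
    """Fit the post-pulse decay T(t) = T_env + dT0 * exp(-t/tau).

    Initialized from a log-linear regression of T - T_env, then refined by
    nonlinear least squares with equal weights. Raises if the series does
    not start above T_env or does not decay toward it.
    """
    t = series.times - series.times[0]
    excess = series.temperature - T_env
    if excess[0] <= 0:
        raise ValueError("series must start above the environment temperature")
    n = len(t)
    head = excess[: max(2, n // 5)].mean()
    tail = excess[-max(2, n // 5):].mean()
    if tail >= head * 0.999:
        raise ValueError("series does not decay toward T_env; cannot fit relaxation")
    pos = excess > 0
    lin = stats.linregress(t[pos], np.log(excess[pos]))
    tau0 = -1.0 / lin.slope if lin.slope < 0 else (t[-1] - t[0])
    p0 = [float(np.exp(lin.intercept)), float(tau0)]
    popt, pcov = curve_fit(
        lambda tt, dT0, tau: T_env + dT0 * np.exp(-tt / tau),
        t,
        series.temperature,
        p0=p0,
        maxfev=10000,
    )
    resid = series.temperature - (T_env + popt[0] * np.exp(-t / popt[1]))
    return RelaxationFit(
        tau=float(popt[1]),
        tau_stderr=float(np.sqrt(pcov[1, 1])),
        dT0=float(popt[0]),
        T_env=T_env,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def kapitza_conductance(sheet: GrapheneSheet, tau: float) -> float:
    """ITC G_K = C / (tau * A) = rho_g c_g d / tau, in MW m^-2 K^-1.

    tau in ps. Intensive: independent of the sheet area A.
    """
    if tau <= 0:
        raise ValueError("relaxation time must be positive")
    return sheet.heat_capacity_per_area / (tau * 1e-12) / 1e6


def critical_power(curve: DeltaTCurve, delta_T_c: float = 20.0) -> float:
    """Critical power density p_c (GW/m^2) where dT first reaches delta_T_c.

    Located by piecewise-linear interpolation at the first upward crossing
    of the threshold between measured power points.
    """
    dT = curve.delta_T
    p = curve.power
    above = dT >= delta_T_c
    if not above.any():
        raise ValueError(
            f"threshold {delta_T_c:g} K never crossed (max dT = {dT.max():g} K)"
        )
    i = int(np.argmax(above))
    if i == 0:
        return float(p[0])
    frac = (delta_T_c - dT[i - 1]) / (dT[i] - dT[i - 1])
    return float(p[i - 1] + frac * (p[i] - p[i - 1]))
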