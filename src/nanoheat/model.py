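"""Serial-resistor model of heat dissipation across the bio-nano interface.

The sheet-water-lipid hybrid is modelled as two thermal resistors in
series: the graphene/water/lipid interface, with interfacial conductance
G_C, and the lipid bilayer, a Fourier conductor of conductivity kappa_L and
thickness delta terminating in a water reservoir (heat sink) at T_e. The
intercalated water layer is treated as isothermal (plateau at T_W), because
its conductivity (~0.61 W/m/K) is several-fold higher than the lipid's
(~0.12 W/m/K).

Steady state, with through-interface flux density q = eta * p:

    T_W  = T_e + q * delta / kappa_L          (lipid conduction)
    T_G  = T_W + q / G_C                      (interfacial drop)
    T(z) linear from T_W at the lipid surface z_s down to T_e at z_s+delta

Transient, lumped-parameter (sheet as a single heat-capacity node):

    rho_g c_g d dT/dt = eta*p - G_C (T - T_W),  T(0) = T_W
    => T_g(t) = T_W + (eta*p/G_C) * (1 - exp(-G_C t / (rho_g c_g d)))

Fitting is exposed statsmodels-style: :class:`TransientHeatingModel` and
:class:`SteadyProfileModel` are built from data and their ``fit()`` returns
a Results object carrying estimates, standard errors and a ``summary()``.
The flux-partition factor eta (default 1, the pure serial model)
accommodates parallel heat leakage through bulk water outside the confined
region and can be fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import curve_fit

from .thermal import GrapheneSheet, TemperatureProfile, TemperatureSeries

__all__ = [
    "InterfaceStack",
    "steady_state_profile",
    "transient_graphene_temperature",
    "TransientHeatingModel",
    "TransientHeatingResults",
    "SteadyProfileModel",
    "SteadyProfileResults",
    "fit_transient",
    "fit_steady_parameters",
    "predict_critical_power",
    "fit_flux_partition",
]

_GW = 1e9  # W/m^2 per GW/m^2
_MW = 1e6  # W/m^2/K per MW/m^2/K
_NM = 1e-9


@dataclass
class InterfaceStack:
    """Parameters of the serial interface + lipid-conductor model.

    G_C : interfacial conductance, MW m^-2 K^-1.
    kappa_L, kappa_W : lipid and water thermal conductivities, W m^-1 K^-1.
    delta : lipid bilayer thickness, nm (4 nm, typical POPC bilayer).
    t_W : intercalated water layer thickness, nm.
    z_s : position of the lipid surface, nm (defaults to t_W).
    T_e : heat-sink temperature, K.
    eta : flux-partition factor in [0, 1]; fraction of the heating power
        that crosses the interface (1 = pure serial model).
    """

    G_C: float = 12.60
    kappa_L: float = 0.12
    delta: float = 4.0
    kappa_W: float = 0.61
    t_W: float = 1.0
    z_s: float | None = None
    T_e: float = 300.0
    eta: float = 1.0

    def __post_init__(self):
        if min(self.G_C, self.kappa_L, self.delta) <= 0:
            raise ValueError("G_C, kappa_L and delta must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.z_s is None:
            self.z_s = self.t_W

    def to_dict(self) -> dict:
        return asdict(self)

    def water_temperature(self, p: float) -> float:
        """Steady plateau T_W (K) at power density p (GW/m^2)."""
        q = self.eta * p * _GW
        return self.T_e + q * self.delta * _NM / self.kappa_L

    def graphene_temperature(self, p: float) -> float:
        """Steady sheet temperature T_G (K) at power density p (GW/m^2)."""
        q = self.eta * p * _GW
        return self.water_temperature(p) + q / (self.G_C * _MW)


def steady_state_profile(
    stack: InterfaceStack,
    p: float,
    bin_width: float = 0.1,
    sheet_thickness: float = 0.34,
) -> tuple[TemperatureProfile, dict]:
    """Piecewise steady-state temperature profile T(z) at power density p.

    z runs from -sheet_thickness (inside the sheet, at T_G) through the
    isothermal water plateau (T_W) to the far lipid surface at z_s + delta
    (T_e). Returns the profile and a summary {T_G, T_W, T_zs, T_e}.
    """
    if p < 0:
        raise ValueError("power density must be >= 0")
    T_W = stack.water_temperature(p)
    T_G = stack.graphene_temperature(p)
    z = np.arange(-sheet_thickness + bin_width / 2, stack.z_s + stack.delta, bin_width)
    temp = np.empty_like(z)
    sheet = z < 0
    water = (z >= 0) & (z < stack.z_s)
    lipid = z >= stack.z_s
    temp[sheet] = T_G
    temp[water] = T_W
    temp[lipid] = T_W + (stack.T_e - T_W) * (z[lipid] - stack.z_s) / stack.delta
    profile = TemperatureProfile(z_bins=z, temperature=temp)
    return profile, {"T_G": T_G, "T_W": T_W, "T_zs": T_W, "T_e": stack.T_e}


def transient_graphene_temperature(
    sheet: GrapheneSheet,
    stack: InterfaceStack,
    p: float,
    times,
    T_W: float | None = None,
) -> TemperatureSeries:
    """Lumped-parameter sheet temperature under constant heating power.

    Closed-form solution of rho_g c_g d dT/dt = eta*p - G_C (T - T_W) with
    T(0) = T_W; time constant tau = rho_g c_g d / G_C, plateau rise
    eta*p/G_C. T_W defaults to the stack's steady plateau at power p.
    """
    if p < 0:
        raise ValueError("power density must be >= 0")
    times = np.asarray(times, dtype=float)
    if T_W is None:
        T_W = stack.water_temperature(p)
    tau_ps = sheet.heat_capacity_per_area / (stack.G_C * _MW) / 1e-12
    rise = stack.eta * p * _GW / (stack.G_C * _MW)
    temp = T_W + rise * (1.0 - np.exp(-times / tau_ps))
    return TemperatureSeries(times=times, temperature=temp, label="graphene")


# ---------------------------------------------------------------------------
# model / results classes


@dataclass
class TransientHeatingResults:
    """Fit of the lumped heating solution; params in field units."""

    G_C: float  # MW m^-2 K^-1
    G_C_stderr: float
    eta: float
    eta_stderr: float | None
    tau: float  # ps
    T_W: float
    rms_residual: float  # K
    identifiable: bool
    model: "TransientHeatingModel" = field(repr=False, default=None)

    @property
    def params(self) -> dict:
        return {"G_C": self.G_C, "eta": self.eta}

    @property
    def bse(self) -> dict:
        return {"G_C": self.G_C_stderr, "eta": self.eta_stderr}

    def summary(self) -> str:
        lines = [
            "Transient lumped-parameter heating fit",
            "=" * 46,
            f"{'G_C (MW m^-2 K^-1)':<28}{self.G_C:>12.4f} +/- {self.G_C_stderr:.4f}",
        ]
        if self.eta_stderr is not None:
            lines.append(f"{'eta (flux partition)':<28}{self.eta:>12.4f} +/- {self.eta_stderr:.4f}")
        else:
            lines.append(f"{'eta (fixed)':<28}{self.eta:>12.4f}")
        lines += [
            f"{'time constant tau (ps)':<28}{self.tau:>12.2f}",
            f"{'water plateau T_W (K)':<28}{self.T_W:>12.2f}",
            f"{'rms residual (K)':<28}{self.rms_residual:>12.4g}",
            f"{'identifiable':<28}{str(self.identifiable):>12}",
        ]
        return "\n".join(lines)


class TransientHeatingModel:
    """Fit G_C (and optionally eta) to a sheet heating curve T_g(t).

    Parameters
    ----------
    series : TemperatureSeries from a constant-power heating protocol.
    sheet : GrapheneSheet supplying the areal heat capacity rho_g c_g d.
    power : heating power density p, GW/m^2.
    T_W : water plateau temperature, K (defaults to the series' initial
        value, per the lumped solution's initial condition).
    fit_eta : also fit the flux-partition factor (default fixed at `eta`).
    """

    def __init__(
        self,
        series: TemperatureSeries,
        sheet: GrapheneSheet,
        power: float,
        T_W: float | None = None,
        eta: float = 1.0,
        fit_eta: bool = False,
    ):
        self.series = series
        self.sheet = sheet
        self.power = power
        self.T_W = float(series.temperature[0]) if T_W is None else T_W
        self.eta = eta
        self.fit_eta = fit_eta

    def predict(self, G_C: float, eta: float | None = None, times=None) -> np.ndarray:
        eta = self.eta if eta is None else eta
        t = self.series.times if times is None else np.asarray(times, float)
        t = t - self.series.times[0]
        tau_ps = self.sheet.heat_capacity_per_area / (G_C * _MW) / 1e-12
        rise = eta * self.power * _GW / (G_C * _MW)
        return self.T_W + rise * (1.0 - np.exp(-t / tau_ps))

    def _initial_G_C(self) -> float:
        plateau = self.series.temperature[-1] - self.T_W
        if plateau <= 0:
            return 10.0
        return self.eta * self.power * _GW / plateau / _MW

    def fit(self) -> TransientHeatingResults:
        t = self.series.times - self.series.times[0]
        T = self.series.temperature
        g0 = max(self._initial_G_C(), 1e-3)
        try:
            if self.fit_eta:
                popt, pcov = curve_fit(
                    lambda tt, g, e: self.predict(g, e, tt + self.series.times[0]),
                    t, T, p0=[g0, self.eta], maxfev=20000,
                )
                g_fit, eta_fit = popt
                g_err, eta_err = np.sqrt(np.diag(pcov))
            else:
                popt, pcov = curve_fit(
                    lambda tt, g: self.predict(g, None, tt + self.series.times[0]),
                    t, T, p0=[g0], maxfev=20000,
                )
                g_fit, eta_fit = popt[0], self.eta
                g_err, eta_err = float(np.sqrt(pcov[0, 0])), None
        except RuntimeError:
            warnings.warn("transient fit did not converge; G_C unidentifiable",
                          stacklevel=2)
            return TransientHeatingResults(
                G_C=np.nan, G_C_stderr=np.inf, eta=self.eta, eta_stderr=None,
                tau=np.nan, T_W=self.T_W, rms_residual=np.nan,
                identifiable=False, model=self,
            )
        tau_ps = self.sheet.heat_capacity_per_area / (g_fit * _MW) / 1e-12
        resid = T - self.predict(g_fit, eta_fit)
        # early-time-only data (t_max << tau) carries no conductance information
        identifiable = bool(np.isfinite(g_err)) and t[-1] >= 0.5 * tau_ps and (
            g_err / abs(g_fit) < 0.5 if g_fit else False
        )
        if not identifiable:
            warnings.warn(
                "heating curve does not approach its plateau; the fitted "
                "conductance has a wide confidence interval", stacklevel=2,
            )
        return TransientHeatingResults(
            G_C=float(g_fit), G_C_stderr=float(g_err), eta=float(eta_fit),
            eta_stderr=None if eta_err is None else float(eta_err),
            tau=float(tau_ps), T_W=self.T_W,
            rms_residual=float(np.sqrt(np.mean(resid**2))),
            identifiable=identifiable, model=self,
        )


@dataclass
class SteadyProfileResults:
    """Fit of the piecewise steady profile; params in field units."""

    G_C: float  # MW m^-2 K^-1 (inf if the interface drop vanishes)
    G_C_stderr: float
    kappa_L: float  # W m^-1 K^-1
    kappa_L_stderr: float
    T_W: float
    rms_residual: float
    identifiable: bool
    model: "SteadyProfileModel" = field(repr=False, default=None)

    @property
    def params(self) -> dict:
        return {"G_C": self.G_C, "kappa_L": self.kappa_L}

    @property
    def bse(self) -> dict:
        return {"G_C": self.G_C_stderr, "kappa_L": self.kappa_L_stderr}

    def summary(self) -> str:
        return "\n".join([
            "Steady-state resistor-network profile fit",
            "=" * 46,
            f"{'G_C (MW m^-2 K^-1)':<28}{self.G_C:>12.4f} +/- {self.G_C_stderr:.4f}",
            f"{'kappa_L (W m^-1 K^-1)':<28}{self.kappa_L:>12.4f} +/- {self.kappa_L_stderr:.4f}",
            f"{'water plateau T_W (K)':<28}{self.T_W:>12.2f}",
            f"{'rms residual (K)':<28}{self.rms_residual:>12.4g}",
            f"{'identifiable':<28}{str(self.identifiable):>12}",
        ])


class SteadyProfileModel:
    """Fit (G_C, kappa_L) to a steady-state temperature profile.

    The profile's bins are classified by the known geometry: sheet (z < 0),
    water plateau (0 <= z < z_s) and lipid conductor (z_s <= z <= z_s +
    delta); the piecewise solution at flux density q = eta*p is then fitted
    by least squares.
    """

    def __init__(
        self,
        profile: TemperatureProfile,
        power: float,
        z_s: float,
        delta: float,
        eta: float = 1.0,
        T_e: float = 300.0,
    ):
        self.profile = profile
        self.power = power
        self.z_s = z_s
        self.delta = delta
        self.eta = eta
        self.T_e = T_e
        occ = np.isfinite(profile.temperature)
        z, T = profile.z_bins[occ], profile.temperature[occ]
        self._sheet = z < 0
        self._water = (z >= 0) & (z < z_s)
        self._lipid = (z >= z_s) & (z <= z_s + delta + 1e-9)
        self._z, self._T = z, T
        if not self._lipid.any() or not (self._sheet.any() and self._water.any()):
            raise ValueError(
                "profile must cover the sheet, water and lipid regions"
            )

    def predict(self, G_C: float, kappa_L: float, z=None) -> np.ndarray:
        z = self._z if z is None else np.asarray(z, float)
        q = self.eta * self.power * _GW
        T_W = self.T_e + q * self.delta * _NM / kappa_L
        T_G = T_W + q / (G_C * _MW)
        out = np.empty_like(z)
        out[z < 0] = T_G
        wat = (z >= 0) & (z < self.z_s)
        out[wat] = T_W
        lip = z >= self.z_s
        out[lip] = T_W + (self.T_e - T_W) * (z[lip] - self.z_s) / self.delta
        return out

    def fit(self) -> SteadyProfileResults:
        z, T = self._z, self._T
        q = self.eta * self.power * _GW
        # moment estimates: lipid drop -> kappa_L, interface step -> G_C
        lipid_drop = T[self._water].mean() - self.T_e
        if lipid_drop <= 0 or np.ptp(T[self._lipid]) < 1e-12:
            raise ValueError("degenerate profile: no temperature gradient to fit")
        k0 = q * self.delta * _NM / lipid_drop
        step = T[self._sheet].mean() - T[self._water].mean()
        if step <= 0:
            warnings.warn(
                "no interface temperature drop: G_C is unidentifiable (infinite)",
                stacklevel=2,
            )
            return SteadyProfileResults(
                G_C=np.inf, G_C_stderr=np.inf, kappa_L=float(k0),
                kappa_L_stderr=np.nan, T_W=float(T[self._water].mean()),
                rms_residual=np.nan, identifiable=False, model=self,
            )
        g0 = q / step / _MW
        popt, pcov = curve_fit(
            lambda zz, g, k: self.predict(g, k, zz), z, T, p0=[g0, k0], maxfev=20000
        )
        g_fit, k_fit = popt
        g_err, k_err = np.sqrt(np.diag(pcov))
        resid = T - self.predict(g_fit, k_fit)
        T_W = self.T_e + q * self.delta * _NM / k_fit
        return SteadyProfileResults(
            G_C=float(g_fit), G_C_stderr=float(g_err),
            kappa_L=float(k_fit), kappa_L_stderr=float(k_err),
            T_W=float(T_W), rms_residual=float(np.sqrt(np.mean(resid**2))),
            identifiable=bool(np.isfinite(g_err) and np.isfinite(k_err)),
            model=self,
        )


def fit_transient(
    series: TemperatureSeries, sheet: GrapheneSheet, p: float, **kwargs
) -> TransientHeatingResults:
    """Convenience wrapper: TransientHeatingModel(series, sheet, p).fit()."""
    return TransientHeatingModel(series, sheet, p, **kwargs).fit()


def fit_steady_parameters(
    profile: TemperatureProfile, p: float, z_s: float, delta: float, **kwargs
) -> SteadyProfileResults:
    """Convenience wrapper: SteadyProfileModel(profile, p, z_s, delta).fit()."""
    return SteadyProfileModel(profile, p, z_s, delta, **kwargs).fit()


def predict_critical_power(
    stack: InterfaceStack, delta_T_c: float, location: str = "lipid_surface"
) -> float:
    """Critical power density p_c (GW/m^2) for a lipid temperature-rise cap.

    Inverts the steady solution: the hottest lipid point is its inner
    surface, where the rise is eta*p*delta/kappa_L, so
    p_c = kappa_L * dT_c / (eta * delta); the volume-average lipid rise is
    half the surface rise, doubling p_c.
    """
    if delta_T_c <= 0:
        raise ValueError("delta_T_c must be positive")
    if stack.eta == 0:
        return np.inf
    p_c = stack.kappa_L * delta_T_c / (stack.eta * stack.delta * _NM) / _GW
    if location == "lipid_surface":
        return p_c
    if location == "lipid_average":
        return 2.0 * p_c
    raise ValueError(f"unknown location {location!r}")


def fit_flux_partition(
    stack: InterfaceStack,
    delta_T_c: float,
    p_c_observed: float,
    location: str = "lipid_surface",
) -> float:
    """Flux-partition eta that reconciles the serial model with an observed p_c.

    With the pure serial model (eta = 1) the predicted critical power is
    kappa_L*dT_c/delta (surface) or twice that (average); an observed p_c
    larger than this implies that only a fraction eta of the heating power
    crosses the interface. Reported as a fitted partition, not a prediction.
    """
    factor = 1.0 if location == "lipid_surface" else 2.0
    if location not in ("lipid_surface", "lipid_average"):
        raise ValueError(f"unknown location {location!r}")
    eta = factor * stack.kappa_L * delta_T_c / (stack.delta * _NM) / (p_c_observed * _GW)
    return float(eta)
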