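"""Synthetic MD-surrogate generators.

Three generators provide inputs with the statistical structure the analysis
pipeline assumes, without running atomistic MD:

* :func:`generate_layered_positions` — water molecules whose z-coordinates
  follow a layered density (bulk plateau plus Gaussian near-wall peaks),
  emulating the structured intercalated water layer between a graphene
  sheet and a lipid bilayer.
* :func:`generate_brownian_trajectory` — free Brownian particles with a
  prescribed diffusion coefficient, the fixture for the Einstein-relation
  MSD pipeline.
* :func:`simulate_lattice` — an explicit-update 1D lattice of heat
  capacities coupled by conductances (sheet | water | lipid | sink), a
  desk-scale stand-in for the velocity-rescaling heating and pulse-
  relaxation MD protocols.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import K_B, AMU_KG, NM_PER_PS, M_WATER, N_A, G_CM3_TO_G_NM3
from .thermal import TemperatureProfile, TemperatureSeries
from .trajectory import Trajectory

__all__ = [
    "LayeredDensitySpec",
    "BrownianSpec",
    "LatticeThermalSpec",
    "LatticeResult",
    "generate_layered_positions",
    "generate_brownian_trajectory",
    "simulate_lattice",
    "maxwell_boltzmann_velocities",
]


# ---------------------------------------------------------------------------
# layered water density


@dataclass
class LayeredDensitySpec:
    """Target water density: bulk plateau + Gaussian peaks within the gap.

    peaks: list of (center_nm, amplitude_g_cm3 above bulk, width_nm sigma).
    gap_extent: span of the water gallery in nm (z in [0, gap_extent],
    z measured from the graphene plane). area: interface area in nm^2.
    """

    bulk_density: float = 0.997
    peaks: list = field(default_factory=list)
    gap_extent: float = 2.0
    area: float = 27.55  # 5.36 nm x 5.14 nm supercell
    n_molecules: int = 10_000
    seed: int = 0

    def validate(self):
        if self.bulk_density < 0:
            raise ValueError("bulk_density must be >= 0")
        if self.gap_extent <= 0 or self.area <= 0:
            raise ValueError("gap_extent and area must be positive")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        for c, a, w in self.peaks:
            if a < 0:
                raise ValueError("peak amplitudes must be >= 0")
            if w <= 0:
                raise ValueError("peak widths must be positive")
            if not 0 <= c <= self.gap_extent:
                raise ValueError("peak centers must lie within the gap")

    def density(self, z):
        """Target density rho(z) in g/cm^3 on z in [0, gap_extent] (nm)."""
        z = np.asarray(z, dtype=float)
        rho = np.full_like(z, self.bulk_density)
        for c, a, w in self.peaks:
            rho = rho + a * np.exp(-0.5 * ((z - c) / w) ** 2)
        return rho

    def total_mass_g(self, z0: float = None, z1: float = None) -> float:
        """Analytic mass A * integral(rho dz) over [z0, z1] in grams."""
        from scipy.special import erf

        z0 = 0.0 if z0 is None else z0
        z1 = self.gap_extent if z1 is None else z1
        integ = self.bulk_density * (z1 - z0)
        for c, a, w in self.peaks:
            integ += (
                a
                * w
                * np.sqrt(np.pi / 2.0)
                * (erf((z1 - c) / (np.sqrt(2) * w)) - erf((z0 - c) / (np.sqrt(2) * w)))
            )
        return float(integ * self.area * G_CM3_TO_G_NM3)


def generate_layered_positions(spec: LayeredDensitySpec) -> Trajectory:
    """Sample a single frame of molecule positions from the layered density.

    z is drawn from the mixture density by inverse-CDF sampling on a fine
    grid; x, y are uniform over the interface area. Each molecule carries an
    effective mass total_mass/n_molecules so that the binned profile
    converges to the spec density as n_molecules grows.
    """
    spec.validate()
    grid = np.linspace(0.0, spec.gap_extent, 8192)
    rho = spec.density(grid)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (rho[1:] + rho[:-1]) * np.diff(grid))])
    if cdf[-1] <= 0:
        raise ValueError("density is zero everywhere; spec is not normalizable")
    cdf /= cdf[-1]
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n_molecules)
    z = np.interp(u, cdf, grid)
    lx = np.sqrt(spec.area)
    xy = rng.random((spec.n_molecules, 2)) * lx
    pos = np.column_stack([xy, z])[None, :, :]

    mass_per_molecule = spec.total_mass_g() / spec.n_molecules * N_A  # g/mol
    return Trajectory(
        positions=pos,
        masses=np.full(spec.n_molecules, mass_per_molecule),
        species=np.full(spec.n_molecules, "W"),
        box=np.array([lx, lx, spec.gap_extent]),
        periodic=np.array([True, True, False]),
        times=np.array([0.0]),
    )


# ---------------------------------------------------------------------------
# Brownian dynamics


@dataclass
class BrownianSpec:
    """Free Brownian motion with diffusion coefficient D (nm^2/ps)."""

    diffusion_coefficient: float = 0.25
    n_particles: int = 500
    n_frames: int = 2000
    dt: float = 1.0  # ps
    d_i: int = 3
    seed: int = 0

    def validate(self):
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.d_i not in (1, 2, 3):
            raise ValueError("d_i must be 1, 2 or 3")


def generate_brownian_trajectory(spec: BrownianSpec) -> Trajectory:
    """Independent Gaussian increments per active axis, variance 2*D*dt.

    Coordinates are unwrapped (the box is a non-periodic bounding volume),
    so the trajectory feeds the MSD pipeline directly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(2.0 * spec.diffusion_coefficient * spec.dt)
    steps = np.zeros((spec.n_frames - 1, spec.n_particles, 3))
    if sigma > 0:
        steps[:, :, : spec.d_i] = rng.normal(
            0.0, sigma, size=(spec.n_frames - 1, spec.n_particles, spec.d_i)
        )
    pos = np.concatenate(
        [np.zeros((1, spec.n_particles, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    extent = max(1.0, float(np.abs(pos).max()) * 2.0 + 1.0)
    return Trajectory(
        positions=pos,
        masses=np.full(spec.n_particles, M_WATER),
        species=np.full(spec.n_particles, "W"),
        box=np.full(3, extent),
        periodic=np.zeros(3, dtype=bool),
        times=np.arange(spec.n_frames) * spec.dt,
    )


def maxwell_boltzmann_velocities(masses, temperature: float, seed: int = 0) -> np.ndarray:
    """Per-axis Gaussian velocities (nm/ps) at the given kinetic temperature."""
    rng = np.random.default_rng(seed)
    m_kg = np.asarray(masses, dtype=float) * AMU_KG
    std = np.sqrt(K_B * temperature / m_kg) / NM_PER_PS
    return rng.normal(size=(len(m_kg), 3)) * std[:, None]


# ---------------------------------------------------------------------------
# 1D lattice heat-conduction surrogate


@dataclass
class LatticeThermalSpec:
    """Sheet | water | lipid chain of heat capacities and conductances.

    layer_sites: sites per layer (sheet, water, lipid).
    site_heat_capacity: J/K per site, per layer.
    link_conductance: W/K between adjacent sites within each layer.
    interface_conductance: (sheet-water, water-lipid) junction conductances, W/K.
    sink_coupling couples the last lipid site to a reservoir at
    sink_temperature. heating_power is injected uniformly into the sheet
    layer. area maps lattice conductances to per-area (Kapitza) units.
    """

    layer_sites: tuple = (1, 4, 8)
    site_heat_capacity: tuple = (1e-20, 2e-21, 2e-21)  # J/K
    link_conductance: tuple = (1e-9, 1e-9, 1e-9)  # W/K
    interface_conductance: tuple = (3e-10, 1e-9)  # W/K
    sink_temperature: float = 300.0  # K
    sink_coupling: float = 1e-9  # W/K
    heating_power: float = 0.0  # W
    dt: float = 0.5  # ps
    n_steps: int = 20_000
    noise_amplitude: float = 0.0  # K
    area: float = 27.55  # nm^2, for per-area conversions
    seed: int = 0

    def validate(self):
        if any(n < 1 for n in self.layer_sites):
            raise ValueError("each layer needs at least one site")
        if any(c <= 0 for c in self.site_heat_capacity):
            raise ValueError("heat capacities must be positive")
        if any(g <= 0 for g in self.link_conductance) or any(
            g <= 0 for g in self.interface_conductance
        ):
            raise ValueError("conductances must be positive")
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt and n_steps must be positive")
        gmax = max(
            max(self.link_conductance),
            max(self.interface_conductance),
            self.sink_coupling,
        )
        cmin = min(
            self.site_heat_capacity[i]
            for i in range(3)
            if self.layer_sites[i] > 0
        )
        if self.dt * 1e-12 * gmax / cmin >= 0.5:
            raise ValueError(
                "explicit update unstable: dt*max(conductance)/min(capacity) "
                f"= {self.dt * 1e-12 * gmax / cmin:.3g} >= 0.5"
            )

    def build(self):
        """Return (capacities, link_conductances, layer_index) site arrays."""
        ns, nw, nl = self.layer_sites
        caps = np.concatenate(
            [
                np.full(ns, self.site_heat_capacity[0]),
                np.full(nw, self.site_heat_capacity[1]),
                np.full(nl, self.site_heat_capacity[2]),
            ]
        )
        layer = np.concatenate([np.zeros(ns, int), np.ones(nw, int), np.full(nl, 2)])
        glinks = []
        for i in range(ns + nw + nl - 1):
            if layer[i] == layer[i + 1]:
                glinks.append(self.link_conductance[layer[i]])
            elif layer[i] == 0:
                glinks.append(self.interface_conductance[0])
            else:
                glinks.append(self.interface_conductance[1])
        return caps, np.array(glinks), layer

    def interface_conductance_per_area(self, which: int = 0) -> float:
        """Junction conductance in MW/m^2/K for per-area comparisons."""
        g = self.interface_conductance[which]  # W/K
        return g / (self.area * 1e-18) / 1e6


@dataclass
class LatticeResult:
    """Recorded lattice state: per-layer mean temperatures and site fields."""

    times: np.ndarray  # ps
    site_temperatures: np.ndarray  # (n_records, n_sites) K
    layer_index: np.ndarray  # (n_sites,)
    capacities: np.ndarray  # (n_sites,) J/K
    energy: np.ndarray  # (n_records,) total lattice energy, J
    spec: LatticeThermalSpec

    _LAYERS = ("sheet", "water", "lipid")

    def layer_series(self, layer: str) -> TemperatureSeries:
        k = self._LAYERS.index(layer)
        mask = self.layer_index == k
        w = self.capacities[mask]
        temp = self.site_temperatures[:, mask] @ w / w.sum()
        return TemperatureSeries(times=self.times, temperature=temp, label=layer)

    def profile(self, index: int = -1) -> TemperatureProfile:
        """Site temperatures as a pseudo-spatial profile (site index * 1 nm)."""
        z = np.arange(self.site_temperatures.shape[1], dtype=float)
        return TemperatureProfile(
            z_bins=z,
            temperature=self.site_temperatures[index],
            averaging_window=self.spec.dt,
        )

    def sink_power(self, index: int = -1) -> float:
        """Instantaneous power delivered to the sink, W."""
        return float(
            self.spec.sink_coupling
            * (self.site_temperatures[index, -1] - self.spec.sink_temperature)
        )


def simulate_lattice(
    spec: LatticeThermalSpec,
    protocol: str = "heating",
    pulse_duration: float = 100.0,  # ps
    pulse_target: float = 500.0,  # K
    initial_temperature=None,
    record_stride: int = 1,
) -> LatticeResult:
    """Explicit-update heat exchange on the sheet|water|lipid chain.

    Per step, each site i exchanges dE_i = sum_j g_ij (T_j - T_i) dt with its
    neighbours (antisymmetric, hence energy-conserving to round-off); the
    sheet layer receives the protocol's heating power and the terminal lipid
    site exchanges with the sink. The ``pulse_relaxation`` protocol ramps
    the sheet layer's temperature to `pulse_target` over `pulse_duration`
    (the analogue of MD velocity rescaling), then releases it to relax
    freely. `initial_temperature` may be a scalar or a per-site array;
    defaults to the sink temperature everywhere.
    """
    spec.validate()
    if protocol not in ("heating", "pulse_relaxation"):
        raise ValueError(f"unknown protocol {protocol!r}")
    caps, glinks, layer = spec.build()
    n_sites = len(caps)
    t0 = spec.sink_temperature if initial_temperature is None else initial_temperature
    temps = np.broadcast_to(np.asarray(t0, dtype=float), (n_sites,)).copy()
    sheet_mask = layer == 0
    dt_s = spec.dt * 1e-12
    t_sheet0 = temps[sheet_mask].mean()

    rng = np.random.default_rng(spec.seed)
    n_rec = spec.n_steps // record_stride + 1
    rec_T = np.empty((n_rec, n_sites))
    rec_t = np.empty(n_rec)
    rec_E = np.empty(n_rec)
    rec_T[0] = temps
    rec_t[0] = 0.0
    rec_E[0] = float(caps @ temps)
    k = 1
    noise_std = spec.noise_amplitude * np.sqrt(spec.dt)
    for step in range(spec.n_steps):
        t_ps = step * spec.dt
        flux = glinks * (temps[1:] - temps[:-1])  # W, positive = rightward into i
        dE = np.zeros(n_sites)
        dE[:-1] += flux
        dE[1:] -= flux
        if protocol == "heating":
            dE[sheet_mask] += spec.heating_power / sheet_mask.sum()
        dE[-1] += spec.sink_coupling * (spec.sink_temperature - temps[-1])
        temps = temps + dE * dt_s / caps
        if protocol == "pulse_relaxation" and t_ps < pulse_duration:
            frac = min(1.0, (t_ps + spec.dt) / pulse_duration)
            temps[sheet_mask] = t_sheet0 + frac * (pulse_target - t_sheet0)
        if noise_std > 0:
            temps = temps + rng.normal(0.0, noise_std, n_sites)
        if not np.all(np.isfinite(temps)) or np.abs(temps).max() > 1e7:
            raise RuntimeError(
                f"lattice update diverged at step {step + 1} "
                f"(t = {t_ps + spec.dt:.3g} ps); reduce dt"
            )
        if (step + 1) % record_stride == 0:
            rec_T[k] = temps
            rec_t[k] = (step + 1) * spec.dt
            rec_E[k] = float(caps @ temps)
            k += 1
    return LatticeResult(
        times=rec_t[:k],
        site_temperatures=rec_T[:k],
        layer_index=layer,
        capacities=caps,
        energy=rec_E[:k],
        spec=spec,
    )
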