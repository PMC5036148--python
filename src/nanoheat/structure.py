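"""Slab mass-density profiles and intercalated-water descriptors.

The intercalated water layer between a graphene sheet and a lipid bilayer
is characterized by two numbers: its thickness t_W — the span of the region
where the water mass density is at or above the bulk value — and M_1, the
water mass under the first density peak next to the wall, A * integral of
rho(z) dz between the peak's boundaries. z = 0 is the graphene plane and z
increases toward the lipid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema

from .constants import G_CM3_TO_G_NM3, WATER_BULK_DENSITY
from .trajectory import Trajectory

__all__ = [
    "DensityProfile",
    "PeakRegion",
    "FirstPeakMass",
    "density_profile",
    "detect_peaks",
    "water_layer_thickness",
    "first_peak_mass",
]


@dataclass
class DensityProfile:
    """Binned mass density vs distance from the graphene plane."""

    bin_edges: np.ndarray  # nm, len n_bins + 1
    density: np.ndarray  # g/cm^3 per bin
    area: float  # nm^2
    bulk_density: float = WATER_BULK_DENSITY

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.bin_edges) != len(self.density) + 1:
            raise ValueError("bin_edges must have len(density)+1 entries")
        if np.any(self.density < 0):
            raise ValueError("densities must be >= 0")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total_mass_g(self) -> float:
        """Sum of density * bin volume, grams."""
        widths = np.diff(self.bin_edges)
        return float(np.sum(self.density * widths) * self.area * G_CM3_TO_G_NM3)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"z_nm": self.bin_centers, "density_g_cm3": self.density}
        )


@dataclass
class PeakRegion:
    """One super-bulk density peak: [z0, z1] boundaries around the maximum."""

    z0: float
    z1: float
    z_max: float
    amplitude: float  # g/cm^3 at the maximum
    i0: int = field(default=0, repr=False)
    i1: int = field(default=0, repr=False)
    i_max: int = field(default=0, repr=False)


@dataclass
class FirstPeakMass:
    """Integrated water mass under the first near-wall peak."""

    mass_g: float
    mass_g_per_nm2: float
    region: PeakRegion


def density_profile(
    traj: Trajectory,
    species=None,
    bin_width: float = 0.1,
    origin: float = 0.0,
    z_max: float | None = None,
    bulk_density: float | None = None,
    bulk_window: tuple | None = None,
) -> DensityProfile:
    """Frame-averaged slab mass density along z, in g/cm^3.

    Parameters
    ----------
    species : label or list of labels to select (None = all particles).
    origin : z position of the graphene plane (nm); densities are binned in
        z - origin.
    bulk_density : reference bulk density; if None and `bulk_window`
        (z-interval in nm) is given, the mean density over that far-field
        window is used; otherwise 0.997 g/cm^3.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = traj.select(species)
    if not mask.any():
        raise ValueError("species selection matches no particles")
    z = traj.positions[:, mask, 2] - origin
    masses = traj.masses[mask]
    if z_max is None:
        z_max = float(z.max()) + bin_width
    # bins aligned to the origin grid so slab boundaries are reproducible
    z_lo = np.floor(float(z.min()) / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((z_max - z_lo) / bin_width - 1e-9)))
    edges = z_lo + np.arange(n_bins + 1) * bin_width
    # clip the top edge so every particle lands in a bin
    hist = np.zeros(n_bins)
    for frame in z:
        idx = np.clip(((frame - z_lo) / bin_width).astype(int), 0, n_bins - 1)
        hist += np.bincount(idx, weights=masses, minlength=n_bins)
    hist /= traj.n_frames  # mean mass (g/mol) per bin
    vol_cm3 = traj.area_xy * bin_width * 1e-21
    from .constants import AMU_G

    dens = hist * AMU_G / vol_cm3
    if bulk_density is None:
        if bulk_window is not None:
            centers = z_lo + (np.arange(n_bins) + 0.5) * bin_width
            sel = (centers >= bulk_window[0]) & (centers <= bulk_window[1])
            if not sel.any():
                raise ValueError("bulk_window selects no bins")
            bulk_density = float(dens[sel].mean())
        else:
            bulk_density = WATER_BULK_DENSITY
    return DensityProfile(
        bin_edges=edges, density=dens, area=traj.area_xy, bulk_density=bulk_density
    )


def detect_peaks(profile: DensityProfile) -> list[PeakRegion]:
    """Local density maxima above bulk, ordered by distance from the wall.

    Each peak's boundaries sit at the flanking local minima, the points
    where the density crosses below bulk, or the profile ends — whichever
    comes first walking away from the maximum. The walk also stops once the
    per-bin decrease falls below 5% of the peak's prominence, so that a
    noisy plateau does not randomly extend the peak region. Boundary ties
    break toward the wall.
    """
    rho = profile.density
    if len(rho) < 3:
        raise ValueError("need at least 3 bins to detect peaks")
    centers = profile.bin_centers
    maxima = argrelextrema(rho, np.greater_equal, order=1)[0]
    # dedupe plateaus: keep the first index of equal-valued runs
    keep = [m for m in maxima if m == 0 or rho[m] > rho[m - 1] or m - 1 not in maxima]
    peaks = []
    for m in keep:
        if rho[m] < profile.bulk_density or m in (0, len(rho) - 1):
            continue
        tol = 0.05 * max(rho[m] - profile.bulk_density, 0.0)
        i0 = m
        while (
            i0 > 0
            and rho[i0 - 1] <= rho[i0] - tol
            and rho[i0 - 1] >= profile.bulk_density
        ):
            i0 -= 1
        i1 = m
        while (
            i1 < len(rho) - 1
            and rho[i1 + 1] <= rho[i1] - tol
            and rho[i1 + 1] >= profile.bulk_density
        ):
            i1 += 1
        peaks.append(
            PeakRegion(
                z0=centers[i0],
                z1=centers[i1],
                z_max=centers[m],
                amplitude=float(rho[m]),
                i0=i0,
                i1=i1,
                i_max=m,
            )
        )
    # merge duplicates that share a maximum region
    uniq, seen = [], set()
    for p in peaks:
        if p.i_max not in seen:
            uniq.append(p)
            seen.add(p.i_max)
    uniq.sort(key=lambda p: p.z_max)
    return uniq


def water_layer_thickness(profile: DensityProfile, bridge_bins: int = 1) -> float:
    """Thickness t_W of the intercalated water layer, nm.

    t_W is the total width of the contiguous run of bins with density >=
    bulk that contains the first super-bulk peak; isolated sub-bulk dips of
    up to `bridge_bins` bins are bridged over (robustness to sampling
    noise). Returns 0 with a warning if the profile never reaches bulk.
    """
    rho = profile.density
    above = rho >= profile.bulk_density
    if not above.any():
        warnings.warn("density never reaches bulk; t_W = 0", stacklevel=2)
        return 0.0
    # bridge isolated sub-bulk dips
    bridged = above.copy()
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            j = i
            while j < n and not above[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= bridge_bins:
                bridged[i:j] = True
            i = j
        else:
            i += 1
    # contiguous runs of bridged bins
    runs = []
    i = 0
    while i < n:
        if bridged[i]:
            j = i
            while j < n and bridged[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    first_above = int(np.argmax(above))
    for i0, i1 in runs:
        if i0 <= first_above < i1:
            return float((i1 - i0) * profile.bin_width)
    return float((runs[0][1] - runs[0][0]) * profile.bin_width)


def first_peak_mass(profile: DensityProfile) -> FirstPeakMass:
    """Water mass M_1 under the first near-wall density peak.

    Trapezoidal integral of A * rho(z) over [z0, z1] of the peak nearest the
    wall whose amplitude reaches the bulk density.
    """
    peaks = detect_peaks(profile)
    if not peaks:
        raise ValueError("no qualifying peak: no local maximum reaches bulk density")
    p = peaks[0]
    centers = profile.bin_centers
    sl = slice(p.i0, p.i1 + 1)
    integ = np.trapezoid(profile.density[sl], centers[sl])  # g/cm^3 * nm
    mass_per_area = integ * G_CM3_TO_G_NM3  # g per nm^2
    return FirstPeakMass(
        mass_g=float(mass_per_area * profile.area),
        mass_g_per_nm2=float(mass_per_area),
        region=p,
    )
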