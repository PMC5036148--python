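"""Mean-square displacement and Einstein-relation diffusion coefficients.

D = lim_{t->inf} <|r(t) - r(0)|^2> / (2 d_i t), with the ensemble average
taken over particles and over multiple time origins (stride 1). The MSD is
computed with the standard FFT autocorrelation decomposition, which gives
the exact multiple-origin average in O(F log F) per particle and axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory import Trajectory

__all__ = ["MSDCurve", "DiffusionResult", "msd", "diffusion_coefficient"]

_AXES = {1: (0,), 2: (0, 1), 3: (0, 1, 2)}


@dataclass
class MSDCurve:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # nm^2
    d_i: int
    n_origins: np.ndarray  # origins averaged per lag

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"lag_ps": self.lag_times, "msd_nm2": self.msd})


@dataclass
class DiffusionResult:
    """Fitted diffusion coefficient with its standard error."""

    D: float  # nm^2/ps
    stderr: float  # nm^2/ps
    d_i: int
    fit_window: tuple  # (t0_ps, t1_ps) actually used
    negative_slope: bool = False

    @property
    def D_m2_per_s(self) -> float:
        return self.D * 1e-18 / 1e-12

    def to_dict(self) -> dict:
        return {
            "D_nm2_per_ps": self.D,
            "D_m2_per_s": self.D_m2_per_s,
            "stderr_nm2_per_ps": self.stderr,
        }


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """Multiple-time-origin MSD for one batch, r of shape (F, P).

    Returns the per-lag average of (r[t0+m] - r[t0])^2 over all origins t0,
    summed over the particle axis; standard S1 - 2*S2 decomposition with S2
    from the FFT autocorrelation.
    """
    F = r.shape[0]
    nfft = 1 << (2 * F - 1).bit_length()
    fr = np.fft.rfft(r, n=nfft, axis=0)
    acf = np.fft.irfft(fr * np.conj(fr), n=nfft, axis=0)[:F].real  # S2 * counts
    sq = r**2
    ssq = sq.sum(axis=0)
    zeros = np.zeros((1, r.shape[1]))
    prefix = np.concatenate([zeros, np.cumsum(sq, axis=0)])[:F]  # sum_{k<m} sq[k]
    suffix = np.concatenate([zeros, np.cumsum(sq[::-1], axis=0)])[:F]  # sum_{k>=F-m}
    s1 = 2.0 * ssq[None, :] - prefix - suffix
    counts = np.arange(F, 0, -1)[:, None]
    return ((s1 - 2.0 * acf) / counts).sum(axis=1)


def msd(
    traj: Trajectory,
    species=None,
    d_i: int = 3,
    max_lag_fraction: float = 0.5,
    axes: tuple | None = None,
) -> MSDCurve:
    """Ensemble and multiple-time-origin averaged MSD, restricted to d_i axes.

    Coordinates must be unwrapped: a single-step displacement larger than
    half the (periodic) box aborts with an instruction to unwrap first.
    `axes` selects which Cartesian axes span the diffusion space (defaults
    to the first d_i axes).
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for an MSD")
    if axes is None:
        axes = _AXES[d_i]
    elif len(axes) != d_i:
        raise ValueError("len(axes) must equal d_i")
    mask = traj.select(species)
    if not mask.any():
        raise ValueError("species selection matches no particles")
    pos = traj.positions[:, mask, :][:, :, list(axes)]
    if traj.periodic.any():
        jumps = np.abs(np.diff(pos, axis=0))
        half = traj.box[list(axes)] / 2.0
        if np.any(jumps > half[None, None, :]):
            raise ValueError(
                "single-step displacement exceeds half the box: coordinates "
                "appear wrapped; unwrap periodic images before computing the MSD"
            )
    F, P, _ = pos.shape
    total = np.zeros(F)
    for a in range(d_i):
        total += _msd_fft(pos[:, :, a])
    total /= P
    n_lags = max(2, int(np.floor(max_lag_fraction * (F - 1))) + 1)
    n_lags = min(n_lags, F)
    lag = traj.times[:n_lags] - traj.times[0]
    return MSDCurve(
        lag_times=lag,
        msd=total[:n_lags],
        d_i=d_i,
        n_origins=np.arange(F, F - n_lags, -1),
    )


def _resolve_window(curve: MSDCurve, fit_window) -> tuple:
    tmax = curve.lag_times[-1]
    if fit_window is None:
        fit_window = (0.1, 0.5)
    t0, t1 = fit_window
    if t1 <= 1.0 and t0 < 1.0:  # interpret as fractions of max lag
        t0, t1 = t0 * tmax, t1 * tmax
    if t1 > tmax + 1e-12 or t0 >= t1:
        raise ValueError(f"fit window ({t0:g}, {t1:g}) ps outside available lags")
    return t0, t1


def diffusion_coefficient(
    curves: MSDCurve | list,
    fit_window: tuple | None = None,
) -> DiffusionResult:
    """Einstein-relation D from the MSD slope over the fit window.

    fit_window: (t0, t1) in ps, or as fractions of the max lag when both
    are <= 1 (default 10%-50%). A list of curves — independent runs — is
    fitted run by run and averaged; the stderr is then the standard error
    of the run means. A negative fitted slope returns D = 0 with a warning.
    """
    if isinstance(curves, MSDCurve):
        curve = curves
        t0, t1 = _resolve_window(curve, fit_window)
        sel = (curve.lag_times >= t0) & (curve.lag_times <= t1)
        if sel.sum() < 2:
            raise ValueError("fit window contains fewer than 2 lag points")
        res = stats.linregress(curve.lag_times[sel], curve.msd[sel])
        D = res.slope / (2.0 * curve.d_i)
        err = res.stderr / (2.0 * curve.d_i)
        if D < 0:
            warnings.warn("negative MSD slope; returning D = 0", stacklevel=2)
            return DiffusionResult(0.0, err, curve.d_i, (t0, t1), negative_slope=True)
        return DiffusionResult(float(D), float(err), curve.d_i, (t0, t1))
    results = [diffusion_coefficient(c, fit_window) for c in curves]
    ds = np.array([r.D for r in results])
    stderr = ds.std(ddof=1) / np.sqrt(len(ds)) if len(ds) > 1 else results[0].stderr
    return DiffusionResult(
        float(ds.mean()),
        float(stderr),
        results[0].d_i,
        results[0].fit_window,
        negative_slope=all(r.negative_slope for r in results),
    )
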