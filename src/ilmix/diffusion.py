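"""Mean squared displacement, time-averaged MSD, anomalous-diffusion
fitting and the ergodicity-breaking parameter.

Definitions (d = 3 dimensions, lag time Delta in ps):

* MSD(t)       = (1/N) sum_i |r_i(t) - r_i(0)|^2
* TAMSD_i(D)   = mean over all window pairs (T, T+D) of |r_i(T+D) - r_i(T)|^2
* <TAMSD>(D)   = (1/N) sum_i TAMSD_i(D)
* power law      <TAMSD>(D) = K Delta^alpha, with K absorbing the 2d
  factor; both the raw prefactor and the 2d-normalized generalized
  diffusion coefficient K_alpha = K/(2d) are reported
* chi(D)       = Var[TAMSD_i(D)] / Mean[TAMSD_i(D)]^2  (population variance)

alpha = 1 is normal diffusion, alpha < 1 subdiffusion.  For an ergodic
process (Brownian motion, fractional Brownian motion) the MSD and the
particle-averaged TAMSD overlap; continuous-time random walks with
heavy-tailed waits age, and the two curves separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "LagGrid",
    "TamsdResult",
    "DiffusionFit",
    "EBCurve",
    "ErgodicityReport",
    "msd",
    "tamsd",
    "particle_averaged_tamsd",
    "analyze_tamsd",
    "fit_anomalous",
    "eb_parameter",
    "ergodicity_report",
    "k_alpha_to_cm2",
]

DIMENSIONS = 3


@dataclass(frozen=True)
class LagGrid:
    """Lag times Delta (ps) on which TAMSDs are evaluated.

    The default spacing of 25 ps (0.025 ns) matches the analysis the
    curves were designed for; the default maximum lag is half the
    measurement time, beyond which too few windows remain for averaging.
    """

    spacing: float = 25.0  # ps
    max_lag: float | None = None  # ps; None -> half the trajectory span

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("lag spacing must be positive")
        if self.max_lag is not None and self.max_lag < self.spacing:
            raise ValueError("max_lag must be at least the spacing")

    def frame_lags(self, dt: float, n_frames: int, full_window: bool = False) -> np.ndarray:
        """Integer frame lags for a trajectory with uniform frame spacing dt."""
        step = max(1, int(round(self.spacing / dt)))
        span = (n_frames - 1) * dt
        max_lag = self.max_lag if self.max_lag is not None else (
            span if full_window else span / 2.0
        )
        max_frames = min(n_frames - 1, int(np.floor(max_lag / dt)))
        lags = np.arange(step, max_frames + 1, step)
        if len(lags) == 0:
            raise ValueError("lag grid is empty for this trajectory")
        return lags


@dataclass
class TamsdResult:
    lags: np.ndarray  # ps
    per_particle: np.ndarray  # (N, L)
    mean: np.ndarray  # (L,) particle-averaged TAMSD
    msd_times: np.ndarray  # ps
    msd: np.ndarray
    n_particles: int
    measurement_time: float  # ps


@dataclass
class DiffusionFit:
    """Power-law fit <TAMSD>(Delta) = K Delta^alpha (log-log OLS)."""

    alpha: float
    k_raw: float  # raw prefactor, A^2 / ps^alpha
    k_alpha: float  # 2d-normalized generalized diffusion coefficient
    window: tuple[float, float]  # ps
    residual: float  # rms of log residuals
    n_points: int

    def k_alpha_1e6_cm2(self, normalized: bool = True) -> float:
        """K in units of 1e-6 cm^2 s^-alpha."""
        k = self.k_alpha if normalized else self.k_raw
        return k_alpha_to_cm2(k, self.alpha) / 1e-6


def k_alpha_to_cm2(k_a2_ps: float, alpha: float) -> float:
    """Convert a prefactor from A^2/ps^alpha to cm^2/s^alpha."""
    return k_a2_ps * 1e-16 / (1e-12) ** alpha


@dataclass
class EBCurve:
    lags: np.ndarray  # ps
    chi: np.ndarray
    measurement_time: float  # ps


def _uniform_dt(traj: Trajectory) -> float:
    times = traj.times
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trajectory frame spacing is not uniform")
    return float(dts[0])


def _require_unwrapped(traj: Trajectory) -> None:
    if traj.wrapped:
        raise ValueError(
            "displacement analysis needs unwrapped coordinates; call unwrap() first"
        )


def msd(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble MSD from the initial frame: (times, values)."""
    _require_unwrapped(traj)
    coords = traj.coordinates
    disp = coords - coords[0]
    values = np.einsum("fnd,fnd->f", disp, disp) / coords.shape[1]
    times = traj.times - traj.times[0]
    return times, values


def _tamsd_all_lags(coords: np.ndarray) -> np.ndarray:
    """TAMSD at every integer lag for each particle, via FFT.

    coords: (F, N, d) continuous coordinates.  Returns (N, F) where entry
    [i, m] is the mean over the F - m windows of the squared displacement
    at lag m frames.  O(F log F) per particle and dimension.
    """
    f, n, d = coords.shape
    x = np.moveaxis(coords, 0, -1)  # (N, d, F)
    nfft = 1 << int(np.ceil(np.log2(2 * f)))
    fx = np.fft.rfft(x, nfft, axis=-1)
    acf = np.fft.irfft(fx * np.conj(fx), nfft, axis=-1)[..., :f].real  # (N, d, F)
    s2 = acf.sum(axis=1)  # sum over dims -> (N, F)
    sq = (x**2).sum(axis=1)  # (N, F) squared norms per frame
    # S1(m) = sum_{k=0}^{F-m-1} (|r(k)|^2 + |r(k+m)|^2), computed recursively
    out = np.empty((n, f))
    q = 2.0 * sq.sum(axis=1)
    sq_pad = np.concatenate([sq, np.zeros((n, 1))], axis=1)
    for m in range(f):
        if m > 0:
            q = q - sq_pad[:, m - 1] - sq_pad[:, f - m]
        counts = f - m
        out[:, m] = q / counts - 2.0 * s2[:, m] / counts
    return out


def _tamsd_direct(track: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Reference double-loop TAMSD for one track at the given frame lags."""
    out = np.empty(len(lags))
    for k, m in enumerate(lags):
        d = track[m:] - track[:-m] if m > 0 else np.zeros_like(track)
        out[k] = np.einsum("fd,fd->f", d, d).mean() if m > 0 else 0.0
    return out


def tamsd(track: np.ndarray, lags: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """TAMSD of a single track (F, d) at integer frame ``lags``.

    The divisor at lag m is the number of windows, F - m.  Returned
    values correspond to lag times ``lags * dt``.
    """
    track = np.asarray(track, dtype=float)
    lags = np.asarray(lags, dtype=int)
    if np.any(lags < 0) or np.any(lags >= len(track)):
        raise ValueError("lags must be in [0, n_frames)")
    all_lags = _tamsd_all_lags(track[:, None, :])[0]
    return all_lags[lags]


def particle_averaged_tamsd(
    traj: Trajectory, grid: LagGrid | None = None, full_window: bool = False
) -> TamsdResult:
    """Per-particle and particle-averaged TAMSD plus the ensemble MSD."""
    return analyze_tamsd(traj, grid, full_window)


def analyze_tamsd(
    traj: Trajectory, grid: LagGrid | None = None, full_window: bool = False
) -> TamsdResult:
    _require_unwrapped(traj)
    if grid is None:
        grid = LagGrid()
    dt = _uniform_dt(traj)
    coords = traj.coordinates
    lags = grid.frame_lags(dt, len(coords), full_window)
    per_particle = _tamsd_all_lags(coords)[:, lags]
    mean = per_particle.mean(axis=0)
    msd_times, msd_vals = msd(traj)
    span = float(traj.times[-1] - traj.times[0])
    return TamsdResult(
        lags=lags * dt,
        per_particle=per_particle,
        mean=mean,
        msd_times=msd_times,
        msd=msd_vals,
        n_particles=coords.shape[1],
        measurement_time=span,
    )


def fit_anomalous(
    lags: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float] | None = None,
    log_subsample: int | None = 50,
) -> DiffusionFit:
    """OLS of log <TAMSD> on log Delta.

    ``window`` restricts the fit to lag times in [lo, hi] ps.  With
    ``log_subsample`` the lags are thinned to approximately log-uniform
    spacing before the regression so that the dense long-lag end does
    not dominate; pass None to fit the grid as is.
    """
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = lags > 0
    if window is not None:
        mask &= (lags >= window[0]) & (lags <= window[1])
    lags, values = lags[mask], values[mask]
    if len(lags) < 2:
        raise ValueError("fit window contains fewer than 2 lags")
    if np.any(values <= 0):
        raise ValueError("nonpositive TAMSD values in the fit window")
    if log_subsample is not None and len(lags) > log_subsample:
        targets = np.geomspace(lags[0], lags[-1], log_subsample)
        idx = np.unique(np.searchsorted(lags, targets).clip(0, len(lags) - 1))
        lags, values = lags[idx], values[idx]
    slope, intercept = np.polyfit(np.log(lags), np.log(values), 1)
    pred = intercept + slope * np.log(lags)
    residual = float(np.sqrt(np.mean((np.log(values) - pred) ** 2)))
    k_raw = float(np.exp(intercept))
    return DiffusionFit(
        alpha=float(slope),
        k_raw=k_raw,
        k_alpha=k_raw / (2.0 * DIMENSIONS),
        window=(float(lags[0]), float(lags[-1])),
        residual=residual,
        n_points=len(lags),
    )


def eb_parameter(
    per_particle: np.ndarray,
    lags: np.ndarray,
    measurement_time: float = float("nan"),
    sample_variance: bool = False,
) -> EBCurve:
    """Ergodicity-breaking parameter chi(Delta) = Var/Mean^2 over particles.

    Population variance by default (the definitional form); the sample
    (N-1) variance is available behind the flag.
    """
    per_particle = np.asarray(per_particle, dtype=float)
    mean = per_particle.mean(axis=0)
    var = per_particle.var(axis=0, ddof=1 if sample_variance else 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = np.where(mean > 0, var / mean**2, 0.0)
    return EBCurve(lags=np.asarray(lags, dtype=float), chi=chi,
                   measurement_time=measurement_time)


@dataclass
class ErgodicityReport:
    sup_distance: float  # relative sup-distance MSD vs <TAMSD>
    overlap: str  # "ergodic-overlap" | "aging/non-overlap"
    regime: str  # "normal" | "near-normal" | "subdiffusive"
    fit: DiffusionFit
    eb: EBCurve
    tamsd: TamsdResult = field(repr=False)


def ergodicity_report(
    traj: Trajectory,
    grid: LagGrid | None = None,
    overlap_tolerance: float = 0.15,
) -> ErgodicityReport:
    """Compare MSD with the particle-averaged TAMSD and classify.

    The relative sup-distance is evaluated on the common lag window; the
    trajectory is "ergodic-overlap" below ``overlap_tolerance``.  The
    diffusion regime comes from the fitted exponent: normal for
    alpha >= 0.96, subdiffusive below 0.90, near-normal between.
    """
    res = analyze_tamsd(traj, grid)
    dt = _uniform_dt(traj)
    frame_lags = np.round(res.lags / dt).astype(int)
    msd_at_lags = res.msd[frame_lags]
    valid = msd_at_lags > 0
    if not np.any(valid):
        raise ValueError("MSD vanishes on the whole lag window")
    rel = np.abs(res.mean[valid] - msd_at_lags[valid]) / msd_at_lags[valid]
    sup = float(rel.max())
    fit = fit_anomalous(res.lags, res.mean)
    if fit.alpha >= 0.96:
        regime = "normal"
    elif fit.alpha < 0.90:
        regime = "subdiffusive"
    else:
        regime = "near-normal"
    label = "ergodic-overlap" if sup < overlap_tolerance else "aging/non-overlap"
    eb = eb_parameter(res.per_particle, res.lags, res.measurement_time)
    return ErgodicityReport(
        sup_distance=sup, overlap=label, regime=regime, fit=fit, eb=eb, tamsd=res
    )


def tamsd_frame(res: TamsdResult) -> pd.DataFrame:
    return pd.DataFrame({"lag_ps": res.lags, "tamsd_A2": res.mean})
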