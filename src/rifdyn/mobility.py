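"""Ensemble MSD and confined-subdiffusion fitting.

The mean-square displacement of each focus track is measured against the
focus's first observed, drift-corrected position, averaged over tracks per
lag (the ensemble reading of the displacement definition), and fitted with
the confined-subdiffusion model

    MSD(dt) = r_c^2 * (1 - exp(-2 * d * D_c * dt / r_c^2)),   d = 2,

whose short-time slope is ``2*d*D_c`` and whose plateau is ``r_c^2``.  The
ranking value used to order conditions by mobility is ``D_c * r_c / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

DIM = 2


class MsdError(ValueError):
    """No qualifying tracks or invalid MSD input."""


class FitFailureError(RuntimeError):
    """Confined-diffusion fit failed to converge."""


def confined_msd_model(lag_s, d_c: float, r_c: float, d: int = DIM):
    """Confined-subdiffusion MSD (nm^2) at lag(s) in seconds."""
    lag = np.asarray(lag_s, dtype=float)
    return r_c**2 * (1.0 - np.exp(-2.0 * d * d_c * lag / r_c**2))


@dataclass
class MSDCurve:
    """Ensemble MSD versus lag with per-lag SEM and track counts."""

    lag_s: np.ndarray
    msd_nm2: np.ndarray
    sem_nm2: np.ndarray
    n_tracks: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd_nm2 = np.asarray(self.msd_nm2, dtype=float)
        self.sem_nm2 = np.asarray(self.sem_nm2, dtype=float)
        self.n_tracks = np.asarray(self.n_tracks, dtype=int)
        if np.any(np.diff(self.lag_s) <= 0):
            raise MsdError("lags must be strictly increasing")
        if np.any(self.msd_nm2 < 0) or np.any(self.sem_nm2 < 0):
            raise MsdError("MSD and SEM must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "lag_s": self.lag_s,
            "msd_nm2": self.msd_nm2,
            "sem_nm2": self.sem_nm2,
            "n_tracks": self.n_tracks,
        })


def ensemble_msd(positions: np.ndarray, frame_interval_s: float,
                 condition: str = "") -> MSDCurve:
    """MSD of dense tracks given as an ``(n_tracks, n_frames, 2)`` array (nm).

    Fast path for simulated walks: every track contributes every lag, the
    reference is each track's first frame.  Lag 0 (MSD identically zero) is
    included with zero SEM.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 2 or pos.shape[1] < 2:
        raise MsdError(f"expected (n_tracks, n_frames>=2, 2), got {pos.shape}")
    disp = pos[:, 1:, :] - pos[:, :1, :]
    sq = np.einsum("tkc,tkc->tk", disp, disp)
    n = pos.shape[0]
    mean = sq.mean(axis=0)
    sem = sq.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    lags = np.arange(0, pos.shape[1]) * frame_interval_s
    return MSDCurve(
        lag_s=lags,
        msd_nm2=np.concatenate([[0.0], mean]),
        sem_nm2=np.concatenate([[0.0], sem]),
        n_tracks=np.full(pos.shape[1], n),
        condition=condition,
    )


def compute_msd(tracks: pd.DataFrame, frame_interval_s: float = 60.0,
                min_track_length: int = 3, min_tracks_per_lag: int = 10,
                condition: str = "") -> MSDCurve:
    """Ensemble MSD from a linked track table.

    For every track of at least ``min_track_length`` observations, squared
    displacements from the track's first observed (COM-corrected) position
    are accumulated at every available lag; the ensemble mean and SEM are
    taken over tracks per lag.  Lags supported by fewer than
    ``min_tracks_per_lag`` tracks are discarded to avoid tail noise.
    """
    required = {"track_id", "frame", "x_com_nm", "y_com_nm"}
    if missing := required - set(tracks.columns):
        raise KeyError(f"tracks missing required columns: {sorted(missing)}")
    sums: dict[int, list[float]] = {}
    for _, grp in tracks.groupby("track_id", sort=True):
        if len(grp) < min_track_length:
            continue
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        pos = grp[["x_com_nm", "y_com_nm"]].to_numpy(dtype=float)
        disp = pos - pos[0]
        sq = np.einsum("kc,kc->k", disp, disp)
        for lag_frames, value in zip(frames[1:] - frames[0], sq[1:]):
            sums.setdefault(int(lag_frames), []).append(float(value))
    lags = sorted(k for k, v in sums.items() if len(v) >= min_tracks_per_lag)
    if not lags:
        raise MsdError("no qualifying tracks for MSD "
                       f"(min_track_length={min_track_length}, "
                       f"min_tracks_per_lag={min_tracks_per_lag})")
    mean = np.array([np.mean(sums[k]) for k in lags])
    sem = np.array([
        np.std(sums[k], ddof=1) / np.sqrt(len(sums[k])) if len(sums[k]) > 1 else 0.0
        for k in lags])
    n = np.array([len(sums[k]) for k in lags])
    return MSDCurve(
        lag_s=np.concatenate([[0.0], np.array(lags, dtype=float) * frame_interval_s]),
        msd_nm2=np.concatenate([[0.0], mean]),
        sem_nm2=np.concatenate([[0.0], sem]),
        n_tracks=np.concatenate([[n.max()], n]),
        condition=condition,
    )


@dataclass
class SubdiffusionFit:
    """Fitted confined-subdiffusion parameters with uncertainties."""

    d_c: float           #: diffusion coefficient, nm^2/s
    d_c_se: float
    r_c: float           #: confinement radius, nm
    r_c_se: float
    dimension: int = DIM
    rss: float = np.nan
    dof: int = 0
    unconstrained: bool = False  #: no plateau within the observation window
    condition: str = ""

    @property
    def product(self) -> float:
        """Unrounded mobility ranking value ``D_c * r_c / 1000``."""
        return self.d_c * self.r_c / 1000.0

    @property
    def product_rounded(self) -> int:
        return int(round(self.product))

    def predict(self, lag_s):
        return confined_msd_model(lag_s, self.d_c, self.r_c, self.dimension)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "d_c_nm2_per_s": self.d_c,
            "d_c_se": self.d_c_se,
            "r_c_nm": self.r_c,
            "r_c_se": self.r_c_se,
            "dimension": self.dimension,
            "product": self.product,
            "product_rounded": self.product_rounded,
            "rss": self.rss,
            "dof": self.dof,
            "unconstrained": self.unconstrained,
        }


def fit_subdiffusion(curve: MSDCurve, d: int = DIM, n_restarts: int = 5,
                     seed: int = 0) -> SubdiffusionFit:
    """Fit the confined-subdiffusion model to an ensemble MSD curve.

    Weighted nonlinear least squares with weights ``1/SEM^2`` where all SEMs
    are positive (unweighted otherwise); initial guesses ``r_c0 =
    sqrt(max MSD)`` and ``D_c0`` from the first-lag secant slope divided by
    ``2 d``; bounds ``D_c >= 0``, ``r_c > 0``.  Parameter standard errors
    come from the Jacobian covariance.  On failure the fit restarts from
    jittered initial guesses; persistent failure raises
    :class:`FitFailureError`.  A fitted radius far beyond the observed MSD
    plateau (``r_c^2 > 10 * max MSD``) is flagged ``unconstrained``.
    """
    sel = curve.lag_s > 0
    lags = curve.lag_s[sel]
    msd = curve.msd_nm2[sel]
    sem = curve.sem_nm2[sel]
    if len(lags) < 5:
        raise MsdError(f"need >= 5 positive lags to fit, got {len(lags)}")
    if not np.all(np.isfinite(msd)):
        raise MsdError("MSD values must be finite")

    max_msd = float(msd.max())
    if max_msd <= 0:
        raise FitFailureError("MSD is identically zero; nothing to fit")
    r0 = np.sqrt(max_msd)
    dc0 = max(msd[0] / lags[0] / (2.0 * d), 1e-12)
    sigma = sem if np.all(sem > 0) else None

    def model(lag, d_c, r_c):
        return confined_msd_model(lag, d_c, r_c, d)

    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            p0 = (dc0, r0)
        else:
            p0 = (dc0 * rng.uniform(0.3, 3.0), r0 * rng.uniform(0.5, 2.0))
        try:
            popt, pcov = curve_fit(
                model, lags, msd, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
                bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000)
            perr = np.sqrt(np.diag(pcov))
            resid = msd - model(lags, *popt)
            fit = SubdiffusionFit(
                d_c=float(popt[0]), d_c_se=float(perr[0]),
                r_c=float(popt[1]), r_c_se=float(perr[1]),
                dimension=d, rss=float(np.sum(resid**2)), dof=len(lags) - 2,
                unconstrained=bool(popt[1] ** 2 > 10.0 * max_msd),
                condition=curve.condition)
            return fit
        except (RuntimeError, ValueError) as err:  # non-convergence
            last_err = err
    raise FitFailureError(
        f"confined-diffusion fit failed after {n_restarts + 1} starts: {last_err}")


def mobility_product(fit_or_dc, r_c: float | None = None) -> tuple[int, float]:
    """Ranking value ``D_c * r_c / 1000``: (nearest integer, unrounded)."""
    if r_c is None:
        value = fit_or_dc.product
    else:
        value = fit_or_dc * r_c / 1000.0
    return int(round(value)), float(value)
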