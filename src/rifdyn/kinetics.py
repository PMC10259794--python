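"""Time-course statistics of repair foci.

Covers the focus-frequency series (mean foci per nucleus over time, SEM over
nuclei), the dose-additivity prediction for sequential mixed exposures,
linear decay/rise fits, relative-area normalisation, high-order polynomial
kinetics fits on a conditioned time axis, windowed normal fits of the focus
area distribution, and the total / relative focus intensity series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import relative_intensity

#: Doses (Gy) of the mixed-exposure components and of the single exposures
#: they are fractions of: (component dose, full single dose).
DOSE_ALPHA_PAIR = (0.83, 1.7)
DOSE_GAMMA_PAIR = (1.02, 2.0)

#: Focus-area analysis windows, minutes since irradiation start (closed).
EARLY_WINDOW = (0.0, 99.0)
LATE_WINDOW = (100.0, 300.0)


class KineticsError(ValueError):
    pass


@dataclass
class FrequencySeries:
    """Mean foci per nucleus versus time with SEM over nuclei."""

    t_min: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_nuclei: int
    condition: str = ""

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if np.any(np.diff(self.t_min) <= 0):
            raise KineticsError("time grid must be strictly increasing")
        if np.any(self.mean < 0) or np.any(self.sem < 0):
            raise KineticsError("mean and SEM must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition, "t_min": self.t_min,
            "mean": self.mean, "sem": self.sem, "n_nuclei": self.n_nuclei,
        })

    def interp(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of mean and SEM onto a new grid."""
        t = np.asarray(t, dtype=float)
        if t.min() < self.t_min.min() - 1e-9 or t.max() > self.t_min.max() + 1e-9:
            raise KineticsError("interpolation grid extends beyond the recording range")
        return np.interp(t, self.t_min, self.mean), np.interp(t, self.t_min, self.sem)


def focus_frequency_series(observations: pd.DataFrame, n_nuclei: int,
                           t_grid: np.ndarray | None = None,
                           condition: str = "") -> FrequencySeries:
    """Mean foci per nucleus at each time point.

    The mean is the total number of registered foci divided by the number of
    imaged nuclei (nuclei without foci count as zero); the SEM is taken over
    the per-nucleus counts.  ``t_grid`` defaults to the sorted unique
    ``t_min`` values present in ``observations``; a requested time point with
    no recorded frame raises an error.
    """
    if n_nuclei < 1:
        raise KineticsError("n_nuclei must be >= 1")
    if "t_min" not in observations.columns:
        raise KeyError("observations must carry t_min")
    recorded = np.unique(observations["t_min"].to_numpy(dtype=float))
    if t_grid is None:
        t_grid = recorded
        if len(t_grid) == 0:
            raise KineticsError("no observations and no explicit time grid")
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if len(recorded) and (
                t_grid.min() < recorded.min() - 1e-9 or t_grid.max() > recorded.max() + 1e-9):
            raise KineticsError("requested time outside the recording range")

    counts = (observations.groupby(["t_min", "nucleus_id"]).size()
              .unstack(fill_value=0) if len(observations) else pd.DataFrame())
    mean = np.zeros(len(t_grid))
    sem = np.zeros(len(t_grid))
    for i, t in enumerate(t_grid):
        if len(counts) and t in counts.index:
            per_nucleus = counts.loc[t].to_numpy(dtype=float)
        else:
            per_nucleus = np.array([])
        full = np.zeros(n_nuclei)
        full[:len(per_nucleus)] = per_nucleus
        mean[i] = full.sum() / n_nuclei
        sem[i] = full.std(ddof=1) / np.sqrt(n_nuclei) if n_nuclei > 1 else 0.0
    return FrequencySeries(t_grid, mean, sem, n_nuclei, condition)


def additivity_prediction(series_alpha: FrequencySeries, series_gamma: FrequencySeries,
                          series_control: FrequencySeries,
                          dose_alpha_pair: tuple[float, float] = DOSE_ALPHA_PAIR,
                          dose_gamma_pair: tuple[float, float] = DOSE_GAMMA_PAIR,
                          ) -> FrequencySeries:
    """Expected mixed-beam focus frequency under the additivity assumption.

    The excess over control of each single-radiation response is scaled by
    the dose fraction its component contributes to the mixed exposure:

        predicted(t) = control(t)
                     + (D_a / D_A) * [alpha(t) - control(t)]
                     + (D_g / D_G) * [gamma(t) - control(t)]

    SEMs are propagated in quadrature with the same weights.  All three
    series are linearly interpolated onto the union of their grids inside the
    common time range first.
    """
    w_a = dose_alpha_pair[0] / dose_alpha_pair[1]
    w_g = dose_gamma_pair[0] / dose_gamma_pair[1]
    t_lo = max(s.t_min.min() for s in (series_alpha, series_gamma, series_control))
    t_hi = min(s.t_min.max() for s in (series_alpha, series_gamma, series_control))
    if t_lo > t_hi:
        raise KineticsError("series do not share a common time range")
    grid = np.unique(np.concatenate([
        s.t_min[(s.t_min >= t_lo) & (s.t_min <= t_hi)]
        for s in (series_alpha, series_gamma, series_control)]))
    a, a_sem = series_alpha.interp(grid)
    g, g_sem = series_gamma.interp(grid)
    c, c_sem = series_control.interp(grid)
    pred = c + w_a * (a - c) + w_g * (g - c)
    var = ((1.0 - w_a - w_g) * c_sem) ** 2 + (w_a * a_sem) ** 2 + (w_g * g_sem) ** 2
    return FrequencySeries(grid, np.maximum(pred, 0.0), np.sqrt(var),
                           n_nuclei=min(series_alpha.n_nuclei, series_gamma.n_nuclei,
                                        series_control.n_nuclei),
                           condition="predicted_additive")


@dataclass
class LinearFit:
    """Ordinary least-squares line ``y = a t + b`` over a time window."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    window: tuple[float, float]
    n: int

    @property
    def dof(self) -> int:
        return self.n - 2

    def predict(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept


def fit_linear(series: FrequencySeries, window: tuple[float, float]) -> LinearFit:
    """OLS fit of the series mean against time inside ``window`` (closed)."""
    t0, t1 = window
    sel = (series.t_min >= t0) & (series.t_min <= t1)
    if sel.sum() < 3:
        raise KineticsError(f"need >= 3 points in window {window}, got {int(sel.sum())}")
    t = series.t_min[sel]
    y = series.mean[sel]
    res = sps.linregress(t, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.stderr), float(res.intercept_stderr),
                     window, int(sel.sum()))


def relative_area(areas) -> np.ndarray:
    """Areas divided by the maximum area recorded for the treatment."""
    arr = np.asarray(areas, dtype=float)
    if arr.size == 0:
        raise KineticsError("empty area list")
    if np.any(arr <= 0):
        raise KineticsError("areas must be > 0")
    return arr / arr.max()


@dataclass
class PolynomialFit:
    """Least-squares polynomial on a time axis affinely mapped to [-1, 1].

    ``coeffs`` are in descending powers of the scaled variable; the mapping
    is a pure reparameterisation and predictions are returned on the original
    minute axis.
    """

    order: int
    coeffs: np.ndarray
    coeff_se: np.ndarray
    domain: tuple[float, float]

    def _scale(self, t):
        t0, t1 = self.domain
        return 2.0 * (np.asarray(t, dtype=float) - t0) / (t1 - t0) - 1.0

    def predict(self, t):
        return np.polyval(self.coeffs, self._scale(t))


def _fit_polynomial(t, y, order: int) -> PolynomialFit:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < order + 2:
        raise KineticsError(f"need >= {order + 2} points for an order-{order} fit, got {len(t)}")
    t0, t1 = float(t.min()), float(t.max())
    if t1 <= t0:
        raise KineticsError("degenerate time axis")
    s = 2.0 * (t - t0) / (t1 - t0) - 1.0
    if len(t) >= order + 3:
        coeffs, cov = np.polyfit(s, y, order, cov=True)
        se = np.sqrt(np.diag(cov))
    else:  # exactly order+2 points: covariance is singular, report zeros
        coeffs = np.polyfit(s, y, order)
        se = np.zeros_like(coeffs)
    if not np.all(np.isfinite(coeffs)):
        raise KineticsError("polynomial fit produced non-finite coefficients")
    return PolynomialFit(order, coeffs, se, (t0, t1))


def fit_area_polynomial(t_min, mean_area, order: int = 8) -> PolynomialFit:
    """Order-8 polynomial describing mean focus area versus time."""
    return _fit_polynomial(t_min, mean_area, order)


def fit_intensity_polynomial(t_min, mean_intensity, order: int = 6) -> PolynomialFit:
    """Order-6 polynomial describing total focus intensity versus time."""
    return _fit_polynomial(t_min, mean_intensity, order)


@dataclass
class AreaWindowFit:
    """Normal fit of the per-focus area distribution in a time window."""

    window: tuple[float, float]
    mu_um2: float
    sigma_um2: float
    n_foci: int
    degenerate: bool = False  #: sigma collapsed to ~0 (constant areas)


def area_window_fit(observations: pd.DataFrame,
                    window: tuple[float, float] = EARLY_WINDOW,
                    min_foci: int = 10) -> AreaWindowFit:
    """Fit a normal distribution to per-focus areas inside a time window.

    Maximum likelihood on the raw areas (sample mean and standard
    deviation), i.e. no histogram binning enters the estimate.
    """
    t0, t1 = window
    sel = (observations["t_min"] >= t0) & (observations["t_min"] <= t1)
    areas = observations.loc[sel, "area_um2"].to_numpy(dtype=float)
    if len(areas) < min_foci:
        raise KineticsError(
            f"too few foci in window {window}: {len(areas)} < {min_foci}")
    mu, sigma = float(np.mean(areas)), float(np.std(areas))
    degenerate = sigma < 1e-12 * max(abs(mu), 1.0)
    return AreaWindowFit(window, mu, sigma, len(areas), degenerate)


def total_intensity_series(observations: pd.DataFrame, nuclei: pd.DataFrame,
                           condition: str = "") -> FrequencySeries:
    """Mean total focus intensity per nucleus versus time.

    Per nucleus and frame, focus intensities are summed; nuclei with no
    detected foci contribute zero.  The mean and SEM are across nuclei.
    """
    nucleus_ids = np.sort(nuclei["nucleus_id"].unique())
    n_nuclei = len(nucleus_ids)
    if n_nuclei == 0:
        raise KineticsError("no nuclei")
    grid = np.sort(nuclei["t_min"].unique())
    totals = (observations.groupby(["t_min", "nucleus_id"])["intensity_au"].sum()
              if len(observations) else pd.Series(dtype=float))
    mean = np.zeros(len(grid))
    sem = np.zeros(len(grid))
    for i, t in enumerate(grid):
        per = np.zeros(n_nuclei)
        if len(totals) and t in totals.index.get_level_values(0):
            sub = totals.loc[t]
            for j, nid in enumerate(nucleus_ids):
                if nid in sub.index:
                    per[j] = sub.loc[nid]
        mean[i] = per.mean()
        sem[i] = per.std(ddof=1) / np.sqrt(n_nuclei) if n_nuclei > 1 else 0.0
    return FrequencySeries(grid, mean, sem, n_nuclei, condition)


def relative_intensity_series(observations: pd.DataFrame, nuclei: pd.DataFrame,
                              condition: str = "") -> FrequencySeries:
    """Mean relative focus intensity ``I_focus / (I_nucleus - I_focus)`` vs time.

    The ratio is formed per nucleus and frame and then averaged across
    nuclei.  Frames where the summed focus intensity reaches the whole-
    nucleus intensity are skipped with a warning.
    """
    nuc = nuclei.set_index(["nucleus_id", "frame"])
    totals = (observations.groupby(["nucleus_id", "frame"])["intensity_au"].sum()
              if len(observations) else pd.Series(dtype=float))
    rows: dict[float, list[float]] = {}
    for (nid, frame), row in nuc.iterrows():
        i_focus = float(totals.get((nid, frame), 0.0))
        i_nucleus = float(row["i_nucleus"])
        t = float(row["t_min"])
        if i_nucleus <= i_focus:
            warnings.warn(
                f"nucleus {nid} frame {frame}: focus intensity >= nucleus intensity; "
                "frame skipped", RuntimeWarning, stacklevel=2)
            continue
        rows.setdefault(t, []).append(relative_intensity(i_focus, i_nucleus))
    if not rows:
        raise KineticsError("no frames with a defined relative intensity")
    grid = np.array(sorted(rows))
    mean = np.array([np.mean(rows[t]) for t in grid])
    sem = np.array([
        np.std(rows[t], ddof=1) / np.sqrt(len(rows[t])) if len(rows[t]) > 1 else 0.0
        for t in grid])
    n = int(nuclei["nucleus_id"].nunique())
    return FrequencySeries(grid, np.maximum(mean, 0.0), sem, n, condition)
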