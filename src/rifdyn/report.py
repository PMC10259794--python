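"""Figure-style plots and summary tables for a pipeline run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering for CLI / batch use

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .kinetics import FrequencySeries
from .mobility import MSDCurve, SubdiffusionFit

_COLOURS = {
    "control": "0.5", "alpha": "tab:red", "gamma": "tab:blue",
    "alpha_then_gamma": "tab:orange", "gamma_then_alpha": "tab:purple",
    "predicted_additive": "black",
}


def _series_style(condition: str) -> dict:
    style = {"color": _COLOURS.get(condition, None), "label": condition}
    if condition == "predicted_additive":
        style["linestyle"] = "--"
    return style


def plot_frequency(series: dict[str, FrequencySeries], path) -> Path:
    """Focus frequency vs time with SEM corridors; additivity dashed."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond, s in series.items():
        style = _series_style(cond)
        ax.plot(s.t_min, s.mean, **style)
        ax.fill_between(s.t_min, s.mean - s.sem, s.mean + s.sem,
                        color=style["color"], alpha=0.2, linewidth=0)
    ax.set_xlabel("time since irradiation start (min)")
    ax.set_ylabel("mean foci per nucleus")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_intensity(series: dict[str, FrequencySeries], path,
                   ylabel: str = "total focus intensity (a.u.)") -> Path:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond, s in series.items():
        style = _series_style(cond)
        ax.plot(s.t_min, s.mean, **style)
        ax.fill_between(s.t_min, s.mean - s.sem, s.mean + s.sem,
                        color=style["color"], alpha=0.2, linewidth=0)
    ax.set_xlabel("time since irradiation start (min)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_msd(curves: dict[str, MSDCurve], fits: dict[str, SubdiffusionFit], path) -> Path:
    """Ensemble MSD per condition with confined-subdiffusion fit lines."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond, c in curves.items():
        style = _series_style(cond)
        ax.errorbar(c.lag_s / 60.0, c.msd_nm2 / 1e6, yerr=c.sem_nm2 / 1e6,
                    fmt=".", ms=3, alpha=0.6, color=style["color"], label=cond)
        fit = fits.get(cond)
        if fit is not None:
            grid = np.linspace(0, c.lag_s.max(), 200)
            ax.plot(grid / 60.0, fit.predict(grid) / 1e6, color=style["color"])
    ax.set_xlabel("lag (min)")
    ax.set_ylabel(r"MSD ($\mu m^2$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def summary_tables(results: dict[str, dict]) -> dict[str, pd.DataFrame]:
    """Tables summarising frequencies, area windows and mobility fits."""
    freq_rows, area_rows, fit_rows = [], [], []
    for cond, res in results.items():
        s = res.get("frequency")
        if s is not None and len(s.t_min):
            freq_rows.append({
                "condition": cond,
                "start_mean": s.mean[0], "start_sem": s.sem[0],
                "peak_mean": s.mean.max(),
                "peak_t_min": s.t_min[int(np.argmax(s.mean))],
                "end_mean": s.mean[-1], "end_sem": s.sem[-1],
            })
        for label in ("early", "late"):
            fitw = res.get(f"area_{label}")
            if fitw is not None:
                area_rows.append({
                    "condition": cond, "window": label,
                    "mu_um2": fitw.mu_um2, "sigma_um2": fitw.sigma_um2,
                    "n_foci": fitw.n_foci,
                })
        sd = res.get("subdiffusion")
        if sd is not None:
            fit_rows.append(sd.to_dict())
    tables = {
        "frequency_summary": pd.DataFrame(freq_rows),
        "area_windows": pd.DataFrame(area_rows),
        "mobility_fits": pd.DataFrame(fit_rows),
    }
    if len(tables["mobility_fits"]):
        tables["mobility_fits"] = tables["mobility_fits"].sort_values(
            "product", ascending=False).reset_index(drop=True)
    return tables


def render_report(results: dict[str, dict], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    freq = {c: r["frequency"] for c, r in results.items() if r.get("frequency") is not None}
    if freq:
        written.append(plot_frequency(freq, outdir / "frequency.png"))
    total = {c: r["total_intensity"] for c, r in results.items()
             if r.get("total_intensity") is not None}
    if total:
        written.append(plot_intensity(total, outdir / "total_intensity.png"))
    rel = {c: r["relative_intensity"] for c, r in results.items()
           if r.get("relative_intensity") is not None}
    if rel:
        written.append(plot_intensity(rel, outdir / "relative_intensity.png",
                                      ylabel="relative focus intensity"))
    curves = {c: r["msd"] for c, r in results.items() if r.get("msd") is not None}
    fits = {c: r["subdiffusion"] for c, r in results.items()
            if r.get("subdiffusion") is not None}
    if curves:
        written.append(plot_msd(curves, fits, outdir / "msd.png"))
    for name, table in summary_tables(results).items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    return written
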