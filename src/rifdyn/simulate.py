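"""Synthetic time-lapse movies of DNA-repair foci in interphase nuclei.

The generator emulates live-cell recordings of GFP-tagged repair foci after
exposure to densely ionising (alpha) and/or sparsely ionising (gamma)
radiation, applied alone or sequentially in either order:

* per-nucleus focus counts are Poisson with a condition-specific mean at the
  start of recording; alpha-like foci cluster along straight particle-traversal
  chords, gamma-like foci are dispersed uniformly in the nucleus;
* focus lifetimes follow a two-population exponential mixture (fast-decaying
  "simple" damage vs slow "complex" damage);
* focus motion is a stationary per-axis Ornstein-Uhlenbeck (OU) process whose
  exact ensemble mean-square displacement equals the confined-subdiffusion
  model ``MSD(dt) = r_c^2 (1 - exp(-2 d D_c dt / r_c^2))`` with ``d = 2``;
* frames are rendered as an elliptical nucleus (with whole-nucleus drift)
  plus one 2-D Gaussian spot per live focus, with Poisson shot noise and
  Gaussian read noise, quantised to 16-bit.

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical config and seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

DIM = 2  #: dimensionality of the analysed space (2-D widefield imaging)

CONDITIONS = ("control", "alpha", "gamma", "alpha_then_gamma", "gamma_then_alpha")

#: Fitted confined-diffusion parameters (D_c nm^2/s, r_c nm) measured per
#: condition in live U2OS cells; used as generative motion presets.
MOTION_PRESETS: dict[str, tuple[float, float]] = {
    "gamma_then_alpha": (349.0, 1014.0),
    "alpha": (242.1, 980.5),
    "alpha_then_gamma": (240.8, 897.0),
    "gamma": (206.0, 961.4),
    "control": (206.0, 961.4),  # background foci move like gamma-induced ones
}

#: Mean foci per nucleus at the start of recording, per condition.
INITIAL_COUNT_PRESETS: dict[str, float] = {
    "control": 1.0,
    "alpha": 17.1,
    "gamma": 30.9,
    "alpha_then_gamma": 28.3,
    "gamma_then_alpha": 25.2,
}

#: Minutes between the start of irradiation and the first recorded frame
#: (exposure duration plus ~4 min of live-cell chamber assembly); with 1-based
#: frame indices the first mixed-beam frame lands on minute 16.
RECORDING_OFFSET_PRESETS: dict[str, float] = {
    "control": 4.0,
    "alpha": 11.5,
    "gamma": 9.6,
    "alpha_then_gamma": 15.0,
    "gamma_then_alpha": 15.0,
}

# Dose shares of the mixed exposure: 0.83 Gy alpha + 1.02 Gy gamma = 1.85 Gy.
MIXED_ALPHA_SHARE = round(0.83 / 1.85, 3)   # 0.449
MIXED_GAMMA_SHARE = round(1.02 / 1.85, 3)   # 0.551


class SimulationError(ValueError):
    """Invalid simulation configuration or inputs."""


@dataclass(frozen=True)
class MotionParams:
    """Confined-diffusion motion parameters of one focus subpopulation."""

    d_c: float  #: diffusion coefficient, nm^2/s
    r_c: float  #: confinement (diffusion) radius, nm

    def __post_init__(self) -> None:
        if self.d_c < 0:
            raise SimulationError(f"d_c must be >= 0, got {self.d_c}")
        if self.r_c <= 0:
            raise SimulationError(f"r_c must be > 0, got {self.r_c}")


@dataclass(frozen=True)
class FocusOptics:
    """Rendered appearance of a focus: peak amplitude and spot width."""

    amplitude_mean: float  #: peak counts above local background, a.u.
    amplitude_sd: float
    psf_sigma_mean_nm: float  #: Gaussian spot sigma, nm
    psf_sigma_sd_nm: float

    def __post_init__(self) -> None:
        for name in ("amplitude_mean", "amplitude_sd", "psf_sigma_mean_nm", "psf_sigma_sd_nm"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


#: Appearance presets: dispersed (gamma-like) foci are dimmer and smaller,
#: chord-clustered (alpha-like) foci brighter and slightly larger.
DISPERSED_OPTICS = FocusOptics(350.0, 50.0, 78.0, 6.0)
CLUSTERED_OPTICS = FocusOptics(550.0, 80.0, 105.0, 10.0)


@dataclass(frozen=True)
class SubpopulationParams:
    """One focus subpopulation: decay, motion, placement and appearance.

    ``placement`` is ``"dispersed"`` (uniform in the nucleus, low-LET-like) or
    ``"clustered"`` (along particle-traversal chords, high-LET-like).
    ``area_mean_um2``/``area_sd_um2`` parameterise the normal distribution of
    ground-truth focus areas carried in the output tables.
    """

    label: str
    weight: float
    decay_rate_per_min: float
    motion: MotionParams
    placement: str = "dispersed"
    area_mean_um2: float = 0.25
    area_sd_um2: float = 0.05
    optics: FocusOptics = DISPERSED_OPTICS

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise SimulationError(f"subpopulation weight must be in [0, 1], got {self.weight}")
        if self.decay_rate_per_min < 0:
            raise SimulationError("decay rate must be >= 0")
        if self.placement not in ("dispersed", "clustered"):
            raise SimulationError(f"unknown placement {self.placement!r}")
        if self.area_mean_um2 <= 0 or self.area_sd_um2 < 0:
            raise SimulationError("area distribution parameters must be positive")


@dataclass(frozen=True)
class AlphaGeometry:
    """Geometry of alpha-particle traversals through the imaged plane."""

    foci_per_traversal: float = 3.0   #: mean foci induced along one chord
    chord_spacing_nm: float = 1200.0  #: mean along-chord spacing between foci
    spacing_jitter_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.foci_per_traversal <= 0:
            raise SimulationError("foci_per_traversal must be > 0")
        if self.chord_spacing_nm < 0 or self.spacing_jitter_frac < 0:
            raise SimulationError("spacing parameters must be >= 0")


@dataclass(frozen=True)
class NucleusGeometry:
    """Elliptical nucleus: semi-axes (nm) and in-plane orientation (rad)."""

    a_nm: float
    b_nm: float
    phi_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.a_nm <= 0 or self.b_nm <= 0:
            raise SimulationError("nucleus semi-axes must be > 0")

    @property
    def area_um2(self) -> float:
        return np.pi * self.a_nm * self.b_nm / 1e6


@dataclass(frozen=True)
class SimulationConfig:
    """Full ground-truth parameterisation of one synthetic experiment."""

    condition: str
    initial_count_mean: float
    subpopulations: tuple[SubpopulationParams, ...]
    recording_start_offset_min: float
    n_nuclei: int = 10
    frame_interval_s: float = 60.0
    n_frames: int = 300
    pixel_size_nm: float = 100.0
    image_shape: tuple[int, int] = (256, 256)
    nucleus_semi_axes_nm: tuple[float, float] = (6000.0, 4000.0)
    nucleus_axis_jitter: float = 0.08
    alpha_geometry: AlphaGeometry = AlphaGeometry()
    camera_offset: float = 100.0       #: counts outside the nucleus
    background_level: float = 400.0    #: counts inside the nucleus
    read_noise_sd: float = 10.0
    poisson_noise: bool = True
    nucleus_drift_step_nm: float = 20.0
    birth_rate_per_min: float = 0.0    #: new background foci per nucleus per min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SimulationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.n_frames < 2:
            raise SimulationError("n_frames must be >= 2")
        if self.n_nuclei < 1:
            raise SimulationError("n_nuclei must be >= 1")
        for name in (
            "initial_count_mean", "recording_start_offset_min", "frame_interval_s",
            "pixel_size_nm", "camera_offset", "background_level", "read_noise_sd",
            "nucleus_drift_step_nm", "birth_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if any(ax <= 0 for ax in self.nucleus_semi_axes_nm):
            raise SimulationError("nucleus semi-axes must be > 0")
        total = sum(s.weight for s in self.subpopulations)
        if not self.subpopulations or abs(total - 1.0) > 1e-9:
            raise SimulationError(f"subpopulation weights must sum to 1, got {total}")

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    def frame_times_min(self) -> np.ndarray:
        """Minutes since irradiation start for 1-based frames 1..n_frames."""
        return self.recording_start_offset_min + np.arange(1, self.n_frames + 1) * self.frame_interval_min

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _condition_subpopulations(condition: str) -> tuple[SubpopulationParams, ...]:
    motion = MotionParams(*MOTION_PRESETS[condition])
    if condition == "control":
        return (
            SubpopulationParams("background", 1.0, 0.02, motion,
                                "dispersed", 0.219, 0.035, DISPERSED_OPTICS),
        )
    if condition == "gamma":
        return (
            SubpopulationParams("simple", 0.8, 0.006, motion,
                                "dispersed", 0.219, 0.035, DISPERSED_OPTICS),
            SubpopulationParams("complex", 0.2, 0.0005, motion,
                                "dispersed", 0.210, 0.043, DISPERSED_OPTICS),
        )
    if condition == "alpha":
        return (
            SubpopulationParams("simple", 0.5, 0.03, motion,
                                "clustered", 0.513, 0.045, CLUSTERED_OPTICS),
            SubpopulationParams("complex", 0.5, 0.007, motion,
                                "clustered", 0.32, 0.11, CLUSTERED_OPTICS),
        )
    if condition == "alpha_then_gamma":
        return (
            SubpopulationParams("gamma_simple", MIXED_GAMMA_SHARE, 0.01, motion,
                                "dispersed", 0.348, 0.052, DISPERSED_OPTICS),
            SubpopulationParams("alpha_complex", MIXED_ALPHA_SHARE, 0.0006, motion,
                                "clustered", 0.60, 0.14, CLUSTERED_OPTICS),
        )
    if condition == "gamma_then_alpha":
        return (
            SubpopulationParams("gamma_simple", MIXED_GAMMA_SHARE, 0.012, motion,
                                "dispersed", 0.220, 0.025, DISPERSED_OPTICS),
            SubpopulationParams("alpha_complex", MIXED_ALPHA_SHARE, 0.002, motion,
                                "clustered", 0.262, 0.086, CLUSTERED_OPTICS),
        )
    raise SimulationError(f"unknown condition {condition!r}")


def make_condition_preset(condition: str, **overrides) -> SimulationConfig:
    """Return the fully populated default config for one treatment condition.

    Presets carry the measured per-condition start-of-recording focus counts,
    confined-diffusion motion parameters and recording-start offsets; decay
    mixtures are calibrated so that expected counts at the end of the 300-min
    recording match the observed end-of-observation means (see docs/methods.md).

    Parameters
    ----------
    condition:
        One of ``control, alpha, gamma, alpha_then_gamma, gamma_then_alpha``.
    **overrides:
        Any :class:`SimulationConfig` field, e.g. ``n_frames=60, seed=7``.
    """
    if condition not in CONDITIONS:
        raise SimulationError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    cfg = SimulationConfig(
        condition=condition,
        initial_count_mean=INITIAL_COUNT_PRESETS[condition],
        subpopulations=_condition_subpopulations(condition),
        recording_start_offset_min=RECORDING_OFFSET_PRESETS[condition],
    )
    return cfg.replace(**overrides) if overrides else cfg


def expected_count(config: SimulationConfig, t_since_recording_min) -> np.ndarray:
    """Expected live foci per nucleus, ``M * sum_i w_i exp(-lambda_i t)``."""
    t = np.asarray(t_since_recording_min, dtype=float)
    out = np.zeros_like(t)
    for sub in config.subpopulations:
        out = out + sub.weight * np.exp(-sub.decay_rate_per_min * t)
    return config.initial_count_mean * out


# ---------------------------------------------------------------------------
# focus field sampling
# ---------------------------------------------------------------------------

def sample_nucleus_geometry(config: SimulationConfig, rng: np.random.Generator) -> NucleusGeometry:
    """Draw one nucleus: jittered semi-axes, uniform random orientation."""
    j = config.nucleus_axis_jitter
    a0, b0 = config.nucleus_semi_axes_nm
    a = a0 * (1.0 + rng.uniform(-j, j))
    b = b0 * (1.0 + rng.uniform(-j, j))
    return NucleusGeometry(a, b, rng.uniform(0.0, np.pi))


def _rotate(xy: np.ndarray, phi: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    return xy @ rot.T


def _uniform_in_ellipse(n: int, geom: NucleusGeometry, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside the rotated ellipse, nm, centre-of-mass frame."""
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    th = rng.uniform(0.0, 2 * np.pi, n)
    xy = np.column_stack([geom.a_nm * r * np.cos(th), geom.b_nm * r * np.sin(th)])
    return _rotate(xy, geom.phi_rad)


def _chord_positions(k: int, geom: NucleusGeometry, ageo: AlphaGeometry,
                     rng: np.random.Generator) -> np.ndarray:
    """Place ``k`` collinear foci along one random traversal chord.

    The chord is sampled in the unit-circle space of the ellipse (random
    direction, uniform offset) and mapped back, so it is always a straight
    segment with both endpoints on the nuclear envelope.  Foci are laid out at
    the configured along-chord spacing around a uniformly chosen anchor and
    clamped to the chord, which keeps the total count (and hence the Poisson
    mean) intact for short chords at the price of locally compressed spacing.
    """
    psi = rng.uniform(0.0, 2 * np.pi)
    u = rng.uniform(-1.0, 1.0)           # offset of the chord in unit-circle space
    half = np.sqrt(max(1.0 - u * u, 0.0))
    n_hat = np.array([np.cos(psi), np.sin(psi)])
    t_hat = np.array([-np.sin(psi), np.cos(psi)])
    p1u, p2u = u * n_hat - half * t_hat, u * n_hat + half * t_hat
    scale = np.array([geom.a_nm, geom.b_nm])
    p1 = _rotate((p1u * scale)[None, :], geom.phi_rad)[0]
    p2 = _rotate((p2u * scale)[None, :], geom.phi_rad)[0]
    length = float(np.linalg.norm(p2 - p1))
    direction = (p2 - p1) / max(length, 1e-9)
    s = ageo.chord_spacing_nm
    offsets = (np.arange(k) - (k - 1) / 2.0) * s
    if ageo.spacing_jitter_frac > 0 and s > 0:
        offsets = offsets + rng.normal(0.0, ageo.spacing_jitter_frac * s, k)
    span = offsets.max() - offsets.min() if k > 1 else 0.0
    if span < length:  # place the whole run inside the chord at full spacing
        anchor = rng.uniform(-offsets.min(), length - offsets.max())
        along = anchor + offsets
    elif k > 1:  # chord shorter than the run: spread evenly (compressed spacing)
        along = np.linspace(0.0, length, k)
    else:
        along = np.array([length / 2.0])
    return p1[None, :] + along[:, None] * direction[None, :]


def _draw_truncated_normal(mean, sd, lo, n, rng):
    out = rng.normal(mean, sd, n)
    return np.maximum(out, lo)


def sample_focus_field(config: SimulationConfig, geometry: NucleusGeometry,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Sample the foci present in one nucleus at the start of recording.

    Dispersed (gamma-like) subpopulations contribute ``Poisson(M * w)`` foci
    uniformly inside the nucleus; clustered (alpha-like) subpopulations
    contribute a Poisson number of traversal chords each carrying a Poisson
    number of collinear foci, so the total clustered mean is ``M * w`` too.

    Returns a frame with one row per focus: ``focus_id, subpop, chord_id,
    x_nm, y_nm`` (nucleus-COM frame), ``area_um2, psf_sigma_nm, amplitude,
    birth_min`` (birth at the start of recording).
    """
    if geometry.a_nm <= 0 or geometry.b_nm <= 0:
        raise SimulationError("empty nucleus mask: non-positive semi-axes")
    mean_total = config.initial_count_mean

    rows: list[dict] = []
    dispersed = [s for s in config.subpopulations if s.placement == "dispersed"]
    clustered = [s for s in config.subpopulations if s.placement == "clustered"]

    def _append(positions: np.ndarray, subs: Sequence[SubpopulationParams],
                weights: np.ndarray, chord_id: int) -> None:
        n = len(positions)
        if n == 0:
            return
        idx = rng.choice(len(subs), size=n, p=weights)
        for i in range(n):
            sub = subs[idx[i]]
            rows.append({
                "subpop": sub.label,
                "chord_id": chord_id,
                "x_nm": positions[i, 0],
                "y_nm": positions[i, 1],
                "area_um2": float(_draw_truncated_normal(
                    sub.area_mean_um2, sub.area_sd_um2, 0.02, 1, rng)[0]),
                "psf_sigma_nm": float(_draw_truncated_normal(
                    sub.optics.psf_sigma_mean_nm, sub.optics.psf_sigma_sd_nm, 40.0, 1, rng)[0]),
                "amplitude": float(_draw_truncated_normal(
                    sub.optics.amplitude_mean, sub.optics.amplitude_sd,
                    0.1 * sub.optics.amplitude_mean, 1, rng)[0]),
            })

    if dispersed:
        w = np.array([s.weight for s in dispersed])
        n_disp = rng.poisson(mean_total * w.sum())
        _append(_uniform_in_ellipse(n_disp, geometry, rng), dispersed, w / w.sum(), -1)

    if clustered:
        w = np.array([s.weight for s in clustered])
        mean_clustered = mean_total * w.sum()
        m = config.alpha_geometry.foci_per_traversal
        n_chords = rng.poisson(mean_clustered / m)
        for chord in range(n_chords):
            k = rng.poisson(m)
            if k == 0:
                continue
            pos = _chord_positions(k, geometry, config.alpha_geometry, rng)
            _append(pos, clustered, w / w.sum(), chord)

    df = pd.DataFrame(rows, columns=["subpop", "chord_id", "x_nm", "y_nm",
                                     "area_um2", "psf_sigma_nm", "amplitude"])
    df.insert(0, "focus_id", np.arange(len(df), dtype=int))
    # Condition means are defined at the first recorded frame, so foci are
    # born (and their memoryless decay clock starts) exactly there.
    df["birth_min"] = config.recording_start_offset_min + config.frame_interval_min
    return df


def assign_lifetimes(field: pd.DataFrame, config: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw an exponential lifetime per focus from its subpopulation rate.

    ``death_min = birth_min + Exp(rate)``; a zero rate yields an infinite
    lifetime (the focus persists to the final frame).  The resulting expected
    per-nucleus count curve is ``M * sum_i w_i exp(-lambda_i t)`` with ``t``
    minutes since recording start.
    """
    rates = {s.label: s.decay_rate_per_min for s in config.subpopulations}
    unknown = set(field["subpop"]) - set(rates)
    if unknown:
        raise SimulationError(f"foci with unknown subpopulation labels: {sorted(unknown)}")
    out = field.copy()
    lifetimes = np.empty(len(out))
    for i, (sub, birth) in enumerate(zip(out["subpop"], out["birth_min"])):
        lam = rates[sub]
        if lam < 0:
            raise SimulationError("negative decay rate")
        lifetimes[i] = np.inf if lam == 0 else rng.exponential(1.0 / lam)
    out["death_min"] = out["birth_min"].to_numpy() + lifetimes
    return out


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def simulate_confined_walk(d_c: float, r_c: float, n_frames: int, dt_s: float,
                           rng: np.random.Generator, n_tracks: int = 1) -> np.ndarray:
    """Simulate stationary confined random walks (exact discrete-time OU).

    Each axis follows an Ornstein-Uhlenbeck process with relaxation rate
    ``theta = 2 * DIM * d_c / r_c**2`` and stationary standard deviation
    ``r_c / 2``, using the exact transition ``x' = x e^{-theta dt} +
    N(0, sigma^2 (1 - e^{-2 theta dt}))`` (no Euler discretisation error).
    The initial position is drawn from the stationary law, so the ensemble
    MSD relative to the first frame equals the confined-subdiffusion model
    ``r_c^2 (1 - exp(-2*DIM*d_c*lag/r_c^2))`` at every lag.

    Returns an array of shape ``(n_tracks, n_frames, 2)`` in nm, centred on
    the (zero) home position of each focus.
    """
    if d_c < 0:
        raise SimulationError(f"d_c must be >= 0, got {d_c}")
    if r_c <= 0:
        raise SimulationError(f"degenerate confinement: r_c must be > 0, got {r_c}")
    if n_frames < 2:
        raise SimulationError("n_frames must be >= 2")
    if dt_s <= 0:
        raise SimulationError("dt_s must be > 0")
    theta = 2.0 * DIM * d_c / r_c**2
    sigma = r_c / 2.0
    decay = np.exp(-theta * dt_s)
    innov_sd = sigma * np.sqrt(max(1.0 - decay**2, 0.0))
    pos = np.empty((n_tracks, n_frames, 2))
    pos[:, 0, :] = rng.normal(0.0, sigma, (n_tracks, 2))
    for k in range(1, n_frames):
        pos[:, k, :] = pos[:, k - 1, :] * decay + rng.normal(0.0, innov_sd, (n_tracks, 2))
    return pos


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _ellipse_interior(shape: tuple[int, int], center_px: np.ndarray,
                      geom: NucleusGeometry, pixel_size_nm: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - center_px[0]) * pixel_size_nm
    dy = (yy - center_px[1]) * pixel_size_nm
    c, s = np.cos(geom.phi_rad), np.sin(geom.phi_rad)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    return (xr / geom.a_nm) ** 2 + (yr / geom.b_nm) ** 2 <= 1.0


def _add_gaussian_spot(img: np.ndarray, x_px: float, y_px: float,
                       amplitude: float, sigma_px: float) -> None:
    h, w = img.shape
    rad = max(int(np.ceil(5 * sigma_px)), 2)
    x0, x1 = int(np.floor(x_px)) - rad, int(np.floor(x_px)) + rad + 1
    y0, y1 = int(np.floor(y_px)) - rad, int(np.floor(y_px)) + rad + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-0.5 * ((xs - x_px) / sigma_px) ** 2)
    gy = np.exp(-0.5 * ((ys - y_px) / sigma_px) ** 2)
    img[y0c:y1c, x0c:x1c] += amplitude * gy[:, None] * gx[None, :]


def render_movie(config: SimulationConfig, geometry: NucleusGeometry,
                 records: pd.DataFrame, rng: np.random.Generator,
                 nucleus_id: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one nucleus into a 16-bit movie and its ground-truth table.

    ``records`` is the output of :func:`assign_lifetimes`.  Each frame is an
    elliptical nucleus at ``background_level`` (on a ``camera_offset`` floor,
    soft-edged) carried by a random-walk drift, plus one 2-D Gaussian per live
    focus, plus optional Poisson shot noise and Gaussian read noise.  Foci
    ride on the nucleus drift; ground-truth positions are reported in the
    nucleus-COM frame.  A focus pushed outside the image bounds is clipped and
    flagged in the ``clipped`` column.
    """
    n_frames = config.n_frames
    h, w = config.image_shape
    px = config.pixel_size_nm
    times = config.frame_times_min()

    # whole-nucleus drift random walk (nm), rms step = nucleus_drift_step_nm
    steps = rng.normal(0.0, config.nucleus_drift_step_nm / np.sqrt(2), (n_frames, 2))
    steps[0] = 0.0
    drift_nm = np.cumsum(steps, axis=0)
    center0 = np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    # per-focus confined walks (relative to each focus's home position)
    walks = {}
    for _, rec in records.iterrows():
        sub = next(s for s in config.subpopulations if s.label == rec["subpop"])
        walks[rec["focus_id"]] = simulate_confined_walk(
            sub.motion.d_c, sub.motion.r_c, n_frames, config.frame_interval_s, rng)[0]

    births = records["birth_min"].to_numpy()
    deaths = records["death_min"].to_numpy()
    if np.any(deaths <= births):
        raise SimulationError("death_min must exceed birth_min")
    inside = (records["x_nm"] / geometry.a_nm) ** 2 + (records["y_nm"] / geometry.b_nm) ** 2
    # positions were sampled in the rotated frame; check in axis frame
    axis_xy = _rotate(records[["x_nm", "y_nm"]].to_numpy(), -geometry.phi_rad) if len(records) else np.zeros((0, 2))
    if len(records) and np.any((axis_xy[:, 0] / geometry.a_nm) ** 2 + (axis_xy[:, 1] / geometry.b_nm) ** 2 > 1.0 + 1e-6):
        raise SimulationError("focus records must lie inside the nucleus")

    stack = np.empty((n_frames, h, w), dtype=np.uint16)
    truth_rows: list[dict] = []
    for k in range(n_frames):
        center_px = center0 + drift_nm[k] / px
        img = np.full((h, w), float(config.camera_offset))
        interior = _ellipse_interior((h, w), center_px, geometry, px)
        img += (config.background_level - config.camera_offset) * interior
        img = ndi.gaussian_filter(img, 2.0)  # soft nuclear envelope

        t_k = times[k]
        live = (births <= t_k) & (t_k <= deaths)
        for row_i in np.flatnonzero(live):
            rec = records.iloc[row_i]
            walk = walks[rec["focus_id"]]
            pos_nm = np.array([rec["x_nm"], rec["y_nm"]]) + walk[k] - walk[0]
            x_px = center_px[0] + pos_nm[0] / px
            y_px = center_px[1] + pos_nm[1] / px
            clipped = not (0 <= x_px < w and 0 <= y_px < h)
            if clipped:
                x_px = float(np.clip(x_px, 0, w - 1))
                y_px = float(np.clip(y_px, 0, h - 1))
            sigma_px = rec["psf_sigma_nm"] / px
            _add_gaussian_spot(img, x_px, y_px, rec["amplitude"], sigma_px)
            truth_rows.append({
                "nucleus_id": nucleus_id,
                "focus_id": int(rec["focus_id"]),
                "frame": k + 1,
                "t_min": t_k,
                "x_nm": pos_nm[0],
                "y_nm": pos_nm[1],
                "subpop": rec["subpop"],
                "area_um2": rec["area_um2"],
                "intensity_au": rec["amplitude"] * 2 * np.pi * sigma_px**2,
                "clipped": clipped,
            })

        if config.poisson_noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, img.shape)
        stack[k] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(truth_rows, columns=[
        "nucleus_id", "focus_id", "frame", "t_min", "x_nm", "y_nm",
        "subpop", "area_um2", "intensity_au", "clipped"])
    return stack, truth


@dataclass
class ExperimentResult:
    """Movies and ground truth for one simulated multi-nucleus experiment."""

    config: SimulationConfig
    movies: list[np.ndarray]
    geometries: list[NucleusGeometry]
    truth: pd.DataFrame
    fields: pd.DataFrame  #: per-focus records (birth/death, subpop, home position)

    def metadata(self, nucleus_id: int) -> dict:
        c = self.config
        return {
            "condition": c.condition,
            "nucleus_id": int(nucleus_id),
            "pixel_size_nm": float(c.pixel_size_nm),
            "frame_interval_s": float(c.frame_interval_s),
            "recording_start_offset_min": float(c.recording_start_offset_min),
            "seed": int(c.seed),
        }


def simulate_experiment(config: SimulationConfig) -> ExperimentResult:
    """Simulate ``config.n_nuclei`` nuclei: movies plus ground-truth tables."""
    rng = np.random.default_rng(config.seed)
    movies, geoms, truths, fields = [], [], [], []
    for nid in range(config.n_nuclei):
        geom = sample_nucleus_geometry(config, rng)
        field = sample_focus_field(config, geom, rng)
        field = _add_background_births(field, config, rng)
        field = assign_lifetimes(field, config, rng)
        stack, truth = render_movie(config, geom, field, rng, nucleus_id=nid)
        movies.append(stack)
        geoms.append(geom)
        truths.append(truth)
        field = field.copy()
        field.insert(0, "nucleus_id", nid)
        fields.append(field)
    def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        non_empty = [f for f in frames if len(f)]
        if non_empty:
            return pd.concat(non_empty, ignore_index=True)
        return frames[0] if frames else pd.DataFrame()

    return ExperimentResult(config, movies, geoms, _concat(truths), _concat(fields))


def _add_background_births(field: pd.DataFrame, config: SimulationConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Optional late focus births (dispersed, first subpopulation's traits)."""
    if config.birth_rate_per_min <= 0:
        return field
    duration = config.n_frames * config.frame_interval_min
    n_new = rng.poisson(config.birth_rate_per_min * duration)
    if n_new == 0:
        return field
    sub = config.subpopulations[0]
    geom = NucleusGeometry(*config.nucleus_semi_axes_nm)
    pos = _uniform_in_ellipse(n_new, geom, rng)
    start = config.recording_start_offset_min
    births = start + rng.uniform(0.0, duration, n_new)
    new = pd.DataFrame({
        "focus_id": np.arange(len(field), len(field) + n_new),
        "subpop": sub.label,
        "chord_id": -1,
        "x_nm": pos[:, 0],
        "y_nm": pos[:, 1],
        "area_um2": _draw_truncated_normal(sub.area_mean_um2, sub.area_sd_um2, 0.02, n_new, rng),
        "psf_sigma_nm": _draw_truncated_normal(
            sub.optics.psf_sigma_mean_nm, sub.optics.psf_sigma_sd_nm, 40.0, n_new, rng),
        "amplitude": _draw_truncated_normal(
            sub.optics.amplitude_mean, sub.optics.amplitude_sd,
            0.1 * sub.optics.amplitude_mean, n_new, rng),
        "birth_min": births,
    })
    return pd.concat([field, new], ignore_index=True)


def truth_to_observations(truth: pd.DataFrame) -> pd.DataFrame:
    """Recast a ground-truth table as a detector-style observation table.

    Lets the kinetics stage be exercised on exact tables without rendering and
    re-detecting; positions are already in the nucleus-COM frame.
    """
    obs = truth.rename(columns={}).copy()
    obs["x_com_nm"] = obs["x_nm"]
    obs["y_com_nm"] = obs["y_nm"]
    obs["intensity_raw_au"] = obs["intensity_au"]
    return obs[["nucleus_id", "focus_id", "frame", "t_min", "x_nm", "y_nm",
                "x_com_nm", "y_com_nm", "area_um2", "intensity_au", "intensity_raw_au"]]
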