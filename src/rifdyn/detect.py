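"""Nucleus segmentation and per-frame focus detection/measurement.

The detector is a deterministic, fully documented replacement for the
interactive commercial spot detection typically used for repair-focus
counting:

* nucleus: Otsu threshold on a Gaussian-smoothed frame, largest connected
  component, holes filled; centre of mass (COM) is the intensity-weighted
  centroid of the masked pixels;
* foci: multiscale scale-normalised Laplacian-of-Gaussian (LoG) maxima inside
  the nucleus, thresholded at ``median + threshold_k * MAD`` of the in-mask
  LoG response (MAD scaled by 1.4826 so ``threshold_k`` reads as robust
  sigma units); each focus region is the set of pixels connected to the peak
  that lie above half the peak's background-subtracted height; overlapping
  detections within one spot sigma are resolved by keeping the stronger peak.

Focus area is the half-maximum region size (a convention, stated in
docs/methods.md) and focus intensity is the background-subtracted sum over
that region (the raw sum is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu


class EmptyFrameError(ValueError):
    """Frame contains no usable foreground."""


class UndefinedRatioError(ValueError):
    """Relative focus intensity is undefined (nucleus not brighter than foci)."""


@dataclass(frozen=True)
class DetectionParams:
    """Tunable focus-detection parameters.

    ``log_sigmas`` are the LoG scales in pixels (chosen to bracket the
    expected spot sigma); ``threshold_k`` is the robust-z threshold on the
    in-mask LoG response.  Defaults were tuned once against the simulator's
    ground truth to give >=95% recall at <=5% false positives per nucleus
    frame for the default gamma-like preset.
    """

    smooth_sigma: float = 2.0
    log_sigmas: tuple[float, ...] = (0.6, 0.9, 1.3, 1.9)
    threshold_k: float = 5.0
    min_peak_distance: int = 1


@dataclass
class NucleusFrame:
    """One nucleus in one frame: mask, COM and photometry."""

    frame: int                 #: 1-based frame index
    mask: np.ndarray           #: boolean pixel mask
    com_px: tuple[float, float]  #: (x, y) intensity-weighted centroid, pixels
    i_nucleus: float           #: total intensity over the mask, a.u.
    background: float          #: robust off-focus background, a.u./pixel


def segment_nucleus(frame: np.ndarray, smooth_sigma: float = 2.0) -> NucleusFrame:
    """Segment the (single) nucleus in a 2-D frame.

    Raises :class:`EmptyFrameError` for an empty or constant frame.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D frame, got shape {img.shape}")
    if np.any(img < 0):
        raise ValueError("frame must be non-negative")
    if img.max() == img.min():
        raise EmptyFrameError("empty frame: no intensity contrast")
    smoothed = ndi.gaussian_filter(img, smooth_sigma)
    mask = smoothed > threshold_otsu(smoothed)
    if not mask.any():
        raise EmptyFrameError("empty frame: no foreground pixels above threshold")
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndi.binary_fill_holes(mask)

    yy, xx = np.nonzero(mask)
    weights = img[yy, xx]
    total = weights.sum()
    com = (float((xx * weights).sum() / total), float((yy * weights).sum() / total))
    background = float(np.median(img[mask]))
    return NucleusFrame(frame=0, mask=mask, com_px=com,
                        i_nucleus=float(total), background=background)


def _log_response(img: np.ndarray, sigmas: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Scale-normalised LoG blob response; returns (max response, argmax scale)."""
    stack = np.stack([-(s ** 2) * ndi.gaussian_laplace(img, s) for s in sigmas])
    return stack.max(axis=0), stack.argmax(axis=0)


def _half_max_region(img_bgsub: np.ndarray, peak_yx: tuple[int, int],
                     sigma_px: float) -> np.ndarray:
    """Boolean mask of pixels connected to the peak above half its height."""
    h, w = img_bgsub.shape
    py, px_ = peak_yx
    rad = max(int(np.ceil(6 * sigma_px)), 4)
    y0, y1 = max(py - rad, 0), min(py + rad + 1, h)
    x0, x1 = max(px_ - rad, 0), min(px_ + rad + 1, w)
    window = img_bgsub[y0:y1, x0:x1]
    above = window >= 0.5 * img_bgsub[py, px_]
    labels, _ = ndi.label(above)
    region = labels == labels[py - y0, px_ - x0]
    out = np.zeros((h, w), dtype=bool)
    out[y0:y1, x0:x1] = region
    return out


def detect_foci(frame: np.ndarray, nucleus: NucleusFrame, pixel_size_nm: float,
                params: DetectionParams = DetectionParams()) -> pd.DataFrame:
    """Detect and measure foci in one frame inside a nucleus mask.

    Returns one row per focus with sub-pixel position (image frame, nm),
    half-maximum area (um^2), background-subtracted and raw total intensity
    (a.u.), the LoG peak response and best-matching scale.  An empty frame of
    foci yields an empty table (no error).
    """
    img = np.asarray(frame, dtype=float)
    mask = nucleus.mask
    if not mask.any():
        raise EmptyFrameError("nucleus mask is empty")
    resp, best_scale = _log_response(img, params.log_sigmas)
    in_mask = resp[mask]
    med = np.median(in_mask)
    mad = 1.4826 * np.median(np.abs(in_mask - med))
    thr = med + params.threshold_k * mad

    columns = ["frame", "x_px", "y_px", "x_nm", "y_nm", "area_um2",
               "intensity_au", "intensity_raw_au", "peak_response", "scale_px"]
    if mad == 0 and np.all(in_mask <= med):
        return pd.DataFrame(columns=columns)

    peaks = peak_local_max(resp, min_distance=params.min_peak_distance,
                           threshold_abs=thr, exclude_border=False)
    # Otsu cuts the soft nuclear envelope at its midpoint, so a focus sitting
    # on the envelope can peak just outside the mask.  Rescue peaks in a thin
    # dilated rim, but only where the raw pixel outshines the in-nucleus
    # background (rim noise ridges sit on the falling envelope, well below it).
    in_mask_pk = mask[peaks[:, 0], peaks[:, 1]]
    rim = ndi.binary_dilation(mask, iterations=2) & ~mask
    bright = img[peaks[:, 0], peaks[:, 1]] > nucleus.background
    rim_pk = rim[peaks[:, 0], peaks[:, 1]] & bright
    peaks = peaks[in_mask_pk | rim_pk]
    if len(peaks) == 0:
        return pd.DataFrame(columns=columns)

    # resolve overlapping detections: keep the stronger peak within one spot
    # sigma (the smaller of the two best-matching scales, so a blended pair
    # detected at a coarser scale does not swallow a resolvable neighbour)
    responses = resp[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(responses)[::-1]
    kept: list[int] = []
    for i in order:
        sig_i = params.log_sigmas[best_scale[peaks[i, 0], peaks[i, 1]]]
        ok = True
        for j in kept:
            sig = min(sig_i, params.log_sigmas[best_scale[peaks[j, 0], peaks[j, 1]]])
            if np.hypot(*(peaks[i] - peaks[j])) <= sig:
                ok = False
                break
        if ok:
            kept.append(i)
    peaks = peaks[kept]

    bg = nucleus.background
    img_bgsub = img - bg
    rows = []
    for py, px_ in peaks:
        sigma_px = params.log_sigmas[best_scale[py, px_]]
        region = _half_max_region(img_bgsub, (py, px_), sigma_px)
        npx = int(region.sum())
        if npx == 0:
            continue
        ry, rx = np.nonzero(region)
        weights = np.maximum(img_bgsub[ry, rx], 0.0)
        wsum = weights.sum()
        if wsum <= 0:
            continue
        cx = float((rx * weights).sum() / wsum)
        cy = float((ry * weights).sum() / wsum)
        rows.append({
            "frame": nucleus.frame,
            "x_px": cx,
            "y_px": cy,
            "x_nm": cx * pixel_size_nm,
            "y_nm": cy * pixel_size_nm,
            "area_um2": npx * (pixel_size_nm / 1000.0) ** 2,
            "intensity_au": float(img_bgsub[ry, rx].sum()),
            "intensity_raw_au": float(img[ry, rx].sum()),
            "peak_response": float(resp[py, px_]),
            "scale_px": float(sigma_px),
        })
    return pd.DataFrame(rows, columns=columns)


def relative_intensity(i_focus: float, i_nucleus: float) -> float:
    """Relative focus intensity ``I = I_focus / (I_nucleus - I_focus)``.

    The denominator is the off-focus (background) share of the total nuclear
    intensity, so equal focus and off-focus shares give ``I = 1``.
    """
    if i_focus < 0:
        raise UndefinedRatioError(f"i_focus must be >= 0, got {i_focus}")
    if i_nucleus <= i_focus:
        raise UndefinedRatioError(
            f"undefined ratio: i_nucleus ({i_nucleus}) must exceed i_focus ({i_focus})")
    return i_focus / (i_nucleus - i_focus)


def process_movie(stack: np.ndarray, metadata: dict,
                  params: DetectionParams = DetectionParams()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run segmentation + detection on every frame of one single-nucleus movie.

    ``metadata`` must carry ``nucleus_id``, ``pixel_size_nm``,
    ``frame_interval_s`` and ``recording_start_offset_min`` (the sidecar
    convention of :mod:`rifdyn.io`).  Returns ``(nuclei, observations)``
    tables; ``t_min`` is minutes since irradiation start,
    ``offset + frame_index * frame_interval``.
    """
    nucleus_id = int(metadata.get("nucleus_id", 0))
    px = float(metadata["pixel_size_nm"])
    offset = float(metadata["recording_start_offset_min"])
    dt_min = float(metadata.get("frame_interval_s", 60.0)) / 60.0

    nuc_rows, obs_frames = [], []
    for k in range(stack.shape[0]):
        frame_idx = k + 1
        nucleus = segment_nucleus(stack[k], params.smooth_sigma)
        nucleus.frame = frame_idx
        t_min = offset + frame_idx * dt_min
        nuc_rows.append({
            "nucleus_id": nucleus_id,
            "frame": frame_idx,
            "t_min": t_min,
            "com_x_nm": nucleus.com_px[0] * px,
            "com_y_nm": nucleus.com_px[1] * px,
            "i_nucleus": nucleus.i_nucleus,
            "background": nucleus.background,
            "area_px": int(nucleus.mask.sum()),
        })
        obs = detect_foci(stack[k], nucleus, px, params)
        if len(obs):
            obs.insert(0, "nucleus_id", nucleus_id)
            obs["t_min"] = t_min
            obs_frames.append(obs)

    nuclei = pd.DataFrame(nuc_rows)
    obs_cols = ["nucleus_id", "frame", "t_min", "x_nm", "y_nm", "x_px", "y_px",
                "area_um2", "intensity_au", "intensity_raw_au", "peak_response", "scale_px"]
    if obs_frames:
        observations = pd.concat(obs_frames, ignore_index=True)[obs_cols]
    else:
        observations = pd.DataFrame(columns=obs_cols)
    return nuclei, observations
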