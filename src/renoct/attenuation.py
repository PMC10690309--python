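"""Per-image attenuation-coefficient estimation from B-scan log-slopes.

Under the Beer-Lambert model ``I(z) = I0 * exp(-2 mu z)`` the attenuation
coefficient of a single A-scan is recovered from the slope of the natural-log
intensity against physical depth:

    mu = -(1/2) * d log I / dz        [mm^-1]

The estimator fits ordinary least squares over a fixed depth window (default
250 px) in every A-scan of a fixed lateral region of interest (default
200 px, laterally centered, starting a small offset below the detected
lens-surface band), and averages the per-column slopes into one mu per image.

Nonpositive pixels carry no usable log-intensity and are excluded; a column
whose window retains fewer than a configured fraction of positive pixels is
not computable, and an image with too few computable columns is flagged
invalid rather than given a number.  This makes the fluid-filled pelvis an
explicit failure mode: with no tissue signal below the lens surface its
logarithms cannot be formed, and such images abstain instead of being forced
into the mu scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from renoct.phantom import BScan, PhantomDataset

__all__ = [
    "RoiSpec",
    "AttenuationEstimate",
    "locate_surface",
    "ascan_mu",
    "image_mu",
    "estimate_table",
]


@dataclass(frozen=True)
class RoiSpec:
    """Region-of-interest placement for the slope fit.

    Defaults follow the published analysis window: 200 px wide x 250 px
    deep, laterally centered ("top middle"), with the depth window anchored
    a fixed offset below the detected lens-surface band.
    """

    width_px: int = 200
    depth_px: int = 250
    lateral_anchor: str = "center"  # "center" or an integer start column
    depth_offset_px: int = 10

    def resolve(self, scan: BScan, surface_row: int) -> tuple[slice, slice]:
        """Return (row_slice, col_slice) of the ROI inside ``scan``."""
        if self.width_px > scan.n_lateral or self.depth_px > scan.n_depth:
            raise ValueError(
                f"ROI {self.width_px}x{self.depth_px} exceeds image "
                f"{scan.n_lateral}x{scan.n_depth}"
            )
        if self.lateral_anchor == "center":
            c0 = (scan.n_lateral - self.width_px) // 2
        else:
            c0 = int(self.lateral_anchor)
        r0 = surface_row + self.depth_offset_px
        if c0 < 0 or c0 + self.width_px > scan.n_lateral:
            raise ValueError("ROI lateral anchor outside the image")
        if r0 < 0 or r0 + self.depth_px > scan.n_depth:
            raise ValueError("ROI depth window outside the image")
        return slice(r0, r0 + self.depth_px), slice(c0, c0 + self.width_px)


@dataclass
class AttenuationEstimate:
    """Per-image mu with per-A-scan provenance.

    ``mu_image`` is the arithmetic mean of the computable per-column slopes;
    it is NaN (and ``valid`` is False) when fewer than the configured
    fraction of columns is computable.
    """

    mu_image: float
    mu_columns: np.ndarray
    n_valid_columns: int
    roi: RoiSpec = field(default_factory=RoiSpec)
    valid: bool = True
    surface_row: int = 0


def locate_surface(scan: BScan) -> int:
    """Depth index of the GRIN-lens surface band.

    Returns the argmax of the laterally averaged intensity profile,
    restricted to the top 10% of rows.  An all-zero image yields 0 with a
    warning.
    """
    if scan.pixels.size == 0:
        raise ValueError("empty scan")
    profile = scan.pixels.mean(axis=1)
    top = max(1, scan.n_depth // 10)
    if np.all(profile[:top] == 0):
        warnings.warn("no surface signal found; defaulting surface to row 0")
        return 0
    return int(np.argmax(profile[:top]))


def ascan_mu(
    column: np.ndarray,
    window_start: int,
    window_len: int,
    axial_pitch_mm: float,
    *,
    min_valid_fraction: float = 0.5,
    method: str = "ols",
) -> float:
    """Attenuation coefficient (mm^-1) of one A-scan, or NaN if not computable.

    Fits log(I) against physical depth (mm) over the window, using only
    strictly positive pixels, and returns ``mu = -slope / 2``.  If fewer
    than ``min_valid_fraction`` of the window's pixels are positive the
    column is declared not computable (NaN) — this is what happens to every
    pelvis column.  ``method`` may be ``"ols"`` (the contract) or
    ``"theil-sen"`` (robust alternative).
    """
    column = np.asarray(column, dtype=np.float64)
    if axial_pitch_mm <= 0:
        raise ValueError("axial_pitch_mm must be positive")
    if window_start < 0 or window_start + window_len > column.shape[0]:
        raise IndexError("depth window outside the profile")
    window = column[window_start : window_start + window_len]
    mask = window > 0
    n = int(mask.sum())
    if n < max(2, int(np.ceil(min_valid_fraction * window_len))):
        return float("nan")
    z_mm = np.arange(window_len, dtype=np.float64) * axial_pitch_mm
    y = np.log(window[mask])
    x = z_mm[mask]
    if method == "ols":
        slope = _ols_slope(x, y)
    elif method == "theil-sen":
        slope = stats.theilslopes(y, x).slope
    else:
        raise ValueError(f"unknown slope method: {method!r}")
    return -0.5 * float(slope)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    denom = float(xm @ xm)
    if denom == 0.0:
        return float("nan")
    return float(xm @ y) / denom


def image_mu(
    scan: BScan,
    roi: RoiSpec | None = None,
    *,
    min_valid_fraction_px: float = 0.5,
    min_valid_fraction_cols: float = 0.5,
    method: str = "ols",
) -> AttenuationEstimate:
    """Mean attenuation coefficient of one B-scan over the ROI.

    Each ROI column is fitted independently (see :func:`ascan_mu`); the
    image-level mu is the mean of the computable columns.  The estimate is
    flagged invalid when fewer than ``min_valid_fraction_cols`` of the
    columns are computable, rather than reporting a number from too little
    signal.
    """
    if roi is None:
        roi = RoiSpec()
    surface = locate_surface(scan)
    rows, cols = roi.resolve(scan, surface)
    window = scan.pixels[rows, cols]  # (depth_px, width_px)

    if method != "ols":
        mu_cols = np.array(
            [
                ascan_mu(
                    scan.pixels[:, c],
                    rows.start,
                    roi.depth_px,
                    scan.axial_pitch_mm,
                    min_valid_fraction=min_valid_fraction_px,
                    method=method,
                )
                for c in range(cols.start, cols.stop)
            ]
        )
    else:
        mu_cols = _masked_ols_mu(
            window, scan.axial_pitch_mm, min_valid_fraction_px
        )

    valid_mask = np.isfinite(mu_cols)
    n_valid = int(valid_mask.sum())
    min_cols = max(1, int(np.ceil(min_valid_fraction_cols * roi.width_px)))
    valid = n_valid >= min_cols
    mu = float(mu_cols[valid_mask].mean()) if valid else float("nan")
    return AttenuationEstimate(
        mu_image=mu,
        mu_columns=mu_cols,
        n_valid_columns=n_valid,
        roi=roi,
        valid=valid,
        surface_row=surface,
    )


def _masked_ols_mu(
    window: np.ndarray, axial_pitch_mm: float, min_valid_fraction: float
) -> np.ndarray:
    """Vectorized masked log-slope fit across all ROI columns at once."""
    depth_px = window.shape[0]
    mask = window > 0
    n = mask.sum(axis=0)
    z = np.arange(depth_px, dtype=np.float64)[:, None] * axial_pitch_mm
    with np.errstate(divide="ignore", invalid="ignore"):
        logi = np.where(mask, np.log(np.where(mask, window, 1.0)), 0.0)
        sx = (mask * z).sum(axis=0)
        sy = logi.sum(axis=0)
        sxx = (mask * z * z).sum(axis=0)
        sxy = (z * logi).sum(axis=0)
        denom = n * sxx - sx * sx
        slope = np.where(denom > 0, (n * sxy - sx * sy) / np.where(denom > 0, denom, 1.0), np.nan)
    min_px = max(2, int(np.ceil(min_valid_fraction * depth_px)))
    slope[n < min_px] = np.nan
    return -0.5 * slope


def estimate_table(
    dataset: PhantomDataset,
    roi: RoiSpec | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-image mu table for a whole dataset.

    Columns: scan_id, subject_id, label, mu, n_valid_columns, valid — the
    interchange format consumed by the classifier and the cross-testing
    harness.
    """
    rows = []
    for rec, scan in zip(dataset.manifest.itertuples(index=False), dataset.scans):
        est = image_mu(scan, roi=roi, **kwargs)
        rows.append(
            {
                "scan_id": rec.scan_id,
                "subject_id": rec.subject_id,
                "label": rec.label,
                "mu": est.mu_image,
                "n_valid_columns": est.n_valid_columns,
                "valid": est.valid,
            }
        )
    return pd.DataFrame(rows)
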