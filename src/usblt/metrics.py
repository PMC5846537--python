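"""Reconstruction quality metrics and 1D profile tools.

VR   = |ROI| / |tROI|                       (volume ratio, ideal 1)
DICE = 2 |ROI & tROI| / (|ROI| + |tROI|)    (overlap, ideal 1)
MSE  = (1/N) sum_i (x_i - x0_i)^2           (over all N mesh nodes)

|.| is the physical volume of a node set (lumped FEM nodal volumes).  The
reconstructed ROI contains the nodes whose value strictly exceeds a median
threshold; because most nodes are exactly zero, the median is taken over
the nodes above 1% of the expected source intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .mesh import Mesh

__all__ = [
    "source_threshold",
    "roi_nodes",
    "volume_ratio",
    "dice_coefficient",
    "mean_square_error",
    "MetricsReport",
    "ProfileMeasurement",
    "extract_profile",
    "fwhm_profile",
    "michelson_contrast",
    "two_source_contrast",
]


def source_threshold(x_hat: np.ndarray, expected_value: float) -> float:
    """Median of the nodal values above 1% of the expected source intensity."""
    if expected_value <= 0:
        raise ValueError("expected value must be positive")
    x = np.asarray(x_hat, dtype=float)
    candidates = x[x > 0.01 * expected_value]
    if candidates.size == 0:
        raise ValueError(
            "no node exceeds 1% of the expected intensity; the reconstruction "
            "produced no usable source"
        )
    return float(np.median(candidates))


def roi_nodes(x_hat: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of nodes strictly above the threshold (may be empty)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.flatnonzero(np.asarray(x_hat, dtype=float) > threshold)


def _set_volume(indices, volumes: np.ndarray) -> float:
    return float(volumes[np.asarray(indices, dtype=np.int64)].sum())


def volume_ratio(roi, troi, volumes: np.ndarray) -> float:
    """Volume-weighted VR = vol(ROI) / vol(tROI)."""
    troi = np.asarray(troi, dtype=np.int64)
    if troi.size == 0:
        raise ValueError("true source node set is empty")
    return _set_volume(roi, volumes) / _set_volume(troi, volumes)


def dice_coefficient(roi, troi, volumes: np.ndarray) -> float:
    """Volume-weighted DICE = 2 vol(ROI & tROI) / (vol(ROI) + vol(tROI))."""
    roi = np.asarray(roi, dtype=np.int64)
    troi = np.asarray(troi, dtype=np.int64)
    denom = _set_volume(roi, volumes) + _set_volume(troi, volumes)
    if denom == 0:
        raise ValueError("both node sets are empty")
    inter = np.intersect1d(roi, troi, assume_unique=False)
    return 2.0 * _set_volume(inter, volumes) / denom


def mean_square_error(x_hat: np.ndarray, x_true: np.ndarray) -> float:
    """Mean over all mesh nodes of the squared intensity error."""
    x_hat = np.asarray(x_hat, dtype=float)
    x_true = np.asarray(x_true, dtype=float)
    if x_hat.shape != x_true.shape:
        raise ValueError("reconstruction and truth have different lengths")
    return float(np.mean((x_hat - x_true) ** 2))


@dataclass
class MetricsReport:
    """Per-trial VR/DICE/MSE with mean and population std per method."""

    trials: pd.DataFrame  # columns: trial, method, vr, dice, mse

    def summary(self) -> pd.DataFrame:
        # population std (ddof=0): a single realization reports std 0
        rows = []
        for method, grp in self.trials.groupby("method", sort=False):
            row = {"method": method, "n_trials": len(grp)}
            for m in ("vr", "dice", "mse"):
                row[f"{m}_mean"] = float(grp[m].mean())
                row[f"{m}_std"] = float(np.std(grp[m].to_numpy(), ddof=0))
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ProfileMeasurement:
    """1D intensity profile along one lattice axis through a fixed point."""

    axis: str
    fixed_point: tuple
    positions: np.ndarray
    values: np.ndarray
    fwhm: float | None
    fwhm_defined: bool
    peak_positions: np.ndarray
    peak_values: np.ndarray
    valley_value: float | None


_AXES = {"x": 0, "y": 1, "z": 2}


def extract_profile(x_hat: np.ndarray, mesh: Mesh, axis: str, point) -> tuple[np.ndarray, np.ndarray]:
    """Sample the nodal field along the lattice line through ``point``."""
    if axis not in _AXES:
        raise ValueError("axis must be 'x', 'y' or 'z'")
    ax = _AXES[axis]
    point = np.asarray(point, dtype=float)
    others = [a for a in range(3) if a != ax]
    mask = np.ones(mesh.n_nodes, dtype=bool)
    for a in others:
        mask &= np.abs(mesh.nodes[:, a] - point[a]) < 1e-6
    if not mask.any():
        raise ValueError("the requested line passes through no mesh nodes")
    idx = np.flatnonzero(mask)
    order = np.argsort(mesh.nodes[idx, ax])
    idx = idx[order]
    return mesh.nodes[idx, ax], np.asarray(x_hat, dtype=float)[idx]


def _half_max_width(positions: np.ndarray, values: np.ndarray):
    """FWHM around the global peak by linear interpolation of the half-max
    crossings; returns (fwhm, defined)."""
    peak_i = int(np.argmax(values))
    half = values[peak_i] / 2.0
    if values[peak_i] <= 0:
        return None, False

    def crossing(direction: int):
        i = peak_i
        while 0 <= i + direction < len(values):
            j = i + direction
            if values[j] < half:
                # interpolate between i and j
                frac = (values[i] - half) / (values[i] - values[j])
                return positions[i] + frac * (positions[j] - positions[i])
            i = j
        return None

    left = crossing(-1)
    right = crossing(+1)
    if left is None or right is None:
        return None, False
    return float(right - left), True


def fwhm_profile(x_hat: np.ndarray, mesh: Mesh, axis: str, point) -> ProfileMeasurement:
    """Profile along ``axis`` through ``point`` with FWHM and peak analysis."""
    positions, values = extract_profile(x_hat, mesh, axis, point)
    fwhm, defined = _half_max_width(positions, values)
    peaks, _ = find_peaks(values)
    # endpoints can be maxima too
    ends = [i for i in (0, len(values) - 1)
            if len(values) > 1 and values[i] > values[1 if i == 0 else -2]]
    peaks = np.unique(np.concatenate([peaks, np.array(ends, dtype=int)])) if len(ends) else peaks
    valley = None
    if peaks.size >= 2:
        top2 = peaks[np.argsort(values[peaks])[-2:]]
        a, b = int(top2.min()), int(top2.max())
        valley = float(values[a:b + 1].min())
    return ProfileMeasurement(
        axis=axis,
        fixed_point=tuple(np.asarray(point, dtype=float)),
        positions=positions,
        values=values,
        fwhm=fwhm,
        fwhm_defined=defined,
        peak_positions=positions[peaks],
        peak_values=values[peaks],
        valley_value=valley,
    )


def michelson_contrast(peak: float, valley: float) -> float:
    """(peak - valley) / (peak + valley); peak is the smaller of two peaks."""
    if peak <= 0:
        raise ValueError("peak value must be positive")
    if valley < 0:
        valley = 0.0
    return (peak - valley) / (peak + valley)


def two_source_contrast(profile: ProfileMeasurement) -> float | None:
    """Michelson contrast of the two dominant peaks; None when the profile
    has fewer than two local maxima (merged sources)."""
    if profile.peak_values.size < 2 or profile.valley_value is None:
        return None
    top2 = np.sort(profile.peak_values)[-2:]
    return michelson_contrast(float(top2[0]), profile.valley_value)
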