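"""Deformation metrics used to quantify tissue loading.

Element-wise metrics: the first (largest) principal value of the
Green-Lagrange strain tensor E = (F^T F - I)/2, the first principal value of
the rate-of-deformation tensor D = (L + L^T)/2, and the Tresca maximum shear
stress (sigma_max - sigma_min)/2.  Peaks are running maxima over output
steps; regional summaries are the 95th percentile of element peaks
(count-based by default, area-weighted behind a flag) and area fractions
exceeding injury-relevant thresholds (strain 0.2, strain rate 30 1/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "green_lagrange_principal",
    "rate_of_deformation_principal",
    "max_shear_stress",
    "ElementPeaks",
    "accumulate_peaks",
    "roi_percentile",
    "exceedance_fraction",
    "ROISummary",
    "summarize_rois",
    "STRAIN_THRESHOLD",
    "RATE_THRESHOLD",
]

STRAIN_THRESHOLD = 0.2      # principal Green-Lagrange strain
RATE_THRESHOLD = 30.0       # 1/s, principal rate of deformation


def _as_plane_strain_3x3(T: np.ndarray, f33: float) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.shape[-2:] == (3, 3):
        return T
    out = np.zeros(T.shape[:-2] + (3, 3))
    out[..., :2, :2] = T
    out[..., 2, 2] = f33
    return out


def green_lagrange_principal(F):
    """Largest eigenvalue of E = (F^T F - I)/2 (plane strain, F33 = 1).

    Accepts a single 2x2/3x3 deformation gradient or a batch (..., 2, 2);
    returns a float or an array of floats.
    """
    F3 = _as_plane_strain_3x3(F, 1.0)
    if np.any(np.linalg.det(F3) <= 0):
        raise ValueError("det F <= 0: inverted configuration")
    C = np.swapaxes(F3, -1, -2) @ F3
    E = 0.5 * (C - np.eye(3))
    w = np.linalg.eigvalsh(E)
    out = w[..., -1]
    return float(out) if out.ndim == 0 else out


def rate_of_deformation_principal(L):
    """Largest eigenvalue of D = (L + L^T)/2 (1/s).

    The out-of-plane row/column is zero in plane strain, so a 2x2 velocity
    gradient is embedded with L33 = 0.
    """
    L3 = _as_plane_strain_3x3(L, 0.0)
    if not np.all(np.isfinite(L3)):
        raise ValueError("velocity gradient must be finite")
    D = 0.5 * (L3 + np.swapaxes(L3, -1, -2))
    w = np.linalg.eigvalsh(D)
    out = w[..., -1]
    return float(out) if out.ndim == 0 else out


def max_shear_stress(sigma, tol: float = 1e-8):
    """Tresca maximum shear stress (sigma_max - sigma_min)/2 in Pa.

    The input must be a symmetric Cauchy stress; a full 3x3 (including the
    out-of-plane normal stress of plane strain) is used when provided.
    """
    s = np.asarray(sigma, dtype=float)
    s3 = _as_plane_strain_3x3(s, 0.0)
    asym = np.abs(s3 - np.swapaxes(s3, -1, -2)).max()
    scale = max(np.abs(s3).max(), 1.0)
    if asym > tol * scale:
        raise ValueError("Cauchy stress must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (s3 + np.swapaxes(s3, -1, -2)))
    out = 0.5 * (w[..., -1] - w[..., 0])
    return float(out) if out.ndim == 0 else out


@dataclass
class ElementPeaks:
    """Per-element temporal peaks of the injury metrics.

    Arrays are aligned with the element ordering of the originating mesh;
    ``area`` is the reference-configuration element area (plane strain,
    unit thickness).
    """

    strain_peak: np.ndarray
    rate_peak: np.ndarray
    shear_stress_peak: np.ndarray
    area: np.ndarray
    n_steps: int = 0

    @classmethod
    def zeros(cls, n_elements: int, area: np.ndarray) -> "ElementPeaks":
        z = lambda: np.zeros(n_elements)
        return cls(z(), z(), z(), np.asarray(area, dtype=float), 0)

    def update(self, strain, rate, shear) -> None:
        """Fold one output step into the running maxima."""
        np.maximum(self.strain_peak, strain, out=self.strain_peak)
        np.maximum(self.rate_peak, rate, out=self.rate_peak)
        np.maximum(self.shear_stress_peak, shear, out=self.shear_stress_peak)
        self.n_steps += 1


def accumulate_peaks(history, area) -> ElementPeaks:
    """Running maxima over a history of (strain, rate, shear) step fields."""
    history = list(history)
    if not history:
        raise ValueError("empty field history")
    n = np.asarray(history[0][0]).size
    peaks = ElementPeaks.zeros(n, area)
    for strain, rate, shear in history:
        peaks.update(np.asarray(strain), np.asarray(rate), np.asarray(shear))
    return peaks


def _roi_mask(labels, roi) -> np.ndarray:
    labels = np.asarray(labels)
    mask = labels == roi
    if not mask.any():
        raise KeyError(f"unknown or empty ROI label: {roi!r}")
    return mask


def roi_percentile(values, labels, roi, q: float = 95.0,
                   area=None) -> float:
    """q-th percentile of per-element values within one ROI.

    Linear interpolation between closest ranks (position 1 + q/100*(n-1)),
    unweighted across elements; pass ``area`` for an area-weighted variant.
    """
    mask = _roi_mask(labels, roi)
    v = np.asarray(values, dtype=float)[mask]
    if v.size < 2:
        raise ValueError(f"ROI {roi!r} needs at least 2 elements")
    if area is None:
        return float(np.percentile(v, q))
    w = np.asarray(area, dtype=float)[mask]
    order = np.argsort(v)
    v, w = v[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(q / 100.0, cw, v))


def exceedance_fraction(peaks: ElementPeaks, labels, roi,
                        threshold: float, which: str) -> float:
    """Area fraction of an ROI whose element peak exceeds a threshold."""
    mask = _roi_mask(labels, roi)
    if which == "strain":
        v = peaks.strain_peak
    elif which == "rate":
        v = peaks.rate_peak
    else:
        raise ValueError("which must be 'strain' or 'rate'")
    a = peaks.area[mask]
    return float(a[v[mask] > threshold].sum() / a.sum())


@dataclass
class ROISummary:
    """Regional summary: 95th-percentile peaks and exceedance fractions."""

    roi: str
    strain_p95: float
    rate_p95: float
    exceed_strain_frac: float
    exceed_rate_frac: float
    n_elements: int
    area: float

    def as_dict(self) -> dict:
        return {
            "roi": self.roi,
            "strain_p95": self.strain_p95,
            "rate_p95": self.rate_p95,
            "exceed_strain_frac": self.exceed_strain_frac,
            "exceed_rate_frac": self.exceed_rate_frac,
            "n_elements": self.n_elements,
            "area": self.area,
        }


def summarize_rois(peaks: ElementPeaks, labels, rois=None,
                   q: float = 95.0, area_weighted: bool = False
                   ) -> dict[str, ROISummary]:
    """Build :class:`ROISummary` objects for each requested ROI label."""
    labels = np.asarray(labels)
    if rois is None:
        rois = [r for r in np.unique(labels) if r != ""]
    out = {}
    for roi in rois:
        mask = _roi_mask(labels, roi)
        w = peaks.area if area_weighted else None
        out[str(roi)] = ROISummary(
            roi=str(roi),
            strain_p95=roi_percentile(peaks.strain_peak, labels, roi, q, w),
            rate_p95=roi_percentile(peaks.rate_peak, labels, roi, q, w),
            exceed_strain_frac=exceedance_fraction(
                peaks, labels, roi, STRAIN_THRESHOLD, "strain"),
            exceed_rate_frac=exceedance_fraction(
                peaks, labels, roi, RATE_THRESHOLD, "rate"),
            n_elements=int(mask.sum()),
            area=float(peaks.area[mask].sum()),
        )
    return out
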