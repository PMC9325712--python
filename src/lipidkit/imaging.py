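"""MALDI-imaging semi-quantification: peak picking, markers, ROI statistics.

An ion image is a pixel grid sharing one centroided m/z axis.  The
processing order is fixed: per-pixel TIC normalization, then marker
extraction (maximum intensity within +-0.05 Da of the marker mass), then
per-ROI statistics normalized by area (pixel count); raw-intensity marker
images are also supported since both conventions occur in practice.

Peak candidates are local maxima of the mean spectrum at signal-to-noise
>= 3 (noise estimated as 1.4826 x the median absolute deviation of the
mean spectrum by default), grouped by single linkage within 0.5 Da.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "SpectrumGrid",
    "MarkerWindow",
    "ROIMask",
    "ROISummary",
    "detect_peaks",
    "group_peaks",
    "tic_normalize",
    "marker_image",
    "roi_summary",
    "grid_from_imzml",
]


@dataclass
class SpectrumGrid:
    """Pixelated ion image: (height, width, n_bins) cube on a shared m/z axis."""

    mz: np.ndarray
    intensities: np.ndarray  # shape (height, width, n_bins)
    pixel_size_um: float = 60.0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must have shape (height, width, n_bins)")
        if self.mz.ndim != 1 or self.mz.size != self.intensities.shape[2]:
            raise ValueError("m/z axis length must match the intensity cube")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if np.nanmin(self.intensities) < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape[:2]

    @property
    def tic(self) -> np.ndarray:
        """Per-pixel total ion count (sum over the m/z axis)."""
        return self.intensities.sum(axis=2)

    def mean_spectrum(self) -> np.ndarray:
        return np.nanmean(self.intensities.reshape(-1, self.mz.size), axis=0)

    # ---- plain-text grid I/O (axis CSV + pixel x bin matrix CSV + JSON header)

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        h, w, b = self.intensities.shape
        np.savetxt(prefix.with_suffix(".axis.csv"), self.mz, delimiter=",")
        np.savetxt(
            prefix.with_suffix(".pixels.csv"),
            self.intensities.reshape(h * w, b),
            delimiter=",",
        )
        prefix.with_suffix(".json").write_text(
            json.dumps({"width": w, "height": h, "pixel_size_um": self.pixel_size_um})
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "SpectrumGrid":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        mz = np.loadtxt(prefix.with_suffix(".axis.csv"), delimiter=",")
        flat = np.loadtxt(prefix.with_suffix(".pixels.csv"), delimiter=",")
        cube = flat.reshape(header["height"], header["width"], mz.size)
        return cls(mz, cube, header["pixel_size_um"])


@dataclass(frozen=True)
class MarkerWindow:
    """Marker mass range: center +- half_width Da (default +-0.05)."""

    center: float
    half_width: float = 0.05

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


@dataclass
class ROIMask:
    """Labeled boolean pixel mask (T tumor, S stroma, etc.)."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass(frozen=True)
class ROISummary:
    """The per-ROI statistic set reported by the imaging pipeline."""

    label: str
    n_pixels: int
    total: float
    mean_per_mm2: float
    mean_per_pixel: float
    sd_per_pixel: float
    rsd: float
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    n_missing: int = 0

    def as_dict(self) -> dict:
        return {
            "roi": self.label,
            "n_pixels": self.n_pixels,
            "sum": self.total,
            "mean_per_mm2": self.mean_per_mm2,
            "mean_per_pixel": self.mean_per_pixel,
            "sd_per_pixel": self.sd_per_pixel,
            "rsd": self.rsd,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "min": self.minimum,
            "max": self.maximum,
            "n_missing": self.n_missing,
        }


def detect_peaks(
    grid: SpectrumGrid,
    snr: float = 3.0,
    noise_estimator: str = "mad",
    noise_band: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate peak m/z values from the mean spectrum at a SNR threshold.

    Local maxima of the mean spectrum whose baseline-subtracted intensity
    (spectrum minus its median) reaches snr x noise are kept.  Noise is
    1.4826 x the median absolute deviation of the mean spectrum (``"mad"``,
    default) or the standard deviation of a signal-free band (``"band"``
    with ``noise_band=(lo, hi)`` in Da).

    Returns (candidate m/z, candidate intensity), both sorted by m/z; an
    all-zero grid yields empty arrays.
    """
    spectrum = grid.mean_spectrum()
    if not np.any(spectrum > 0):
        return np.array([]), np.array([])
    if noise_estimator == "mad":
        noise = 1.4826 * np.median(np.abs(spectrum - np.median(spectrum)))
    elif noise_estimator == "band":
        if noise_band is None:
            raise ValueError("noise_band=(lo, hi) required for the 'band' estimator")
        sel = (grid.mz >= noise_band[0]) & (grid.mz <= noise_band[1])
        if not sel.any():
            raise ValueError("noise_band contains no m/z bins")
        noise = float(np.std(spectrum[sel]))
    else:
        raise ValueError(f"unknown noise estimator {noise_estimator!r}")
    idx, _ = find_peaks(spectrum)
    # find_peaks requires interior maxima; admit axis endpoints explicitly
    ends = [i for i in (0, spectrum.size - 1)
            if spectrum.size > 1
            and spectrum[i] > spectrum[1 if i == 0 else -2]]
    idx = np.union1d(idx, ends).astype(int)
    signal = spectrum - np.median(spectrum)
    keep = signal[idx] >= snr * noise if noise > 0 else signal[idx] > 0
    idx = idx[keep]
    return grid.mz[idx], spectrum[idx]


def group_peaks(
    candidates: Sequence[float],
    intensities: Sequence[float] | None = None,
    window: float = 0.5,
) -> np.ndarray:
    """Single-linkage grouping of sorted candidates within a Da window.

    Neighbors closer than ``window`` merge (chains merge transitively);
    each marker center is the intensity-weighted mean of its group.
    """
    mz = np.asarray(candidates, dtype=float)
    if mz.size == 0:
        return np.array([])
    if np.any(np.diff(mz) < 0):
        raise ValueError("candidates must be sorted ascending")
    w = (
        np.ones_like(mz)
        if intensities is None
        else np.asarray(intensities, dtype=float)
    )
    breaks = np.nonzero(np.diff(mz) >= window)[0] + 1
    centers = [
        float(np.average(g, weights=gw))
        for g, gw in zip(np.split(mz, breaks), np.split(w, breaks))
    ]
    return np.array(centers)


def tic_normalize(grid: SpectrumGrid) -> tuple[SpectrumGrid, int]:
    """Scale each pixel's spectrum to percentages of its TIC (sum = 100).

    Zero-TIC pixels are emitted as missing (NaN) and counted; the count is
    returned alongside the normalized grid.
    """
    tic = grid.tic
    zero = tic <= 0
    safe = np.where(zero, 1.0, tic)
    norm = grid.intensities / safe[..., None] * 100.0
    norm[zero] = np.nan
    out = SpectrumGrid.__new__(SpectrumGrid)
    out.mz = grid.mz.copy()
    out.intensities = norm
    out.pixel_size_um = grid.pixel_size_um
    return out, int(zero.sum())


def marker_image(grid: SpectrumGrid, window: MarkerWindow) -> np.ndarray:
    """Per-pixel maximum intensity within the marker mass range.

    Rejects windows that overlap no bin of the m/z axis, reporting the
    axis bounds.
    """
    sel = (grid.mz >= window.center - window.half_width) & (
        grid.mz <= window.center + window.half_width
    )
    if not sel.any():
        raise ValueError(
            f"marker window {window.center} +- {window.half_width} Da overlaps "
            f"no bin of the m/z axis [{grid.mz[0]:.4f}, {grid.mz[-1]:.4f}]"
        )
    return np.max(grid.intensities[:, :, sel], axis=2)


def roi_summary(
    marker: np.ndarray, mask: ROIMask, pixel_size_um: float = 60.0
) -> ROISummary:
    """All ROI statistics over the masked pixels of a marker image.

    mean_per_mm2 divides the summed intensity by the ROI area
    (n_pixels x pixel area in mm^2); quartiles use linear interpolation
    (inclusive convention); SD is the population SD (single-pixel ROI
    gives 0).  Missing (NaN) pixels inside the mask are excluded and
    counted.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape != mask.mask.shape:
        raise ValueError(
            f"marker shape {marker.shape} does not match mask shape {mask.mask.shape}"
        )
    if not mask.mask.any():
        raise ValueError(f"ROI {mask.label!r}: empty mask")
    values = marker[mask.mask]
    n_missing = int(np.isnan(values).sum())
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError(f"ROI {mask.label!r}: all masked pixels are missing")
    n = values.size
    total = float(values.sum())
    area_mm2 = n * (pixel_size_um / 1000.0) ** 2
    mean = total / n
    sd = float(values.std(ddof=0))
    q1, med, q3 = (float(v) for v in np.percentile(values, [25, 50, 75]))
    return ROISummary(
        label=mask.label,
        n_pixels=n,
        total=total,
        mean_per_mm2=total / area_mm2,
        mean_per_pixel=mean,
        sd_per_pixel=sd,
        rsd=sd / mean if mean > 0 else float("nan"),
        median=med,
        q1=q1,
        q3=q3,
        minimum=float(values.min()),
        maximum=float(values.max()),
        n_missing=n_missing,
    )


def roi_summaries_table(
    markers: dict[str, np.ndarray],
    masks: Sequence[ROIMask],
    pixel_size_um: float = 60.0,
) -> pd.DataFrame:
    """Tidy summary table keyed by (marker, ROI label)."""
    rows = []
    for name, image in markers.items():
        for mask in masks:
            rec = roi_summary(image, mask, pixel_size_um).as_dict()
            rec["marker"] = name
            rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["marker"] + [c for c in df.columns if c != "marker"]]


def grid_from_imzml(path: str | Path, pixel_size_um: float = 60.0) -> SpectrumGrid:
    """Ingest a continuous-mode imzML file (shared m/z axis) as a grid.

    Requires the optional ``pyimzml`` dependency.
    """
    from pyimzml.ImzMLParser import ImzMLParser  # lazy optional import

    parser = ImzMLParser(str(path))
    coords = np.array([(x, y) for x, y, _ in parser.coordinates])
    xs = coords[:, 0] - coords[:, 0].min()
    ys = coords[:, 1] - coords[:, 1].min()
    width, height = int(xs.max()) + 1, int(ys.max()) + 1
    mz0, _ = parser.getspectrum(0)
    cube = np.zeros((height, width, len(mz0)))
    for i, (x, y) in enumerate(zip(xs, ys)):
        mz, inten = parser.getspectrum(i)
        if len(mz) != len(mz0) or not np.allclose(mz, mz0):
            raise ValueError("imzML file is not continuous-mode (shared m/z axis)")
        cube[y, x, :] = inten
    return SpectrumGrid(np.asarray(mz0, dtype=float), cube, pixel_size_um)
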