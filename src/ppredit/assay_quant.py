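"""Quantification of companion assays: Sanger extents, REMSA binding, Kd fits."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class TracePeaks:
    """Chromatogram peak intensities at the edited position."""

    peak_edited: float    # T peak
    peak_unedited: float  # C peak

    def __post_init__(self) -> None:
        if self.peak_edited < 0 or self.peak_unedited < 0:
            raise ValueError("peak intensities must be non-negative")
        if self.peak_edited == 0 and self.peak_unedited == 0:
            raise ValueError("both peaks zero; extent undefined")


@dataclass
class TitrationCurve:
    concentrations: np.ndarray  # uM
    fraction_bound: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=np.float64)
        self.fraction_bound = np.asarray(self.fraction_bound, dtype=np.float64)
        if self.concentrations.shape != self.fraction_bound.shape:
            raise ValueError("concentrations and fractions differ in length")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentration")
        if np.any((self.fraction_bound < 0) | (self.fraction_bound > 1)):
            raise ValueError("fraction bound outside [0, 1]")


@dataclass(frozen=True)
class KdFit:
    kd: float
    fmax: float
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if not 0 < self.fmax <= 1.05:
            raise ValueError("fmax must lie in (0, 1.05]")


class FitError(RuntimeError):
    """Non-convergent or under-determined binding fit."""


def sanger_extent(peaks: TracePeaks) -> float:
    """Editing extent (%) from T vs C peak intensities."""
    return 100.0 * peaks.peak_edited / (peaks.peak_edited + peaks.peak_unedited)


def fraction_bound(bound_intensity: float, unbound_intensity: float) -> float:
    if bound_intensity < 0 or unbound_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = bound_intensity + unbound_intensity
    if total == 0:
        raise ValueError("both band intensities zero")
    return bound_intensity / total


def binding_isotherm(c: np.ndarray, kd: float, fmax: float) -> np.ndarray:
    """1:1 hyperbolic isotherm F(c) = fmax * c / (kd + c)."""
    c = np.asarray(c, dtype=np.float64)
    return fmax * c / (kd + c)


def fit_kd(curve: TitrationCurve) -> KdFit:
    """Bounded least-squares fit of the 1:1 isotherm.

    Initialisation is deterministic: Kd0 is the concentration closest to the
    half-maximal observed fraction, fmax0 the maximal observed fraction.
    """
    c = curve.concentrations
    f = curve.fraction_bound
    if len(np.unique(c)) < 3:
        raise FitError("need at least 3 distinct concentrations")
    fmax0 = float(max(f.max(), 1e-3))
    half = fmax0 / 2.0
    positive = c[c > 0]
    if positive.size == 0:
        raise FitError("all concentrations are zero")
    kd0 = float(c[np.argmin(np.abs(f - half))])
    if kd0 <= 0:
        kd0 = float(positive.min())
    try:
        popt, _ = curve_fit(
            binding_isotherm,
            c,
            f,
            p0=[kd0, min(fmax0, 1.05)],
            bounds=([1e-12, 1e-12], [np.inf, 1.05]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"Kd fit did not converge: {exc}") from exc
    kd, fmax = float(popt[0]), float(popt[1])
    rss = float(np.sum((f - binding_isotherm(c, kd, fmax)) ** 2))
    return KdFit(kd=kd, fmax=fmax, rss=rss, n_points=int(len(c)))


def additivity_gap(combined: float, a: float, b: float) -> float:
    """combined - (a + b), all on the percentage scale."""
    for v in (combined, a, b):
        if not 0 <= v <= 100:
            raise ValueError(f"percentage {v} outside [0, 100]")
    return combined - (a + b)


def read_titration(path: str | Path, replicate_id: str = "") -> TitrationCurve:
    """Two-column TSV: concentration_uM, fraction_bound."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need concentration and fraction columns")
    return TitrationCurve(
        concentrations=df[cols[0]].to_numpy(dtype=float),
        fraction_bound=df[cols[1]].to_numpy(dtype=float),
        replicate_id=replicate_id or Path(path).stem,
    )


def read_trace_peaks(path: str | Path) -> list[TracePeaks]:
    """TSV with peak_edited / peak_unedited columns (one row per trace)."""
    df = pd.read_csv(path, sep="\t")
    if not {"peak_edited", "peak_unedited"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns peak_edited, peak_unedited")
    return [TracePeaks(float(r.peak_edited), float(r.peak_unedited)) for r in df.itertuples()]
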