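"""Cross-sample aggregation: the sites-by-samples extent matrix and summaries.

The central object mirrors the published comparison-table layout: one row per
edited site (the engineered target plus off-targets), one column per sample,
each cell holding an editing extent in percent plus a significance flag
(whether the site passed the filter cascade in that sample). Sub-threshold
extents are retained unflagged; significance is a flag, not a mask.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filter_cascade import EditingEvent

SiteKey = tuple[str, int, str]  # (chrom, pos, strand)


def site_label(key: SiteKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


@dataclass
class CrossSampleMatrix:
    extent: pd.DataFrame          # percent, NaN where a site was not covered
    flags: pd.DataFrame           # bool, True where the site passed the cascade
    target_labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.extent.index.equals(self.flags.index) or not self.extent.columns.equals(
            self.flags.columns
        ):
            raise ValueError("extent and flag frames must share index and columns")
        vals = self.extent.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 100)):
                raise ValueError("extents must lie in [0, 100]")

    @property
    def samples(self) -> list[str]:
        return list(self.extent.columns)

    @property
    def sites(self) -> list[str]:
        return list(self.extent.index)

    @property
    def offtarget_labels(self) -> list[str]:
        return [s for s in self.sites if s not in self.target_labels]

    @property
    def n_samples(self) -> pd.Series:
        """Per-row count of significant detections."""
        return self.flags.sum(axis=1).astype(int)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for label in self.sites:
            row: dict[str, object] = {"site": label}
            for s in self.samples:
                v = self.extent.loc[label, s]
                if pd.isna(v):
                    row[s] = ""
                else:
                    row[s] = f"{v:g}{'*' if self.flags.loc[label, s] else ''}"
            row["n_samples"] = int(self.flags.loc[label].sum())
            row["is_target"] = int(label in self.target_labels)
            rows.append(row)
        pd.DataFrame(rows, columns=["site", *self.samples, "n_samples", "is_target"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CrossSampleMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        cols = list(df.columns)
        if cols[0] != "site" or "n_samples" not in cols:
            raise ValueError(f"{path}: expected 'site', sample columns, 'n_samples'")
        sample_cols = [c for c in cols[1:] if c not in ("n_samples", "is_target")]
        extent = pd.DataFrame(index=df["site"], columns=sample_cols, dtype=float)
        flags = pd.DataFrame(False, index=df["site"], columns=sample_cols)
        targets: set[str] = set()
        for _, rec in df.iterrows():
            label = rec["site"]
            for s in sample_cols:
                cell = str(rec[s]).strip()
                if not cell:
                    continue
                flagged = cell.endswith("*")
                extent.loc[label, s] = float(cell.rstrip("*"))
                flags.loc[label, s] = flagged
            declared = int(rec["n_samples"])
            if declared != int(flags.loc[label].sum()):
                raise ValueError(
                    f"{path}: row {label} declares n_samples={declared}, "
                    f"flags give {int(flags.loc[label].sum())}"
                )
            if "is_target" in df.columns and str(rec["is_target"]).strip() in ("1", "True"):
                targets.add(label)
        return cls(extent=extent, flags=flags, target_labels=targets)


def build_matrix(
    events_by_sample: Mapping[str, Sequence[EditingEvent]],
    extent_lookup: Mapping[str, Mapping[SiteKey, float]] | None = None,
    target_key: SiteKey | None = None,
) -> CrossSampleMatrix:
    """Assemble the matrix from per-sample surviving events.

    Row universe: the union of significant sites across samples (plus the
    target if given). ``extent_lookup[sample][key]`` optionally supplies
    sub-threshold editing fractions (0..1 scale) for unflagged cells where
    the site was covered.
    """
    extent_lookup = extent_lookup or {}
    samples = sorted(events_by_sample)
    keys: set[SiteKey] = set()
    for evs in events_by_sample.values():
        keys.update(e.key for e in evs)
    if target_key is not None:
        keys.add(target_key)
    ordered = sorted(keys, key=lambda k: (k != target_key, k))
    labels = [site_label(k) for k in ordered]

    extent = pd.DataFrame(np.nan, index=labels, columns=samples)
    flags = pd.DataFrame(False, index=labels, columns=samples)
    for sample in samples:
        significant = {e.key: e for e in events_by_sample[sample]}
        lookup = extent_lookup.get(sample, {})
        for key, label in zip(ordered, labels):
            if key in significant:
                extent.loc[label, sample] = 100.0 * significant[key].f_rna
                flags.loc[label, sample] = True
            elif key in lookup:
                extent.loc[label, sample] = 100.0 * lookup[key]
    targets = {site_label(target_key)} if target_key is not None else set()
    return CrossSampleMatrix(extent=extent, flags=flags, target_labels=targets)


def multiplicity_histogram(matrix: CrossSampleMatrix) -> dict[int, int]:
    """n_samples -> off-target site count (target rows excluded)."""
    counts = matrix.n_samples.loc[matrix.offtarget_labels]
    return dict(sorted(Counter(int(v) for v in counts if v > 0).items()))


def per_sample_offtarget_counts(matrix: CrossSampleMatrix) -> dict[str, int]:
    """Significant off-target rows per sample column (zeros reported)."""
    sub = matrix.flags.loc[matrix.offtarget_labels]
    return {s: int(sub[s].sum()) for s in matrix.samples}


def efficiency_vs_offtargets(
    matrix: CrossSampleMatrix,
) -> tuple[list[tuple[float, int]], float, float]:
    """Per-sample (target extent, off-target count) points with OLS slope, R^2."""
    if not matrix.target_labels:
        raise ValueError("matrix has no target row")
    target = sorted(matrix.target_labels)[0]
    counts = per_sample_offtarget_counts(matrix)
    points = []
    for s in matrix.samples:
        extent = matrix.extent.loc[target, s]
        if pd.isna(extent):
            continue
        points.append((float(extent), counts[s]))
    if len(points) < 2:
        raise ValueError("need at least 2 samples with a target extent")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points], dtype=float)
    if np.all(y == y[0]) or np.all(x == x[0]):
        slope = 0.0 if np.all(y == y[0]) else np.nan
        return points, slope, 0.0
    fit = stats.linregress(x, y)
    return points, float(fit.slope), float(fit.rvalue**2)


def score_vs_extent(scores: Sequence[float], extents: Sequence[float]) -> float:
    """R^2 of editing extent regressed on total recognition-code score."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(extents, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired score/extent values")
    if np.all(x == x[0]):
        raise ValueError("degenerate score variance")
    if np.all(y == y[0]):
        raise ValueError("degenerate extent variance")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)
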