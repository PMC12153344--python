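"""The published filter sequence for candidate C-to-U events.

Per sample, candidates pass through, in order:

1. fraction filter   — RNA-vs-DNA editing-fraction difference of at least
   ``min_fraction_delta`` and a DNA mismatch fraction bounded by
   ``dna_error_ratio`` times the RNA fraction;
2. depth filter      — depth strictly above the ``depth_quantile`` quantile
   of the sample's candidate depths;
3. score filter      — score strictly above the ``pct_high`` percentile of
   the sample's candidate scores when the site's own RNA fraction is at
   least ``rate_switch``, else the ``pct_low`` percentile;
4. control subtraction — any site surviving filters 1-3 in a negative-control
   sample is removed everywhere.

Quantiles/percentiles use the linearly interpolated (type-7) convention.
Depth and score distributions are taken over the sample's full candidate set;
computing them only over fraction-filter survivors would leave a handful of
events whose own percentiles then eliminate them.

Strict ">" comparisons are relaxed to ">=" only when the distribution is
degenerate (all values equal), where the strict rule would silently drop
every event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .editing_detection import CandidateEvent

logger = logging.getLogger(__name__)

FILTER_NAMES = ("fraction", "depth", "score", "control")


@dataclass(frozen=True)
class FilterConfig:
    min_fraction_delta: float = 0.01
    dna_error_ratio: float = 0.01
    depth_quantile: float = 0.01
    pct_high: float = 95.0
    pct_low: float = 98.0
    rate_switch: float = 0.10

    def __post_init__(self) -> None:
        for name in ("min_fraction_delta", "dna_error_ratio", "depth_quantile", "rate_switch"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        for name in ("pct_high", "pct_low"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name}={v} must lie in (0, 100)")
        if self.pct_low < self.pct_high:
            raise ValueError("pct_low must be >= pct_high")


@dataclass
class EditingEvent:
    """A candidate that survived the whole cascade."""

    chrom: str
    pos: int
    transcript_strand: str
    f_rna: float
    f_dna: float
    depth: int
    score: float
    sample_id: str
    passed_filters: list[str] = field(default_factory=lambda: list(FILTER_NAMES))
    is_target: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.transcript_strand)


def fraction_filter(ev: CandidateEvent, cfg: FilterConfig) -> bool:
    return (
        ev.f_rna - ev.f_dna >= cfg.min_fraction_delta
        and ev.f_dna <= cfg.dna_error_ratio * ev.f_rna
    )


def depth_threshold(events: Sequence[CandidateEvent], cfg: FilterConfig) -> float:
    if not events:
        raise ValueError("depth_threshold needs at least one event")
    depths = np.array([e.depth for e in events], dtype=np.float64)
    return float(np.quantile(depths, cfg.depth_quantile))


def score_threshold(
    events: Sequence[CandidateEvent], ev: CandidateEvent, cfg: FilterConfig
) -> float:
    if not len(events):
        raise ValueError("score_threshold needs a non-empty score distribution")
    scores = np.array([e.score for e in events], dtype=np.float64)
    pct = cfg.pct_high if ev.f_rna >= cfg.rate_switch else cfg.pct_low
    return float(np.percentile(scores, pct))


def subtract_controls(
    events: Iterable[EditingEvent], control_events: Iterable[EditingEvent | CandidateEvent]
) -> list[EditingEvent]:
    control_keys = {e.key for e in control_events}
    return [e for e in events if e.key not in control_keys]


def _strictly_above(values: np.ndarray, threshold: float) -> np.ndarray:
    mask = values > threshold
    if not mask.any() and len(values) and np.all(values == values[0]):
        return values >= threshold  # degenerate all-equal case
    return mask


def _filter_sample(
    candidates: Sequence[CandidateEvent], cfg: FilterConfig
) -> tuple[list[EditingEvent], dict[str, int]]:
    """Filters 1-3 for one sample, with per-filter rejection counts."""
    rejections = {name: 0 for name in FILTER_NAMES}
    if not candidates:
        return [], rejections

    # thresholds over the full candidate set (see module docstring)
    d_thr = depth_threshold(candidates, cfg)
    scores = np.array([e.score for e in candidates], dtype=np.float64)
    s_thr_high = float(np.percentile(scores, cfg.pct_high))
    s_thr_low = float(np.percentile(scores, cfg.pct_low))
    depths = np.array([e.depth for e in candidates], dtype=np.float64)
    depth_degenerate = bool(np.all(depths == depths[0]))
    score_degenerate = bool(np.all(scores == scores[0]))

    survivors: list[EditingEvent] = []
    for ev in candidates:
        if not fraction_filter(ev, cfg):
            rejections["fraction"] += 1
            continue
        if not (ev.depth > d_thr or (depth_degenerate and ev.depth >= d_thr)):
            rejections["depth"] += 1
            continue
        s_thr = s_thr_high if ev.f_rna >= cfg.rate_switch else s_thr_low
        if not (ev.score > s_thr or (score_degenerate and ev.score >= s_thr)):
            rejections["score"] += 1
            continue
        survivors.append(
            EditingEvent(
                chrom=ev.chrom,
                pos=ev.pos,
                transcript_strand=ev.transcript_strand,
                f_rna=ev.f_rna,
                f_dna=ev.f_dna,
                depth=ev.depth,
                score=ev.score,
                sample_id=ev.sample_id,
                passed_filters=["fraction", "depth", "score"],
            )
        )
    return survivors, rejections


def run_cascade(
    candidates_by_sample: Mapping[str, Sequence[CandidateEvent]],
    control_candidates_by_sample: Mapping[str, Sequence[CandidateEvent]] | None = None,
    cfg: FilterConfig | None = None,
    target_key: tuple[str, int, str] | None = None,
) -> tuple[dict[str, list[EditingEvent]], pd.DataFrame]:
    """Apply the full cascade; returns per-sample events and an audit table.

    Negative-control samples run through filters 1-3 under their own
    thresholds; their surviving site keys are removed from every sample.
    The audit table has one row per (sample, filter) rejection count plus the
    survivor count, so ``candidates = survivors + sum(rejections)`` per sample.
    """
    cfg = cfg or FilterConfig()
    control_candidates_by_sample = control_candidates_by_sample or {}

    control_keys: set[tuple[str, int, str]] = set()
    for name, cands in control_candidates_by_sample.items():
        ctrl_events, _ = _filter_sample(cands, cfg)
        if ctrl_events:
            logger.info("control %s: %d artifact site(s) flagged", name, len(ctrl_events))
        control_keys.update(e.key for e in ctrl_events)

    events_by_sample: dict[str, list[EditingEvent]] = {}
    audit_rows = []
    for name, cands in candidates_by_sample.items():
        survivors, rejections = _filter_sample(cands, cfg)
        kept = []
        for ev in survivors:
            if ev.key in control_keys:
                rejections["control"] += 1
            else:
                ev.passed_filters.append("control")
                ev.is_target = target_key is not None and ev.key == target_key
                kept.append(ev)
        events_by_sample[name] = kept
        assert len(cands) == len(kept) + sum(rejections.values())
        logger.info(
            "%s: %d candidates -> %d events (rejected: %s)", name, len(cands), len(kept), rejections
        )
        audit_rows.append(
            {"sample": name, "n_candidates": len(cands), "n_events": len(kept), **rejections}
        )
    audit = pd.DataFrame(
        audit_rows, columns=["sample", "n_candidates", "n_events", *FILTER_NAMES]
    )
    return events_by_sample, audit


def events_to_vcf(
    events: Sequence[EditingEvent], genome_id: str, path
) -> None:
    """Minimal VCF v4.2 with EDF/DDF/SCORE/DP/STRAND in INFO."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=ppredit",
        f"##contig=<ID={genome_id}>",
        '##INFO=<ID=EDF,Number=1,Type=Float,Description="RNA editing fraction">',
        '##INFO=<ID=DDF,Number=1,Type=Float,Description="DNA control mismatch fraction">',
        '##INFO=<ID=SCORE,Number=1,Type=Float,Description="RNA-vs-DNA G statistic">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=STRAND,Number=1,Type=String,Description="Transcript strand">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for ev in sorted(events, key=lambda e: (e.chrom, e.pos, e.transcript_strand)):
        ref, alt = ("C", "T") if ev.transcript_strand == "+" else ("G", "A")
        info = (
            f"EDF={ev.f_rna:.6g};DDF={ev.f_dna:.6g};SCORE={ev.score:.6g};"
            f"DP={ev.depth};STRAND={ev.transcript_strand}"
        )
        lines.append(f"{ev.chrom}\t{ev.pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def events_to_bed(events: Sequence[EditingEvent], path) -> None:
    """BED6 of surviving events (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for ev in sorted(events, key=lambda e: (e.chrom, e.pos, e.transcript_strand)):
            name = "target" if ev.is_target else "offtarget"
            fh.write(
                f"{ev.chrom}\t{ev.pos - 1}\t{ev.pos}\t{name}\t"
                f"{min(1000, int(round(ev.score)))}\t{ev.transcript_strand}\n"
            )
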