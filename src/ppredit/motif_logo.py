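"""Editing-extent-weighted position frequency matrices over the -15..+1 window."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .filter_cascade import EditingEvent
from .seqio import GenomeSequence, as_sequence, revcomp

logger = logging.getLogger(__name__)

WINDOW_OFFSETS = tuple(range(-15, 2))  # 17 nt, edited C at offset 0
RNA_BASES = ("A", "C", "G", "U")
_DNA2RNA = str.maketrans("T", "U")


@dataclass
class WeightedPFM:
    offsets: tuple[int, ...]
    freqs: np.ndarray  # (len(offsets), 4) over A,C,G,U rows-sum-to-1
    n_sequences: int
    weight_sum: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (len(self.offsets), 4):
            raise ValueError("freqs must be (n_offsets, 4)")
        if np.any(self.freqs < 0):
            raise ValueError("negative frequencies")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-offset frequencies must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, index=list(self.offsets), columns=list(RNA_BASES))


def extract_windows(
    genome: GenomeSequence | str,
    events: Iterable[EditingEvent],
    weight_attr: str = "f_rna",
) -> list[tuple[str, float]]:
    """17-nt transcript-strand windows (-15..+1) weighted by editing extent.

    Events flagged as the engineered target are excluded; windows that run
    off the genome are skipped with a warning.
    """
    seq = as_sequence(genome)
    out: list[tuple[str, float]] = []
    for ev in events:
        if ev.is_target:
            continue
        if ev.transcript_strand == "+":
            start, stop = ev.pos - 15, ev.pos + 1  # 1-based inclusive
            if start < 1 or stop > len(seq):
                logger.warning("window for %s:%d out of bounds; skipped", ev.chrom, ev.pos)
                continue
            window = seq[start - 1 : stop]
        else:
            start, stop = ev.pos - 1, ev.pos + 15
            if start < 1 or stop > len(seq):
                logger.warning("window for %s:%d out of bounds; skipped", ev.chrom, ev.pos)
                continue
            window = revcomp(seq[start - 1 : stop])
        out.append((window.translate(_DNA2RNA), float(getattr(ev, weight_attr))))
    return out


def weighted_pfm(windows: Sequence[tuple[str, float]]) -> WeightedPFM:
    """freq(b, j) = sum_k w_k [s_k[j] = b] / sum_k w_k."""
    if not windows:
        raise ValueError("weighted_pfm needs at least one window")
    length = len(windows[0][0])
    if any(len(s) != length for s, _ in windows):
        raise ValueError("windows have unequal lengths")
    weights = np.array([w for _, w in windows], dtype=np.float64)
    if np.any(weights < 0):
        raise ValueError("negative weights")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all-zero weights")
    counts = np.zeros((length, 4), dtype=np.float64)
    index = {b: i for i, b in enumerate(RNA_BASES)}
    for s, w in windows:
        s = s.upper().translate(_DNA2RNA)
        for j, b in enumerate(s):
            try:
                counts[j, index[b]] += w
            except KeyError:
                raise ValueError(f"non-ACGU base {b!r} in window") from None
    offsets = WINDOW_OFFSETS if length == len(WINDOW_OFFSETS) else tuple(range(length))
    return WeightedPFM(
        offsets=offsets, freqs=counts / wsum, n_sequences=len(windows), weight_sum=float(wsum)
    )


def information_content(pfm: WeightedPFM) -> np.ndarray:
    """IC_j = 2 + sum_b p log2 p, with 0*log 0 = 0; bounded by [0, 2] bits."""
    p = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return np.clip(ic, 0.0, 2.0)


def consensus(pfm: WeightedPFM) -> tuple[str, list[bool]]:
    """Per-offset arg-max base; alphabetical on exact ties, with a tie flag."""
    bases = []
    ties = []
    for row in pfm.freqs:
        best = float(row.max())
        winners = [RNA_BASES[i] for i in range(4) if row[i] == best]
        bases.append(winners[0])
        ties.append(len(winners) > 1)
    return "".join(bases), ties


def ic_matrix(pfm: WeightedPFM) -> pd.DataFrame:
    """IC-scaled frequency matrix (the canonical logo artifact)."""
    ic = information_content(pfm)
    return pd.DataFrame(
        pfm.freqs * ic[:, None], index=list(pfm.offsets), columns=list(RNA_BASES)
    )
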