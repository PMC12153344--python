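"""Candidate C-to-U event calling from stranded per-site base counts.

Count tables are TSVs with one row per covered genome position:

    chrom  pos  ref  fA fC fG fT  rA rC rG rT  sample

``f*`` columns count bases from forward-oriented reads, ``r*`` from
reverse-oriented reads; both are expressed as genome-forward base identities
(the producer has already complemented reverse-read bases), so orientation
collapse is a plain sum. Editing shows up as C->T on the forward view for
+ strand transcripts and G->A for - strand transcripts.

The per-site confidence score is the likelihood-ratio chi-square (G statistic)
of the 2x2 [ref, alt] x [RNA, DNA] table, a transparent stand-in for an
external caller's score: the downstream thresholds are percentile-based, so
any monotone contrast is equivalent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .seqio import GenomeSequence, as_sequence

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "fA", "fC", "fG", "fT", "rA", "rC", "rG", "rT", "sample"]
_BASES = ("A", "C", "G", "T")


class UndefinedFractionError(ZeroDivisionError):
    """Editing fraction requested where ref + alt = 0."""


@dataclass
class StrandedSiteCounts:
    chrom: str
    pos: int
    ref: str
    fwd_counts: dict[str, int]
    rev_counts: dict[str, int]
    sample_id: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES:
            raise ValueError(f"ref base {self.ref!r} not in A/C/G/T")
        for counts in (self.fwd_counts, self.rev_counts):
            for b, c in counts.items():
                if b not in _BASES:
                    raise ValueError(f"count key {b!r} not in A/C/G/T")
                if c < 0:
                    raise ValueError(f"negative count {c} for base {b}")

    def total(self, base: str) -> int:
        return self.fwd_counts.get(base, 0) + self.rev_counts.get(base, 0)

    @property
    def depth(self) -> int:
        return sum(self.fwd_counts.values()) + sum(self.rev_counts.values())


@dataclass
class OrientedCounts:
    """Counts collapsed onto the transcript strand for one site."""

    transcript_strand: str
    ref_count: int
    alt_count: int
    other_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


@dataclass
class CandidateEvent:
    chrom: str
    pos: int
    transcript_strand: str
    f_rna: float
    f_dna: float
    depth: int
    score: float
    sample_id: str

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.transcript_strand)


def load_counts_table(path: str | Path) -> pd.DataFrame:
    """Validated count-table DataFrame; raises with a line number on bad rows."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "sample": str})
    if list(df.columns) != COUNT_COLUMNS:
        raise ValueError(f"{path}: header must be {COUNT_COLUMNS}, got {list(df.columns)}")
    count_cols = COUNT_COLUMNS[3:11]
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2
        if rec.ref not in _BASES:
            raise ValueError(f"{path} line {line}: ref base {rec.ref!r} not in A/C/G/T")
    counts = df[count_cols]
    try:
        counts = counts.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-integer base count ({exc})") from exc
    if (counts.to_numpy() < 0).any():
        bad = int(np.argwhere((counts.to_numpy() < 0).any(axis=1))[0][0]) + 2
        raise ValueError(f"{path} line {bad}: negative base count")
    df[count_cols] = counts
    df["pos"] = df["pos"].astype(np.int64)
    return df


def read_site_counts(path: str | Path) -> list[StrandedSiteCounts]:
    """Record-level view of a count table."""
    df = load_counts_table(path)
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            StrandedSiteCounts(
                chrom=rec.chrom,
                pos=int(rec.pos),
                ref=rec.ref,
                fwd_counts={b: int(getattr(rec, f"f{b}")) for b in _BASES},
                rev_counts={b: int(getattr(rec, f"r{b}")) for b in _BASES},
                sample_id=rec.sample,
            )
        )
    return out


def write_counts_table(df: pd.DataFrame, path: str | Path) -> None:
    if list(df.columns) != COUNT_COLUMNS:
        raise ValueError(f"count table must have columns {COUNT_COLUMNS}")
    df.to_csv(path, sep="\t", index=False)


def orient_counts(site: StrandedSiteCounts, strand: str) -> OrientedCounts:
    """Collapse fwd/rev counts onto the transcript strand.

    + strand: ref = C, alt (edited) = T; - strand: ref = G, alt = A, all in
    the genome-forward view. Summing the two orientation maps is the whole
    collapse because counts are stored as genome-forward identities.
    """
    if strand == "+":
        expected, alt_base = "C", "T"
    elif strand == "-":
        expected, alt_base = "G", "A"
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if site.ref != expected:
        raise ValueError(
            f"{site.chrom}:{site.pos} ref is {site.ref}, expected {expected} for strand {strand}"
        )
    ref_count = site.total(expected)
    alt_count = site.total(alt_base)
    other = site.depth - ref_count - alt_count
    return OrientedCounts(strand, ref_count, alt_count, other)


def editing_fraction(oriented: OrientedCounts) -> float:
    """alt / (ref + alt); 'other' bases never enter the ratio."""
    denom = oriented.ref_count + oriented.alt_count
    if denom == 0:
        raise UndefinedFractionError("ref + alt = 0; editing fraction undefined")
    return oriented.alt_count / denom


def g_statistic_arrays(
    rna_ref: np.ndarray, rna_alt: np.ndarray, dna_ref: np.ndarray, dna_alt: np.ndarray
) -> np.ndarray:
    """Vectorised 2x2 G statistic, 2*sum O*ln(O/E), zero cells contributing 0."""
    a = np.asarray(rna_ref, dtype=np.float64)
    b = np.asarray(rna_alt, dtype=np.float64)
    c = np.asarray(dna_ref, dtype=np.float64)
    d = np.asarray(dna_alt, dtype=np.float64)
    n = a + b + c + d
    if np.any(n <= 0):
        raise ValueError("zero total depth in G statistic")
    g = np.zeros_like(a)
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c), (d, c + d, b + d)):
        expected = row * col / n
        g += xlogy(obs, obs) - xlogy(obs, expected)
    return np.maximum(2.0 * g, 0.0)


def site_score(rna: OrientedCounts, dna: OrientedCounts) -> float:
    """G statistic of [ref, alt] x [RNA, DNA]; symmetric in the two samples."""
    if rna.ref_count + rna.alt_count == 0 or dna.ref_count + dna.alt_count == 0:
        raise ValueError("site_score requires ref+alt depth > 0 in both samples")
    return float(
        g_statistic_arrays(
            np.array([rna.ref_count]),
            np.array([rna.alt_count]),
            np.array([dna.ref_count]),
            np.array([dna.alt_count]),
        )[0]
    )


def _oriented_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Per-row collapsed ref/alt/depth for C (+) and G (-) rows."""
    out = df[["chrom", "pos", "ref"]].copy()
    totals = {b: (df[f"f{b}"] + df[f"r{b}"]).to_numpy() for b in _BASES}
    depth = sum(totals.values())
    is_c = (df["ref"] == "C").to_numpy()
    is_g = (df["ref"] == "G").to_numpy()
    out["strand"] = np.where(is_c, "+", np.where(is_g, "-", "."))
    out["ref_n"] = np.where(is_c, totals["C"], np.where(is_g, totals["G"], 0))
    out["alt_n"] = np.where(is_c, totals["T"], np.where(is_g, totals["A"], 0))
    out["depth"] = depth
    return out[is_c | is_g]


def call_candidates(
    genome: GenomeSequence | str,
    rna_table: pd.DataFrame,
    dna_table: pd.DataFrame,
    sample_id: str,
) -> list[CandidateEvent]:
    """One candidate per genome C (+) / G (-) covered in both tables.

    Sites missing from the DNA table, or with zero oriented depth on either
    side, are skipped (and counted in a debug log).
    """
    seq = as_sequence(genome)
    rna = _oriented_frame(rna_table)
    dna = _oriented_frame(dna_table)

    # ref column must match the genome
    for tbl, label in ((rna, "RNA"), (dna, "DNA")):
        pos = tbl["pos"].to_numpy()
        if np.any((pos < 1) | (pos > len(seq))):
            raise ValueError(f"{label} table positions outside genome bounds")
        genome_ref = np.frombuffer(seq.encode(), dtype=np.uint8)[pos - 1]
        if np.any(genome_ref != np.frombuffer("".join(tbl["ref"]).encode(), dtype=np.uint8)):
            raise ValueError(f"{label} table ref bases disagree with the genome")

    merged = rna.merge(
        dna[["chrom", "pos", "ref_n", "alt_n"]],
        on=["chrom", "pos"],
        how="inner",
        suffixes=("_rna", "_dna"),
    )
    n_skipped = len(rna) - len(merged)
    usable = (merged["ref_n_rna"] + merged["alt_n_rna"] > 0) & (
        merged["ref_n_dna"] + merged["alt_n_dna"] > 0
    )
    n_skipped += int((~usable).sum())
    if n_skipped:
        logger.debug("%s: skipped %d sites without paired RNA/DNA coverage", sample_id, n_skipped)
    merged = merged[usable]
    if merged.empty:
        return []

    f_rna = merged["alt_n_rna"] / (merged["ref_n_rna"] + merged["alt_n_rna"])
    f_dna = merged["alt_n_dna"] / (merged["ref_n_dna"] + merged["alt_n_dna"])
    scores = g_statistic_arrays(
        merged["ref_n_rna"].to_numpy(),
        merged["alt_n_rna"].to_numpy(),
        merged["ref_n_dna"].to_numpy(),
        merged["alt_n_dna"].to_numpy(),
    )
    return [
        CandidateEvent(
            chrom=chrom,
            pos=int(pos),
            transcript_strand=strand,
            f_rna=float(fr),
            f_dna=float(fd),
            depth=int(depth),
            score=float(sc),
            sample_id=sample_id,
        )
        for chrom, pos, strand, fr, fd, depth, sc in zip(
            merged["chrom"], merged["pos"], merged["strand"], f_rna, f_dna, merged["depth"], scores
        )
    ]
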