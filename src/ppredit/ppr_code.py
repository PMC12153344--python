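"""PPR recognition-code model: factors, scoring tables, site profiles, genome scan.

A PPR factor is an ordered (N-to-C) list of 35-aa repeat motifs. Each
nucleotide-binding motif aligns with one transcript position upstream of the
edited C (offset 0): the last binding motif sits at offset -4 and every
preceding motif one step further upstream, so a tract of n binding motifs
covers offsets -(n+3)..-4. The C-terminal E1/E2 domains, when a scoring-table
entry exists for their specificity residues, extend the scored window to
offsets -3 and -2. Per-position scores come from a (aa5, aa_last) x nucleotide
lookup table; the site total is their sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import GenomeSequence, as_sequence

RNA_BASES = ("A", "C", "G", "U")
_DNA2RNA = str.maketrans("T", "U")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

MOTIF_CLASSES = ("P", "L", "S", "P2", "L2", "S2", "E1", "E2", "DYW")
_NON_BINDING = frozenset({"E1", "E2", "DYW"})

_AA_CODES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class MissingPairError(KeyError):
    """A (aa5, aa_last) residue pair queried against a table that lacks it."""


@dataclass(frozen=True)
class PPRMotif:
    motif_class: str
    aa5: str
    aa_last: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        for aa in (self.aa5, self.aa_last):
            if aa not in _AA_CODES:
                raise ValueError(f"invalid one-letter residue {aa!r}")

    @property
    def binds_nucleotide(self) -> bool:
        return self.motif_class not in _NON_BINDING

    @property
    def pair(self) -> tuple[str, str]:
        return (self.aa5, self.aa_last)


@dataclass(frozen=True)
class PPRFactor:
    """An ordered PPR tract; nucleotide-binding motifs must be contiguous."""

    name: str
    motifs: tuple[PPRMotif, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "motifs", tuple(self.motifs))
        binding = [m.binds_nucleotide for m in self.motifs]
        if not any(binding):
            raise ValueError("factor has no nucleotide-binding motif")
        first, last = binding.index(True), len(binding) - binding[::-1].index(True) - 1
        if not all(binding[first : last + 1]):
            raise ValueError("nucleotide-binding motifs must be contiguous")
        tail = [m.motif_class for m in self.motifs[last + 1 :]]
        expected_order = [c for c in ("E1", "E2", "DYW") if c in tail]
        if tail != expected_order:
            raise ValueError(f"C-terminal domains out of order: {tail}")

    @property
    def binding_motifs(self) -> tuple[PPRMotif, ...]:
        return tuple(m for m in self.motifs if m.binds_nucleotide)


class ScoringTable:
    """(aa5, aa_last) -> {A,C,G,U} -> score lookup.

    Missing pairs raise :class:`MissingPairError`; silent zero-fills would
    mask factor/table mismatches.
    """

    def __init__(self, entries: Mapping[tuple[str, str], Mapping[str, float]]):
        self._entries: dict[tuple[str, str], dict[str, float]] = {}
        for pair, row in entries.items():
            if set(row) != set(RNA_BASES):
                raise ValueError(f"entry {pair} must score exactly A,C,G,U")
            values = {b: float(row[b]) for b in RNA_BASES}
            if not all(math.isfinite(v) for v in values.values()):
                raise ValueError(f"non-finite score in entry {pair}")
            self._entries[tuple(pair)] = values

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(self._entries)

    def row(self, pair: tuple[str, str]) -> dict[str, float]:
        try:
            return dict(self._entries[tuple(pair)])
        except KeyError:
            raise MissingPairError(f"residue pair {pair} not in scoring table") from None

    def score(self, pair: tuple[str, str], base: str) -> float:
        base = base.upper().translate(_DNA2RNA)
        if base not in RNA_BASES:
            raise ValueError(f"cannot score base {base!r}")
        return self.row(pair)[base]

    def top_base(self, pair: tuple[str, str]) -> str:
        """Highest-scoring nucleotide for a pair; ties resolve alphabetically."""
        row = self.row(pair)
        return max(RNA_BASES, key=lambda b: (row[b], -RNA_BASES.index(b)))

    def worst_base(self, pair: tuple[str, str]) -> str:
        row = self.row(pair)
        return min(RNA_BASES, key=lambda b: (row[b], RNA_BASES.index(b)))


def read_scoring_table(path: str | Path) -> ScoringTable:
    """Read a scoring-table TSV: a residue-pair key column + A,C,G,U columns.

    The key column holds the two specificity residues, either concatenated
    (``ND``) or separated (``N-D``/``N D``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) != 5 or [c.upper().replace("T", "U") for c in cols[1:]] != list(RNA_BASES):
        raise ValueError(
            f"{path}: expected columns <pair>, A, C, G, U; got {cols}"
        )
    entries: dict[tuple[str, str], dict[str, float]] = {}
    for i, rec in df.iterrows():
        raw = str(rec[cols[0]]).strip()
        key = "".join(ch for ch in raw.upper() if ch.isalpha())
        if len(key) != 2:
            raise ValueError(f"{path} line {i + 2}: bad residue-pair key {raw!r}")
        pair = (key[0], key[1])
        if pair in entries:
            raise ValueError(f"{path} line {i + 2}: duplicate residue pair {raw!r}")
        try:
            entries[pair] = {b: float(rec[c]) for b, c in zip(RNA_BASES, cols[1:])}
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 2}: non-numeric score") from exc
    return ScoringTable(entries)


def write_scoring_table(table: ScoringTable, path: str | Path) -> None:
    rows = [
        {"pair": f"{p[0]}{p[1]}", **table.row(p)}
        for p in table.pairs
    ]
    pd.DataFrame(rows, columns=["pair", *RNA_BASES]).to_csv(path, sep="\t", index=False)


def read_factor(path: str | Path, name: str | None = None) -> PPRFactor:
    """Read a factor definition TSV with columns motif_class, aa5, aa_last."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"motif_class", "aa5", "aa_last"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: factor file needs columns {sorted(required)}")
    motifs = tuple(
        PPRMotif(r.motif_class.strip(), r.aa5.strip(), r.aa_last.strip())
        for r in df.itertuples()
    )
    return PPRFactor(name=name or Path(path).stem, motifs=motifs)


def write_factor(factor: PPRFactor, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"motif_class": m.motif_class, "aa5": m.aa5, "aa_last": m.aa_last}
            for m in factor.motifs
        ]
    ).to_csv(path, sep="\t", index=False)


def align_offsets(factor: PPRFactor) -> dict[int, int]:
    """Map motif index (position in ``factor.motifs``) to transcript offset.

    The k-th of n binding motifs lands at -(n+3)+(k-1), so the last binding
    motif is at -4; E1 and E2 map to -3 and -2.
    """
    offsets: dict[int, int] = {}
    binding = [i for i, m in enumerate(factor.motifs) if m.binds_nucleotide]
    n = len(binding)
    for k, idx in enumerate(binding):
        offsets[idx] = -(n + 3) + k
    for idx, m in enumerate(factor.motifs):
        if m.motif_class == "E1":
            offsets[idx] = -3
        elif m.motif_class == "E2":
            offsets[idx] = -2
    return offsets


def scored_offsets(factor: PPRFactor, table: ScoringTable) -> list[tuple[int, int]]:
    """(motif index, offset) pairs that contribute to the site score.

    Binding motifs always score (a missing pair is an error); E1/E2 score
    only when the table carries their residue pair.
    """
    offsets = align_offsets(factor)
    out: list[tuple[int, int]] = []
    for idx, m in enumerate(factor.motifs):
        if m.binds_nucleotide:
            if m.pair not in table:
                raise MissingPairError(
                    f"motif {idx} ({m.motif_class} {m.aa5}/{m.aa_last}) absent from table"
                )
            out.append((idx, offsets[idx]))
        elif m.motif_class in ("E1", "E2") and m.pair in table:
            out.append((idx, offsets[idx]))
    return sorted(out, key=lambda t: t[1])


@dataclass
class SiteScoreProfile:
    """Per-position recognition-code scores for one candidate cis-element."""

    chrom: str
    pos: int
    strand: str
    offsets: list[int]
    nucleotides: list[str]
    per_position_scores: list[float]
    classes: list[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(sum(self.per_position_scores))


def classify_score(score: float, tau: float = 0.0) -> str:
    if score > tau:
        return "favored"
    if score < -tau:
        return "disfavored"
    return "neutral"


def transcript_base(seq: str, pos: int, strand: str, offset: int) -> str:
    """Transcript-strand RNA base at ``offset`` relative to 1-based ``pos``."""
    if strand == "+":
        g = seq[pos - 1 + offset]
        return g.translate(_DNA2RNA)
    g = seq[pos - 1 - offset]
    return {"A": "U", "C": "G", "G": "C", "T": "A"}[g]


def score_site(
    factor: PPRFactor,
    table: ScoringTable,
    genome: GenomeSequence | str,
    pos: int,
    strand: str,
    chrom: str = "",
    tau: float = 0.0,
    require_c: bool = True,
) -> SiteScoreProfile:
    """Score the cis-element upstream of an edited C at ``pos`` on ``strand``."""
    seq = as_sequence(genome)
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    expected = "C" if strand == "+" else "G"
    if require_c and seq[pos - 1] != expected:
        raise ValueError(
            f"position {pos} is {seq[pos - 1]}, not {expected}, on the genome "
            f"forward strand for a {strand}-strand edited C"
        )
    pairs_offsets = scored_offsets(factor, table)
    lo = min(o for _, o in pairs_offsets)
    if strand == "+" and pos + lo < 1:
        raise IndexError(f"window {pos + lo}..{pos} out of genome bounds")
    if strand == "-" and pos - lo > len(seq):
        raise IndexError(f"window {pos}..{pos - lo} out of genome bounds")

    offsets, nts, scores = [], [], []
    for idx, off in pairs_offsets:
        nt = transcript_base(seq, pos, strand, off)
        offsets.append(off)
        nts.append(nt)
        scores.append(table.score(factor.motifs[idx].pair, nt))
    profile = SiteScoreProfile(
        chrom=chrom or (genome.id if isinstance(genome, GenomeSequence) else "seq"),
        pos=pos,
        strand=strand,
        offsets=offsets,
        nucleotides=nts,
        per_position_scores=scores,
        classes=[classify_score(s, tau) for s in scores],
    )
    assert abs(profile.total - sum(scores)) < 1e-12
    return profile


def max_total_score(factor: PPRFactor, table: ScoringTable) -> float:
    """Best attainable site total: sum of per-motif maxima."""
    return float(
        sum(max(table.row(factor.motifs[i].pair).values()) for i, _ in scored_offsets(factor, table))
    )


def _score_luts(factor: PPRFactor, table: ScoringTable) -> tuple[np.ndarray, np.ndarray]:
    """Per scored motif: offset array and a (motif, 4) DNA-base score LUT."""
    pairs_offsets = scored_offsets(factor, table)
    offs = np.array([o for _, o in pairs_offsets], dtype=np.int64)
    lut = np.empty((len(pairs_offsets), 4), dtype=np.float64)
    for j, (idx, _) in enumerate(pairs_offsets):
        row = table.row(factor.motifs[idx].pair)
        # DNA order A,C,G,T on the transcript strand; T scores as U
        lut[j] = [row["A"], row["C"], row["G"], row["U"]]
    return offs, lut


def scan_genome(
    factor: PPRFactor,
    table: ScoringTable,
    genome: GenomeSequence | str,
    min_total: float = float("-inf"),
    chrom: str | None = None,
) -> pd.DataFrame:
    """Score every C (both strands) with a complete upstream window.

    Returns a DataFrame (chrom, pos, strand, total) sorted by total
    descending, ties by (chrom, pos, strand).
    """
    seq = as_sequence(genome)
    name = chrom or (genome.id if isinstance(genome, GenomeSequence) else "seq")
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        code[enc == ord(b)] = i
    offs, lut = _score_luts(factor, table)
    lo = int(offs.min())
    L = len(seq)

    records: list[pd.DataFrame] = []
    # + strand: edited C at i (0-based), window i+off, needs i+lo >= 0
    pos0 = np.nonzero(code == _BASE_INDEX["C"])[0]
    pos0 = pos0[pos0 + lo >= 0]
    if pos0.size:
        tot = np.zeros(pos0.size)
        for j, off in enumerate(offs):
            tot += lut[j, code[pos0 + off]]
        records.append(pd.DataFrame({"chrom": name, "pos": pos0 + 1, "strand": "+", "total": tot}))
    # - strand: genome-forward G; transcript offset o maps to i-o; complement
    # (A<->T, C<->G) is index 3-code
    pos0 = np.nonzero(code == _BASE_INDEX["G"])[0]
    pos0 = pos0[pos0 - lo <= L - 1]
    if pos0.size:
        tot = np.zeros(pos0.size)
        for j, off in enumerate(offs):
            tot += lut[j, 3 - code[pos0 - off]]
        records.append(pd.DataFrame({"chrom": name, "pos": pos0 + 1, "strand": "-", "total": tot}))

    if not records:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "total"])
    df = pd.concat(records, ignore_index=True)
    df = df[df["total"] >= min_total]
    df = df.sort_values(
        by=["total", "chrom", "pos", "strand"], ascending=[False, True, True, True]
    ).reset_index(drop=True)
    return df


def profiles_to_matrix(profiles: Iterable[SiteScoreProfile]) -> pd.DataFrame:
    """Sites x offsets score matrix (heat-map export)."""
    profiles = list(profiles)
    if not profiles:
        return pd.DataFrame()
    offsets = profiles[0].offsets
    data = {}
    for p in profiles:
        if p.offsets != offsets:
            raise ValueError("profiles have inconsistent offset layouts")
        data[f"{p.chrom}:{p.pos}:{p.strand}"] = p.per_position_scores
    return pd.DataFrame(data, index=offsets).T
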