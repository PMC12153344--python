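"""Generators for every input the pipeline consumes, with known ground truth.

All randomness flows from explicit seeds; independent substreams for each
(sample, role) pair are derived from the master seed so that tables are
reproducible individually and jointly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import ppr_code, reporting
from .assay_quant import TitrationCurve, binding_isotherm
from .editing_detection import COUNT_COLUMNS
from .seqio import GenomeSequence

ROLES = ("rna", "dna_control", "negative_control")

#: engineered target fragment span around the edited C (offsets, inclusive)
TARGET_FRAGMENT = (-33, 5)
#: minimum spacing between planted sites so target fragments cannot overlap
MIN_SITE_SPACING = 40

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RNA2DNA = str.maketrans("U", "T")


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 10_000
    gc_fraction: float = 0.5
    n_target_sites: int = 1
    n_decoy_sites: int = 4
    editing_fractions: tuple[float, ...] = (0.8, 0.05, 0.1, 0.2, 0.4)
    depth_mean: float = 300.0
    depth_dispersion: float = 20.0
    seq_error_rate: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        for name in ("gc_fraction", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.editing_fractions):
            raise ValueError("editing_fractions must lie in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.n_target_sites < 0 or self.n_decoy_sites < 0:
            raise ValueError("site counts must be non-negative")
        n_sites = self.n_target_sites + self.n_decoy_sites
        if n_sites and len(self.editing_fractions) < n_sites:
            raise ValueError("need one editing fraction per planted site")
        object.__setattr__(self, "editing_fractions", tuple(self.editing_fractions))


@dataclass(frozen=True)
class PlantedSite:
    position: int          # 1-based coordinate of the edited C
    strand: str            # '+' or '-'
    true_fraction: float
    n_code_deviations: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.true_fraction <= 1.0:
            raise ValueError("true_fraction must lie in [0, 1]")
        if self.n_code_deviations < 0:
            raise ValueError("n_code_deviations must be non-negative")


def _substream(seed: int, *tags: str) -> np.random.Generator:
    keys = [seed] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(keys)


def simulate_genome(config: SimulationConfig, chrom: str = "synth") -> GenomeSequence:
    rng = _substream(config.rng_seed, "genome")
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=config.genome_length, p=probs)
    seq = _BASES[codes].tobytes().decode()
    return GenomeSequence(id=chrom, seq=seq)


def _site_window_positions(
    factor: ppr_code.PPRFactor, table: ppr_code.ScoringTable, site: PlantedSite
) -> dict[int, int]:
    """offset -> 0-based genome index for every scored window position."""
    out = {}
    for _, off in ppr_code.scored_offsets(factor, table):
        idx = site.position - 1 + off if site.strand == "+" else site.position - 1 - off
        out[off] = idx
    return out


def plant_sites(
    genome: GenomeSequence,
    factor: ppr_code.PPRFactor,
    table: ppr_code.ScoringTable,
    sites: list[PlantedSite],
    rng: np.random.Generator | int | None = None,
) -> GenomeSequence:
    """Write each site's preferred cis-element into the genome.

    The scored window (transcript strand) is set to the factor's top-scoring
    nucleotide per aligned motif; ``n_code_deviations`` randomly chosen window
    positions are then mutated to a non-top nucleotide, and the edited
    position itself is set to C (transcript strand).
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    seq = np.frombuffer(genome.seq.encode(), dtype=np.uint8).copy()
    offsets = ppr_code.scored_offsets(factor, table)
    claimed: set[int] = set()
    comp = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}

    for site in sites:
        window = _site_window_positions(factor, table, site)
        indices = set(window.values()) | {site.position - 1}
        if min(indices) < 0 or max(indices) >= len(seq):
            raise IndexError(f"site at {site.position}{site.strand}: window out of bounds")
        if indices & claimed:
            raise ValueError(f"site at {site.position}{site.strand}: window overlaps another site")
        claimed |= indices
        if site.n_code_deviations > len(offsets):
            raise ValueError(
                f"n_code_deviations={site.n_code_deviations} exceeds {len(offsets)} scored motifs"
            )

        def write(offset: int, rna_base: str) -> None:
            dna = rna_base.translate(_RNA2DNA)
            base = dna if site.strand == "+" else comp[rna_base]
            seq[window[offset] if offset != 0 else site.position - 1] = ord(base)

        for idx_motif, off in offsets:
            write(off, table.top_base(factor.motifs[idx_motif].pair))
        # edited C itself (genome-forward G for - strand sites)
        seq[site.position - 1] = ord("C" if site.strand == "+" else "G")

        if site.n_code_deviations:
            chosen = rng.choice(len(offsets), size=site.n_code_deviations, replace=False)
            for j in sorted(int(c) for c in chosen):
                idx_motif, off = offsets[j]
                top = table.top_base(factor.motifs[idx_motif].pair)
                others = [b for b in ppr_code.RNA_BASES if b != top]
                write(off, others[int(rng.integers(len(others)))])

    return GenomeSequence(id=genome.id, seq=seq.tobytes().decode())


def _draw_depths(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    mean, r = config.depth_mean, config.depth_dispersion
    if np.isinf(r):
        return rng.poisson(mean, size=n)
    # NB with mean m and dispersion r: var = m + m^2/r
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def simulate_counts(
    genome: GenomeSequence,
    sites: list[PlantedSite],
    config: SimulationConfig,
    role: str,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Stranded per-site base-count table for one sample.

    Depth per position follows a negative-binomial law; at planted sites the
    edited-base count is Binomial(depth, true_fraction) on the transcript
    strand (C->T forward, G->A reverse in the genome-forward view) for the
    ``rna`` role only. Every read is independently substituted at
    ``seq_error_rate``, uniformly over the three alternative bases. Counts are
    split between forward- and reverse-oriented reads with equal probability;
    both halves are expressed as genome-forward base identities.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    sample_id = sample_id or role
    rng = _substream(config.rng_seed, "counts", role, sample_id)
    L = len(genome.seq)
    enc = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    ref_code = np.searchsorted(_BASES, enc)

    depth = _draw_depths(rng, config, L)
    counts = np.zeros((L, 4), dtype=np.int64)

    # planted editing (rna role only)
    alt_at = np.zeros(L, dtype=np.int64)
    alt_base_code = np.zeros(L, dtype=np.int64)
    if role == "rna":
        for site in sites:
            i = site.position - 1
            expected = "C" if site.strand == "+" else "G"
            if genome.seq[i] != expected:
                raise ValueError(
                    f"planted site {site.position}{site.strand}: genome has "
                    f"{genome.seq[i]}, expected {expected}"
                )
            alt_at[i] = rng.binomial(depth[i], site.true_fraction)
            alt_base_code[i] = 3 if site.strand == "+" else 0  # T or A

    unedited = depth - alt_at
    if config.seq_error_rate > 0:
        n_err = rng.binomial(unedited, config.seq_error_rate)
        err_split = rng.multinomial(n_err, [1 / 3] * 3)
    else:
        n_err = np.zeros(L, dtype=np.int64)
        err_split = np.zeros((L, 3), dtype=np.int64)

    counts[np.arange(L), ref_code] += unedited - n_err
    # distribute errors over the three non-reference bases
    others = np.array([[b for b in range(4) if b != r] for r in range(4)])
    for k in range(3):
        np.add.at(counts, (np.arange(L), others[ref_code, k]), err_split[:, k])
    np.add.at(counts, (np.arange(L), alt_base_code), alt_at)

    assert np.array_equal(counts.sum(axis=1), depth)

    fwd = rng.binomial(counts, 0.5)
    rev = counts - fwd
    df = pd.DataFrame(
        {
            "chrom": genome.id,
            "pos": np.arange(1, L + 1),
            "ref": np.array(list(genome.seq)),
            "fA": fwd[:, 0], "fC": fwd[:, 1], "fG": fwd[:, 2], "fT": fwd[:, 3],
            "rA": rev[:, 0], "rC": rev[:, 1], "rG": rev[:, 2], "rT": rev[:, 3],
            "sample": sample_id,
        },
        columns=COUNT_COLUMNS,
    )
    return df


def place_sites(
    config: SimulationConfig,
    genome_length: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[PlantedSite]:
    """Deterministically place target and decoy sites >= MIN_SITE_SPACING apart.

    Targets carry zero code deviations; decoys carry 1-3. Editing fractions
    are assigned in config order (targets first).
    """
    rng = rng or _substream(config.rng_seed, "placement")
    L = genome_length or config.genome_length
    n = config.n_target_sites + config.n_decoy_sites
    if n == 0:
        return []
    margin = abs(TARGET_FRAGMENT[0]) + 1
    lo, hi = margin + 1, L - TARGET_FRAGMENT[1] - 1
    if hi - lo < (n - 1) * MIN_SITE_SPACING:
        raise ValueError("genome too short for the requested number of planted sites")
    positions: list[int] = []
    attempts = 0
    while len(positions) < n:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place sites with the required spacing")
        cand = int(rng.integers(lo, hi + 1))
        if all(abs(cand - p) >= MIN_SITE_SPACING for p in positions):
            positions.append(cand)
    positions.sort()
    sites = []
    for i, pos in enumerate(positions):
        is_target = i < config.n_target_sites
        sites.append(
            PlantedSite(
                position=pos,
                strand="+" if rng.random() < 0.5 else "-",
                true_fraction=config.editing_fractions[i],
                n_code_deviations=0 if is_target else int(rng.integers(1, 4)),
            )
        )
    return sites


def simulate_dataset(
    config: SimulationConfig,
    factor: ppr_code.PPRFactor | None = None,
    table: ppr_code.ScoringTable | None = None,
    n_rna_samples: int = 1,
    n_negative_controls: int = 1,
) -> dict:
    """Genome + planted truth + count tables for a full pipeline run."""
    factor = factor or default_factor()
    table = table or default_scoring_table()
    genome = simulate_genome(config)
    sites = place_sites(config)
    genome = plant_sites(genome, factor, table, sites, rng=_substream(config.rng_seed, "plant"))
    tables: dict[str, pd.DataFrame] = {}
    roles: dict[str, str] = {}
    for i in range(n_rna_samples):
        name = f"rna{i + 1}"
        tables[name] = simulate_counts(genome, sites, config, "rna", sample_id=name)
        roles[name] = "rna"
    tables["dna"] = simulate_counts(genome, sites, config, "dna_control", sample_id="dna")
    roles["dna"] = "dna_control"
    for i in range(n_negative_controls):
        name = f"neg{i + 1}"
        tables[name] = simulate_counts(genome, sites, config, "negative_control", sample_id=name)
        roles[name] = "negative_control"
    return {
        "genome": genome,
        "sites": sites,
        "factor": factor,
        "table": table,
        "tables": tables,
        "roles": roles,
    }


def simulate_titration(
    kd: float,
    fmax: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int | None = None,
    replicate_id: str = "",
) -> TitrationCurve:
    """1:1 isotherm evaluated at the given concentrations plus Gaussian noise."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    c = np.asarray(concentrations, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    f = binding_isotherm(c, kd, fmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=c.shape)
    return TitrationCurve(
        concentrations=c, fraction_bound=np.clip(f, 0.0, 1.0), replicate_id=replicate_id
    )


def default_factor() -> ppr_code.PPRFactor:
    with resources.as_file(resources.files("ppredit.data") / "default_factor.tsv") as p:
        return ppr_code.read_factor(p, name="syn3pls")


def default_scoring_table() -> ppr_code.ScoringTable:
    with resources.as_file(resources.files("ppredit.data") / "default_scoring_table.tsv") as p:
        return ppr_code.read_scoring_table(p)


def table2_fixture_path() -> Path:
    with resources.as_file(resources.files("ppredit.data") / "table2_fixture.tsv") as p:
        return Path(p)


def transcribe_table2_fixture() -> reporting.CrossSampleMatrix:
    """The packaged cross-sample comparison-table fixture."""
    return reporting.CrossSampleMatrix.from_tsv(table2_fixture_path())


def truth_table(sites: list[PlantedSite], chrom: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": chrom,
                "pos": s.position,
                "strand": s.strand,
                "true_fraction": s.true_fraction,
                "n_code_deviations": s.n_code_deviations,
            }
            for s in sites
        ],
        columns=["chrom", "pos", "strand", "true_fraction", "n_code_deviations"],
    )
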