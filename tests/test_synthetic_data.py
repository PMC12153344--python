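import numpy as np
import pytest

from ppredit import ppr_code
from ppredit import synthetic_data as sd
from ppredit.editing_detection import COUNT_COLUMNS


class TestSimulationConfig:
    def test_valid(self):
        sd.SimulationConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"genome_length": 50},
            {"gc_fraction": 1.2},
            {"seq_error_rate": -0.1},
            {"depth_mean": 0},
            {"depth_dispersion": 0},
            {"editing_fractions": (1.5,), "n_target_sites": 1, "n_decoy_sites": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            sd.SimulationConfig(**kwargs)


class TestSimulateGenome:
    def test_determinism(self):
        cfg = sd.SimulationConfig(genome_length=1000, gc_fraction=0.5, rng_seed=1)
        assert sd.simulate_genome(cfg).seq == sd.simulate_genome(cfg).seq

    def test_gc_one_boundary(self):
        cfg = sd.SimulationConfig(genome_length=500, gc_fraction=1.0, rng_seed=2)
        assert set(sd.simulate_genome(cfg).seq) <= {"G", "C"}

    def test_gc_content_recovered(self):
        # oracle: count G+C over the generated string
        cfg = sd.SimulationConfig(genome_length=50_000, gc_fraction=0.4, rng_seed=7)
        seq = sd.simulate_genome(cfg).seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.37 <= gc <= 0.43

    def test_length(self):
        cfg = sd.SimulationConfig(genome_length=1234, rng_seed=0)
        assert len(sd.simulate_genome(cfg)) == 1234


class TestPlantSites:
    def test_perfect_match_attains_max(self, factor, table):
        cfg = sd.SimulationConfig(genome_length=500, rng_seed=3)
        genome = sd.simulate_genome(cfg)
        site = sd.PlantedSite(position=100, strand="+", true_fraction=0.5)
        planted = sd.plant_sites(genome, factor, table, [site], rng=0)
        profile = ppr_code.score_site(factor, table, planted, 100, "+")
        assert profile.total == pytest.approx(ppr_code.max_total_score(factor, table))

    def test_all_deviations_recomputable(self, factor, table):
        # every scored position mutated away from the top base; the total must
        # equal an independent per-position lookup and be strictly below max
        cfg = sd.SimulationConfig(genome_length=500, rng_seed=3)
        genome = sd.simulate_genome(cfg)
        n_scored = len(ppr_code.scored_offsets(factor, table))
        site = sd.PlantedSite(position=100, strand="+", true_fraction=0.5, n_code_deviations=n_scored)
        planted = sd.plant_sites(genome, factor, table, [site], rng=1)
        profile = ppr_code.score_site(factor, table, planted, 100, "+")
        by_hand = 0.0
        for (idx, off), nt in zip(ppr_code.scored_offsets(factor, table), profile.nucleotides):
            pair = factor.motifs[idx].pair
            assert nt != table.top_base(pair)
            by_hand += table.score(pair, nt)
        assert profile.total == pytest.approx(by_hand)
        assert profile.total < ppr_code.max_total_score(factor, table)

    def test_minus_strand_writes_g(self, factor, table):
        cfg = sd.SimulationConfig(genome_length=500, rng_seed=4)
        genome = sd.simulate_genome(cfg)
        site = sd.PlantedSite(position=400, strand="-", true_fraction=0.5)
        planted = sd.plant_sites(genome, factor, table, [site], rng=0)
        assert planted.base(400) == "G"

    def test_overlapping_windows_rejected(self, factor, table):
        cfg = sd.SimulationConfig(genome_length=500, rng_seed=5)
        genome = sd.simulate_genome(cfg)
        sites = [
            sd.PlantedSite(position=100, strand="+", true_fraction=0.5),
            sd.PlantedSite(position=105, strand="+", true_fraction=0.5),
        ]
        with pytest.raises(ValueError, match="overlap"):
            sd.plant_sites(genome, factor, table, sites, rng=0)

    def test_out_of_bounds_rejected(self, factor, table):
        cfg = sd.SimulationConfig(genome_length=500, rng_seed=5)
        genome = sd.simulate_genome(cfg)
        with pytest.raises(IndexError):
            sd.plant_sites(
                genome, factor, table,
                [sd.PlantedSite(position=5, strand="+", true_fraction=0.5)], rng=0,
            )


class TestSimulateCounts:
    def _planted(self, factor, table, *, error, fraction, seed, depth=10_000, length=500):
        cfg = sd.SimulationConfig(
            genome_length=length, depth_mean=depth, depth_dispersion=1e9,
            seq_error_rate=error, rng_seed=seed,
        )
        genome = sd.simulate_genome(cfg)
        site = sd.PlantedSite(position=250, strand="+", true_fraction=fraction)
        genome = sd.plant_sites(genome, factor, table, [site], rng=0)
        return cfg, genome, site

    def test_no_editing_no_error_gives_zero_alt(self, factor, table):
        cfg, genome, site = self._planted(factor, table, error=0.0, fraction=0.0, seed=6)
        df = sd.simulate_counts(genome, [site], cfg, "rna")
        row = df[df["pos"] == site.position].iloc[0]
        assert row["fT"] + row["rT"] == 0

    def test_half_fraction_recovered(self, factor, table):
        # binomial 99% interval at n=10000, p=0.5 is within +-0.013
        cfg, genome, site = self._planted(factor, table, error=0.0, fraction=0.5, seed=7)
        df = sd.simulate_counts(genome, [site], cfg, "rna")
        row = df[df["pos"] == site.position].iloc[0]
        alt = row["fT"] + row["rT"]
        ref = row["fC"] + row["rC"]
        assert 0.47 <= alt / (alt + ref) <= 0.53

    def test_dna_control_error_rate(self, factor, table):
        cfg = sd.SimulationConfig(
            genome_length=10_000, depth_mean=100, depth_dispersion=1e9,
            seq_error_rate=0.001, rng_seed=8,
        )
        genome = sd.simulate_genome(cfg)
        df = sd.simulate_counts(genome, [], cfg, "dna_control")
        counts = df[["fA", "fC", "fG", "fT", "rA", "rC", "rG", "rT"]].to_numpy()
        depth = counts.sum(axis=1)
        ref_idx = np.array(["ACGT".index(b) for b in df["ref"]])
        total_ref = counts[np.arange(len(df)), ref_idx] + counts[np.arange(len(df)), ref_idx + 4]
        mismatch = (depth - total_ref) / np.maximum(depth, 1)
        assert np.mean(mismatch) == pytest.approx(0.001, rel=0.15)

    def test_dna_control_ignores_editing(self, factor, table):
        cfg, genome, site = self._planted(factor, table, error=0.0, fraction=0.9, seed=9)
        df = sd.simulate_counts(genome, [site], cfg, "dna_control")
        row = df[df["pos"] == site.position].iloc[0]
        assert row["fT"] + row["rT"] == 0

    def test_determinism_and_schema(self, factor, table):
        cfg, genome, site = self._planted(factor, table, error=0.001, fraction=0.3, seed=10)
        a = sd.simulate_counts(genome, [site], cfg, "rna", sample_id="s1")
        b = sd.simulate_counts(genome, [site], cfg, "rna", sample_id="s1")
        assert a.equals(b)
        assert list(a.columns) == COUNT_COLUMNS

    def test_depth_conservation(self, factor, table):
        cfg, genome, site = self._planted(factor, table, error=0.01, fraction=0.3, seed=11)
        df = sd.simulate_counts(genome, [site], cfg, "rna")
        counts = df[["fA", "fC", "fG", "fT", "rA", "rC", "rG", "rT"]].to_numpy()
        # all base counts are non-negative and rows sum to a plausible NB draw
        assert (counts >= 0).all()

    def test_bad_role(self, factor, table):
        cfg, genome, site = self._planted(factor, table, error=0.0, fraction=0.5, seed=12)
        with pytest.raises(ValueError, match="role"):
            sd.simulate_counts(genome, [site], cfg, "rna_sample")

    def test_minus_strand_alt_is_a(self, factor, table):
        cfg = sd.SimulationConfig(
            genome_length=500, depth_mean=1000, depth_dispersion=1e9,
            seq_error_rate=0.0, rng_seed=13,
        )
        genome = sd.simulate_genome(cfg)
        site = sd.PlantedSite(position=250, strand="-", true_fraction=0.5)
        genome = sd.plant_sites(genome, factor, table, [site], rng=0)
        df = sd.simulate_counts(genome, [site], cfg, "rna")
        row = df[df["pos"] == site.position].iloc[0]
        assert row["fA"] + row["rA"] > 300
        assert row["fT"] + row["rT"] == 0


class TestRecoveryProperty:
    def test_recovery_within_3sd(self, factor, table):
        cfg = sd.SimulationConfig(
            genome_length=1000, n_target_sites=1, n_decoy_sites=2,
            editing_fractions=(0.3, 0.6, 0.1), depth_mean=2000, depth_dispersion=1e9,
            seq_error_rate=0.0, rng_seed=14,
        )
        data = sd.simulate_dataset(cfg, factor, table)
        df = data["tables"]["rna1"]
        for site in data["sites"]:
            row = df[df["pos"] == site.position].iloc[0]
            if site.strand == "+":
                alt, ref = row["fT"] + row["rT"], row["fC"] + row["rC"]
            else:
                alt, ref = row["fA"] + row["rA"], row["fG"] + row["rG"]
            n = alt + ref
            f_hat = alt / n
            sd3 = 3 * np.sqrt(site.true_fraction * (1 - site.true_fraction) / n)
            assert abs(f_hat - site.true_fraction) <= sd3


class TestSimulateTitration:
    def test_half_saturation(self):
        curve = sd.simulate_titration(kd=0.7, fmax=1.0, concentrations=[0.7], noise_sd=0.0)
        assert curve.fraction_bound[0] == pytest.approx(0.5)

    def test_zero_concentration(self):
        curve = sd.simulate_titration(kd=0.7, fmax=0.9, concentrations=[0.0], noise_sd=0.0)
        assert curve.fraction_bound[0] == 0.0

    def test_closed_form(self):
        c = np.linspace(0.1, 4, 20)
        curve = sd.simulate_titration(kd=0.5, fmax=1.0, concentrations=c, noise_sd=0.0)
        assert np.allclose(curve.fraction_bound, c / (0.5 + c), atol=1e-12)

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            sd.simulate_titration(kd=0.0, fmax=1.0, concentrations=[1.0])

    def test_noise_reproducible(self):
        a = sd.simulate_titration(0.5, 1.0, [0.1, 1, 2], noise_sd=0.05, seed=3)
        b = sd.simulate_titration(0.5, 1.0, [0.1, 1, 2], noise_sd=0.05, seed=3)
        assert np.array_equal(a.fraction_bound, b.fraction_bound)


class TestTable2Fixture:
    def test_offtarget_row_count(self, fixture_matrix):
        assert len(fixture_matrix.offtarget_labels) == 34

    def test_rpoa_sample14(self, fixture_matrix):
        assert fixture_matrix.extent.loc["rpoA", "sample14"] == pytest.approx(4.5)
        assert bool(fixture_matrix.flags.loc["rpoA", "sample14"])

    def test_site_1838803_n_samples(self, fixture_matrix):
        assert int(fixture_matrix.n_samples.loc["1838803"]) == 8

    def test_twelve_sample_columns(self, fixture_matrix):
        assert len(fixture_matrix.samples) == 12


class TestPlaceSites:
    def test_spacing(self):
        cfg = sd.SimulationConfig(
            genome_length=5000, n_target_sites=2, n_decoy_sites=8,
            editing_fractions=tuple([0.5] * 10), rng_seed=15,
        )
        sites = sd.place_sites(cfg)
        positions = sorted(s.position for s in sites)
        assert all(b - a >= sd.MIN_SITE_SPACING for a, b in zip(positions, positions[1:]))
        assert sum(s.n_code_deviations == 0 for s in sites) >= 2

    def test_too_short(self):
        cfg = sd.SimulationConfig(
            genome_length=150, n_target_sites=3, n_decoy_sites=3,
            editing_fractions=tuple([0.5] * 6), rng_seed=16,
        )
        with pytest.raises(ValueError):
            sd.place_sites(cfg)
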