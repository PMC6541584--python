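import numpy as np
import pytest

from telodiff import (
    GenomeAnnotation,
    KdeConfig,
    ValidationError,
    flag_chromosomes,
    kde_positions,
    permutation_envelope,
    positional_analysis,
    scaled_bandwidth,
    telomere_fraction,
)
from telodiff.enrichment import DensityEnvelope, TelomereStats


def uniform_universe(n_per_chrom, lengths, seed=0) -> GenomeAnnotation:
    rng = np.random.default_rng(seed)
    gene_start_of = {}
    i = 0
    for chrom, L in lengths.items():
        for _ in range(n_per_chrom):
            gene_start_of[f"t{i}"] = (chrom, int(rng.integers(0, L)))
            i += 1
    return GenomeAnnotation(dict(lengths), gene_start_of)


class TestScaledBandwidth:
    def test_reference_chromosome_keeps_reference_bandwidth(self):
        ann = GenomeAnnotation({"chrA": 50_000_000}, {})
        cfg = KdeConfig(ref_chrom="chrA", ref_bandwidth_bp=2e6)
        assert scaled_bandwidth("chrA", ann, cfg) == 2e6

    def test_linear_scaling(self):
        ann = GenomeAnnotation({"chrA": 50_000_000, "chrB": 100_000_000}, {})
        cfg = KdeConfig(ref_chrom="chrA", ref_bandwidth_bp=2e6)
        assert scaled_bandwidth("chrB", ann, cfg) == 4e6

    def test_unknown_chromosome_rejected(self):
        ann = GenomeAnnotation({"chrA": 50_000_000}, {})
        with pytest.raises(ValidationError, match="unknown"):
            scaled_bandwidth("chrZ", ann, KdeConfig(ref_chrom="chrA"))

    def test_ref_defaults_to_chr20_when_present(self):
        ann = GenomeAnnotation({"chr20": 64_000_000, "chr1": 249_000_000}, {})
        assert KdeConfig().resolve_ref_chrom(ann) == "chr20"


class TestKde:
    def test_single_position_peak_at_nearest_grid_point(self):
        grid, dens = kde_positions([30_000_000], 100_000_000, 2e6, 256)
        peak = grid[np.argmax(dens)]
        nearest = grid[np.argmin(np.abs(grid - 30_000_000))]
        assert peak == nearest

    def test_two_separated_clusters_give_two_local_maxima(self):
        L = 100_000_000
        pos = [L // 4] * 5 + [3 * L // 4] * 5
        grid, dens = kde_positions(pos, L, 2e6, 512)
        interior = dens[1:-1]
        maxima = np.where((interior > dens[:-2]) & (interior > dens[2:]))[0] + 1
        peaks = grid[maxima]
        assert any(abs(p - L / 4) < 5e6 for p in peaks)
        assert any(abs(p - 3 * L / 4) < 5e6 for p in peaks)
        assert len(maxima) == 2

    def test_interior_mass_integrates_to_one(self):
        rng = np.random.default_rng(4)
        L = 100_000_000
        pos = rng.uniform(0.3 * L, 0.7 * L, size=50)
        grid, dens = kde_positions(pos, L, 2e6, 512)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.1)

    def test_matches_independent_kernel_sum(self):
        # oracle: independently written scalar loop over kernels
        rng = np.random.default_rng(6)
        for _ in range(30):
            L = float(rng.integers(10_000, 1_000_000))
            n = int(rng.integers(1, 12))
            pos = rng.uniform(0, L, size=n)
            bw = float(rng.uniform(L / 50, L / 5))
            grid, dens = kde_positions(pos, L, bw, 33)
            for j in range(0, 33, 8):
                acc = 0.0
                for x in pos:
                    acc += np.exp(-0.5 * ((grid[j] - x) / bw) ** 2)
                acc /= n * bw * np.sqrt(2 * np.pi)
                assert abs(acc - dens[j]) < 1e-9

    @pytest.mark.parametrize(
        "pos,L,bw",
        [([], 100.0, 1.0), ([150.0], 100.0, 1.0), ([10.0], 100.0, 0.0)],
    )
    def test_invalid_inputs_rejected(self, pos, L, bw):
        with pytest.raises(ValidationError):
            kde_positions(pos, L, bw, 64)


class TestEnvelope:
    def test_degenerate_universe_collapses_band(self):
        # every transcript at the same position: all replicate densities equal
        ann = GenomeAnnotation(
            {"chrA": 1_000_000},
            {f"t{i}": ("chrA", 500_000) for i in range(20)},
        )
        cfg = KdeConfig(ref_chrom="chrA", n_replicates=50, grid_points_per_chrom=32)
        rng = np.random.default_rng(0)
        lower, upper = permutation_envelope(ann, 5, "chrA", cfg, rng)
        assert np.allclose(lower, upper)

    def test_lower_below_upper_everywhere(self):
        ann = uniform_universe(50, {"chrA": 50_000_000, "chrB": 30_000_000})
        cfg = KdeConfig(ref_chrom="chrA", n_replicates=100, grid_points_per_chrom=64)
        rng = np.random.default_rng(1)
        lower, upper = permutation_envelope(ann, 30, "chrA", cfg, rng)
        assert np.all(lower <= upper + 1e-15)
        assert np.all(lower >= 0)

    def test_overdrawn_selection_rejected(self):
        ann = uniform_universe(5, {"chrA": 50_000_000})
        with pytest.raises(ValidationError, match="n_select"):
            permutation_envelope(
                ann, 99, "chrA", KdeConfig(ref_chrom="chrA"), np.random.default_rng(0)
            )


class TestTelomereFraction:
    def test_gene_near_end_is_telomeric(self):
        ann = GenomeAnnotation({"chrA": 50_000_000}, {"t0": ("chrA", 45_000_000)})
        stats = telomere_fraction(["t0"], ann, 10_000_000)
        assert stats.overall_fraction_telomeric == 1.0

    def test_gene_at_midpoint_is_not(self):
        ann = GenomeAnnotation({"chrA": 100_000_000}, {"t0": ("chrA", 50_000_000)})
        stats = telomere_fraction(["t0"], ann, 10_000_000)
        assert stats.overall_fraction_telomeric == 0.0

    def test_all_in_windows_gives_unit_fraction(self):
        ann = GenomeAnnotation(
            {"chrA": 100_000_000},
            {"t0": ("chrA", 1_000), "t1": ("chrA", 99_999_000), "t2": ("chrA", 5_000_000)},
        )
        stats = telomere_fraction(["t0", "t1", "t2"], ann, 10_000_000)
        assert stats.overall_fraction_telomeric == 1.0
        assert stats.per_chrom_fraction["chrA"] == 1.0

    def test_boundary_inclusive(self):
        ann = GenomeAnnotation({"chrA": 100_000_000}, {"t0": ("chrA", 10_000_000)})
        stats = telomere_fraction(["t0"], ann, 10_000_000)
        assert stats.overall_fraction_telomeric == 1.0

    def test_unannotated_de_transcript_is_error(self):
        ann = GenomeAnnotation({"chrA": 100_000_000}, {})
        with pytest.raises(ValidationError, match="unannotated"):
            telomere_fraction(["ghost"], ann, 10_000_000)


class TestFlagging:
    def _env(self, chrom, observed_exceeds):
        grid = np.linspace(0, 100_000_000, 64)
        upper = np.full(64, 1e-8)
        observed = np.full(64, 5e-9)
        if observed_exceeds:
            observed[1] = 2e-8  # inside the left telomeric window
        return DensityEnvelope(
            chrom=chrom, grid=grid, observed=observed,
            lower=np.zeros(64), upper=upper,
            n_observed_points=10, bandwidth_bp=2e6,
        )

    def test_fraction_without_exceedance_not_flagged(self):
        stats = TelomereStats(0.5, {"chrA": 0.5}, 10)
        flagged = flag_chromosomes([self._env("chrA", False)], stats, KdeConfig(ref_chrom="chrA"))
        assert flagged == set()

    def test_conjunction_flags(self):
        stats = TelomereStats(0.5, {"chrA": 0.5}, 10)
        flagged = flag_chromosomes([self._env("chrA", True)], stats, KdeConfig(ref_chrom="chrA"))
        assert flagged == {"chrA"}

    def test_exceedance_without_fraction_not_flagged(self):
        stats = TelomereStats(0.1, {"chrA": 0.1}, 10)
        flagged = flag_chromosomes([self._env("chrA", True)], stats, KdeConfig(ref_chrom="chrA"))
        assert flagged == set()

    def test_empty_de_set_gives_empty_flags(self):
        ann = uniform_universe(20, {"chrA": 50_000_000})
        envs, stats = positional_analysis(
            [], list(ann.gene_start_of), ann,
            KdeConfig(ref_chrom="chrA", n_replicates=10, grid_points_per_chrom=16),
        )
        assert envs == [] and stats.flagged_chroms == set()


class TestDeterminism:
    def test_same_seed_identical_envelopes(self):
        ann = uniform_universe(40, {"chrA": 60_000_000, "chrB": 40_000_000}, seed=3)
        de_ids = list(ann.gene_start_of)[:25]
        cfg = KdeConfig(ref_chrom="chrA", n_replicates=100,
                        grid_points_per_chrom=64, seed=11)
        e1, s1 = positional_analysis(de_ids, list(ann.gene_start_of), ann, cfg)
        e2, s2 = positional_analysis(de_ids, list(ann.gene_start_of), ann, cfg)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.lower, b.lower)
            assert np.array_equal(a.upper, b.upper)
            assert np.array_equal(a.observed, b.observed)
        assert s1.flagged_chroms == s2.flagged_chroms
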