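import numpy as np
import pytest
from scipy import stats

from mfakit.coverage import WindowScheme, make_windows
from mfakit.synthetic import (ConfigurationError, GCBiasSpec,
                              RearrangementSpec, SimulationConfig,
                              apply_rearrangements, copy_number_profile,
                              generate_genome, simulate_fragments,
                              write_fixture_set)


class TestGenerateGenome:
    def test_overall_gc_near_target(self):
        cfg = SimulationConfig(genome_length=100_000,
                               gc_blocks=((100_000, 0.5),), seed=1)
        g = generate_genome(cfg)
        gc = g.gc_mask.mean()
        assert 0.47 <= gc <= 0.53

    def test_per_block_gc_within_tolerance(self):
        cfg = SimulationConfig(genome_length=50_000,
                               gc_blocks=((5000, 0.3), (5000, 0.7)), seed=2)
        g = generate_genome(cfg)
        for i in range(10):
            block_gc = g.gc_mask[i * 5000:(i + 1) * 5000].mean()
            target = 0.3 if i % 2 == 0 else 0.7
            assert abs(block_gc - target) <= 0.03

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(genome_length=20_000, seed=3)
        assert generate_genome(cfg).sequence == generate_genome(cfg).sequence

    def test_invalid_gc_target_rejected(self):
        cfg = SimulationConfig(genome_length=10_000, gc_blocks=((10_000, 1.5),))
        with pytest.raises(ConfigurationError):
            generate_genome(cfg)
        with pytest.raises(ConfigurationError):
            generate_genome(SimulationConfig(genome_length=0))

    def test_window_boundary_downstream(self):
        # a genome exactly one window long is usable; one bp shorter is not
        scheme = WindowScheme(1000, 500)
        make_windows(1000, scheme)
        with pytest.raises(Exception):
            make_windows(999, scheme)


class TestCopyNumberProfile:
    def test_random_mode_flat(self):
        p = copy_number_profile(10_000, "random")
        assert np.all(p.values == p.values[0])

    def test_single_origin_closed_form(self):
        L = 1_000_000
        p = copy_number_profile(L, "single_origin", [0], k=1.0)
        assert p.values[0] / p.values[L // 2] == pytest.approx(2.0)
        # maximum at the origin, minimum at the antipodal terminus
        assert np.argmax(p.values) == 0
        assert np.argmin(p.values) == L // 2

    def test_zero_amplitude_equals_random(self):
        p0 = copy_number_profile(10_000, "single_origin", [1234], k=0.0)
        pr = copy_number_profile(10_000, "random")
        np.testing.assert_allclose(p0.values, pr.values)

    def test_multi_origin_max_of_gradients(self):
        L = 100_000
        p = copy_number_profile(L, "multi_origin", [0, L // 2], k=1.0)
        # each origin is a local maximum; midpoints between them are minima
        assert p.values[0] == pytest.approx(2.0)
        assert p.values[L // 2] == pytest.approx(2.0)
        assert p.values[L // 4] == pytest.approx(2 ** 0.5)

    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            copy_number_profile(1000, "single_origin", [0], k=-1.0)
        with pytest.raises(ConfigurationError):
            copy_number_profile(1000, "single_origin", [5000])
        with pytest.raises(ConfigurationError):
            copy_number_profile(1000, "unknown")


class TestSimulateFragments:
    L = 100_000

    def _genome(self, seed=1):
        return generate_genome(SimulationConfig(
            genome_length=self.L, gc_blocks=((self.L, 0.5),), seed=seed))

    def test_fragment_count_conserved(self):
        g = self._genome()
        flat = copy_number_profile(self.L, "random")
        frags = simulate_fragments(g, flat, GCBiasSpec.identity(), 150, 5000, 7)
        assert len(frags) == 5000
        # chimeric wrap splits count once but carry two blocks
        assert frags.total_bases == 5000 * 150

    def test_flat_profile_uniform_bins(self):
        g = self._genome()
        flat = copy_number_profile(self.L, "random")
        frags = simulate_fragments(g, flat, GCBiasSpec.identity(), 150, 100_000, 8)
        bins = np.bincount(frags.b1_start * 10 // self.L, minlength=10)
        p = stats.chisquare(bins).pvalue
        assert p > 0.001

    def test_origin_gradient_density_ratio(self):
        g = self._genome()
        prof = copy_number_profile(self.L, "single_origin", [0], k=1.0)
        frags = simulate_fragments(g, prof, GCBiasSpec.identity(), 150, 400_000, 9)
        starts = np.concatenate([frags.b1_start[~frags.is_chimeric],
                                 frags.b2_start[frags.is_chimeric]])
        w = 5000
        near_ori = np.sum((starts < w) | (starts >= self.L - w))
        ter = self.L // 2
        near_ter = np.sum((starts >= ter - w) & (starts < ter + w))
        assert near_ori / near_ter == pytest.approx(2.0, rel=0.10)

    def test_step_bias_doubles_high_gc_blocks(self):
        cfg = SimulationConfig(genome_length=self.L,
                               gc_blocks=((5000, 0.3), (5000, 0.7)), seed=4)
        g = generate_genome(cfg)
        flat = copy_number_profile(self.L, "random")
        frags = simulate_fragments(g, flat, GCBiasSpec.step(0.5, 2.0),
                                   150, 200_000, 10)
        block = (frags.b1_start // 5000) % 2
        ratio = np.sum(block == 1) / np.sum(block == 0)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_wrap_fragments_split_into_two_blocks(self):
        g = self._genome()
        flat = copy_number_profile(self.L, "random")
        frags = simulate_fragments(g, flat, GCBiasSpec.identity(), 150, 50_000, 11)
        chim = frags.is_chimeric
        assert chim.any()
        # wrap split: first block starts at 0, second ends at L, same strand
        assert np.all(frags.b1_start[chim] == 0)
        assert np.all(frags.b2_end[chim] == self.L)
        assert np.all(frags.b1_strand[chim] == frags.b2_strand[chim])
        # no coordinate ever reaches past L
        assert frags.b1_end.max() <= self.L

    def test_deterministic_under_seed(self):
        g = self._genome()
        flat = copy_number_profile(self.L, "random")
        a = simulate_fragments(g, flat, GCBiasSpec.identity(), 150, 1000, 42)
        b = simulate_fragments(g, flat, GCBiasSpec.identity(), 150, 1000, 42)
        np.testing.assert_array_equal(a.b1_start, b.b1_start)
        np.testing.assert_array_equal(a.b1_strand, b.b1_strand)


class TestApplyRearrangements:
    L = 100_000

    def _setup(self, seed=5):
        g = generate_genome(SimulationConfig(
            genome_length=self.L, gc_blocks=((self.L, 0.5),), seed=seed))
        return g, copy_number_profile(self.L, "random")

    def test_zero_fraction_identical_to_plain_simulation(self):
        g, flat = self._setup()
        spec = RearrangementSpec("inversion", 30_000, 80_000, 0.0)
        a = apply_rearrangements(g, flat, GCBiasSpec.identity(), 150, 2000,
                                 [spec], 21)
        b = simulate_fragments(g, flat, GCBiasSpec.identity(), 150, 2000, 21)
        np.testing.assert_array_equal(a.b1_start, b.b1_start)

    def test_full_excision_leaves_no_bases_inside(self):
        g, flat = self._setup()
        spec = RearrangementSpec("excision", 40_000, 60_000, 1.0)
        frags = apply_rearrangements(g, flat, GCBiasSpec.identity(), 150,
                                     20_000, [spec], 22)
        bs, be = frags.block_arrays()
        inside = (be > 40_000) & (bs < 60_000)
        assert inside.sum() == 0
        assert len(frags) == 20_000

    def test_inversion_chimera_count_matches_crossing_rate(self):
        g, flat = self._setup()
        f, depth, flen = 0.10, 300.0, 150
        n = int(depth * self.L / flen)
        spec = RearrangementSpec("inversion", 30_000, 80_000, f)
        frags = apply_rearrangements(g, flat, GCBiasSpec.identity(), flen, n,
                                     [spec], 23)
        chim = frags.is_chimeric & (frags.b1_start != 0)
        # expected junctions per breakpoint: f * (n/L) * (flen - 1)
        expected = 2 * f * n / self.L * (flen - 1)
        assert frags.is_chimeric.sum() > 0
        assert chim.sum() == pytest.approx(expected, rel=0.35)

    def test_junction_blocks_flank_breakpoints(self):
        g, flat = self._setup()
        a, b = 30_000, 80_000
        spec = RearrangementSpec("inversion", a, b, 1.0)
        frags = apply_rearrangements(g, flat, GCBiasSpec.identity(), 150,
                                     50_000, [spec], 24)
        chim = frags.is_chimeric & (frags.b1_start != 0)
        hh = chim & (frags.b1_strand == 1) & (frags.b2_strand == -1)
        tt = chim & (frags.b1_strand == -1) & (frags.b2_strand == 1)
        assert np.all(frags.b1_end[hh] == a)
        assert np.all(frags.b2_end[hh] == b)
        assert np.all(frags.b1_start[tt] == a)
        assert np.all(frags.b2_start[tt] == b)

    def test_invalid_specs_rejected(self):
        g, flat = self._setup()
        with pytest.raises(ConfigurationError):
            RearrangementSpec("inversion", 5000, 4000, 0.1)
        with pytest.raises(ConfigurationError):
            RearrangementSpec("inversion", 100, 200, 1.5)
        with pytest.raises(ConfigurationError):
            apply_rearrangements(
                g, flat, GCBiasSpec.identity(), 150, 100,
                [RearrangementSpec("excision", 50, 5000, 0.5)], 1)


class TestWriteFixtureSet:
    def _config(self, n=2000, seed=6):
        return SimulationConfig(genome_length=20_000,
                                gc_blocks=((20_000, 0.5),),
                                origins=(5_000,), n_fragments=n, seed=seed)

    def test_smoke_and_parseable(self, tmp_path):
        paths = write_fixture_set(self._config(), tmp_path)
        from mfakit.fragments import FragmentSet
        from mfakit.genome import read_fasta
        g = read_fasta(paths["genome"])
        assert g.length == 20_000
        frags = FragmentSet.from_bed(paths["exponential"])
        assert len(frags) == 2000
        import json
        truth = json.loads(paths["truth"].read_text())
        assert truth["origins"] == [5000]
        assert truth["mean_depth"] == pytest.approx(2000 * 150 / 20_000)

    def test_byte_identical_under_repeated_seed(self, tmp_path):
        p1 = write_fixture_set(self._config(), tmp_path / "a")
        p2 = write_fixture_set(self._config(), tmp_path / "b")
        assert p1["exponential"].read_bytes() == p2["exponential"].read_bytes()
        assert p1["genome"].read_bytes() == p2["genome"].read_bytes()

    def test_zero_fragments_gives_empty_valid_bed(self, tmp_path):
        paths = write_fixture_set(self._config(n=0), tmp_path)
        from mfakit.fragments import FragmentSet
        assert len(FragmentSet.from_bed(paths["exponential"])) == 0
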