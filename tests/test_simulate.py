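"""Synthetic screen generator: library construction, fitness link,
competitive-growth propagation, and FASTQ emission."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dockscreen import (SimulationConfig, assign_fitness,
                        build_synthetic_library, emit_fastq,
                        simulate_selection)
from dockscreen.motifs import HEPTP_MOTIF, LIBRARY_CONSENSUS, scan_motif
from dockscreen.simulate import ConfigError, _time_for_doublings


class TestConfig:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.doubling_grid[0] == 0.0 and cfg.reference_genotype == "WT"

    @pytest.mark.parametrize("kwargs", [
        dict(frac_heptp=1.5),
        dict(frac_heptp=0.2, heptp_window=None),
        dict(doubling_grid=(1.0, 2.0)),
        dict(doubling_grid=(0.0, 2.0, 2.0)),
        dict(read_depth=0),
        dict(fold_loss_bounds=(0.5, 40.0)),
        dict(kd_bounds=(-1.0, 10.0)),
        dict(r0=0.0),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            SimulationConfig.from_dict({"n_memberz": 10})


class TestLibraryGeneration:
    def test_exact_heptp_fraction(self):
        cfg = SimulationConfig(n_members=100, frac_heptp=0.2, seed=7)
        lib = build_synthetic_library(cfg)
        n_match = sum(bool(scan_motif(m.peptide, HEPTP_MOTIF)) for m in lib)
        assert n_match == 20
        by_class = sum(m.motif_class == "HEPTP_like" for m in lib)
        assert by_class == 20

    def test_every_member_matches_consensus(self, small_library):
        assert all(scan_motif(m.peptide, LIBRARY_CONSENSUS)
                   for m in small_library)

    def test_empty_library(self):
        lib = build_synthetic_library(SimulationConfig(n_members=0))
        assert len(lib) == 0

    def test_deterministic_for_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(n_members=50, frac_heptp=0.1, seed=9)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        build_synthetic_library(cfg).to_tsv(a)
        build_synthetic_library(cfg).to_tsv(b)
        assert a.read_bytes() == b.read_bytes()

    def test_seed_changes_library(self):
        base = SimulationConfig(n_members=50, seed=1)
        other = SimulationConfig(n_members=50, seed=2)
        assert (build_synthetic_library(base).peptides()
                != build_synthetic_library(other).peptides())


class TestFitness:
    def test_neutral_when_s_zero(self, small_library):
        cfg = SimulationConfig(n_members=40, frac_heptp=0.2, seed=3, s=0.0)
        fit = assign_fitness(small_library, cfg)
        for g in cfg.genotypes:
            assert np.allclose(fit.rates(g, "selective"), cfg.r0)
            assert np.allclose(fit.rates(g, "nonselective"), cfg.r0)

    def test_occupancy_limits(self, small_library, small_config):
        fit = assign_fitness(small_library, small_config)
        kd = fit.kd.copy()
        kd.iloc[:, :] = np.inf
        kd.iloc[0, 0] = 0.0
        fit.kd = kd
        theta = fit.occupancy(small_config.genotypes[0],
                              small_config.bait_concentration)
        assert theta.iloc[0] == 1.0 and (theta.iloc[1:] == 0.0).all()

    def test_fold_loss_occupancy_arithmetic(self):
        # Kd == C gives occupancy 1/2; a 10-fold affinity loss gives 1/11
        c = 2.5
        assert c / (c + c) == 0.5
        assert c / (c + 10 * c) == pytest.approx(1 / 11)

    def test_mutant_fold_loss_only_for_heptp(self, small_library, small_config,
                                             small_fitness):
        ref = small_config.reference_genotype
        for m in small_library:
            for mut in small_config.genotypes[1:]:
                ratio = (small_fitness.kd.loc[m.member_id, mut]
                         / small_fitness.kd.loc[m.member_id, ref])
                if m.motif_class == "HEPTP_like":
                    lo, hi = small_config.fold_loss_bounds
                    assert lo <= ratio <= hi
                else:
                    assert ratio == pytest.approx(1.0)

    def test_empty_library_rejected(self, small_config):
        lib = build_synthetic_library(SimulationConfig(n_members=0))
        with pytest.raises(ConfigError):
            assign_fitness(lib, small_config)


class TestSelection:
    def test_counts_sum_to_depth(self, small_table, small_config):
        assert (small_table.totals == small_config.read_depth).all()

    def test_equal_rates_conserve_frequencies(self, small_library):
        cfg = SimulationConfig(n_members=40, frac_heptp=0.2, seed=3, s=0.0,
                               genotypes=("WT",), conditions=("selective",),
                               n_replicates=1)
        fit = assign_fitness(small_library, cfg)
        table = simulate_selection(small_library, fit, cfg, sampling=False)
        first = table.counts.iloc[:, 0]
        for col in table.counts.columns[1:]:
            assert np.allclose(table.counts[col], first)

    def test_two_member_slope_matches_numerical_oracle(self):
        """ln(F_fast,t / F_fast,0) vs doublings for a rare fast grower:
        slope should approach ln2 * (g_fast/g_bar - 1) with g_bar ~ g_slow,
        cross-checked against direct ODE integration of the two-member
        system."""
        r0 = 0.5
        g = np.array([r0, 2 * r0])
        n0 = np.array([0.999, 0.001])

        # oracle: integrate dN/dt = g*N and read frequencies on a doubling grid
        def rhs(t, n):
            return g * n

        grid = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        times = [_time_for_doublings(n0, g, d) for d in grid]
        sol = solve_ivp(rhs, (0, times[-1]), n0, t_eval=times, rtol=1e-10,
                        atol=1e-12)
        freq = sol.y[1] / sol.y.sum(axis=0)
        y = np.log(freq / freq[0])
        slope = np.polyfit(grid, y, 1)[0]
        expected = np.log(2) * (2 * r0 / r0 - 1)
        assert slope == pytest.approx(expected, rel=0.05)

        # the simulator's deterministic core agrees with the ODE oracle
        sim_freq = []
        for d in grid:
            t = _time_for_doublings(n0, g, d)
            n_t = n0 * np.exp(g * t)
            sim_freq.append(n_t[1] / n_t.sum())
        assert np.allclose(sim_freq, freq, rtol=1e-6)

    def test_doubling_times_hit_requested_doublings(self):
        rng = np.random.default_rng(0)
        n0 = rng.uniform(0.5, 2.0, size=20)
        g = rng.uniform(0.2, 1.0, size=20)
        for d in (0.0, 1.0, 3.5, 7.0):
            t = _time_for_doublings(n0, g, d)
            total = np.sum(n0 * np.exp(g * t))
            assert np.log2(total / n0.sum()) == pytest.approx(d, abs=1e-9)

    def test_monotone_in_occupancy(self, small_library, small_config,
                                   small_fitness):
        """Tightening one member's Kd never lowers its final frequency
        (deterministic core)."""
        cfg = SimulationConfig(n_members=40, frac_heptp=0.2, seed=3,
                               genotypes=("WT",), conditions=("selective",),
                               n_replicates=1)
        fit = assign_fitness(small_library, cfg)
        final = {}
        for kd_scale in (1.0, 0.1):
            f = assign_fitness(small_library, cfg)
            kd = f.kd.copy()
            kd.iloc[5, 0] *= kd_scale
            theta = cfg.bait_concentration / (cfg.bait_concentration + kd)
            f.kd, f.growth = kd, cfg.r0 * (1 + cfg.s * theta)
            table = simulate_selection(small_library, f, cfg, sampling=False)
            final[kd_scale] = table.counts.iloc[5, -1]
        assert final[0.1] >= final[1.0]

    def test_deterministic_tables(self, small_config, small_library,
                                  small_fitness):
        a = simulate_selection(small_library, small_fitness, small_config)
        b = simulate_selection(small_library, small_fitness, small_config)
        assert a.counts.equals(b.counts) and a.samples.equals(b.samples)

    def test_replicates_differ_only_by_sampling(self, small_table):
        reps = small_table.samples["replicate"].unique()
        assert len(reps) > 1
        cols = small_table.samples
        c1 = small_table.counts[cols[(cols.replicate == 1)
                                     & (cols.doublings == 0)].index]
        c2 = small_table.counts[cols[(cols.replicate == 2)
                                     & (cols.doublings == 0)].index]
        assert not np.array_equal(c1.to_numpy(), c2.to_numpy())

    def test_overdispersion_inflates_variance(self, small_library):
        def rep_var(overdisp):
            cfg = SimulationConfig(n_members=40, frac_heptp=0.2, seed=3,
                                   genotypes=("WT",), conditions=("selective",),
                                   n_replicates=8, read_depth=20_000,
                                   doubling_grid=(0.0, 1.0),
                                   overdispersion=overdisp)
            fit = assign_fitness(small_library, cfg)
            tab = simulate_selection(small_library, fit, cfg)
            base = tab.counts[tab.samples[tab.samples.doublings == 0].index]
            return base.var(axis=1).mean()

        assert rep_var(50.0) > 3 * rep_var(None)


class TestFastq:
    def test_count_conservation(self, tmp_path, small_library):
        cfg = SimulationConfig(n_members=40, frac_heptp=0.2, seed=3,
                               read_depth=200, genotypes=("WT",),
                               conditions=("selective",), n_replicates=1,
                               doubling_grid=(0.0, 2.0))
        fit = assign_fitness(small_library, cfg)
        table = simulate_selection(small_library, fit, cfg)
        paths = emit_fastq(table, small_library, out_dir=tmp_path, seed=1)
        sid = table.counts.columns[0]
        text = paths[sid].read_text().splitlines()
        assert len(text) == 4 * 200
        target = small_library.members[3]
        n_inserts = sum(target.dna in line for line in text[1::4])
        assert n_inserts == int(table.counts.loc[target.member_id, sid])

    def test_empty_table_gives_empty_fastq(self, tmp_path, small_library,
                                           small_table):
        empty = small_table.counts.iloc[:, :1] * 0
        import dockscreen
        sub = dockscreen.CountTable(empty,
                                    small_table.samples.iloc[:1].assign(doublings=0.0))
        paths = emit_fastq(sub, small_library, out_dir=tmp_path)
        assert list(paths.values())[0].read_text() == ""

    def test_read_order_deterministic(self, tmp_path, small_library, small_table):
        p1 = emit_fastq(small_table, small_library, out_dir=tmp_path / "a", seed=5)
        p2 = emit_fastq(small_table, small_library, out_dir=tmp_path / "b", seed=5)
        sid = small_table.counts.columns[0]
        assert p1[sid].read_text() == p2[sid].read_text()

    def test_empty_anchor_rejected(self, small_table, small_library, tmp_path):
        with pytest.raises(ValueError, match="anchors"):
            emit_fastq(small_table, small_library, anchors=("", "TTT"),
                       out_dir=tmp_path)
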