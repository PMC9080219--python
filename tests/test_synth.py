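"""Synthetic community generator: environment, latent dynamics, sampling,
and recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from planktonet.synth import (
    SynthConfig,
    SynthTruth,
    daylength_cbm,
    evaluate_recovery,
    generate_environment,
    generate_latent_dynamics,
    sample_counts,
    simulate_dataset,
)


class TestEnvironment:
    def test_march_daylength_near_equinox(self):
        env = generate_environment(12, latitude=41.67, seed=0)
        march = env["daylength"].iloc[2]
        assert march == pytest.approx(12.0, abs=0.5)

    def test_daylength_extremes_at_midlatitude(self):
        env = generate_environment(12, latitude=41.67, seed=0)
        by_month = env["daylength"].to_numpy()
        assert np.argmax(by_month) == 5  # June
        assert np.argmin(by_month) == 11  # December

    def test_same_seed_identical(self):
        a = generate_environment(120, seed=3)
        b = generate_environment(120, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_fifteen_variables_and_periodicity(self):
        env = generate_environment(36, seed=1)
        assert env.shape[1] == 16  # 15 configured variables + daylength
        d = env["daylength"].to_numpy()
        assert np.allclose(d[:12], d[12:24])
        assert ((env["daylength"] > 0) & (env["daylength"] < 24)).all()
        assert not env.isna().any().any()

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            generate_environment(6)

    def test_daylength_formula_spans_year(self):
        assert daylength_cbm(172, 41.67) > daylength_cbm(355, 41.67)


class TestLatentDynamics:
    def test_zero_noise_direct_pair_identical_up_to_scale(self):
        cfg = SynthConfig(
            n_otus_per_table=4,
            n_direct_pairs=1,
            n_env_driven_pairs=0,
            noise_sd=0.0,
            negative_fraction=0.0,
            missing_blocks={},
            seed=5,
        )
        env = generate_environment(cfg.n_months, seed=cfg.seed)
        latent, truth = generate_latent_dynamics(cfg, env)
        (pair, sign), = truth.direct_pairs.items()
        a, b = sorted(pair)
        stacked = pd.concat([latent[k] for k in latent])
        ratio = stacked.loc[a].to_numpy() / stacked.loc[b].to_numpy()
        assert sign == 1
        assert np.allclose(ratio, ratio[0])

    def test_winter_otu_peaks_in_winter(self):
        cfg = SynthConfig(
            n_otus_per_table=20,
            n_direct_pairs=0,
            n_env_driven_pairs=0,
            seasonal_fraction=1.0,
            missing_blocks={},
            seed=2,
        )
        env = generate_environment(cfg.n_months, seed=cfg.seed)
        latent, truth = generate_latent_dynamics(cfg, env)
        stacked = pd.concat([latent[k] for k in latent])
        months = stacked.columns.month
        winter = np.isin(months, (12, 1, 2))
        summer = np.isin(months, (6, 7, 8))
        winter_otus = [o for o, s in truth.niche_labels.items() if s == "winter"]
        assert winter_otus
        for otu in winter_otus:
            series = stacked.loc[otu].to_numpy()
            assert series[winter].mean() > series[summer].mean()

    def test_env_driven_pair_monotone_in_driver_at_zero_noise(self):
        cfg = SynthConfig(
            n_otus_per_table=4,
            n_direct_pairs=0,
            n_env_driven_pairs=1,
            noise_sd=0.0,
            negative_fraction=0.0,
            missing_blocks={},
            seed=8,
        )
        env = generate_environment(cfg.n_months, seed=cfg.seed)
        latent, truth = generate_latent_dynamics(cfg, env)
        (pair, var), = truth.env_driven_pairs.items()
        stacked = pd.concat([latent[k] for k in latent])
        order = np.argsort(env[var].to_numpy())
        for otu in sorted(pair):
            series = stacked.loc[otu].to_numpy()
            assert (np.diff(series[order]) >= -1e-12).all()

    def test_planted_classes_disjoint_and_recorded(self):
        cfg = SynthConfig(seed=4, missing_blocks={})
        env = generate_environment(cfg.n_months, seed=cfg.seed)
        latent, truth = generate_latent_dynamics(cfg, env)
        assert len(truth.direct_pairs) == cfg.n_direct_pairs
        assert len(truth.env_driven_pairs) == cfg.n_env_driven_pairs
        assert not set(truth.direct_pairs) & set(truth.env_driven_pairs)
        all_otus = set(pd.concat([latent[k] for k in latent]).index)
        for pair in list(truth.direct_pairs) + list(truth.env_driven_pairs):
            assert pair <= all_otus

    def test_too_many_pairs_rejected(self):
        cfg = SynthConfig(n_otus_per_table=2, n_direct_pairs=3, n_env_driven_pairs=3)
        env = generate_environment(cfg.n_months, seed=0)
        with pytest.raises(ValueError, match="pairs"):
            generate_latent_dynamics(cfg, env)


class TestSampleCounts:
    def test_every_sample_sums_to_read_depth(self, small_dataset):
        cfg, tables, _, _ = small_dataset
        for t in tables:
            assert (t.counts.sum(axis=0) == cfg.read_depth).all()

    def test_degenerate_distribution_puts_all_reads_on_one_otu(self):
        cfg = SynthConfig(n_otus_per_table=3, n_months=12, missing_blocks={}, seed=0)
        idx = pd.period_range("2004-01", periods=12, freq="M")
        latent = {
            key: pd.DataFrame(
                np.vstack([np.ones(12), np.zeros(12), np.zeros(12)]),
                index=[f"{key}_{i}" for i in range(3)],
                columns=idx,
            )
            for key in ("bacteria_pico", "bacteria_nano", "protist_pico", "protist_nano")
        }
        tables = sample_counts(latent, cfg)
        for t in tables:
            assert (t.counts.iloc[0] == cfg.read_depth).all()
            assert (t.counts.iloc[1:] == 0).all().all()

    def test_binomial_mean_at_equal_latent(self):
        # latent (1,1) at depth 4907: OTU-1 count ~ Binomial(4907, 1/2)
        cfg = SynthConfig(n_otus_per_table=2, n_months=12, missing_blocks={}, seed=9)
        idx = pd.period_range("2004-01", periods=12, freq="M")
        keys = ("bacteria_pico", "bacteria_nano", "protist_pico", "protist_nano")
        counts = []
        for rep in range(250):  # 250 seeds x 4 tables x 12 samples = 12000 draws
            latent = {
                k: pd.DataFrame(np.ones((2, 12)), index=[f"{k}_0", f"{k}_1"], columns=idx)
                for k in keys
            }
            tables = sample_counts(latent, cfg.replace(seed=rep))
            counts.extend(t.counts.iloc[0].to_numpy() for t in tables)
        draws = np.concatenate(counts)
        se = np.sqrt(4907 * 0.25 / draws.size)
        assert draws.mean() == pytest.approx(2453.5, abs=3 * se)

    def test_all_zero_latent_column_rejected(self):
        cfg = SynthConfig(n_otus_per_table=1, n_months=12, missing_blocks={}, seed=0)
        idx = pd.period_range("2004-01", periods=12, freq="M")
        mat = np.ones((1, 12)); mat[0, 5] = 0.0
        latent = {
            k: pd.DataFrame(mat.copy(), index=[f"{k}_0"], columns=idx)
            for k in ("bacteria_pico", "bacteria_nano", "protist_pico", "protist_nano")
        }
        with pytest.raises(ValueError, match="all-zero"):
            sample_counts(latent, cfg)

    def test_missing_blocks_absent_from_nano_tables(self):
        cfg = SynthConfig(n_otus_per_table=5, n_direct_pairs=2, n_env_driven_pairs=2, seed=1)  # default gap pattern
        tables, _, _ = simulate_dataset(cfg)
        by_key = {f"{t.domain}_{t.size_fraction}": t for t in tables}
        assert by_key["bacteria_pico"].counts.shape[1] == 120
        assert by_key["bacteria_nano"].counts.shape[1] == 120 - 29
        assert by_key["protist_nano"].counts.shape[1] == 120 - 29


class TestDeterminismAndRecovery:
    def test_fixed_seed_gives_identical_dataset(self):
        cfg = SynthConfig(n_otus_per_table=6, n_direct_pairs=2, n_env_driven_pairs=2, seed=21)
        t1, e1, tr1 = simulate_dataset(cfg)
        t2, e2, tr2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(e1, e2)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.counts, b.counts)
        assert tr1.direct_pairs == tr2.direct_pairs
        assert tr1.env_driven_pairs == tr2.env_driven_pairs

    def test_recovery_scores(self):
        truth = SynthTruth(
            direct_pairs={frozenset(("a", "b")): 1, frozenset(("c", "d")): 1},
            env_driven_pairs={frozenset(("e", "f")): "temperature"},
            niche_labels={},
        )
        perfect = evaluate_recovery([("a", "b"), ("c", "d")], truth)
        assert perfect["direct_recall"] == 1.0
        assert perfect["direct_precision"] == 1.0
        empty = evaluate_recovery([], truth)
        assert empty["direct_recall"] == 0.0
        half = evaluate_recovery([("a", "b")], truth, removed_edges=[("e", "f")])
        assert half["direct_recall"] == 0.5
        assert half["direct_precision"] == 1.0
        assert half["env_driven_recall"] == 1.0

    def test_empty_truth_rejected(self):
        truth = SynthTruth(direct_pairs={}, env_driven_pairs={}, niche_labels={})
        with pytest.raises(ValueError):
            evaluate_recovery([("a", "b")], truth)


class TestNullPipeline:
    def test_false_positive_rate_within_bonferroni_level(self):
        """Without planted structure or seasonality, the core network stays
        empty up to the nominal Bonferroni-corrected level (>=20 seeds)."""
        from planktonet.pipeline import PipelineConfig, run_pipeline

        edges = 0
        tests = 0
        for seed in range(20):
            cfg = PipelineConfig(seed=seed)
            cfg.synthetic = SynthConfig(
                n_otus_per_table=10,
                seasonal_fraction=0.0,
                n_direct_pairs=0,
                n_env_driven_pairs=0,
                missing_blocks={},
            )
            cfg.season.indval_n_perm = 99
            cfg.season.niche_n_perm = 99
            res = run_pipeline(cfg)
            otu_edges = [
                (u, v)
                for u, v in res.core.edges
                if res.core.nodes[u]["kind"] == "otu"
                and res.core.nodes[v]["kind"] == "otu"
            ]
            edges += len(otu_edges)
            tests += res.manifest["n_tests"]
        assert edges / tests <= 0.001
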