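"""BLUEs, masking schemes, augmentation and the cross-validation loop."""

import numpy as np
import pandas as pd
import pytest

from sparsegs.evaluation import (augment_with_historical, cdmean_splits,
                                 compute_blues, make_cv1_masks,
                                 make_cv2_masks, run_crossval)
from sparsegs.simulate import SimulationConfig, simulate_dataset


def _family_lines(df):
    return {f: sorted(d["line_id"].unique())
            for f, d in df.groupby("family")}


@pytest.fixture(scope="module")
def noise_free_dataset():
    return simulate_dataset(SimulationConfig(
        n_families=3, family_size=8, n_chromosomes=2,
        markers_per_chromosome=40, seed=5,
        residual_variances=[0.0, 0.0, 0.0],
        nuisance_variances={"tester": 0, "trial": 0, "rep": 0, "block": 0},
        location_effects={"Kiboko": 0.0, "Kakamega": 0.0}))


class TestComputeBlues:
    def test_noise_free_blue_equals_plot_mean(self, noise_free_dataset):
        ds = noise_free_dataset
        blues = compute_blues(ds.phenotypes)
        means = (ds.phenotypes.groupby(["line_id", "environment"])["yield"]
                 .mean().rename("mean").reset_index())
        merged = blues.merge(means, on=["line_id", "environment"])
        np.testing.assert_allclose(merged["blue"], merged["mean"], atol=1e-5)

    def test_blues_track_line_means_under_noise(self, small_dataset):
        # replicates are balanced across lines, so the GLS genotype
        # solutions stay close to raw line means; they differ only by the
        # incomplete-block and trial adjustments
        blues = compute_blues(small_dataset.phenotypes)
        means = (small_dataset.phenotypes
                 .groupby(["line_id", "environment"])["yield"].mean()
                 .rename("mean").reset_index())
        merged = blues.merge(means, on=["line_id", "environment"])
        for _, sub in merged.groupby("environment"):
            r = np.corrcoef(sub["blue"], sub["mean"])[0, 1]
            assert r > 0.95

    def test_line_without_plots_gets_no_blue(self, small_dataset):
        df = small_dataset.phenotypes
        env = df["environment"].iloc[0]
        victim = df["line_id"].iloc[0]
        pruned = df[~((df["line_id"] == victim)
                      & (df["environment"] == env))]
        blues = compute_blues(pruned)
        idx = blues.set_index(["line_id", "environment"]).index
        assert (victim, env) not in idx


class TestCv1Masks:
    def test_twelve_family_pattern(self):
        family_lines = {f"F{i:02d}": [f"F{i:02d}_L{j}" for j in range(4)]
                        for i in range(12)}
        plans = make_cv1_masks(family_lines, ["WW_A", "WW_B"], ["WS"],
                               n_repeats=10, seed=3)
        assert len(plans) == 10
        for plan in plans:
            masked_a = {f for f in family_lines
                        if all((l, "WW_A") in plan.masked
                               for l in family_lines[f])}
            masked_b = {f for f in family_lines
                        if all((l, "WW_B") in plan.masked
                               for l in family_lines[f])}
            # 6/6 split, each family masked in exactly one WW environment
            assert len(masked_a) == 6 and len(masked_b) == 6
            assert masked_a.isdisjoint(masked_b)
            masked_ws = {f for f in family_lines
                         if all((l, "WS") in plan.masked
                                for l in family_lines[f])}
            # three WS-masked families from each WW-observed group
            assert len(masked_ws & masked_a) == 3
            assert len(masked_ws & masked_b) == 3

    def test_deterministic_under_seed(self):
        family_lines = {f"F{i}": [f"F{i}_L{j}" for j in range(3)]
                        for i in range(8)}
        a = make_cv1_masks(family_lines, ["A", "B"], ["W"], 4, seed=11)
        b = make_cv1_masks(family_lines, ["A", "B"], ["W"], 4, seed=11)
        assert [p.masked for p in a] == [p.masked for p in b]
        c = make_cv1_masks(family_lines, ["A", "B"], ["W"], 4, seed=12)
        assert any(p.masked != q.masked for p, q in zip(a, c))

    def test_every_family_observed_somewhere(self):
        family_lines = {f"F{i}": [f"F{i}_L{j}" for j in range(3)]
                        for i in range(9)}  # odd count
        envs = ["A", "B", "W"]
        for plan in make_cv1_masks(family_lines, ["A", "B"], ["W"], 10,
                                   seed=0):
            for fam, lines in family_lines.items():
                observed = [e for e in envs
                            if not all((l, e) in plan.masked for l in lines)]
                assert observed, f"family {fam} fully masked"


class TestCv2Masks:
    def test_invariants(self, small_dataset, small_grm):
        df = small_dataset.phenotypes
        fl = _family_lines(df)
        ww = sorted(df.loc[df["management"] == "WW", "environment"].unique())
        ws = sorted(df.loc[df["management"] == "WS", "environment"].unique())
        splits = cdmean_splits(small_grm, fl, ww)
        plan = make_cv2_masks(splits, ww, ws, fl)
        for fam, lines in fl.items():
            for line in lines:
                ww_observed = [e for e in ww if (line, e) not in plan.masked]
                assert len(ww_observed) == 1
            split = splits[fam]
            ws_obs = {l for l in lines if (l, ws[0]) not in plan.masked}
            assert ws_obs == split.ws_observed
            # WS calibration draws from both WW-observed groups
            for env in ww:
                group = set(split.lines_in(env))
                assert len(ws_obs & group) >= len(group) // 2

    def test_missing_family_split_rejected(self, small_dataset, small_grm):
        df = small_dataset.phenotypes
        fl = _family_lines(df)
        ww = sorted(df.loc[df["management"] == "WW", "environment"].unique())
        splits = cdmean_splits(small_grm, fl, ww)
        splits.pop(next(iter(splits)))
        with pytest.raises(ValueError, match="without a CV2 split"):
            make_cv2_masks(splits, ww, ["WS"], fl)


@pytest.fixture(scope="module")
def two_year():
    ds = simulate_dataset(SimulationConfig(
        n_families=3, family_size=8, n_chromosomes=2,
        markers_per_chromosome=40, n_years=2, seed=13))
    cur, hist = ds.split_by_year(2017)
    from sparsegs import compute_grm
    return cur, hist, compute_grm(ds.marker_matrix)


class TestAugmentation:
    def test_none_is_identity(self, two_year):
        cur, hist, grm = two_year
        out = augment_with_historical(cur, hist, mode="none")
        pd.testing.assert_frame_equal(out, cur.reset_index(drop=True))

    def test_all_raises_environment_count(self, two_year):
        cur, hist, grm = two_year
        out = augment_with_historical(cur, hist, mode="all", grouping="LMY")
        assert out["environment"].nunique() == 6
        assert cur["environment"].nunique() == 3

    def test_optimized_union_bound(self, two_year):
        cur, hist, grm = two_year
        out = augment_with_historical(cur, hist, mode="optimized", grm=grm,
                                      n_select=5, grouping="MY")
        added = set(out["line_id"]) - set(cur["line_id"])
        # at most n_select per current family, deduplicated
        assert 5 <= len(added) <= 5 * cur["family"].nunique()
        assert added <= set(hist["line_id"])

    def test_single_year_grouping_rejected(self, two_year):
        cur, hist, grm = two_year
        with pytest.raises(ValueError, match="single-year"):
            augment_with_historical(cur, hist, mode="all", grouping="LM")

    def test_overlapping_ids_rejected(self, two_year):
        cur, hist, grm = two_year
        with pytest.raises(ValueError, match="overlap"):
            augment_with_historical(cur, cur, mode="all", grouping="LMY")


@pytest.fixture(scope="module")
def tiny():
    ds = simulate_dataset(SimulationConfig(
        n_families=6, family_size=12, n_chromosomes=3,
        markers_per_chromosome=40, seed=31))
    from sparsegs import compute_grm, filter_markers
    grm = compute_grm(filter_markers(ds.marker_matrix))
    blues = compute_blues(ds.phenotypes)
    return ds, grm, blues


class TestRunCrossval:
    def test_bitwise_reproducibility(self, tiny):
        ds, grm, blues = tiny
        a = run_crossval(ds.phenotypes, grm, scheme="cv1", n_repeats=2,
                         seed=4, blues=blues)
        b = run_crossval(ds.phenotypes, grm, scheme="cv1", n_repeats=2,
                         seed=4, blues=blues)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_masked_phenotypes_never_train(self, tiny):
        # sentinel substitution: corrupting every masked record must leave
        # the fitted accuracies bit-identical
        ds, grm, blues = tiny
        from sparsegs.evaluation import make_cv1_masks, _classify_envs
        ww, ws = _classify_envs(ds.phenotypes)
        base = run_crossval(ds.phenotypes, grm, scheme="cv2", seed=9,
                            blues=blues)
        fl = _family_lines(ds.phenotypes)
        splits = cdmean_splits(grm, fl, ww)
        plan = make_cv2_masks(splits, ww, ws, fl)
        poisoned = ds.phenotypes.copy()
        is_masked = [plan.is_masked(r.line_id, r.environment)
                     for r in poisoned.itertuples()]
        poisoned.loc[is_masked, "yield"] = 1e6
        redo = run_crossval(poisoned, grm, scheme="cv2", seed=9, blues=blues)
        pd.testing.assert_frame_equal(base.records, redo.records)

    def test_accuracy_rows_aggrege_to_mean(self, tiny):
        ds, grm, blues = tiny
        res = run_crossval(ds.phenotypes, grm, scheme="cv2", seed=2,
                           blues=blues)
        by_env = res.mean_by_environment()
        manual = res.records.groupby(["environment", "repeat"])[
            "accuracy"].mean().groupby("environment").mean()
        np.testing.assert_allclose(
            by_env.set_index("environment")["accuracy"], manual)
        assert res.records["accuracy"].between(-1, 1).all()


class TestAugmentationBenefit:
    def test_optimized_historical_never_hurts_on_average(self):
        """Training sets augmented with Avg_GRM-selected historical full
        sibs predict at least as accurately as unaugmented ones, on
        average over 10 replicates."""
        from sparsegs import compute_grm, filter_markers
        gains = []
        for rep in range(10):
            ds = simulate_dataset(SimulationConfig(
                n_families=5, family_size=18, n_chromosomes=3,
                markers_per_chromosome=50, seed=70_000 + rep))
            grm = compute_grm(filter_markers(ds.marker_matrix))
            df = ds.phenotypes
            # carve a "historical" campaign out of the same families: the
            # last third of every family, relabelled as a previous year —
            # maximal founder overlap with the current lines
            hist_lines = {l for f, d in df.groupby("family")
                          for l in sorted(d["line_id"].unique())[-6:]}
            current = df[~df["line_id"].isin(hist_lines)].copy()
            hist = df[df["line_id"].isin(hist_lines)].copy()
            hist["year"] = 2016
            hist["environment"] = hist["environment"].str.replace(
                "2017", "2016")
            hist["trial"] = hist["trial"] + "_hist"
            blues = compute_blues(current)
            acc = {}
            for mode in ("none", "optimized"):
                res = run_crossval(current, grm, scheme="cv2",
                                   grouping="M_plus", structure="FA",
                                   augmentation=mode, historical=hist,
                                   n_select=10, seed=rep, blues=blues)
                acc[mode] = res.mean_accuracy()
            gains.append(acc["optimized"] - acc["none"])
        assert np.mean(gains) >= 0.0, gains
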