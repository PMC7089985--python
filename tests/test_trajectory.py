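"""Developmental trajectory stage: age parsing, filtering, summaries,
permutation test."""

import numpy as np
import pandas as pd
import pytest

from brainvar import (
    BrainExpressionDataset,
    TrajectorySimSpec,
    filter_low_coverage_regions,
    log2_transform,
    parse_age,
    permutation_test_trajectory,
    simulate_trajectory_dataset,
    summarize_trajectory,
)


class TestParseAge:
    @pytest.mark.parametrize(
        "value,unit,days,prenatal",
        [
            (8, "pcw", 56.0, True),
            (40, "yrs", 280 + 40 * 365.25, False),
            (4, "mos", 280 + 4 * 30.44, False),
            (39, "pcw", 273.0, True),
            (41, "pcw", 287.0, False),
        ],
    )
    def test_conversions(self, value, unit, days, prenatal):
        age = parse_age(value, unit)
        assert age.days_post_conception == pytest.approx(days)
        assert age.is_prenatal == prenatal

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            parse_age(8, "weeks")
        with pytest.raises(ValueError):
            parse_age(0, "pcw")


class TestLog2Transform:
    def test_power_of_two(self):
        assert log2_transform(8.0, 0.0) == 3.0

    def test_offset_convention(self):
        assert log2_transform(0.0, 1.0) == 0.0

    def test_zero_without_offset_is_dropped(self):
        assert np.isnan(log2_transform(0.0, 0.0))
        arr = log2_transform(np.array([0.0, 2.0]), 0.0)
        assert np.isnan(arr[0]) and arr[1] == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(-1.0, 0.0)


def _dataset(region_sizes: dict[str, int], zero_in: str | None = None):
    rows, cols = [], []
    k = 0
    for region, n in region_sizes.items():
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"s{k}",
                    "donor_id": f"d{k}",
                    "region": region,
                    "age": float(10 + i),
                    "age_unit": "pcw" if i % 2 == 0 else "yrs",
                }
            )
            cols.append(0.0 if (zero_in == region and i == 0) else 2.0 ** (k % 4))
            k += 1
    meta = pd.DataFrame(rows)
    values = pd.DataFrame([cols], index=["g"], columns=meta["sample_id"])
    return BrainExpressionDataset(meta=meta, values=values)


class TestRegionFilter:
    def test_region_below_threshold_dropped(self):
        ds = _dataset({"A": 4, "B": 6})
        kept, dropped = filter_low_coverage_regions(ds, "g", min_points=5)
        assert dropped == ["A"]
        assert set(kept.meta["region"]) == {"B"}

    def test_min_points_one_keeps_everything(self):
        ds = _dataset({"A": 1, "B": 2})
        kept, dropped = filter_low_coverage_regions(ds, "g", min_points=1)
        assert dropped == []
        assert kept.n_samples == 3

    def test_26_region_atlas_reduces_to_16(self):
        """Mirror of the emulated atlas geometry: 26 regions, 10 of them
        with fewer than 5 retained values, leaves 16."""
        sizes = {f"R{i:02d}": (3 if i < 10 else 7) for i in range(26)}
        ds = _dataset(sizes)
        kept, dropped = filter_low_coverage_regions(ds, "g", min_points=5)
        assert len(dropped) == 10
        assert len(set(kept.meta["region"])) == 16

    def test_zero_rpkm_counts_as_missing(self):
        ds = _dataset({"A": 5, "B": 6}, zero_in="A")
        kept, dropped = filter_low_coverage_regions(ds, "g", min_points=5)
        assert dropped == ["A"]

    def test_all_regions_dropped_is_an_error(self):
        ds = _dataset({"A": 2})
        with pytest.raises(ValueError):
            filter_low_coverage_regions(ds, "g", min_points=5)


class TestSummarize:
    def test_noise_free_synthetic_means_are_exact(self):
        ds = simulate_trajectory_dataset(
            TrajectorySimSpec(mu_prenatal=1.0, mu_postnatal=3.0, sigma=0.0, seed=0)
        )
        summary = summarize_trajectory(ds, "gene_01")
        for row in summary.table.itertuples():
            expected = 1.0 if parse_age(row.age, row.age_unit).is_prenatal else 3.0
            assert row.mean_log2 == pytest.approx(expected, abs=1e-12)

    def test_single_sample_cells(self, tiny_expression_dataset):
        summary = summarize_trajectory(tiny_expression_dataset, "gene_a")
        assert (summary.table["n"] == 1).all()
        assert summary.grand_mean == pytest.approx(np.mean([0, 1, 2, 3]))

    def test_matches_naive_recomputation(self):
        ds = simulate_trajectory_dataset(TrajectorySimSpec(n_donors=4, seed=11))
        summary = summarize_trajectory(ds, "gene_01")
        log2 = np.log2(ds.values.loc["gene_01"].to_numpy())
        assert summary.grand_mean == pytest.approx(log2.mean(), abs=1e-12)
        meta = ds.meta.assign(log2=log2)
        for row in summary.table.itertuples():
            cell = meta[
                (meta.region == row.region)
                & (meta.age == row.age)
                & (meta.age_unit == row.age_unit)
            ]["log2"]
            assert row.n == len(cell)
            assert row.mean_log2 == pytest.approx(cell.mean(), abs=1e-12)

    def test_unknown_gene_rejected(self, tiny_expression_dataset):
        with pytest.raises(KeyError):
            summarize_trajectory(tiny_expression_dataset, "nope")


class TestPermutationTest:
    def test_label_invariant_data_gives_p_one(self):
        ds = _dataset({"A": 10})
        ds.values.loc["g"] = 4.0
        res = permutation_test_trajectory(ds, "g", n_permutations=99, seed=1)
        assert res.observed_statistic == 0.0
        assert res.p_value == 1.0

    def test_planted_five_sigma_shift_reaches_floor(self):
        """50 samples per side, a 5-sigma prenatal/postnatal separation:
        no relabelling matches the observed statistic, so p = 1/(B+1)."""
        tps = tuple([(w, "pcw") for w in range(8, 33)] + [(y, "yrs") for y in range(1, 26)])
        ds = simulate_trajectory_dataset(
            TrajectorySimSpec(
                regions=("R1",), timepoints=tps, mu_prenatal=0.0, mu_postnatal=5.0,
                sigma=1.0, n_donors=2, seed=7,
            )
        )
        res = permutation_test_trajectory(ds, "gene_01", n_permutations=999, seed=8)
        assert res.n_prenatal == res.n_postnatal == 50
        assert res.p_value == pytest.approx(1 / 1000)

    def test_deterministic_under_seed(self):
        ds = simulate_trajectory_dataset(TrajectorySimSpec(seed=3))
        r1 = permutation_test_trajectory(ds, "gene_01", n_permutations=99, seed=42)
        r2 = permutation_test_trajectory(ds, "gene_01", n_permutations=99, seed=42)
        assert r1.n_extreme == r2.n_extreme
        assert r1.p_value == r2.p_value

    def test_p_value_bounds_and_granularity(self):
        ds = simulate_trajectory_dataset(
            TrajectorySimSpec(mu_prenatal=2.0, mu_postnatal=2.0, sigma=1.0, seed=5)
        )
        for b in (1, 9, 99):
            res = permutation_test_trajectory(ds, "gene_01", n_permutations=b, seed=2)
            assert 1 / (b + 1) <= res.p_value <= 1.0
            assert res.p_value * (b + 1) == pytest.approx(round(res.p_value * (b + 1)))

    def test_statistic_shift_invariance_and_sign_flip(self):
        ds = simulate_trajectory_dataset(TrajectorySimSpec(seed=9))
        res = permutation_test_trajectory(ds, "gene_01", n_permutations=49, seed=4)
        shifted = BrainExpressionDataset(
            meta=ds.meta.copy(), values=ds.values * 8.0  # +3 on the log2 scale
        )
        res_shift = permutation_test_trajectory(shifted, "gene_01", n_permutations=49, seed=4)
        assert res_shift.observed_statistic == pytest.approx(res.observed_statistic, abs=1e-9)
        # swapping prenatal/postnatal wholesale flips the statistic's sign
        flipped_meta = ds.meta.copy()
        flipped_meta["age"] = [
            10.0 if parse_age(a, u).is_prenatal else 10.0 for a, u in
            zip(ds.meta["age"], ds.meta["age_unit"])
        ]
        flipped_meta["age_unit"] = [
            "yrs" if parse_age(a, u).is_prenatal else "pcw"
            for a, u in zip(ds.meta["age"], ds.meta["age_unit"])
        ]
        flipped = BrainExpressionDataset(meta=flipped_meta, values=ds.values.copy())
        res_flip = permutation_test_trajectory(flipped, "gene_01", n_permutations=49, seed=4)
        assert res_flip.observed_statistic == pytest.approx(-res.observed_statistic, abs=1e-9)

    def test_too_few_samples_on_one_side_rejected(self):
        ds = _dataset({"A": 6})
        ds.meta["age_unit"] = ["pcw"] * 5 + ["yrs"]
        with pytest.raises(ValueError):
            permutation_test_trajectory(ds, "g", n_permutations=9, seed=0)


def test_null_rejection_rate_is_calibrated():
    """Under mu_pre = mu_post the permutation p-value is uniform: the
    rejection rate at alpha = 0.05 over 200 replicates stays in [0.02, 0.10]."""
    rej = 0
    for i in range(200):
        ds = simulate_trajectory_dataset(
            TrajectorySimSpec(
                mu_prenatal=2.0, mu_postnatal=2.0, sigma=1.0, n_donors=1, seed=2000 + i
            )
        )
        res = permutation_test_trajectory(ds, "gene_01", n_permutations=199, seed=3000 + i)
        rej += res.p_value <= 0.05
    assert 0.02 <= rej / 200 <= 0.10
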