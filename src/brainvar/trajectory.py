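"""Developmental expression trajectories with a permutation test.

Works on RPKM expression matrices annotated with brain region and
developmental age.  Ages are normalised to days post conception (birth at
280 days); values are analysed on the log2 scale; sparsely sampled regions
are dropped; and a label-permutation test asks whether the prenatal vs
postnatal expression difference could have arisen by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGE_UNITS",
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "GESTATION_DAYS",
    "DevelopmentalAge",
    "BrainExpressionDataset",
    "TrajectorySummary",
    "PermutationResult",
    "parse_age",
    "log2_transform",
    "filter_low_coverage_regions",
    "summarize_trajectory",
    "permutation_test_trajectory",
]

GESTATION_DAYS = 280.0
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25
AGE_UNITS = ("pcw", "mos", "yrs")

META_COLUMNS = ("sample_id", "donor_id", "region", "age", "age_unit")


@dataclass(frozen=True)
class DevelopmentalAge:
    """Age normalised to days post conception; prenatal below 280 days."""

    days_post_conception: float

    def __post_init__(self) -> None:
        if not self.days_post_conception > 0:
            raise ValueError("days_post_conception must be positive")

    @property
    def is_prenatal(self) -> bool:
        return self.days_post_conception < GESTATION_DAYS


def parse_age(value: float, unit: str) -> DevelopmentalAge:
    """Convert an (age value, unit) pair to days post conception.

    ``pcw`` (post-conception weeks) maps to ``value * 7``; postnatal units
    add the 280-day gestation: ``mos`` -> ``280 + value * 30.44``, ``yrs``
    -> ``280 + value * 365.25``.
    """
    if unit not in AGE_UNITS:
        raise ValueError(f"unknown age unit {unit!r}; expected one of {AGE_UNITS}")
    if not value > 0:
        raise ValueError(f"age value must be positive, got {value}")
    if unit == "pcw":
        days = value * 7.0
    elif unit == "mos":
        days = GESTATION_DAYS + value * DAYS_PER_MONTH
    else:
        days = GESTATION_DAYS + value * DAYS_PER_YEAR
    return DevelopmentalAge(days_post_conception=days)


@dataclass
class BrainExpressionDataset:
    """RPKM expression matrix plus per-sample annotations.

    ``meta`` has one row per sample with columns ``sample_id, donor_id,
    region, age, age_unit``; ``values`` is a genes x samples DataFrame of
    nonnegative RPKM, columns aligned with ``meta.sample_id``.
    """

    meta: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        meta_ids = list(self.meta["sample_id"])
        if len(set(meta_ids)) != len(meta_ids):
            raise ValueError("duplicate sample_id in metadata")
        val_ids = list(self.values.columns)
        extra = sorted(set(val_ids) - set(meta_ids))
        absent = sorted(set(meta_ids) - set(val_ids))
        if extra or absent:
            raise ValueError(
                "sample ID mismatch between expression and metadata; "
                f"only in expression: {extra}; only in metadata: {absent}"
            )
        # align column order with metadata
        self.values = self.values[meta_ids]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative RPKM values are not allowed")
        bad_unit = set(self.meta["age_unit"]) - set(AGE_UNITS)
        if bad_unit:
            raise ValueError(f"unknown age units: {sorted(bad_unit)}")
        # fail early on unparseable ages
        for v, u in zip(self.meta["age"], self.meta["age_unit"]):
            parse_age(float(v), u)

    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def ages_days(self) -> np.ndarray:
        return np.array(
            [
                parse_age(float(v), u).days_post_conception
                for v, u in zip(self.meta["age"], self.meta["age_unit"])
            ]
        )

    def prenatal_mask(self) -> np.ndarray:
        return self.ages_days() < GESTATION_DAYS


@dataclass(frozen=True)
class TrajectorySummary:
    """Per-(region, timepoint) mean log2 expression for one gene."""

    gene: str
    table: pd.DataFrame  # columns region, age, age_unit, n, mean_log2
    grand_mean: float
    n_retained: int
    n_dropped: int  # zero-RPKM values dropped under offset 0


@dataclass(frozen=True)
class PermutationResult:
    """Prenatal-vs-postnatal permutation test for one gene's trajectory."""

    gene: str
    observed_statistic: float  # mean postnatal log2 - mean prenatal log2
    n_permutations: int
    n_extreme: int
    p_value: float
    n_prenatal: int
    n_postnatal: int
    seed: int | None = None

    def __post_init__(self) -> None:
        b = self.n_permutations
        if not (1 / (b + 1) <= self.p_value <= 1.0):
            raise ValueError("p-value outside [1/(B+1), 1]")


def log2_transform(rpkm, offset: float = 0.0):
    """``log2(rpkm + offset)``; zero RPKM at offset 0 becomes NaN (dropped).

    The RPKM values are used on the log2 scale throughout.  With the
    default offset of 0 a zero value has no finite logarithm, so it is
    excluded from all downstream means and tests rather than imputed;
    a positive offset keeps every value.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    arr = np.asarray(rpkm, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative RPKM")
    with np.errstate(divide="ignore"):
        out = np.log2(arr + offset)
    out = np.where(np.isneginf(out), np.nan, out)
    if np.isscalar(rpkm) or np.ndim(rpkm) == 0:
        return float(out)
    return out


def _gene_log2(dataset: BrainExpressionDataset, gene: str, offset: float) -> np.ndarray:
    if gene not in dataset.values.index:
        raise KeyError(f"gene {gene!r} not in dataset")
    return log2_transform(dataset.values.loc[gene].to_numpy(), offset)


def filter_low_coverage_regions(
    dataset: BrainExpressionDataset,
    gene: str,
    min_points: int = 5,
    offset: float = 0.0,
) -> tuple[BrainExpressionDataset, list[str]]:
    """Drop regions with fewer than ``min_points`` retained values for ``gene``.

    A value is retained when its log2 transform is finite (zero RPKM at
    offset 0 is dropped first).  Returns the reduced dataset and the sorted
    list of removed regions; removing every region is an error.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    vals = _gene_log2(dataset, gene, offset)
    retained = ~np.isnan(vals)
    per_region = (
        pd.Series(retained, index=dataset.meta["region"].to_numpy())
        .groupby(level=0)
        .sum()
    )
    all_regions = set(dataset.meta["region"])
    keep = {r for r in all_regions if per_region.get(r, 0) >= min_points}
    dropped = sorted(all_regions - keep)
    if not keep:
        raise ValueError("all regions dropped by the coverage filter")
    mask = dataset.meta["region"].isin(keep).to_numpy()
    meta = dataset.meta.loc[mask].reset_index(drop=True)
    values = dataset.values.loc[:, meta["sample_id"]]
    return BrainExpressionDataset(meta=meta, values=values), dropped


def summarize_trajectory(
    dataset: BrainExpressionDataset,
    gene: str,
    offset: float = 0.0,
) -> TrajectorySummary:
    """Mean log2 expression per (region, timepoint) plus the grand mean.

    The grand mean is the unweighted mean over all retained per-sample log2
    values (the horizontal reference line of a trajectory plot), not the
    mean of cell means.
    """
    vals = _gene_log2(dataset, gene, offset)
    retained = ~np.isnan(vals)
    if retained.sum() == 0:
        raise ValueError(f"no retained expression values for gene {gene!r}")
    df = dataset.meta.loc[retained, ["region", "age", "age_unit"]].copy()
    df["log2"] = vals[retained]
    table = (
        df.groupby(["region", "age", "age_unit"], as_index=False)
        .agg(n=("log2", "size"), mean_log2=("log2", "mean"))
        .sort_values(["region", "age_unit", "age"], kind="mergesort")
        .reset_index(drop=True)
    )
    return TrajectorySummary(
        gene=gene,
        table=table,
        grand_mean=float(vals[retained].mean()),
        n_retained=int(retained.sum()),
        n_dropped=int((~retained).sum()),
    )


def permutation_test_trajectory(
    dataset: BrainExpressionDataset,
    gene: str,
    n_permutations: int = 999,
    seed: int | None = None,
    offset: float = 0.0,
) -> PermutationResult:
    """Permutation test of the prenatal-vs-postnatal expression difference.

    The statistic is ``mean(postnatal log2) - mean(prenatal log2)`` over
    retained samples.  The null distribution is built by reassigning the
    prenatal/postnatal labels uniformly at random over samples (the group
    sizes are preserved); the two-sided p-value uses the add-one estimator

        p = (#{|T_perm| >= |T_obs|} + 1) / (B + 1),

    which is never zero and is a valid p-value at any B.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    vals = _gene_log2(dataset, gene, offset)
    retained = ~np.isnan(vals)
    vals = vals[retained]
    prenatal = dataset.prenatal_mask()[retained]
    n_pre = int(prenatal.sum())
    n_post = int((~prenatal).sum())
    if n_pre < 2 or n_post < 2:
        raise ValueError(
            f"need >= 2 samples on each side of birth, got {n_pre} prenatal / {n_post} postnatal"
        )
    observed = float(vals[~prenatal].mean() - vals[prenatal].mean())

    rng = np.random.default_rng(seed)
    n = vals.size
    total = vals.sum()
    # permute labels: random subsets of size n_pre play the prenatal role
    idx = np.tile(np.arange(n), (n_permutations, 1))
    idx = rng.permuted(idx, axis=1)[:, :n_pre]
    pre_sums = vals[idx].sum(axis=1)
    perm_stats = (total - pre_sums) / n_post - pre_sums / n_pre
    n_extreme = int(np.sum(np.abs(perm_stats) >= abs(observed) - 1e-12))
    p = (n_extreme + 1) / (n_permutations + 1)
    return PermutationResult(
        gene=gene,
        observed_statistic=observed,
        n_permutations=n_permutations,
        n_extreme=n_extreme,
        p_value=p,
        n_prenatal=n_pre,
        n_postnatal=n_post,
        seed=seed,
    )
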