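"""Cis-eQTL scan of one SNP against expression across regions and genes.

Each (brain region, gene) pair is tested by ordinary least squares of
expression on minor-allele dosage (0/1/2); the family of tests over the
full region x gene grid is controlled by Bonferroni division, with
untestable pairs still counted in the denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeDosage",
    "EqtlDataset",
    "EqtlRecord",
    "EqtlScanResult",
    "dosage_encode",
    "fit_cis_eqtl",
    "bonferroni_threshold",
    "scan_cis",
]


@dataclass(frozen=True)
class GenotypeDosage:
    """Minor-allele dosage (0/1/2, NaN = missing) for one SNP.

    The minor allele is the less frequent allele among non-missing calls
    in the defining sample; ties break to the lexicographically smaller
    allele.
    """

    snp_id: str
    dosage: np.ndarray  # float array, values in {0, 1, 2, nan}
    minor_allele: str
    major_allele: str
    monomorphic: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.dosage, dtype=float)
        ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage values must be 0, 1, 2 or missing")
        object.__setattr__(self, "dosage", d)

    @property
    def minor_allele_freq(self) -> float:
        d = self.dosage[~np.isnan(self.dosage)]
        if d.size == 0:
            return math.nan
        return float(d.sum() / (2 * d.size))


@dataclass
class EqtlDataset:
    """Genotype dosages plus an expression cube (region x gene x individual).

    ``expression`` holds log2-scale values; ``individuals`` aligns the last
    cube axis with every dosage vector.  Missing expression is NaN.
    """

    individuals: list[str]
    regions: list[str]
    genes: list[str]
    expression: np.ndarray  # shape (n_regions, n_genes, n_individuals)
    dosages: dict[str, GenotypeDosage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exp = np.asarray(self.expression, dtype=float)
        shape = (len(self.regions), len(self.genes), len(self.individuals))
        if exp.shape != shape:
            raise ValueError(f"expression shape {exp.shape} != {shape}")
        self.expression = exp
        for snp, dos in self.dosages.items():
            if dos.dosage.shape != (len(self.individuals),):
                raise ValueError(f"dosage for {snp} not aligned with individuals")


@dataclass(frozen=True)
class EqtlRecord:
    """OLS association of one (region, gene) expression with dosage."""

    snp_id: str
    region: str
    gene: str
    n_used: int
    slope: float
    se: float
    t_statistic: float
    p_value: float
    genotype_class_counts: tuple[int, int, int]  # individuals with dosage 0/1/2
    raising_allele: str  # allele whose count increases expression

    def __post_init__(self) -> None:
        if self.n_used != sum(self.genotype_class_counts):
            raise ValueError("n_used inconsistent with genotype class counts")


@dataclass(frozen=True)
class EqtlScanResult:
    """All per-pair records for one SNP plus the Bonferroni threshold."""

    snp_id: str
    records: tuple[EqtlRecord, ...]
    threshold: float
    alpha: float
    n_regions: int
    n_genes: int
    untestable: tuple[tuple[str, str], ...] = ()

    @property
    def significant(self) -> tuple[EqtlRecord, ...]:
        return tuple(r for r in self.records if r.p_value < self.threshold)


def dosage_encode(calls: pd.DataFrame, snp_id: str = "") -> GenotypeDosage:
    """Additively encode genotype calls for one biallelic SNP.

    ``calls`` needs columns ``allele1`` and ``allele2`` (one row per
    individual; None/NaN marks a missing call).  The minor allele is the
    less frequent among non-missing calls, ties breaking to the
    lexicographically smaller allele; dosage counts minor alleles.  A SNP
    with a single observed allele is flagged monomorphic, >2 alleles is an
    error.
    """
    a1 = calls["allele1"].to_numpy(dtype=object)
    a2 = calls["allele2"].to_numpy(dtype=object)
    missing = np.array([x is None or (isinstance(x, float) and math.isnan(x)) for x in a1])
    missing |= np.array([x is None or (isinstance(x, float) and math.isnan(x)) for x in a2])
    observed = list(a1[~missing]) + list(a2[~missing])
    if not observed:
        raise ValueError(f"no genotype calls for SNP {snp_id!r}")
    alleles, counts = np.unique(np.array(observed, dtype=str), return_counts=True)
    if len(alleles) > 2:
        raise ValueError(f"SNP {snp_id!r} has >2 alleles: {list(alleles)}")
    if len(alleles) == 1:
        minor = major = str(alleles[0])
        monomorphic = True
    else:
        monomorphic = False
        if counts[0] == counts[1]:
            minor, major = sorted(map(str, alleles))  # tie -> smaller allele is minor
        else:
            order = np.argsort(counts)
            minor, major = str(alleles[order[0]]), str(alleles[order[1]])
    dosage = np.full(len(calls), np.nan)
    for i in range(len(calls)):
        if not missing[i]:
            dosage[i] = (str(a1[i]) == minor) + (str(a2[i]) == minor)
    return GenotypeDosage(
        snp_id=snp_id,
        dosage=dosage,
        minor_allele=minor,
        major_allele=major,
        monomorphic=monomorphic,
    )


def fit_cis_eqtl(
    dosage: GenotypeDosage,
    expression: np.ndarray,
    region: str = "",
    gene: str = "",
) -> EqtlRecord:
    """OLS of expression on dosage for one (region, gene) pair.

    Individuals missing either value are excluded pairwise.  The slope is
    the expression change per minor allele; the two-sided p-value comes
    from the t distribution with n - 2 df.  Zero residual variance yields
    the smallest positive float as p, with a warning.
    """
    y = np.asarray(expression, dtype=float)
    d = dosage.dosage
    keep = ~(np.isnan(d) | np.isnan(y))
    d, y = d[keep], y[keep]
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 complete individuals, got {n}")
    sxx = float(np.sum((d - d.mean()) ** 2))
    if sxx == 0:
        raise ValueError("monomorphic in tested subset: zero dosage variance")
    sxy = float(np.sum((d - d.mean()) * (y - y.mean())))
    slope = sxy / sxx
    resid = y - y.mean() - slope * (d - d.mean())
    rss = float(np.sum(resid**2))
    df_resid = n - 2
    if rss <= 0:
        warnings.warn(
            f"zero residual variance for ({region}, {gene}); p set to smallest positive float",
            stacklevel=2,
        )
        se = 0.0
        t = math.inf if slope != 0 else 0.0
        p = float(np.nextafter(0, 1)) if slope != 0 else 1.0
    else:
        se = math.sqrt(rss / df_resid / sxx)
        t = slope / se
        p = float(2 * stats.t.sf(abs(t), df_resid))
    counts = tuple(int(np.sum(d == k)) for k in (0, 1, 2))
    raising = dosage.minor_allele if slope >= 0 else dosage.major_allele
    return EqtlRecord(
        snp_id=dosage.snp_id,
        region=region,
        gene=gene,
        n_used=n,
        slope=slope,
        se=se,
        t_statistic=t,
        p_value=p,
        genotype_class_counts=counts,
        raising_allele=raising,
    )


def bonferroni_threshold(alpha: float, n_regions: int, n_genes: int) -> float:
    """Per-test level ``alpha / (n_regions * n_genes)`` at full precision."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_regions < 1 or n_genes < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_regions * n_genes)


def scan_cis(dataset: EqtlDataset, snp_id: str, alpha: float = 0.05) -> EqtlScanResult:
    """Test one SNP against every (region, gene) expression trait.

    The Bonferroni denominator is the full region x gene grid, so pairs
    that cannot be tested (too few complete individuals, or a monomorphic
    dosage subset) still count toward the correction; they are listed in
    ``untestable``.
    """
    if snp_id not in dataset.dosages:
        raise KeyError(f"SNP {snp_id!r} not in dataset")
    dosage = dataset.dosages[snp_id]
    threshold = bonferroni_threshold(alpha, len(dataset.regions), len(dataset.genes))
    records: list[EqtlRecord] = []
    untestable: list[tuple[str, str]] = []
    for i, region in enumerate(dataset.regions):
        for j, gene in enumerate(dataset.genes):
            try:
                rec = fit_cis_eqtl(dosage, dataset.expression[i, j], region, gene)
            except ValueError:
                untestable.append((region, gene))
                continue
            records.append(rec)
    if not records:
        raise ValueError(f"no testable (region, gene) pair for SNP {snp_id!r}")
    return EqtlScanResult(
        snp_id=snp_id,
        records=tuple(records),
        threshold=threshold,
        alpha=alpha,
        n_regions=len(dataset.regions),
        n_genes=len(dataset.genes),
        untestable=tuple(untestable),
    )
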