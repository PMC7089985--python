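"""Synthetic datasets with the statistical structure each stage assumes.

Three generators stand in for the restricted source datasets:

* a developmental expression atlas — Gaussian log2 expression around a
  prenatal and a postnatal mean, exponentiated back to RPKM;
* a brain eQTL panel — Hardy-Weinberg genotypes plus an expression cube
  with a single planted additive cis-effect in one (region, gene) cell;
* a case-control genotype table — multinomial draws from the genotype
  distributions a chosen genetic model, odds ratio and prevalence induce.

Defaults mirror the designs the pipeline emulates: a 16-region,
31-timepoint developmental atlas; a 10-region, 7-gene, 134-individual
eQTL panel; and a 602-case / 604-control association sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import GenotypeCounts2x3
from .eqtl import EqtlDataset, GenotypeDosage
from .models import GeneticModel, genotype_probs_given_status, hwe_genotype_freqs
from .trajectory import BrainExpressionDataset, parse_age

__all__ = [
    "ATLAS_REGIONS",
    "ATLAS_TIMEPOINTS",
    "EQTL_REGIONS",
    "EQTL_GENES",
    "TrajectorySimSpec",
    "EqtlSimSpec",
    "CaseControlSimSpec",
    "simulate_trajectory_dataset",
    "simulate_eqtl_dataset",
    "simulate_case_control",
]

#: The 16 brain regions of the developmental atlas retained by the
#: coverage filter (cortical areas, amygdala, hippocampus, striatum,
#: thalamus, cerebellum).
ATLAS_REGIONS = (
    "A1C", "AMY", "CBC", "DFC", "HIP", "IPC", "ITC", "M1C",
    "MD", "MFC", "OFC", "S1C", "STC", "STR", "V1C", "VFC",
)

#: 31 developmental timepoints, 8 post-conception weeks to 40 years.
ATLAS_TIMEPOINTS = tuple(
    [(w, "pcw") for w in (8, 9, 12, 13, 16, 17, 19, 21, 24, 25, 26, 35, 37)]
    + [(m, "mos") for m in (4, 10)]
    + [(y, "yrs") for y in (1, 2, 3, 4, 8, 11, 13, 15, 18, 19, 21, 23, 30, 36, 37, 40)]
)

#: The 10 adult brain regions of the eQTL panel.
EQTL_REGIONS = (
    "MEDU", "PUTM", "SNIG", "CRBL", "THAL", "TCTX", "WHMT", "OCTX", "FCTX", "HIPP",
)

#: The focal gene and its six cis neighbours.
EQTL_GENES = ("ITIH3", "DNAH1", "GLT8D1", "NISCH", "PBRM1", "SFMBT1", "STAB1")


@dataclass(frozen=True)
class TrajectorySimSpec:
    """Design of a synthetic developmental expression dataset.

    Log2 expression is Gaussian around ``mu_prenatal`` before birth and
    ``mu_postnatal`` after, with sd ``sigma``; stored values are
    ``2**log2`` so the analysis-side log2 recovers the Gaussian model.
    One sample is drawn per donor x region x timepoint.
    """

    regions: tuple[str, ...] = ATLAS_REGIONS
    timepoints: tuple[tuple[float, str], ...] = ATLAS_TIMEPOINTS
    mu_prenatal: float = 1.0
    mu_postnatal: float = 3.0
    sigma: float = 0.75
    n_genes: int = 1
    n_donors: int = 2
    seed: int | None = None
    genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.timepoints:
            raise ValueError("timepoints must be nonempty")
        if not self.regions:
            raise ValueError("regions must be nonempty")
        if self.n_genes < 1 or self.n_donors < 1:
            raise ValueError("n_genes and n_donors must be >= 1")
        if self.mu_prenatal != self.mu_postnatal:
            prenatal = [parse_age(v, u).is_prenatal for v, u in self.timepoints]
            if not (any(prenatal) and not all(prenatal)):
                raise ValueError(
                    "planting a prenatal/postnatal shift requires timepoints on both sides of birth"
                )

    def gene_names(self) -> tuple[str, ...]:
        if self.genes is not None:
            if len(self.genes) != self.n_genes:
                raise ValueError("genes length must equal n_genes")
            return self.genes
        return tuple(f"gene_{i + 1:02d}" for i in range(self.n_genes))


@dataclass(frozen=True)
class EqtlSimSpec:
    """Design of a synthetic eQTL panel with one planted cis-effect.

    Genotypes are Hardy-Weinberg at ``maf``; expression is
    ``baseline + beta * dosage + N(0, sigma)`` in the single
    (``target_region``, ``target_gene``) cell and ``baseline + N(0, sigma)``
    everywhere else.
    """

    n_individuals: int = 134
    maf: float = 0.32
    regions: tuple[str, ...] = EQTL_REGIONS
    genes: tuple[str, ...] = EQTL_GENES
    target_region: str = "HIPP"
    target_gene: str = "ITIH3"
    beta: float = 1.0
    sigma: float = 0.3
    baseline: float = 5.0
    snp_id: str = "rs0000001"
    minor_allele: str = "A"
    major_allele: str = "G"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.target_region not in self.regions:
            raise ValueError(f"target_region {self.target_region!r} not in regions")
        if self.target_gene not in self.genes:
            raise ValueError(f"target_gene {self.target_gene!r} not in genes")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_individuals < 3:
            raise ValueError("n_individuals must be >= 3")


@dataclass(frozen=True)
class CaseControlSimSpec:
    """Design of a synthetic case-control genotype sample.

    Defaults reproduce the emulated power scenario: MAF 0.4709, disease
    prevalence 2%, per-genotype effects from a multiplicative model with
    OR 1.5, 602 cases and 604 controls.
    """

    maf: float = 0.4709
    model: GeneticModel | str = GeneticModel.MULTIPLICATIVE
    odds_ratio: float = 1.5
    prevalence: float = 0.02
    n_case: int = 602
    n_control: int = 604
    snp_id: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", GeneticModel(self.model))
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")


def simulate_trajectory_dataset(spec: TrajectorySimSpec) -> BrainExpressionDataset:
    """Draw a synthetic developmental expression dataset."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    rows = []
    for donor in range(1, spec.n_donors + 1):
        for region in spec.regions:
            for age, unit in spec.timepoints:
                rows.append(
                    {
                        "sample_id": f"d{donor:02d}_{region}_{age:g}{unit}",
                        "donor_id": f"donor_{donor:02d}",
                        "region": region,
                        "age": float(age),
                        "age_unit": unit,
                    }
                )
    meta = pd.DataFrame(rows)
    prenatal = np.array(
        [parse_age(a, u).is_prenatal for a, u in zip(meta["age"], meta["age_unit"])]
    )
    mu = np.where(prenatal, spec.mu_prenatal, spec.mu_postnatal)
    log2_vals = mu + rng.normal(0.0, spec.sigma, size=(len(genes), len(meta)))
    values = pd.DataFrame(
        np.exp2(log2_vals), index=list(genes), columns=list(meta["sample_id"])
    )
    return BrainExpressionDataset(meta=meta, values=values)


def simulate_eqtl_dataset(spec: EqtlSimSpec) -> EqtlDataset:
    """Draw a synthetic eQTL panel with one planted additive cis-effect."""
    rng = np.random.default_rng(spec.seed)
    freqs = hwe_genotype_freqs(spec.maf)  # (MM, Mm, mm) -> dosage (0, 1, 2)
    dosage = rng.choice(np.array([0.0, 1.0, 2.0]), size=spec.n_individuals, p=freqs)
    individuals = [f"ind_{i + 1:03d}" for i in range(spec.n_individuals)]
    shape = (len(spec.regions), len(spec.genes), spec.n_individuals)
    expr = spec.baseline + rng.normal(0.0, spec.sigma, size=shape)
    ri = spec.regions.index(spec.target_region)
    gi = spec.genes.index(spec.target_gene)
    expr[ri, gi] += spec.beta * dosage
    dos = GenotypeDosage(
        snp_id=spec.snp_id,
        dosage=dosage,
        minor_allele=spec.minor_allele,
        major_allele=spec.major_allele,
        monomorphic=bool(np.all(dosage == dosage[0])),
    )
    return EqtlDataset(
        individuals=individuals,
        regions=list(spec.regions),
        genes=list(spec.genes),
        expression=expr,
        dosages={spec.snp_id: dos},
    )


def simulate_case_control(spec: CaseControlSimSpec) -> GenotypeCounts2x3:
    """Draw case/control genotype counts under a planted genetic model.

    The case row is multinomial over P(genotype | case) and the control row
    over P(genotype | control), both induced by the spec's model, OR, MAF
    and prevalence (controls are population non-cases).
    """
    case_p, ctrl_p = genotype_probs_given_status(
        spec.maf, spec.model, spec.odds_ratio, spec.prevalence
    )
    rng = np.random.default_rng(spec.seed)
    case = rng.multinomial(spec.n_case, case_p)
    ctrl = rng.multinomial(spec.n_control, ctrl_p)
    return GenotypeCounts2x3(
        case_MM=int(case[0]),
        case_Mm=int(case[1]),
        case_mm=int(case[2]),
        ctrl_MM=int(ctrl[0]),
        ctrl_Mm=int(ctrl[1]),
        ctrl_mm=int(ctrl[2]),
        snp_id=spec.snp_id,
    )
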