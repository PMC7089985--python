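"""Case-control SNP association: HWE QC, genetic-model selection, power.

The association stage works on a 2x3 table of genotype counts (case and
control counts of MM, Mm, mm) and follows a four-step model-selection
procedure:

1. estimate OR1 = odds(Mm)/odds(MM) and OR2 = odds(mm)/odds(Mm) from the
   raw counts (``odd_g`` = cases with g / controls with g);
2. select the genetic model whose characteristic curve in the
   (ln OR1, ln OR2) plane is closest to the observed point;
3. fit an unconditional logistic regression under the selected model's
   genotype coding to obtain a single OR with Wald CI and p-value;
4. back out the model-constrained OR1/OR2 implied by that fit.

Hardy-Weinberg equilibrium is checked in controls by a goodness-of-fit
chi-square (1 df) before the steps; failure is a warning, not an abort.
A genetic power calculation for the allelic case-control comparison
completes the stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .models import (
    GeneticModel,
    genotype_probs_given_status,
    modified_ors,
    select_genetic_model,
)

__all__ = [
    "GenotypeCounts2x3",
    "HweResult",
    "OrPair",
    "AssociationResult",
    "PowerSpec",
    "hwe_chi_square",
    "pearson_chi2_2x2",
    "odds_ratio_2x2",
    "compute_or1_or2",
    "fit_selected_model",
    "association_pipeline",
    "genetic_power",
]

GENOTYPE_ORDER = ("MM", "Mm", "mm")


@dataclass(frozen=True)
class GenotypeCounts2x3:
    """Case/control genotype counts for one biallelic SNP.

    M is the major and m the minor allele, defined from the pooled control
    sample; counts are subjects, not alleles.
    """

    case_MM: int
    case_Mm: int
    case_mm: int
    ctrl_MM: int
    ctrl_Mm: int
    ctrl_mm: int
    snp_id: str = ""

    def __post_init__(self) -> None:
        for name in ("case_MM", "case_Mm", "case_mm", "ctrl_MM", "ctrl_Mm", "ctrl_mm"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_case == 0 or self.n_control == 0:
            raise ValueError("empty group: both case and control totals must be positive")

    @property
    def case_row(self) -> np.ndarray:
        return np.array([self.case_MM, self.case_Mm, self.case_mm], dtype=float)

    @property
    def ctrl_row(self) -> np.ndarray:
        return np.array([self.ctrl_MM, self.ctrl_Mm, self.ctrl_mm], dtype=float)

    @property
    def n_case(self) -> int:
        return self.case_MM + self.case_Mm + self.case_mm

    @property
    def n_control(self) -> int:
        return self.ctrl_MM + self.ctrl_Mm + self.ctrl_mm


@dataclass(frozen=True)
class HweResult:
    """Goodness-of-fit chi-square test of Hardy-Weinberg proportions (1 df).

    ``allele_freq`` is the estimated frequency of the allele whose
    homozygote is the third genotype class (the minor allele when counts
    arrive in (MM, Mm, mm) order); the statistic is symmetric in the
    labelling.
    """

    chi2: float
    p_value: float
    observed: tuple[float, float, float]
    expected: tuple[float, float, float]
    allele_freq: float


@dataclass(frozen=True)
class OrPair:
    """Step-1 odds ratios: OR1 = odds(Mm)/odds(MM), OR2 = odds(mm)/odds(Mm)."""

    or1: float
    or2: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


@dataclass(frozen=True)
class AssociationResult:
    """Full output of the four-step association pipeline for one SNP."""

    counts: GenotypeCounts2x3
    hwe: HweResult
    hwe_ok: bool
    or1_ori: float
    or2_ori: float
    selected_model: GeneticModel
    model_distances: dict[GeneticModel, float]
    near_null: bool
    or_step3: float
    ci_low: float
    ci_high: float
    p_value: float
    or1_mod: float
    or2_mod: float
    alpha: float
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class PowerSpec:
    """Scenario for the allelic case-control power calculation."""

    maf: float
    prevalence: float
    odds_ratio: float
    n_case: int
    n_control: int
    alpha: float = 0.05
    test: str = "allelic"
    unit: str = "subjects"  # group-size convention; see genetic_power

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test != "allelic":
            raise ValueError(f"unsupported test {self.test!r}")
        if self.unit not in ("subjects", "alleles"):
            raise ValueError(f"unit must be 'subjects' or 'alleles', got {self.unit!r}")


# ---------------------------------------------------------------------------
# Elementary tests


def hwe_chi_square(ctrl_MM: int, ctrl_Mm: int, ctrl_mm: int) -> HweResult:
    """Goodness-of-fit chi-square against Hardy-Weinberg proportions.

    The allele frequency is estimated from the counts themselves; expected
    counts are ``n * (p^2, 2pq, q^2)``; the statistic is compared to a
    chi-square with 1 df (3 classes - 1 - 1 estimated parameter), with no
    continuity correction.
    """
    obs = np.array([ctrl_MM, ctrl_Mm, ctrl_mm], dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    q = (2 * obs[2] + obs[1]) / (2 * n)  # frequency of the third-class allele
    p = 1.0 - q
    expected = n * np.array([p * p, 2 * p * q, q * q])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        chi2=chi2,
        p_value=p_value,
        observed=tuple(float(v) for v in obs),
        expected=tuple(float(v) for v in expected),
        allele_freq=float(q),
    )


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, two-sided p from
    a chi-square with 1 df.  Used e.g. to test gender balance between
    cases and controls.
    """
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m <= 0 for m in margins):
        raise ValueError("all table margins must be positive")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float, alpha: float = 0.05
) -> tuple[float, tuple[float, float], float, bool]:
    """Odds ratio ``ad/bc`` with Wald CI and p for a 2x2 table.

    Layout: rows are case (a, b) and control (c, d); columns exposed /
    unexposed.  Any zero cell triggers the Haldane-Anscombe correction
    (0.5 added to every cell), reported through the returned flag.
    The CI is ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))`` and p is
    the two-sided Wald test of ln OR = 0.
    """
    cells = [a, b, c, d]
    if any(v < 0 for v in cells):
        raise ValueError("counts must be nonnegative")
    corrected = any(v == 0 for v in cells)
    if corrected:
        if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
            raise ValueError("odds ratio undefined: an entire row or column is zero")
        cells = [v + 0.5 for v in cells]
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return float(or_), ci, p, corrected


# ---------------------------------------------------------------------------
# Four-step model selection


def compute_or1_or2(counts: GenotypeCounts2x3) -> OrPair:
    """Step 1: raw OR1 and OR2 from the observed genotype counts."""
    case = counts.case_row
    ctrl = counts.ctrl_row
    for g, name in enumerate(GENOTYPE_ORDER):
        if case[g] == 0 and ctrl[g] == 0:
            raise ValueError(f"genotype {name} absent in both groups")
    corrected = bool(np.any(case == 0) or np.any(ctrl == 0))
    if corrected:
        case = case + 0.5
        ctrl = ctrl + 0.5
    odd = case / ctrl
    return OrPair(or1=float(odd[1] / odd[0]), or2=float(odd[2] / odd[1]), corrected=corrected)


def _model_coding(model: GeneticModel) -> np.ndarray:
    """Per-genotype regressor for the logistic fit (MM, Mm, mm order)."""
    if model is GeneticModel.DOMINANT:
        return np.array([0.0, 1.0, 1.0])
    if model is GeneticModel.RECESSIVE:
        return np.array([0.0, 0.0, 1.0])
    if model is GeneticModel.OVERDOMINANT:
        return np.array([0.0, 1.0, 0.0])
    if model is GeneticModel.ADDITIVE:
        return np.array([0.0, 1.0, 2.0])
    raise ValueError(model)


def _logistic_or(
    case: np.ndarray, ctrl: np.ndarray, x: np.ndarray, alpha: float
) -> tuple[float, tuple[float, float], float]:
    """Unconditional logistic regression of status on one regressor.

    ``case``/``ctrl`` are counts per level of ``x``; the binomial GLM on
    (successes, failures) per level is the exact grouped-data equivalent.
    """
    exog = sm.add_constant(x)
    endog = np.column_stack([case, ctrl])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # saturated grouped fits trip benign perfect-prediction warnings
        warnings.simplefilter("ignore")
        fit = model.fit(tol=1e-12, maxiter=200)
    beta = float(fit.params[1])
    # Wald covariance from the Fisher information at the converged MLE
    # (the solver's last-iteration weights can lag the params by ~1e-6)
    p_hat = np.asarray(fit.predict(exog), dtype=float)
    w = (case + ctrl) * p_hat * (1.0 - p_hat)
    info = exog.T @ (exog * w[:, None])
    se = float(math.sqrt(np.linalg.inv(info)[1, 1]))
    z = stats.norm.ppf(1 - alpha / 2)
    ci = (math.exp(beta - z * se), math.exp(beta + z * se))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return math.exp(beta), ci, p


def fit_selected_model(
    counts: GenotypeCounts2x3,
    model: GeneticModel | str,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float, bool]:
    """Step 3: OR with Wald CI and p under the selected model's coding.

    Binary codings (dominant / recessive / overdominant) collapse the 2x3
    table to a 2x2 and are fitted by logistic regression — identical, up to
    solver tolerance, to the closed-form cross-product OR.  The additive
    model fits a 0/1/2 dosage logistic regression; the multiplicative model
    uses the allele-level 2x2 (each subject contributes two alleles).

    Returns ``(or, (ci_low, ci_high), p, corrected)`` where ``corrected``
    reports a Haldane-Anscombe fallback triggered by an empty coding level
    (separation).
    """
    model = GeneticModel(model)
    case = counts.case_row
    ctrl = counts.ctrl_row

    if model is GeneticModel.MULTIPLICATIVE:
        # allele-level table: m vs M alleles in cases and controls
        a = case[1] + 2 * case[2]
        b = 2 * case[0] + case[1]
        c = ctrl[1] + 2 * ctrl[2]
        d = 2 * ctrl[0] + ctrl[1]
        if 0 in (a, b, c, d):
            or_, ci, p, _ = odds_ratio_2x2(a, b, c, d, alpha)
            return or_, ci, p, True
        or_, ci, p = _logistic_or(
            np.array([b, a]), np.array([d, c]), np.array([0.0, 1.0]), alpha
        )
        return or_, ci, p, False

    if model is GeneticModel.ADDITIVE:
        if np.any(case + ctrl == 0) or np.any(case == 0) or np.any(ctrl == 0):
            case = case + 0.5
            ctrl = ctrl + 0.5
            corrected = True
        else:
            corrected = False
        or_, ci, p = _logistic_or(case, ctrl, _model_coding(model), alpha)
        return or_, ci, p, corrected

    coding = _model_coding(model)
    exposed = coding == 1.0
    a = case[exposed].sum()
    b = case[~exposed].sum()
    c = ctrl[exposed].sum()
    d = ctrl[~exposed].sum()
    if 0 in (a, b, c, d):
        or_, ci, p, _ = odds_ratio_2x2(a, b, c, d, alpha)
        return or_, ci, p, True
    or_, ci, p = _logistic_or(case, ctrl, coding, alpha)
    return or_, ci, p, False


def association_pipeline(
    counts: GenotypeCounts2x3,
    alpha: float = 0.05,
    null_tolerance: float = 0.05,
    model: GeneticModel | str | None = None,
) -> AssociationResult:
    """Run HWE QC and Steps 1-4 on one SNP's genotype counts.

    ``model`` forces a genetic model instead of the Step-2 selection (the
    selection diagnostics are still computed and reported).  An HWE failure
    in controls (p <= 0.05) is reported via ``hwe_ok`` and a warning, not
    an error.
    """
    flags: list[str] = []
    hwe = hwe_chi_square(counts.ctrl_MM, counts.ctrl_Mm, counts.ctrl_mm)
    hwe_ok = hwe.p_value > 0.05
    if not hwe_ok:
        warnings.warn(
            f"controls deviate from Hardy-Weinberg equilibrium (p = {hwe.p_value:.3g})",
            stacklevel=2,
        )
        flags.append("hwe_violation")

    pair = compute_or1_or2(counts)
    if pair.corrected:
        flags.append("zero_cell_correction_step1")
    selected, distances, near_null = select_genetic_model(
        pair.or1, pair.or2, null_tolerance=null_tolerance
    )
    if model is not None:
        selected = GeneticModel(model)
    if near_null:
        flags.append("near_null")

    or_step3, ci, p, corrected = fit_selected_model(counts, selected, alpha=alpha)
    if corrected:
        flags.append("zero_cell_correction_step3")
    or1_mod, or2_mod = modified_ors(selected, or_step3)

    return AssociationResult(
        counts=counts,
        hwe=hwe,
        hwe_ok=hwe_ok,
        or1_ori=pair.or1,
        or2_ori=pair.or2,
        selected_model=selected,
        model_distances=distances,
        near_null=near_null,
        or_step3=or_step3,
        ci_low=ci[0],
        ci_high=ci[1],
        p_value=p,
        or1_mod=or1_mod,
        or2_mod=or2_mod,
        alpha=alpha,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Power


def genetic_power(spec: PowerSpec) -> float:
    """Power of the allelic case-control comparison for a given scenario.

    Case and control minor-allele frequencies are derived from the
    multiplicative genotype-odds model at the spec's MAF, prevalence and
    per-allele OR (baseline odds solved so the population risk equals the
    prevalence).  Power is that of the two-sided two-proportion chi-square
    (equivalently the z-test) comparing those frequencies, via the normal
    approximation:

        power = Phi((delta - z * s0)/s1) + Phi((-delta - z * s0)/s1)

    with ``delta`` the frequency difference, ``s0`` the pooled-null and
    ``s1`` the unpooled alternative standard error.

    ``spec.unit`` sets the group-size convention: ``"subjects"`` (default)
    uses the numbers of case and control subjects as the two group sizes,
    treating the allele frequency as a per-subject exposure probability —
    the convention of the classical case-control power calculators this
    stage mirrors; ``"alleles"`` counts each subject's two chromosomes as
    independent observations (2N per group), which is noticeably more
    optimistic at the same OR.
    """
    case_probs, ctrl_probs = genotype_probs_given_status(
        spec.maf, GeneticModel.MULTIPLICATIVE, spec.odds_ratio, spec.prevalence
    )
    p1 = case_probs[1] / 2 + case_probs[2]  # case minor-allele frequency
    p2 = ctrl_probs[1] / 2 + ctrl_probs[2]
    mult = 2 if spec.unit == "alleles" else 1
    n1 = mult * spec.n_case
    n2 = mult * spec.n_control
    delta = abs(p1 - p2)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    s1 = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    power = stats.norm.cdf((delta - z * s0) / s1) + stats.norm.cdf((-delta - z * s0) / s1)
    return float(power)
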