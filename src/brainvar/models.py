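"""Genetic disease models shared by simulation, association, and power.

A biallelic SNP has genotypes MM (major homozygote), Mm (heterozygote) and
mm (minor homozygote).  A genetic model assigns each genotype an odds
multiplier relative to MM:

================  =========  ==============
model             psi(Mm)    psi(mm)
================  =========  ==============
multiplicative    OR         OR**2
dominant          OR         OR
recessive         1          OR
overdominant      OR         1
additive          OR         2*OR - 1
================  =========  ==============

The additive model is additive on the risk scale under a rare disease,
which translates to ``psi_mm = 2*OR - 1`` on the odds scale; it requires
``OR > 1/2``.

Each model also has a characteristic curve in the (ln OR1, ln OR2) plane,
where OR1 = odds(Mm)/odds(MM) and OR2 = odds(mm)/odds(Mm).  Model selection
picks the curve closest (Euclidean distance) to the observed point.
"""

from __future__ import annotations

import enum
import math

import numpy as np
from scipy import optimize

__all__ = [
    "GeneticModel",
    "MODEL_PRIORITY",
    "genotype_odds_multipliers",
    "hwe_genotype_freqs",
    "genotype_probs_given_status",
    "model_plane_distance",
    "select_genetic_model",
    "modified_ors",
]


class GeneticModel(str, enum.Enum):
    """The five classical single-SNP disease models."""

    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    OVERDOMINANT = "overdominant"


#: Fixed tie-break order for model selection (first wins on exact ties).
MODEL_PRIORITY = (
    GeneticModel.MULTIPLICATIVE,
    GeneticModel.DOMINANT,
    GeneticModel.RECESSIVE,
    GeneticModel.OVERDOMINANT,
    GeneticModel.ADDITIVE,
)


def genotype_odds_multipliers(model: GeneticModel | str, odds_ratio: float) -> np.ndarray:
    """Odds multipliers ``(psi_MM, psi_Mm, psi_mm)`` for a model and OR.

    ``psi_MM`` is always 1.  For the additive model ``odds_ratio`` must
    exceed 1/2 or ``psi_mm`` would be nonpositive.
    """
    model = GeneticModel(model)
    if odds_ratio <= 0:
        raise ValueError(f"odds_ratio must be positive, got {odds_ratio}")
    if model is GeneticModel.MULTIPLICATIVE:
        psi = (1.0, odds_ratio, odds_ratio**2)
    elif model is GeneticModel.DOMINANT:
        psi = (1.0, odds_ratio, odds_ratio)
    elif model is GeneticModel.RECESSIVE:
        psi = (1.0, 1.0, odds_ratio)
    elif model is GeneticModel.OVERDOMINANT:
        psi = (1.0, odds_ratio, 1.0)
    else:  # additive
        if odds_ratio <= 0.5:
            raise ValueError(
                "additive model undefined for odds_ratio <= 1/2 "
                f"(psi_mm = 2*OR - 1 would be <= 0), got {odds_ratio}"
            )
        psi = (1.0, odds_ratio, 2.0 * odds_ratio - 1.0)
    return np.asarray(psi, dtype=float)


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ``(f_MM, f_Mm, f_mm)``."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    q = maf
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def genotype_probs_given_status(
    maf: float,
    model: GeneticModel | str,
    odds_ratio: float,
    prevalence: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype distributions in cases and in (population) controls.

    The population carries Hardy-Weinberg genotype frequencies ``f_g`` at
    ``maf``.  Disease odds are ``o_g = o0 * psi_g`` with the model's
    multipliers; the baseline odds ``o0`` is solved so the population risk
    ``sum_g f_g * o_g / (1 + o_g)`` equals ``prevalence``.  Bayes' rule then
    gives

        P(g | case)    = f_g * r_g / K
        P(g | control) = f_g * (1 - r_g) / (1 - K)

    with ``r_g = o_g/(1+o_g)`` and ``K`` the prevalence.  Controls are
    non-cases, so at appreciable prevalence their genotype frequencies
    deviate slightly from Hardy-Weinberg.

    Returns
    -------
    (case_probs, control_probs) : pair of length-3 arrays over (MM, Mm, mm),
        each summing to 1 within 1e-10.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    f = hwe_genotype_freqs(maf)
    psi = genotype_odds_multipliers(model, odds_ratio)

    def excess(log_o0: float) -> float:
        o = math.exp(log_o0) * psi
        return float(np.sum(f * o / (1.0 + o))) - prevalence

    lo, hi = -60.0, 60.0
    if excess(lo) > 0 or excess(hi) < 0:
        raise ValueError(
            f"prevalence {prevalence} unattainable under model "
            f"{GeneticModel(model).value} with OR {odds_ratio}"
        )
    log_o0 = optimize.brentq(excess, lo, hi, xtol=1e-14)
    o = math.exp(log_o0) * psi
    r = o / (1.0 + o)
    case = f * r / prevalence
    control = f * (1.0 - r) / (1.0 - prevalence)
    return case, control


# ---------------------------------------------------------------------------
# Model-selection plane


def _additive_branch_sqdist(t: float, x: float, y: float) -> float:
    # squared distance from (x, y) to the additive curve point at ln OR = t
    yc = math.log(2.0 * math.exp(t) - 1.0) - t
    return (x - t) ** 2 + (y - yc) ** 2


def _additive_distance(x: float, y: float) -> float:
    """Distance from (x, y) to the additive characteristic curve.

    The curve is ``y = ln(2 e**x - 1) - x`` for ``x > ln(1/2)`` (the locus
    of (ln OR1, ln OR2) points with psi_Mm = OR, psi_mm = 2 OR - 1),
    together with its reflection through the origin (the same constraint
    applied to the protective direction).  Minimised numerically on each
    branch.
    """
    lo = math.log(0.5) + 1e-9
    best = math.inf
    for px, py in ((x, y), (-x, -y)):
        hi = max(abs(px), abs(py)) + 3.0
        res = optimize.minimize_scalar(
            _additive_branch_sqdist,
            bounds=(lo, hi),
            args=(px, py),
            method="bounded",
            options={"xatol": 1e-12},
        )
        best = min(best, float(res.fun))
    return math.sqrt(max(best, 0.0))


def model_plane_distance(model: GeneticModel | str, log_or1: float, log_or2: float) -> float:
    """Euclidean distance from ``(ln OR1, ln OR2)`` to a model's curve.

    Curves: dominant ``y = 0``; recessive ``x = 0``; multiplicative
    ``y = x``; overdominant ``y = -x``; additive as in
    :func:`_additive_distance`.  All pass through the origin.
    """
    model = GeneticModel(model)
    x, y = float(log_or1), float(log_or2)
    if model is GeneticModel.DOMINANT:
        return abs(y)
    if model is GeneticModel.RECESSIVE:
        return abs(x)
    if model is GeneticModel.MULTIPLICATIVE:
        return abs(y - x) / math.sqrt(2.0)
    if model is GeneticModel.OVERDOMINANT:
        return abs(y + x) / math.sqrt(2.0)
    return _additive_distance(x, y)


def select_genetic_model(
    or1: float,
    or2: float,
    null_tolerance: float = 0.05,
) -> tuple[GeneticModel, dict[GeneticModel, float], bool]:
    """Select the disease model whose characteristic curve is nearest.

    Plots ``(ln OR1, ln OR2)`` and returns the model with minimal Euclidean
    distance to its curve, the per-model distances, and a ``near_null`` flag
    raised when the point lies within ``null_tolerance`` of the origin
    (every curve passes through the origin, so the selection is weakly
    identified there — a model is still returned).

    Exact ties are broken by :data:`MODEL_PRIORITY`.
    """
    if or1 <= 0 or or2 <= 0 or not (math.isfinite(or1) and math.isfinite(or2)):
        raise ValueError(f"ORs must be positive and finite, got ({or1}, {or2})")
    x, y = math.log(or1), math.log(or2)
    distances = {m: model_plane_distance(m, x, y) for m in MODEL_PRIORITY}
    best = min(MODEL_PRIORITY, key=lambda m: distances[m])
    near_null = math.hypot(x, y) < null_tolerance
    return best, distances, near_null


def modified_ors(model: GeneticModel | str, or_step3: float) -> tuple[float, float]:
    """Model-constrained ``(OR1, OR2)`` implied by a fitted OR.

    multiplicative -> (OR, OR); dominant -> (OR, 1); recessive -> (1, OR);
    overdominant -> (OR, 1/OR); additive -> (OR, (2 OR - 1)/OR).
    """
    model = GeneticModel(model)
    if or_step3 <= 0:
        raise ValueError(f"or_step3 must be positive, got {or_step3}")
    if model is GeneticModel.MULTIPLICATIVE:
        return or_step3, or_step3
    if model is GeneticModel.DOMINANT:
        return or_step3, 1.0
    if model is GeneticModel.RECESSIVE:
        return 1.0, or_step3
    if model is GeneticModel.OVERDOMINANT:
        return or_step3, 1.0 / or_step3
    if or_step3 <= 0.5:
        raise ValueError(
            f"additive constraint undefined for OR <= 1/2, got {or_step3}"
        )
    return or_step3, (2.0 * or_step3 - 1.0) / or_step3
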