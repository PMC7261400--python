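"""Quantitative bias analysis for linkage-induced misclassification.

When linkage to a register decides a binary status (e.g. linked-to-deaths =
died), missed matches produce false negatives and false matches produce
false positives. Control subsets with known status give the classification
sensitivity Se = P(linked | true positive) and specificity
Sp = P(unlinked | true negative). An observed proportion then relates to
the true one by the forward misclassification model

    p_obs = Se * p_true + (1 - Sp) * (1 - p_true)

whose inverse is the Rogan-Gladen estimator

    p_true = (p_obs + Sp - 1) / (Se + Sp - 1),

defined whenever Se + Sp > 1. Nondifferential misclassification (shared
Se/Sp with Sp < 1) biases an observed risk ratio towards no association;
correcting each group's proportion before taking the ratio removes that
bias. Scenario sweeps over plausible ranges of bias parameters (numbers of
missed and false matches, and the proportion of false matches occurring
between comparable records, which cause no misclassification) give
best/worst-case envelopes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .error_estimation import Proportion, exact_proportion
from .records_io import ConfigError

logger = logging.getLogger("linkqa")

_Z = 1.959963984540054  # two-sided 95% normal quantile


class CorrectionError(ValueError):
    """Se + Sp <= 1: the classifier is uninformative and cannot be inverted."""


@dataclass
class ClassificationAccuracy:
    """Sensitivity/specificity of a link-derived classification.

    Derived from positive controls (known true positives: should link) and
    negative controls (known true negatives: should not link). PPV and NPV
    are deliberately NOT computed: control subsets are not representative
    samples, so the table's rows cannot be summed.
    """

    se: Proportion
    sp: Proportion
    by_subgroup: dict[str, "ClassificationAccuracy"] = field(default_factory=dict)

    @property
    def se_value(self) -> float:
        if not self.se.defined:
            raise CorrectionError("sensitivity undefined (empty positive controls)")
        return self.se.value

    @property
    def sp_value(self) -> float:
        if not self.sp.defined:
            raise CorrectionError("specificity undefined (empty negative controls)")
        return self.sp.value

    @classmethod
    def exact(cls, se: float, sp: float) -> "ClassificationAccuracy":
        """Known (assumed) Se/Sp with no sampling uncertainty."""
        return cls(se=Proportion(0, 0, se, se, se),
                   sp=Proportion(0, 0, sp, sp, sp))


def accuracy_from_controls(
    pos_linked: int, pos_unlinked: int, neg_linked: int, neg_unlinked: int
) -> ClassificationAccuracy:
    """Classification Se/Sp from control-subset link counts.

    Se = pos_linked / (pos_linked + pos_unlinked);
    Sp = neg_unlinked / (neg_unlinked + neg_linked).
    An empty control group leaves the corresponding metric undefined.
    """
    if min(pos_linked, pos_unlinked, neg_linked, neg_unlinked) < 0:
        raise ValueError("control counts must be non-negative")
    return ClassificationAccuracy(
        se=exact_proportion(pos_linked, pos_linked + pos_unlinked),
        sp=exact_proportion(neg_unlinked, neg_unlinked + neg_linked),
    )


def misclassify_proportion(p_true: float, se: float, sp: float) -> float:
    """Forward model: the proportion observed when truth is misclassified."""
    return se * p_true + (1 - sp) * (1 - p_true)


@dataclass
class AdjustedProportion:
    """A Rogan-Gladen-corrected proportion with a delta-method interval."""

    value: float
    se_value: float | None
    lo: float | None
    hi: float | None
    truncated: bool
    p_obs: float


def _check_invertible(se: float, sp: float) -> None:
    if se + sp <= 1:
        raise CorrectionError(
            f"se + sp = {se + sp:.3f} <= 1: uninformative classifier"
        )


def adjust_proportion(
    p_obs: float,
    acc: ClassificationAccuracy,
    n_obs: int | None = None,
) -> AdjustedProportion:
    """Invert the misclassification model for one observed proportion.

    The interval propagates the binomial uncertainty of (p_obs, Se, Sp),
    treated as independent, by the delta method; components whose counts
    are unknown (``n_obs`` None, or accuracy declared exact) contribute no
    variance. Corrections landing outside [0,1] are truncated and flagged
    rather than silently clipped.
    """
    se, sp = acc.se_value, acc.sp_value
    _check_invertible(se, sp)
    denom = se + sp - 1
    raw = (p_obs + sp - 1) / denom
    truncated = not 0 <= raw <= 1
    value = float(np.clip(raw, 0.0, 1.0))

    var = 0.0
    if n_obs:
        var += p_obs * (1 - p_obs) / n_obs / denom**2
    if acc.se.denom:
        var += (raw / denom) ** 2 * se * (1 - se) / acc.se.denom
    if acc.sp.denom:
        var += ((1 - raw) / denom) ** 2 * sp * (1 - sp) / acc.sp.denom
    sd = float(np.sqrt(var)) if var > 0 else None
    lo = hi = None
    if sd is not None:
        lo = float(np.clip(raw - _Z * sd, 0.0, 1.0))
        hi = float(np.clip(raw + _Z * sd, 0.0, 1.0))
    return AdjustedProportion(value=value, se_value=sd, lo=lo, hi=hi,
                              truncated=truncated, p_obs=p_obs)


@dataclass
class AdjustedRiskRatio:
    observed_rr: float | None
    corrected_rr: float | None
    lo: float | None
    hi: float | None
    p1: AdjustedProportion
    p0: AdjustedProportion


def adjust_risk_ratio(
    p1_obs: float,
    p0_obs: float,
    acc1: ClassificationAccuracy,
    acc0: ClassificationAccuracy | None = None,
    n1: int | None = None,
    n0: int | None = None,
) -> AdjustedRiskRatio:
    """Correct a risk ratio group by group.

    ``acc0`` defaults to ``acc1`` (shared, nondifferential accuracy);
    subgroup-specific accuracies may be passed instead and generally give a
    different correction. A corrected reference proportion of zero leaves
    the RR undefined (reported as None, never an exception).
    """
    acc0 = acc0 or acc1
    a1 = adjust_proportion(p1_obs, acc1, n1)
    a0 = adjust_proportion(p0_obs, acc0, n0)
    observed = p1_obs / p0_obs if p0_obs > 0 else None
    if a0.value <= 0 or a1.value < 0:
        logger.warning("corrected reference proportion is zero; RR undefined")
        return AdjustedRiskRatio(observed, None, None, None, a1, a0)
    rr = a1.value / a0.value
    lo = hi = None
    if a1.se_value is not None and a0.se_value is not None and a1.value > 0:
        var_log = (a1.se_value / a1.value) ** 2 + (a0.se_value / a0.value) ** 2
        lo = float(rr * np.exp(-_Z * np.sqrt(var_log)))
        hi = float(rr * np.exp(_Z * np.sqrt(var_log)))
    return AdjustedRiskRatio(observed, float(rr), lo, hi, a1, a0)


# ---------------------------------------------------------------------------
# Scenario sweeps over bias-parameter grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasParameters:
    """Plausible values for the linkage-error bias parameters.

    ``n_missed``: candidate numbers of missed matches (records classified
    negative that are truly positive). ``n_false``: candidate numbers of
    false matches among the positives. ``p_false_comparable``: proportions
    of false matches occurring between records that happen to share the
    analysis-variable value — such false matches cause no misclassification.
    """

    n_missed: Sequence[int] = (0,)
    n_false: Sequence[int] = (0,)
    p_false_comparable: Sequence[float] = (0.0,)

    def validate(self) -> None:
        if any(v < 0 for v in self.n_missed) or any(v < 0 for v in self.n_false):
            raise ConfigError("bias-parameter counts must be non-negative")
        if any(not 0 <= p <= 1 for p in self.p_false_comparable):
            raise ConfigError("p_false_comparable must be in [0,1]")


@dataclass(frozen=True)
class GroupCounts:
    """One analysis group: total records and the number classified positive."""

    n: int
    positives: int

    def __post_init__(self) -> None:
        if not 0 <= self.positives <= self.n:
            raise ConfigError("positives must lie in [0, n]")


@dataclass
class SweepResult:
    """Grid of scenario results plus the overall best/worst-case envelope."""

    table: pd.DataFrame
    envelope: tuple[float, float]
    baseline: float


def _estimand(groups: Sequence[tuple[float, int]], kind: str) -> float | None:
    """groups: (corrected positive count, n) per group."""
    props = [x / n for x, n in groups]
    if kind == "proportion":
        return props[0]
    if props[1] <= 0:
        return None
    return props[0] / props[1]


def scenario_sweep(
    groups: Sequence[GroupCounts],
    params: BiasParameters,
    estimand: str = "proportion",
) -> SweepResult:
    """Recompute an estimand over a grid of bias-parameter scenarios.

    At each grid point, ``n_missed`` truly-positive records are added back
    to the positive counts and ``n_false * (1 - p_false_comparable)``
    misclassifying false matches are removed, allocated between the groups
    at every corner allocation (the estimand is monotone in each group's
    corrected count, so corners attain the extremes — equivalent to
    exhaustive reallocation). Grid points implying negative or impossible
    cell counts are skipped with a warning. Works on aggregate tables; the
    envelope is the min/max over all retained scenarios.
    """
    params.validate()
    if estimand not in {"proportion", "rr"}:
        raise ConfigError(f"unknown estimand {estimand!r}")
    if estimand == "proportion" and len(groups) != 1:
        raise ConfigError("proportion estimand needs exactly one group")
    if estimand == "rr" and len(groups) != 2:
        raise ConfigError("rr estimand needs exactly two groups")

    baseline = _estimand([(g.positives, g.n) for g in groups], estimand)
    rows = []
    for nm, nf, pfc in itertools.product(
        params.n_missed, params.n_false, params.p_false_comparable
    ):
        removable = nf * (1 - pfc)  # false matches that actually misclassify
        values = []
        # corner allocations of missed/false errors between groups
        if len(groups) == 1:
            allocations = [((nm, removable),)]
        else:
            allocations = [
                ((m1, f1), (nm - m1, removable - f1))
                for m1 in (0, nm)
                for f1 in (0, removable)
            ]
        for alloc in allocations:
            corrected = []
            ok = True
            for g, (add, sub) in zip(groups, alloc):
                x = g.positives + add - sub
                if x < 0 or x > g.n:
                    ok = False
                    break
                corrected.append((x, g.n))
            if not ok:
                continue
            v = _estimand(corrected, estimand)
            if v is not None:
                values.append(v)
        if not values:
            logger.warning(
                "scenario (n_missed=%s, n_false=%s, p_fc=%s) implies impossible "
                "cell counts; skipped", nm, nf, pfc,
            )
            continue
        rows.append({
            "n_missed": nm, "n_false": nf, "p_false_comparable": pfc,
            "estimand_min": min(values), "estimand_max": max(values),
        })
    table = pd.DataFrame(rows)
    if len(table):
        env = (float(table["estimand_min"].min()), float(table["estimand_max"].max()))
    else:
        env = (baseline, baseline)
    return SweepResult(table=table, envelope=env, baseline=baseline)
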