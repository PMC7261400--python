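"""Estimating rates and distributions of linkage error.

Implements the audit toolbox used when some ground truth, control subset or
attribute data is available: gold-standard confusion matrices and the four
accuracy metrics with exact binomial intervals, negative-control false-match
rates, implausibility triage (a *minimum* false-match count), linked versus
unlinked comparisons (missed-match estimation under Master/Nested
structures), identifier-quality profiling, and a descriptive comparison of
linked-sample marginals against user-supplied reference marginals.

The pair-level accounting follows the standard 2x2 of assigned link status
against true match status: a = true matches linked, b = false matches,
c = missed matches, d = true non-matches; sensitivity = a/(a+c),
specificity = d/(b+d), PPV = a/(a+b), NPV = d/(c+d).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .linkage_engine import LinkResult, RuleCascade
from .records_io import ConfigError, LinkageStructure, RecordFile
from .synthetic_data import TruthMap, _nhs_check_digit

logger = logging.getLogger("linkqa")


class TruthCoverageError(ValueError):
    """Truth labels do not cover the evaluated pair universe."""


# ---------------------------------------------------------------------------
# Confusion matrix and accuracy metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairUniverse:
    """The set of pairs over which linkage decisions are evaluated.

    Defaults to the full cross product of the (small, gold-standard) key
    sets rather than the blocked candidate set, so that missed matches
    excluded by blocking remain visible. An explicit pair list may be given
    instead.
    """

    left_keys: tuple[str, ...] = ()
    right_keys: tuple[str, ...] = ()
    explicit_pairs: frozenset[tuple[str, str]] | None = None

    @property
    def size(self) -> int:
        if self.explicit_pairs is not None:
            return len(self.explicit_pairs)
        return len(self.left_keys) * len(self.right_keys)

    def contains(self, left_key: str, right_key: str) -> bool:
        if self.explicit_pairs is not None:
            return (left_key, right_key) in self.explicit_pairs
        return left_key in set(self.left_keys) and right_key in set(self.right_keys)


@dataclass
class ConfusionMatrix:
    """Counts of true matches (a), false matches (b), missed matches (c)
    and true non-matches (d) over a declared pair universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def confusion_matrix(
    decisions: LinkResult | pd.DataFrame,
    truth: TruthMap,
    universe: PairUniverse,
) -> ConfusionMatrix:
    """Count linkage decisions against truth over the declared universe.

    Pairs of the universe absent from ``decisions`` are counted as
    non-links (blocking or cascade simply never proposed them). Raises
    :class:`TruthCoverageError` if any universe key lacks a truth label —
    partial truth is never silently ignored.
    """
    pairs = decisions.pairs if isinstance(decisions, LinkResult) else decisions
    links = pairs[pairs["status"] == "link"]
    linked = set(zip(links["left_key"].astype(str), links["right_key"].astype(str)))

    if universe.explicit_pairs is not None:
        left_keys = {p[0] for p in universe.explicit_pairs}
        right_keys = {p[1] for p in universe.explicit_pairs}
    else:
        left_keys, right_keys = set(universe.left_keys), set(universe.right_keys)
    for keys, side in ((left_keys, truth.left), (right_keys, truth.right)):
        uncovered = {k for k in keys if side.get(k) is None}
        if uncovered:
            raise TruthCoverageError(
                f"truth missing for {len(uncovered)} universe keys, "
                f"e.g. {sorted(uncovered)[:3]}"
            )

    if universe.explicit_pairs is not None:
        def _contains(p: tuple[str, str]) -> bool:
            return p in universe.explicit_pairs
    else:
        def _contains(p: tuple[str, str]) -> bool:
            return p[0] in left_keys and p[1] in right_keys
    true_pairs = {p for p in truth.true_pairs() if _contains(p)}
    linked_in = {p for p in linked if _contains(p)}
    a = len(linked_in & true_pairs)
    b = len(linked_in - true_pairs)
    c = len(true_pairs - linked_in)
    d = universe.size - a - b - c
    return ConfusionMatrix(a=a, b=b, c=c, d=d)


@dataclass(frozen=True)
class Proportion:
    """A proportion with an exact (Clopper-Pearson) 95% interval.

    ``defined`` is False when the denominator is zero; the value is then
    None, never a silent NaN.
    """

    numer: int
    denom: int
    value: float | None
    lo: float | None
    hi: float | None

    @property
    def defined(self) -> bool:
        return self.value is not None


def exact_proportion(numer: int, denom: int, alpha: float = 0.05) -> Proportion:
    if denom == 0:
        return Proportion(numer, denom, None, None, None)
    lo, hi = proportion_confint(numer, denom, alpha=alpha, method="beta")
    return Proportion(numer, denom, numer / denom, float(lo), float(hi))


@dataclass
class AccuracyMetrics:
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion


def accuracy_metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> AccuracyMetrics:
    """Sensitivity, specificity, PPV and NPV with exact binomial intervals."""
    return AccuracyMetrics(
        sensitivity=exact_proportion(cm.a, cm.a + cm.c, alpha),
        specificity=exact_proportion(cm.d, cm.b + cm.d, alpha),
        ppv=exact_proportion(cm.a, cm.a + cm.b, alpha),
        npv=exact_proportion(cm.d, cm.c + cm.d, alpha),
    )


# ---------------------------------------------------------------------------
# Negative controls
# ---------------------------------------------------------------------------

def negative_control_rate(
    decisions: LinkResult | pd.DataFrame,
    negative_control_keys: Iterable[str],
    alpha: float = 0.05,
) -> Proportion:
    """False-match rate among records known to have no true match.

    rate = linked negatives / total negatives, with an exact binomial
    interval (one-sided in effect when the count is zero). An empty control
    set yields an undefined proportion with a warning.
    """
    keys = [str(k) for k in negative_control_keys]
    if not keys:
        logger.warning("empty negative-control set; rate undefined")
        return Proportion(0, 0, None, None, None)
    pairs = decisions.pairs if isinstance(decisions, LinkResult) else decisions
    links = pairs[pairs["status"] == "link"]
    linked_lefts = set(links["left_key"].astype(str))
    n_linked = sum(k in linked_lefts for k in keys)
    return exact_proportion(n_linked, len(keys), alpha)


# ---------------------------------------------------------------------------
# Implausibility triage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlausibilityRule:
    """A named predicate over the linked pair table.

    ``predicate`` receives the linked DataFrame (cohort attributes joined
    with linked-record attributes) and returns a boolean mask of flagged
    rows; it must reference only available columns. Classic examples: an
    event dated after the linked death date, or a male patient linked to a
    female-only procedure code.
    """

    name: str
    predicate: Callable[[pd.DataFrame], pd.Series]
    required_columns: tuple[str, ...] = ()


def rule_event_after_death(event_date_col: str, death_date_col: str) -> PlausibilityRule:
    def pred(df: pd.DataFrame) -> pd.Series:
        ev = pd.to_datetime(df[event_date_col], errors="coerce")
        dd = pd.to_datetime(df[death_date_col], errors="coerce")
        return ev > dd
    return PlausibilityRule(
        name=f"{event_date_col}_after_{death_date_col}",
        predicate=pred,
        required_columns=(event_date_col, death_date_col),
    )


def rule_sex_specific(sex_col: str, code_col: str, codes: Iterable[str],
                      required_sex: str) -> PlausibilityRule:
    codeset = {str(c) for c in codes}
    def pred(df: pd.DataFrame) -> pd.Series:
        return df[code_col].astype(str).isin(codeset) & (df[sex_col] != required_sex)
    return PlausibilityRule(
        name=f"{code_col}_requires_sex_{required_sex}",
        predicate=pred,
        required_columns=(sex_col, code_col),
    )


@dataclass
class ImplausibilityReport:
    """Flagged pairs and the implied *minimum* number of false matches.

    The count is a lower bound: more false matches might be present but
    unidentified. Under a 1:1 or many:1 structure, each accepted link beyond
    the first for a record implies at least one false match (pigeonhole),
    and those excess links are included in the bound.
    """

    flagged: pd.DataFrame
    minimum_false_matches: int
    by_rule: dict[str, int] = field(default_factory=dict)


def flag_implausible(
    linked: pd.DataFrame,
    rules: Sequence[PlausibilityRule] = (),
    mode: str = "one_to_one",
    left_key_col: str = "left_key",
) -> ImplausibilityReport:
    """Apply plausibility rules and multiplicity accounting to accepted links.

    ``linked`` is the accepted-link table (one row per linked pair) joined
    with whatever attribute columns the rules need. Raises
    :class:`ConfigError` if a rule references a missing column.
    """
    flags = pd.DataFrame(index=linked.index)
    by_rule: dict[str, int] = {}
    for rule in rules:
        missing = set(rule.required_columns) - set(linked.columns)
        if missing:
            raise ConfigError(f"rule {rule.name!r} needs missing columns {sorted(missing)}")
        mask = rule.predicate(linked).fillna(False).astype(bool)
        flags[rule.name] = mask
        by_rule[rule.name] = int(mask.sum())

    excess = pd.Series(False, index=linked.index)
    if mode in {"one_to_one", "many_to_one"} and left_key_col in linked.columns:
        # all links beyond the first per record are excess under 1:1 / many:1
        excess = linked.groupby(left_key_col).cumcount() > 0
        by_rule["excess_multiplicity"] = int(excess.sum())
    any_flag = flags.any(axis=1) if len(flags.columns) else pd.Series(False, index=linked.index)
    union = any_flag | excess
    flagged = linked[union].copy()
    if len(flags.columns):
        flagged = flagged.join(flags[union])
    return ImplausibilityReport(
        flagged=flagged,
        minimum_false_matches=int(union.sum()),
        by_rule=by_rule,
    )


# ---------------------------------------------------------------------------
# Linked vs unlinked comparison
# ---------------------------------------------------------------------------

@dataclass
class LinkedUnlinkedReport:
    """Covariate comparison of linked vs unlinked cohort records.

    ``estimated_missed_matches`` is the unlinked count when the declared
    structure expects every cohort record to link (Master/Nested); it is
    suppressed (None) under an Intersection structure, where failure to
    link is not interpretable as a missed match.
    """

    table: pd.DataFrame
    n_linked: int
    n_unlinked: int
    estimated_missed_matches: int | None


def _standardized_difference(x1: pd.Series, x0: pd.Series) -> float:
    """Difference in means over pooled SD (pooled proportion variance for
    binary indicators); 0 when both groups are constant and equal."""
    m1, m0 = x1.mean(), x0.mean()
    v1 = x1.var(ddof=1) if len(x1) > 1 else 0.0
    v0 = x0.var(ddof=1) if len(x0) > 1 else 0.0
    pooled = np.sqrt((v1 + v0) / 2)
    if pooled == 0:
        return 0.0 if m1 == m0 else np.inf
    return float((m1 - m0) / pooled)


def compare_linked_unlinked(
    cohort: pd.DataFrame,
    link_indicator: pd.Series,
    covariates: Sequence[str],
    structure: LinkageStructure | None = None,
) -> LinkedUnlinkedReport:
    """Compare covariate distributions between linked and unlinked records.

    Numeric covariates are summarized by group means; categorical ones are
    expanded to per-level indicators. Absolute standardized differences
    above 0.1 are conventionally annotated as imbalanced (descriptive
    only).
    """
    missing = set(covariates) - set(cohort.columns)
    if missing:
        raise ConfigError(f"covariates absent from cohort: {sorted(missing)}")
    ind = link_indicator.reindex(cohort.index).astype(bool)
    linked, unlinked = cohort[ind], cohort[~ind]
    rows = []
    for cov in covariates:
        col = cohort[cov]
        if pd.api.types.is_numeric_dtype(col):
            sd = _standardized_difference(linked[cov].astype(float),
                                          unlinked[cov].astype(float))
            rows.append({
                "covariate": cov, "level": "",
                "linked_mean": float(linked[cov].mean()) if len(linked) else np.nan,
                "unlinked_mean": float(unlinked[cov].mean()) if len(unlinked) else np.nan,
                "std_diff": sd, "imbalanced": abs(sd) > 0.1,
            })
        else:
            for level in sorted(col.dropna().astype(str).unique()):
                i1 = (linked[cov].astype(str) == level).astype(float)
                i0 = (unlinked[cov].astype(str) == level).astype(float)
                sd = _standardized_difference(i1, i0)
                rows.append({
                    "covariate": cov, "level": level,
                    "linked_mean": float(i1.mean()) if len(i1) else np.nan,
                    "unlinked_mean": float(i0.mean()) if len(i0) else np.nan,
                    "std_diff": sd, "imbalanced": abs(sd) > 0.1,
                })
    est_missed = None
    if structure is not None and structure.expects_all_linked:
        est_missed = int((~ind).sum())
    return LinkedUnlinkedReport(
        table=pd.DataFrame(rows),
        n_linked=int(ind.sum()),
        n_unlinked=int((~ind).sum()),
        estimated_missed_matches=est_missed,
    )


# ---------------------------------------------------------------------------
# Identifier quality profiling
# ---------------------------------------------------------------------------

def nhs_number_valid(value: str | None) -> bool:
    """Modulus-11 check for a 10-digit NHS number."""
    if value is None or not re.fullmatch(r"\d{10}", str(value)):
        return False
    digits = [int(c) for c in str(value)]
    return _nhs_check_digit(digits[:9]) == digits[9]


def regex_validator(pattern: str) -> Callable[[str | None], bool]:
    rx = re.compile(pattern)
    return lambda v: v is not None and bool(rx.fullmatch(str(v)))


def iso_date_valid(value: str | None) -> bool:
    if value is None:
        return False
    try:
        pd.Timestamp(str(value))
        return True
    except (ValueError, TypeError):
        return False


@dataclass
class QualityProfile:
    """Per-identifier missing/invalid proportions, overall and by subgroup.

    ``minimum_unlinkable`` counts records that cannot satisfy any cascade
    step because every step references at least one missing-or-invalid
    field — a floor on the number of missed matches.
    """

    overall: pd.DataFrame
    by_group: pd.DataFrame | None
    minimum_unlinkable: int
    unlinkable_keys: list[str] = field(default_factory=list)


def identifier_quality_profile(
    records: RecordFile,
    covariates: Sequence[str] = (),
    validators: Mapping[str, Callable[[str | None], bool]] | None = None,
    cascade: RuleCascade | None = None,
) -> QualityProfile:
    """Profile identifier missingness and validity.

    ``validators`` maps identifier columns to predicates returning True for
    a valid non-missing value (e.g. :func:`nhs_number_valid`); identifiers
    without a validator are only checked for missingness.
    """
    validators = dict(validators or {})
    idents = records.identifier_columns
    usable = pd.DataFrame(index=records.df.index)
    rows = []
    for ident in idents:
        col = records.df[ident]
        missing = col.isna()
        if ident in validators:
            invalid = ~missing & ~col.map(lambda v: validators[ident](v)).astype(bool)
        else:
            invalid = pd.Series(False, index=col.index)
        usable[ident] = ~(missing | invalid)
        rows.append({
            "identifier": ident,
            "n": len(col),
            "missing_prop": float(missing.mean()),
            "invalid_prop": float(invalid.mean()),
        })
    overall = pd.DataFrame(rows)

    by_group = None
    if covariates:
        grows = []
        for cov in covariates:
            if cov not in records.df.columns:
                raise ConfigError(f"covariate {cov!r} absent from file")
            for level, sub in records.df.groupby(records.df[cov].astype(str)):
                for ident in idents:
                    col = sub[ident]
                    grows.append({
                        "covariate": cov, "level": level, "identifier": ident,
                        "n": len(col),
                        "missing_prop": float(col.isna().mean()),
                    })
        by_group = pd.DataFrame(grows)

    unlinkable_keys: list[str] = []
    if cascade is not None:
        sat = np.zeros(len(records.df), dtype=bool)
        for step in cascade.steps:
            step_ok = np.ones(len(records.df), dtype=bool)
            for ident in step:
                if ident not in usable.columns:
                    raise ConfigError(f"cascade identifier {ident!r} not an identifier column")
                step_ok &= usable[ident].to_numpy()
            sat |= step_ok
        unlinkable_keys = records.df.index[~sat].tolist()
    return QualityProfile(
        overall=overall,
        by_group=by_group,
        minimum_unlinkable=len(unlinkable_keys),
        unlinkable_keys=unlinkable_keys,
    )


# ---------------------------------------------------------------------------
# Marginals report (descriptive comparison with user-supplied reference)
# ---------------------------------------------------------------------------

@dataclass
class MarginalsReport:
    """Observed vs reference category proportions; descriptive only."""

    table: pd.DataFrame
    chi_square: float
    largest_contributor: str


def marginals_report(
    observed: pd.Series,
    reference: Mapping[str, float],
) -> MarginalsReport:
    """Compare a linked sample's marginal distribution with reference marginals.

    ``reference`` maps category to proportion (summing to ~1), supplied by
    the user from representative external data; nothing is downloaded.
    Observed categories absent from the reference raise an error listing
    the unmatched categories.
    """
    obs_counts = observed.astype(str).value_counts()
    unmatched = sorted(set(obs_counts.index) - set(map(str, reference)))
    if unmatched:
        raise ConfigError(f"observed categories not in reference: {unmatched}")
    n = int(obs_counts.sum())
    rows = []
    for cat, p_ref in reference.items():
        o = int(obs_counts.get(str(cat), 0))
        p_obs = o / n if n else 0.0
        expected = n * p_ref
        contrib = (o - expected) ** 2 / expected if expected > 0 else 0.0
        rows.append({
            "category": str(cat), "observed_n": o, "observed_prop": p_obs,
            "reference_prop": float(p_ref), "chi_square_contribution": float(contrib),
        })
    table = pd.DataFrame(rows)
    chi2 = float(table["chi_square_contribution"].sum())
    largest = table.loc[table["chi_square_contribution"].idxmax(), "category"] if len(table) else ""
    return MarginalsReport(table=table, chi_square=chi2, largest_contributor=str(largest))
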