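"""Pair comparison, deterministic cascades and Fellegi-Sunter match weights.

The probabilistic model is the classic two-class latent mixture: for each
identifier j, ``m_j`` is the probability the identifier agrees given the two
records belong to the same person, ``u_j`` the probability it agrees given
they do not. Under conditional independence the match weight of a pair is
the base-2 log likelihood ratio

    w = sum_j [ agree_j * log2(m_j/u_j) + disagree_j * log2((1-m_j)/(1-u_j)) ]

with missing comparisons contributing zero (the neutral choice). m and u can
be estimated without training data by the EM algorithm on the observed
agreement patterns. Weights are thresholded into link / possible / non-link,
and a greedy one-to-one assignment resolves multiple matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records_io import ConfigError, Record, RecordFile

logger = logging.getLogger("linkqa")

AGREE, DISAGREE, MISSING = 1, 0, -1
_LEVEL_CHARS = {AGREE: "A", DISAGREE: "D", MISSING: "?"}

_CLAMP = 1e-6


class ModelError(ValueError):
    """A comparison model that would produce inverted weights (m <= u)."""


# ---------------------------------------------------------------------------
# String similarity (standard Jaro-Winkler definition)
# ---------------------------------------------------------------------------

def jaro(s1: str, s2: str) -> float:
    """Jaro similarity: mean of match fractions and transposition term."""
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(len1, len2) // 2 - 1
    match2 = [False] * len2
    matches1: list[str] = []
    idx2: list[int] = []
    for i, c in enumerate(s1):
        lo, hi = max(0, i - window), min(len2, i + window + 1)
        for j in range(lo, hi):
            if not match2[j] and s2[j] == c:
                match2[j] = True
                matches1.append(c)
                idx2.append(j)
                break
    m = len(matches1)
    if m == 0:
        return 0.0
    matches2 = [s2[j] for j in sorted(idx2)]
    t = sum(a != b for a, b in zip(matches1, matches2)) / 2
    return (m / len1 + m / len2 + (m - t) / m) / 3


def jaro_winkler(s1: str, s2: str, prefix_scale: float = 0.1) -> float:
    """Jaro similarity boosted by shared prefix (max 4 chars, scale 0.1)."""
    j = jaro(s1, s2)
    prefix = 0
    for a, b in zip(s1[:4], s2[:4]):
        if a != b:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1 - j)


# ---------------------------------------------------------------------------
# Comparators and comparison vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Comparator:
    """How one identifier is compared.

    ``exact``: agree iff normalized equality. ``jaro_winkler``: similarity
    is computed and binarized at ``cutoff`` (graded agreement weights are
    out of scope). Either side missing always yields a missing level.
    """

    name: str = "exact"
    cutoff: float = 0.88

    def __post_init__(self) -> None:
        if self.name not in {"exact", "jaro_winkler"}:
            raise ConfigError(f"unknown comparator {self.name!r}")
        if not 0 <= self.cutoff <= 1:
            raise ConfigError("comparator cutoff must be in [0,1]")

    def compare(self, a: str | None, b: str | None) -> tuple[int, float | None]:
        """Return (level, similarity-or-None)."""
        if a is None or b is None:
            return MISSING, None
        if self.name == "exact":
            return (AGREE if a == b else DISAGREE), None
        sim = jaro_winkler(a, b)
        return (AGREE if sim >= self.cutoff else DISAGREE), sim


def comparators_from_config(spec: Mapping[str, Mapping[str, Any]]) -> dict[str, Comparator]:
    out = {}
    for ident, c in spec.items():
        out[ident] = Comparator(
            name=c.get("name", "exact"), cutoff=float(c.get("cutoff", 0.88))
        )
    return out


@dataclass
class ComparisonVector:
    """Per-pair agreement pattern over the configured identifiers."""

    pair: tuple[str, str]
    levels: dict[str, int]
    similarity: dict[str, float | None] = field(default_factory=dict)

    @property
    def pattern(self) -> str:
        return "".join(_LEVEL_CHARS[v] for v in self.levels.values())


def compare_pair(
    left: Record, right: Record, comparators: Mapping[str, Comparator]
) -> ComparisonVector:
    """Compare one pair of records on each configured identifier."""
    levels: dict[str, int] = {}
    sims: dict[str, float | None] = {}
    for ident, comp in comparators.items():
        if ident not in left.identifiers or ident not in right.identifiers:
            raise ConfigError(f"identifier {ident!r} absent from record schema")
        lvl, sim = comp.compare(left.identifiers[ident], right.identifiers[ident])
        levels[ident] = lvl
        sims[ident] = sim
    return ComparisonVector(pair=(left.row_key, right.row_key), levels=levels,
                            similarity=sims)


def compare_candidates(
    left: RecordFile,
    right: RecordFile,
    pairs: pd.DataFrame,
    comparators: Mapping[str, Comparator],
) -> pd.DataFrame:
    """Vectorized comparison of a candidate-pair table.

    Returns a DataFrame with columns left_key, right_key and one int8 level
    column per identifier (1 agree / 0 disagree / -1 missing).
    """
    lk = pairs["left_key"].to_numpy(str)
    rk = pairs["right_key"].to_numpy(str)
    out = {"left_key": lk, "right_key": rk}
    for ident, comp in comparators.items():
        if ident not in left.df.columns or ident not in right.df.columns:
            raise ConfigError(f"identifier {ident!r} absent from a file schema")
        av = left.df[ident].reindex(lk).to_numpy(object)
        bv = right.df[ident].reindex(rk).to_numpy(object)
        miss = pd.isna(av) | pd.isna(bv)
        if comp.name == "exact":
            agree = (av == bv) & ~miss
        else:
            agree = np.zeros(len(av), bool)
            cut = comp.cutoff
            for i in np.flatnonzero(~miss):
                agree[i] = jaro_winkler(av[i], bv[i]) >= cut
        lvl = np.where(miss, MISSING, np.where(agree, AGREE, DISAGREE))
        out[ident] = lvl.astype(np.int8)
    return pd.DataFrame(out)


def pattern_strings(vectors: pd.DataFrame, identifiers: Sequence[str]) -> pd.Series:
    """Agreement-pattern string per pair, e.g. 'A?D'."""
    chars = None
    for ident in identifiers:
        s = vectors[ident].map(_LEVEL_CHARS)
        chars = s if chars is None else chars + s
    return chars.rename("pattern")


# ---------------------------------------------------------------------------
# Blocking
# ---------------------------------------------------------------------------

def block_pairs(
    left: RecordFile, right: RecordFile, blocking_keys: Sequence[str]
) -> pd.DataFrame:
    """Candidate pairs agreeing on at least one blocking key, deduplicated.

    Records missing a blocking key cannot agree on it and are excluded from
    that key's block. With no keys the full cross product is returned, with
    a logged warning.
    """
    if not blocking_keys:
        logger.warning("no blocking keys: full cross product of %d x %d records",
                       len(left), len(right))
        return pd.DataFrame(
            [(l, r) for l in left.df.index for r in right.df.index],
            columns=["left_key", "right_key"],
        )
    chunks = []
    for key in blocking_keys:
        if key not in left.df.columns or key not in right.df.columns:
            raise ConfigError(f"blocking key {key!r} absent from a file")
        lf = left.df[[key]].dropna().reset_index()
        rf = right.df[[key]].dropna().reset_index()
        merged = lf.merge(rf, on=key, suffixes=("_l", "_r"))
        chunks.append(merged[["row_key_l", "row_key_r"]])
    pairs = pd.concat(chunks, ignore_index=True).drop_duplicates()
    pairs.columns = ["left_key", "right_key"]
    return pairs.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Deterministic rule cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleCascade:
    """Ordered steps; each step names the identifiers that must all agree.

    A pair is linked at the first satisfied step; the step index (1-based,
    1 = most stringent) is recorded as the match rank, mirroring stepwise
    algorithms such as the three-step NHS number / date of birth / postcode
    / sex procedure used for hospital data.
    """

    steps: tuple[tuple[str, ...], ...]

    @classmethod
    def from_lists(cls, steps: Iterable[Iterable[str]]) -> "RuleCascade":
        return cls(tuple(tuple(s) for s in steps))


def run_cascade(vectors: pd.DataFrame, cascade: RuleCascade) -> pd.DataFrame:
    """Assign each candidate pair its match rank under the cascade.

    Returns the vectors with a ``rank`` column (1-based step index; 0 for
    pairs satisfying no step, i.e. unlinked).
    """
    rank = np.zeros(len(vectors), dtype=int)
    for i, step in enumerate(cascade.steps, start=1):
        ok = np.ones(len(vectors), dtype=bool)
        for ident in step:
            if ident not in vectors.columns:
                raise ConfigError(f"cascade identifier {ident!r} not compared")
            ok &= vectors[ident].to_numpy() == AGREE
        rank = np.where((rank == 0) & ok, i, rank)
    out = vectors.copy()
    out["rank"] = rank
    return out


# ---------------------------------------------------------------------------
# Fellegi-Sunter model and EM estimation
# ---------------------------------------------------------------------------

@dataclass
class ComparisonModel:
    """Per-identifier m/u probabilities plus prior match odds."""

    m: dict[str, float]
    u: dict[str, float]
    prior_odds: float = 1.0

    def __post_init__(self) -> None:
        if set(self.m) != set(self.u):
            raise ModelError("m and u must cover the same identifiers")
        if self.prior_odds <= 0:
            raise ModelError("prior_odds must be positive")

    def clamped(self) -> "ComparisonModel":
        """Clamp probabilities into (0,1) and enforce u < m per identifier."""
        m, u = {}, {}
        for k in self.m:
            mk = float(np.clip(self.m[k], _CLAMP, 1 - _CLAMP))
            uk = float(np.clip(self.u[k], _CLAMP, 1 - _CLAMP))
            if uk >= mk:
                logger.warning("identifier %r has u >= m (%.4f >= %.4f); clamped",
                               k, uk, mk)
                uk = max(mk - _CLAMP, _CLAMP)
            m[k], u[k] = mk, uk
        return ComparisonModel(m=m, u=u, prior_odds=self.prior_odds)

    def agreement_weight(self, ident: str) -> float:
        return float(np.log2(self.m[ident] / self.u[ident]))

    def disagreement_weight(self, ident: str) -> float:
        return float(np.log2((1 - self.m[ident]) / (1 - self.u[ident])))


@dataclass
class EMDiagnostics:
    iterations: int
    converged: bool
    log_likelihood: list[float]
    excluded_identifiers: list[str] = field(default_factory=list)


def default_init(vectors: pd.DataFrame, identifiers: Sequence[str]) -> ComparisonModel:
    """m = 0.9; u = empirical agreement rate; pi = 10/sqrt(n_pairs)."""
    n = max(len(vectors), 1)
    u = {}
    for ident in identifiers:
        lv = vectors[ident].to_numpy()
        obs = lv != MISSING
        u[ident] = float(lv[obs].mean()) if obs.any() else 0.1
        u[ident] = float(np.clip(u[ident], _CLAMP, 0.85))
    pi = min(10 / np.sqrt(n), 0.5)
    return ComparisonModel(
        m={k: 0.9 for k in identifiers}, u=u, prior_odds=pi / (1 - pi)
    )


def estimate_mu_em(
    vectors: pd.DataFrame,
    identifiers: Sequence[str],
    init: ComparisonModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[ComparisonModel, EMDiagnostics]:
    """EM estimation of m, u and the mixture proportion.

    Two-class latent mixture under conditional independence: the E-step
    computes each pair's match responsibility, the M-step re-estimates
    per-identifier m/u (over non-missing comparisons only) and the mixture
    proportion. Stops when the largest parameter change falls below ``tol``
    or after ``max_iter`` iterations; non-convergence is flagged in the
    diagnostics, not fatal. Identifiers with no observed comparisons are
    excluded with a warning.
    """
    identifiers = list(identifiers)
    excluded = [k for k in identifiers
                if (vectors[k].to_numpy() == MISSING).all()]
    for k in excluded:
        logger.warning("identifier %r has no observed comparisons; excluded", k)
    idents = [k for k in identifiers if k not in excluded]
    if len(idents) < 2:
        raise ConfigError("EM needs at least two identifiers with observed variation")
    if init is None:
        init = default_init(vectors, idents)
    init = init.clamped()

    X = vectors[idents].to_numpy(np.int8)  # (n, k): 1/0/-1
    obs = X != MISSING
    agree = X == AGREE
    n = X.shape[0]

    m = np.array([init.m[k] for k in idents])
    u = np.array([init.u[k] for k in idents])
    pi = init.prior_odds / (1 + init.prior_odds)
    loglik: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space; missing levels contribute no term
        lm = np.where(obs, np.where(agree, np.log(m), np.log1p(-m)), 0.0).sum(axis=1)
        lu = np.where(obs, np.where(agree, np.log(u), np.log1p(-u)), 0.0).sum(axis=1)
        a = np.log(pi) + lm
        b = np.log1p(-pi) + lu
        top = np.maximum(a, b)
        ll = float((top + np.log(np.exp(a - top) + np.exp(b - top))).sum())
        loglik.append(ll)
        r = 1.0 / (1.0 + np.exp(b - a))
        # M-step
        rw = r[:, None] * obs
        sw = (1 - r)[:, None] * obs
        new_m = (r[:, None] * (agree & obs)).sum(axis=0) / np.maximum(rw.sum(axis=0), 1e-300)
        new_u = ((1 - r)[:, None] * (agree & obs)).sum(axis=0) / np.maximum(sw.sum(axis=0), 1e-300)
        new_pi = float(r.mean())
        new_m = np.clip(new_m, _CLAMP, 1 - _CLAMP)
        new_u = np.clip(new_u, _CLAMP, 1 - _CLAMP)
        new_pi = float(np.clip(new_pi, _CLAMP, 1 - _CLAMP))
        delta = max(np.abs(new_m - m).max(), np.abs(new_u - u).max(),
                    abs(new_pi - pi))
        m, u, pi = new_m, new_u, new_pi
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    if m.mean() < u.mean():  # label switching: the match class is the rarer, high-agreement one
        m, u, pi = u, m, 1 - pi
    model = ComparisonModel(
        m=dict(zip(idents, m.tolist())),
        u=dict(zip(idents, u.tolist())),
        prior_odds=pi / (1 - pi),
    ).clamped()
    diag = EMDiagnostics(iterations=it, converged=converged,
                         log_likelihood=loglik, excluded_identifiers=excluded)
    return model, diag


# ---------------------------------------------------------------------------
# Weights, classification, assignment
# ---------------------------------------------------------------------------

@dataclass
class WeightedPair:
    pair: tuple[str, str]
    weight: float
    contributions: dict[str, float]


def match_weight(vector: ComparisonVector, model: ComparisonModel) -> WeightedPair:
    """Base-2 log likelihood ratio for one pair; missing contributes 0."""
    contributions: dict[str, float] = {}
    for ident, lvl in vector.levels.items():
        if ident not in model.m:
            raise ModelError(f"model lacks identifier {ident!r}")
        if model.m[ident] <= model.u[ident]:
            raise ModelError(f"m <= u for identifier {ident!r}")
        if lvl == MISSING:
            contributions[ident] = 0.0
        elif lvl == AGREE:
            contributions[ident] = model.agreement_weight(ident)
        else:
            contributions[ident] = model.disagreement_weight(ident)
    return WeightedPair(pair=vector.pair, weight=sum(contributions.values()),
                        contributions=contributions)


def weigh_pairs(
    vectors: pd.DataFrame, model: ComparisonModel, identifiers: Sequence[str]
) -> pd.DataFrame:
    """Vectorized match weights for a comparison table (adds ``weight``)."""
    w = np.zeros(len(vectors))
    for ident in identifiers:
        if model.m[ident] <= model.u[ident]:
            raise ModelError(f"m <= u for identifier {ident!r}")
        lv = vectors[ident].to_numpy()
        w += np.where(lv == AGREE, model.agreement_weight(ident),
                      np.where(lv == DISAGREE, model.disagreement_weight(ident), 0.0))
    out = vectors.copy()
    out["weight"] = w
    return out


def classify_links(
    weighted: pd.DataFrame, lower: float, upper: float
) -> pd.DataFrame:
    """Threshold weights into link / possible / non-link.

    weight >= upper -> link; weight < lower -> non-link; in between ->
    possible (retained for review or imputation). lower == upper gives a
    binary classification with no possibles.
    """
    if lower > upper:
        raise ConfigError(f"lower threshold {lower} exceeds upper {upper}")
    w = weighted["weight"].to_numpy(float)
    status = np.where(w >= upper, "link",
                      np.where(w < lower, "non-link", "possible"))
    out = weighted.copy()
    out["status"] = status
    return out


def weight_threshold_for_posterior(
    model: ComparisonModel, posterior: float = 0.5
) -> float:
    """Weight at which the posterior match probability equals ``posterior``.

    Posterior odds = prior_odds * 2^weight, so the threshold is
    log2(posterior_odds / prior_odds).
    """
    if not 0 < posterior < 1:
        raise ConfigError("posterior must be in (0,1)")
    return float(np.log2(posterior / (1 - posterior)) - np.log2(model.prior_odds))


@dataclass
class LinkResult:
    """Final classified pairs plus resolution diagnostics.

    ``pairs`` has columns left_key, right_key, weight (or rank), status and
    pattern. ``multiplicity_violations`` counts accepted links beyond the
    declared structure's maximum before resolution — under 1:1 or many:1
    matching each such excess link indicates at least one false match.
    """

    pairs: pd.DataFrame
    mode: str = "many_to_many"
    multiplicity_violations: int = 0

    @property
    def links(self) -> pd.DataFrame:
        return self.pairs[self.pairs["status"] == "link"]


def resolve_assignment(
    classified: pd.DataFrame, mode: str = "one_to_one"
) -> LinkResult:
    """Resolve multiple accepted links per record.

    ``one_to_one``: greedy by descending weight, deterministic tie-break on
    (left_key, right_key) lexicographic order; each record used at most
    once; displaced candidates are demoted to possible. ``many_to_one``:
    each left record keeps its single best link. ``many_to_many``: no
    constraint. Greedy rather than optimal assignment: transparent and
    deterministic; an exhaustive optimum exists only as a test oracle.
    """
    if mode not in {"one_to_one", "many_to_one", "many_to_many"}:
        raise ConfigError(f"unknown assignment mode {mode!r}")
    out = classified.copy()
    links = out[out["status"] == "link"]
    violations = 0
    if mode == "one_to_one":
        violations = int((links.groupby("left_key").size() - 1).clip(lower=0).sum()
                         + (links.groupby("right_key").size() - 1).clip(lower=0).sum())
    elif mode == "many_to_one":
        violations = int((links.groupby("left_key").size() - 1).clip(lower=0).sum())
    if mode != "many_to_many" and len(links):
        order = links.sort_values(
            by=["weight", "left_key", "right_key"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        used_left: set[str] = set()
        used_right: set[str] = set()
        demote: list[Any] = []
        for idx, row in order.iterrows():
            if row["left_key"] in used_left or (
                mode == "one_to_one" and row["right_key"] in used_right
            ):
                demote.append(idx)
            else:
                used_left.add(row["left_key"])
                used_right.add(row["right_key"])
        out.loc[demote, "status"] = "possible"
    return LinkResult(pairs=out, mode=mode, multiplicity_violations=violations)
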