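"""End-to-end linkage convenience: block, compare, estimate, weigh, classify,
resolve. Thin orchestration over linkage_engine used by the CLI, the test
suite and worked examples."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .linkage_engine import (
    Comparator,
    ComparisonModel,
    EMDiagnostics,
    LinkResult,
    block_pairs,
    classify_links,
    compare_candidates,
    estimate_mu_em,
    pattern_strings,
    resolve_assignment,
    weigh_pairs,
    weight_threshold_for_posterior,
)
from .records_io import RecordFile


@dataclass
class LinkageRun:
    result: LinkResult
    model: ComparisonModel
    em_diagnostics: EMDiagnostics | None
    vectors: pd.DataFrame
    thresholds: tuple[float, float]


def link_files(
    left: RecordFile,
    right: RecordFile,
    identifiers: Sequence[str],
    comparators: Mapping[str, Comparator] | None = None,
    blocking_keys: Sequence[str] = (),
    model: ComparisonModel | None = None,
    lower: float | None = None,
    upper: float | None = None,
    mode: str = "one_to_one",
) -> LinkageRun:
    """Probabilistic linkage of two record files.

    With no ``model``, m/u/prior odds are estimated by EM on the candidate
    comparison vectors. With no thresholds, both default to the weight at
    which the posterior match probability is 0.5 under the model (a binary
    classification); pass distinct lower/upper to retain possibles.
    """
    comparators = comparators or {i: Comparator() for i in identifiers}
    pairs = block_pairs(left, right, blocking_keys)
    vectors = compare_candidates(left, right, pairs, comparators)
    diag = None
    if model is None:
        model, diag = estimate_mu_em(vectors, list(identifiers))
    weighted = weigh_pairs(vectors, model, list(identifiers))
    if upper is None:
        upper = weight_threshold_for_posterior(model, 0.5)
    if lower is None:
        lower = upper
    classified = classify_links(weighted, lower, upper)
    classified["pattern"] = pattern_strings(classified, list(identifiers))
    result = resolve_assignment(classified, mode=mode)
    return LinkageRun(result=result, model=model, em_diagnostics=diag,
                      vectors=vectors, thresholds=(lower, upper))
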