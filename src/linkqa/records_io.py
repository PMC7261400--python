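"""Reading, writing and validating record files, pair outputs and run configuration.

Record files are CSVs with a header row, one row per person-record. A schema
maps column names to field kinds:

``identifier``
    used for linkage; normalized on load (case-folded, trimmed, internal
    whitespace collapsed). Date identifiers (kind ``identifier:date``) are
    parsed to ISO-8601 ``YYYY-MM-DD``; unparseable dates become missing with
    a logged warning so that identifier-quality audits remain possible.
``attribute``
    analysis variables, carried through untouched.
``truth_id``
    a ground-truth person identifier (synthetic or gold-standard data only).

Missing values are empty cells or any of the configured sentinels
("", "NA", "NULL" by default) and are stored uniformly as ``None``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("linkqa")

DEFAULT_NA_SENTINELS = ("", "NA", "NULL")

IDENTIFIER = "identifier"
IDENTIFIER_DATE = "identifier:date"
ATTRIBUTE = "attribute"
TRUTH_ID = "truth_id"

_VALID_KINDS = {IDENTIFIER, IDENTIFIER_DATE, ATTRIBUTE, TRUTH_ID}

_WS_RUN = re.compile(r"\s+")


class SchemaError(ValueError):
    """A schema names columns or kinds the file cannot satisfy."""


class IntegrityError(ValueError):
    """Row keys are duplicated or pair output references unknown keys."""


class ConfigError(ValueError):
    """Run configuration is malformed or internally inconsistent."""


def normalize_identifier(value: Any) -> str | None:
    """Case-fold, strip and collapse internal whitespace; missing -> None.

    Idempotent: ``normalize_identifier(normalize_identifier(x)) ==
    normalize_identifier(x)``.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    return _WS_RUN.sub(" ", s).upper()


def normalize_date(value: Any) -> str | None:
    """Parse to ISO-8601 YYYY-MM-DD; unparseable -> missing (logged)."""
    s = normalize_identifier(value)
    if s is None:
        return None
    try:
        ts = pd.Timestamp(s)
    except (ValueError, TypeError):
        logger.warning("unparseable date %r treated as missing", value)
        return None
    return ts.strftime("%Y-%m-%d")


@dataclass
class RecordFile:
    """A set of person records with a shared schema.

    ``df`` is indexed by a string row key, unique within the file. Identifier
    columns hold normalized strings or ``None``; attribute columns are kept
    as loaded.
    """

    file_id: str
    df: pd.DataFrame
    schema: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.schema.values()) - _VALID_KINDS
        if unknown:
            raise SchemaError(f"unknown field kinds: {sorted(unknown)}")
        missing = set(self.schema) - set(self.df.columns)
        if missing:
            raise SchemaError(
                f"schema columns absent from file {self.file_id!r}: {sorted(missing)}"
            )
        if self.df.index.has_duplicates:
            dupes = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate row keys in {self.file_id!r}: {dupes[:5]}")

    @property
    def identifier_columns(self) -> list[str]:
        return [c for c, k in self.schema.items() if k.startswith(IDENTIFIER)]

    @property
    def attribute_columns(self) -> list[str]:
        return [c for c, k in self.schema.items() if k == ATTRIBUTE]

    @property
    def truth_column(self) -> str | None:
        for c, k in self.schema.items():
            if k == TRUTH_ID:
                return c
        return None

    def __len__(self) -> int:
        return len(self.df)

    def record(self, row_key: str) -> "Record":
        row = self.df.loc[row_key]
        return Record(
            row_key=row_key,
            identifiers={c: row[c] for c in self.identifier_columns},
            attributes={c: row[c] for c in self.attribute_columns},
            truth_id=row[self.truth_column] if self.truth_column else None,
        )


@dataclass
class Record:
    row_key: str
    identifiers: dict[str, str | None]
    attributes: dict[str, Any] = field(default_factory=dict)
    truth_id: str | None = None


@dataclass(frozen=True)
class LinkageStructure:
    """Set relationship between two files being linked.

    ``master``: the cohort is the large file, the other file a register
    (e.g. deaths); an unlinked cohort record is interpreted as not having
    the registered condition. ``nested``: every cohort record is expected
    to have a match in the larger file; an unlinked record means missing
    data. ``intersection``: only an unknown subset of the cohort links;
    an unlinked record means exclusion from the analysis sample.
    """

    kind: str
    cohort_file: str = "cohort"

    def __post_init__(self) -> None:
        if self.kind not in {"master", "nested", "intersection"}:
            raise ConfigError(f"unknown linkage structure {self.kind!r}")

    @property
    def expects_all_linked(self) -> bool:
        return self.kind in {"master", "nested"}


def read_records(
    path: str | Path,
    schema: Mapping[str, str],
    file_id: str | None = None,
    key_column: str | None = None,
    na_sentinels: Iterable[str] = DEFAULT_NA_SENTINELS,
) -> RecordFile:
    """Load a CSV record file, normalizing identifiers.

    Row keys come from ``key_column`` if given, else the 0-based row index.
    Raises :class:`SchemaError` for schema/column mismatches and
    :class:`IntegrityError` for duplicate row keys.
    """
    path = Path(path)
    sentinels = set(na_sentinels)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(schema) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"columns named in schema but absent: {sorted(missing_cols)}")

    def _to_none(v: Any) -> Any:
        return None if (v is None or str(v) in sentinels) else v

    df = df.map(_to_none)
    for col, kind in schema.items():
        if kind == IDENTIFIER_DATE:
            df[col] = df[col].map(normalize_date)
        elif kind == IDENTIFIER:
            df[col] = df[col].map(normalize_identifier)
    if key_column is not None:
        if key_column not in df.columns:
            raise SchemaError(f"key column {key_column!r} not in file")
        df.index = df[key_column].astype(str)
    else:
        df.index = df.index.astype(str)
    df.index.name = "row_key"
    return RecordFile(file_id=file_id or path.stem, df=df, schema=dict(schema))


PAIR_COLUMNS = ["left_key", "right_key", "step_or_weight", "status"]
PAIR_STATUSES = {"link", "possible", "non-link"}
_WEIGHT_PRECISION = 6


def write_pairs(
    pairs: pd.DataFrame,
    path: str | Path,
    left: RecordFile | None = None,
    right: RecordFile | None = None,
) -> None:
    """Write scored/classified pairs to CSV.

    Pairs carry, per the output contract, the match weight or cascade step
    reached and the candidate status (``link``/``possible``/``non-link``);
    sub-threshold "possible" candidates are retained, never dropped. Extra
    columns (e.g. the per-identifier agreement pattern) are preserved.
    Weights are printed at fixed precision and round-trip through
    :func:`read_pairs`.
    """
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise IntegrityError(f"pair table lacks columns {missing}")
    for rf, col in ((left, "left_key"), (right, "right_key")):
        if rf is not None:
            dangling = set(pairs[col].astype(str)) - set(rf.df.index)
            if dangling:
                raise IntegrityError(
                    f"{col} values not present in file {rf.file_id!r}: "
                    f"{sorted(dangling)[:5]}"
                )
    out = pairs.copy()
    out["left_key"] = out["left_key"].astype(str)
    out["right_key"] = out["right_key"].astype(str)
    out["step_or_weight"] = [
        _format_step_or_weight(v) for v in out["step_or_weight"]
    ]
    cols = PAIR_COLUMNS + [c for c in out.columns if c not in PAIR_COLUMNS]
    out[cols].to_csv(path, index=False)


def _format_step_or_weight(v: Any) -> str:
    if isinstance(v, str):
        return v
    f = float(v)
    if f.is_integer() and abs(f) < 1e6:
        return str(int(f))
    return f"{f:.{_WEIGHT_PRECISION}f}"


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a pair CSV written by :func:`write_pairs`."""
    df = pd.read_csv(path, dtype={"left_key": str, "right_key": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"pair file lacks columns {missing}")
    bad = set(df["status"]) - PAIR_STATUSES
    if bad:
        raise IntegrityError(f"unknown pair statuses {sorted(bad)}")
    return df


KNOWN_COMPARATORS = {"exact", "jaro_winkler"}


@dataclass
class RunConfig:
    """Validated run configuration shared by the CLI subcommands."""

    identifiers: list[str]
    comparators: dict[str, dict[str, Any]]
    cascade: list[list[str]] | None = None
    lower_threshold: float | None = None
    upper_threshold: float | None = None
    blocking_keys: list[str] = field(default_factory=list)
    structure: str = "intersection"
    seed: int = 0
    extra: dict[str, Any] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Raises :class:`ConfigError` for unknown comparator names or thresholds
    out of order (lower must be <= upper).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    identifiers = raw.get("identifiers")
    if not identifiers:
        raise ConfigError("config must name at least one identifier")
    comparators: dict[str, dict[str, Any]] = {}
    for ident in identifiers:
        spec = raw.get("comparators", {}).get(ident, "exact")
        if isinstance(spec, str):
            spec = {"name": spec}
        name = spec.get("name")
        if name not in KNOWN_COMPARATORS:
            raise ConfigError(f"unknown comparator {name!r} for {ident!r}")
        comparators[ident] = spec
    lower = raw.get("lower_threshold")
    upper = raw.get("upper_threshold")
    if lower is not None and upper is not None and lower > upper:
        raise ConfigError(
            f"lower threshold {lower} exceeds upper threshold {upper}"
        )
    cascade = raw.get("cascade")
    if cascade is not None:
        for step in cascade:
            unknown = set(step) - set(identifiers)
            if unknown:
                raise ConfigError(f"cascade step uses unknown identifiers {sorted(unknown)}")
    structure = raw.get("structure", "intersection")
    if structure not in {"master", "nested", "intersection"}:
        raise ConfigError(f"unknown linkage structure {structure!r}")
    return RunConfig(
        identifiers=list(identifiers),
        comparators=comparators,
        cascade=cascade,
        lower_threshold=lower,
        upper_threshold=upper,
        blocking_keys=list(raw.get("blocking_keys", [])),
        structure=structure,
        seed=int(raw.get("seed", 0)),
        extra={
            k: v
            for k, v in raw.items()
            if k
            not in {
                "identifiers",
                "comparators",
                "cascade",
                "lower_threshold",
                "upper_threshold",
                "blocking_keys",
                "structure",
                "seed",
            }
        },
    )


def validate_config_against_schema(config: RunConfig, record_file: RecordFile) -> None:
    """Raise :class:`ConfigError` if the config names identifiers the file lacks."""
    missing = set(config.identifiers) - set(record_file.identifier_columns)
    if missing:
        raise ConfigError(
            f"identifiers {sorted(missing)} not in schema of {record_file.file_id!r}"
        )
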