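"""Truth-labelled synthetic populations and corrupted record files.

Emulates the situation every linkage study faces: one underlying population
observed through two (or more) event-based files whose identifiers carry
recording errors (misspelt names), genuine changes over time (a move to a
new postcode), date-component transpositions, and missingness — plus
household and twin identifier collisions, which are the classic source of
false matches (two household members sharing surname, sex and postcode).

Everything is a pure function of (spec, seed), so downstream stages can be
tested against known truth without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records_io import (
    ATTRIBUTE,
    IDENTIFIER,
    IDENTIFIER_DATE,
    TRUTH_ID,
    ConfigError,
    RecordFile,
)

logger = logging.getLogger("linkqa")

# ---------------------------------------------------------------------------
# Lexicons: fixed, frequency-skewed so that u-probabilities are realistic and
# name collisions actually occur. Sampling weight for rank r is 1/r (Zipf).
# ---------------------------------------------------------------------------

SURNAMES: tuple[str, ...] = (
    "SMITH", "JONES", "TAYLOR", "BROWN", "WILLIAMS", "WILSON", "JOHNSON",
    "DAVIES", "ROBINSON", "WRIGHT", "THOMPSON", "EVANS", "WALKER", "WHITE",
    "ROBERTS", "GREEN", "HALL", "WOOD", "JACKSON", "CLARKE", "PATEL", "KHAN",
    "LEWIS", "JAMES", "PHILLIPS", "MASON", "MITCHELL", "ROSE", "DAVIS",
    "RODGERS", "PARKER", "SCOTT", "TURNER", "KELLY", "COOPER", "HARRIS",
    "WARD", "MARTIN", "HUGHES", "EDWARDS", "MOORE", "KING", "ALLEN", "BAKER",
    "MORRIS", "ANDERSON", "ADAMS", "BELL", "CARTER", "HILL", "COLLINS",
    "YOUNG", "MURPHY", "SHAW", "GRAY", "RICHARDSON", "WATSON", "BENNETT",
    "COOKE", "MORGAN", "PRICE", "REID", "BAILEY", "MURRAY", "COX", "FOSTER",
    "SIMPSON", "GRAHAM", "RUSSELL", "MARSHALL", "STEWART", "HAMILTON",
    "WEBB", "ELLIS", "CHAPMAN", "MILLS", "GIBSON", "RICHARDS", "HUNT",
    "PALMER", "HOLMES", "BARNES", "MILLER", "KNIGHT", "LLOYD", "BUTLER",
    "BARKER", "FISHER", "STEVENS", "DIXON", "HARRISON", "GORDON", "HART",
    "OWEN", "BURTON", "LANE", "REED", "ARMSTRONG", "GRANT", "HENDERSON",
    "PEARSON", "FLETCHER", "KAUR", "SINGH", "ALI", "AHMED", "SHAH", "BEGUM",
    "HUSSAIN", "AKHTAR", "RAHMAN", "MALIK", "O'BRIEN", "O'CONNOR", "RYAN",
    "WALSH", "MCCARTHY", "O'SULLIVAN", "DOYLE", "BYRNE", "GALLAGHER",
    "O'NEILL", "QUINN", "DUFFY", "BRENNAN", "BURKE", "NOLAN", "CAMPBELL",
    "MACDONALD", "ROSS", "PATERSON", "FRASER", "MACLEOD", "DUNCAN", "HUNTER",
    "WALLACE", "KERR", "CRAWFORD", "DOUGLAS", "CAMERON", "JENKINS",
    "HOPKINS", "GRIFFITHS", "REES", "PRITCHARD", "BEVAN", "POWELL", "VAUGHAN",
    "NOVAK", "KOWALSKI", "WOJCIK", "KAMINSKI", "LEWANDOWSKI", "ZIELINSKI",
    "SZYMANSKI", "DABROWSKI", "NGUYEN", "CHEN", "WANG", "LI", "ZHANG", "LIU",
    "KIM", "LEE", "PARK", "CHOI", "TANAKA", "SATO", "SUZUKI", "GARCIA",
    "RODRIGUEZ", "MARTINEZ", "HERNANDEZ", "LOPEZ", "GONZALEZ", "PEREZ",
    "SANCHEZ", "RAMIREZ", "TORRES", "FLORES", "SILVA", "SANTOS", "PEREIRA",
    "OLIVEIRA", "COSTA", "FERREIRA", "ALMEIDA", "SOUSA", "MULLER",
    "SCHMIDT", "SCHNEIDER", "FISCHER", "WEBER", "MEYER", "WAGNER", "BECKER",
    "HOFFMANN", "SCHULZ", "KOCH", "RICHTER", "KLEIN", "WOLF", "NEUMANN",
    "BRAUN", "ZIMMERMANN", "KRUGER", "HARTMANN", "LANGE", "WERNER",
    "SCHWARZ", "KRAUSE", "LEHMANN", "KOHLER", "HERRMANN", "FRANK", "BERGER",
    "WINKLER", "ROTH", "BECK", "LORENZ", "BAUMANN", "SCHUSTER",
)

FORENAMES: tuple[str, ...] = (
    "OLIVER", "GEORGE", "HARRY", "JACK", "JACOB", "NOAH", "CHARLIE",
    "MUHAMMAD", "THOMAS", "OSCAR", "WILLIAM", "JAMES", "HENRY", "LEO",
    "ALFIE", "JOSHUA", "FREDDIE", "ARCHIE", "ETHAN", "ISAAC", "ALEXANDER",
    "JOSEPH", "EDWARD", "SAMUEL", "MAX", "DANIEL", "ARTHUR", "LUCAS",
    "MOHAMMED", "LOGAN", "OLIVIA", "AMELIA", "ISLA", "EMILY", "AVA",
    "POPPY", "ISABELLA", "JESSICA", "LILY", "SOPHIE", "GRACE", "SOPHIA",
    "MIA", "EVIE", "RUBY", "ELLA", "SCARLETT", "FLORENCE", "ISABELLE",
    "CHARLOTTE", "WILLOW", "DAISY", "PHOEBE", "FREYA", "ALICE", "SIENNA",
    "EMMA", "ELSIE", "IMOGEN", "ELIZABETH", "MARGARET", "DOROTHY", "JOAN",
    "PATRICIA", "JEAN", "BARBARA", "DORIS", "KATHLEEN", "IRENE", "BETTY",
    "DAVID", "JOHN", "MICHAEL", "PETER", "ROBERT", "BRIAN", "KEITH",
    "RONALD", "KENNETH", "DEREK", "RAJESH", "SANJAY", "AMIT", "PRIYA",
    "ANITA", "FATIMA", "AISHA", "HASSAN", "IBRAHIM", "YUSUF", "CHLOE",
    "HANNAH", "LAUREN", "MEGAN", "REBECCA", "VICTORIA", "NATASHA", "KATIE",
    "HOLLY", "ABIGAIL", "MATTHEW", "ANDREW", "CHRISTOPHER", "NICHOLAS",
)

_POSTCODE_LETTERS = "ABCDEFGHJKLMNOPRSTUWYZ"  # letters used in UK-style outcodes


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


_SURNAME_W = _zipf_weights(len(SURNAMES))
_FORENAME_W = _zipf_weights(len(FORENAMES))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """What the simulated population looks like.

    ``twin_rate`` is the expected number of twin pairs per person: the
    realized pair count is Binomial(n_persons, twin_rate). Twins share
    surname, date of birth, sex and postcode and differ only in forename.
    ``household_size_distribution`` maps household size to probability;
    household members share surname and postcode. ``outcome_model`` gives
    the per-subgroup probability of the binary outcome (e.g. death, which
    decides membership of a register file).
    """

    n_persons: int = 1000
    twin_rate: float = 0.01
    household_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.35, 3: 0.20, 4: 0.15}
    )
    subgroup_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"majority": 0.8, "minority": 0.2}
    )
    outcome_model: Mapping[str, float] = field(
        default_factory=lambda: {"majority": 0.10, "minority": 0.10}
    )
    dob_start: str = "1940-01-01"
    dob_end: str = "2005-12-31"

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ConfigError("n_persons must be positive")
        if not 0 <= self.twin_rate <= 0.5:
            raise ConfigError("twin_rate must be in [0, 0.5]")
        hs = self.household_size_distribution
        if not hs or any(s < 1 for s in hs) or any(p < 0 for p in hs.values()):
            raise ConfigError("invalid household size distribution")
        if abs(sum(hs.values()) - 1) > 1e-9:
            raise ConfigError("household size probabilities must sum to 1")
        sf = self.subgroup_fractions
        if abs(sum(sf.values()) - 1) > 1e-9:
            raise ConfigError("subgroup fractions must sum to 1")
        if any(not 0 <= p <= 1 for p in sf.values()):
            raise ConfigError("subgroup fractions must be in [0,1]")
        missing = set(sf) - set(self.outcome_model)
        if missing:
            raise ConfigError(f"outcome_model lacks subgroups {sorted(missing)}")


@dataclass(frozen=True)
class FieldCorruption:
    """Per-identifier corruption rates; all in [0,1].

    A field receives at most one corruption event per derivation: a single
    categorical draw chooses among missing / typo / transposition / update /
    intact, so each marginal rate is exactly nominal.
    """

    typo_rate: float = 0.0
    transposition_rate: float = 0.0
    missing_rate: float = 0.0
    update_rate: float = 0.0

    def validate(self, kind: str) -> None:
        rates = (self.typo_rate, self.transposition_rate,
                 self.missing_rate, self.update_rate)
        if any(not 0 <= r <= 1 for r in rates):
            raise ConfigError("corruption rates must lie in [0,1]")
        if self.transposition_rate > 0 and kind != "date":
            raise ConfigError("transposition only applies to date fields")

    def event_probs(self, multiplier: float = 1.0) -> np.ndarray:
        """(missing, typo, transposition, update, none) probabilities."""
        p = np.array([self.missing_rate, self.typo_rate,
                      self.transposition_rate, self.update_rate]) * multiplier
        total = p.sum()
        if total > 1:
            logger.warning(
                "corruption rates sum to %.3f after multiplier %.2f; rescaled",
                total, multiplier,
            )
            p = p / total
            total = 1.0
        return np.append(p, 1.0 - total)


# Field kinds drive which corruption events are legal and how values redraw.
DEFAULT_FIELD_KINDS: dict[str, str] = {
    "nhs": "id", "forename": "name", "surname": "name",
    "dob": "date", "sex": "sex", "postcode": "postcode",
}


@dataclass(frozen=True)
class CorruptionSpec:
    """Per-field error rates with optional subgroup-differential multipliers.

    ``differential`` multiplies every rate for records of the named
    subgroup, the simplest mechanism producing a non-random distribution of
    linkage errors (data quality varying with ethnicity, age or
    socio-economic status).
    """

    fields: Mapping[str, FieldCorruption] = field(default_factory=dict)
    differential: Mapping[str, float] = field(default_factory=dict)
    field_kinds: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_KINDS)
    )

    def validate(self) -> None:
        for name, fc in self.fields.items():
            kind = self.field_kinds.get(name)
            if kind is None:
                raise ConfigError(f"no field kind declared for {name!r}")
            fc.validate(kind)
        if any(m < 0 for m in self.differential.values()):
            raise ConfigError("differential multipliers must be >= 0")


def uniform_corruption(
    typo: float = 0.0, missing: float = 0.0, update_postcode: float = 0.0,
    transpose_dob: float = 0.0, differential: Mapping[str, float] | None = None,
) -> CorruptionSpec:
    """Convenience constructor: typo/missing on names, update on postcode."""
    return CorruptionSpec(
        fields={
            "nhs": FieldCorruption(typo_rate=typo, missing_rate=missing),
            "forename": FieldCorruption(typo_rate=typo, missing_rate=missing),
            "surname": FieldCorruption(typo_rate=typo, missing_rate=missing),
            "dob": FieldCorruption(missing_rate=missing,
                                   transposition_rate=transpose_dob),
            "sex": FieldCorruption(missing_rate=missing),
            "postcode": FieldCorruption(missing_rate=missing,
                                        update_rate=update_postcode),
        },
        differential=dict(differential or {}),
    )


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

def _nhs_check_digit(d9: Iterable[int]) -> int:
    """Modulus-11 check digit over nine digits; 10 means unusable."""
    s = sum(d * w for d, w in zip(d9, range(10, 1, -1)))
    c = 11 - s % 11
    return 0 if c == 11 else c


def _draw_nhs(rng: np.random.Generator) -> str:
    while True:
        d9 = rng.integers(0, 10, size=9)
        d9[0] = rng.integers(1, 10)
        c = _nhs_check_digit(d9)
        if c != 10:
            return "".join(map(str, d9)) + str(c)


def _draw_postcode(rng: np.random.Generator) -> str:
    L = _POSTCODE_LETTERS
    pick = lambda s: s[rng.integers(0, len(s))]
    return (pick(L) + pick(L) + str(rng.integers(1, 10)) + str(rng.integers(0, 10))
            + " " + str(rng.integers(0, 10)) + pick(L) + pick(L))


def _draw_dob(rng: np.random.Generator, start: str, end: str) -> str:
    t0 = pd.Timestamp(start)
    days = (pd.Timestamp(end) - t0).days
    return (t0 + pd.Timedelta(days=int(rng.integers(0, days + 1)))).strftime("%Y-%m-%d")


def generate_population(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Sample a truth-labelled person table.

    Columns: person_id, household_id, nhs, forename, surname, dob, sex,
    postcode, subgroup, outcome, twin_group. Households share surname and
    postcode; twin pairs (Binomial(n, twin_rate) of them) additionally share
    dob and sex, differing only in forename. Deterministic under (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n_persons

    sizes = np.array(sorted(spec.household_size_distribution))
    size_p = np.array([spec.household_size_distribution[s] for s in sizes], float)
    size_p = size_p / size_p.sum()

    subgroups = list(spec.subgroup_fractions)
    sub_p = np.array([spec.subgroup_fractions[g] for g in subgroups], float)

    rows: list[dict] = []
    hid = 0
    while len(rows) < n:
        size = int(rng.choice(sizes, p=size_p))
        size = min(size, n - len(rows))
        surname = str(rng.choice(SURNAMES, p=_SURNAME_W))
        postcode = _draw_postcode(rng)
        subgroup = subgroups[rng.choice(len(subgroups), p=sub_p)]
        for _ in range(size):
            pid = len(rows)
            rows.append({
                "person_id": f"P{pid:06d}",
                "household_id": f"H{hid:06d}",
                "nhs": _draw_nhs(rng),
                "forename": str(rng.choice(FORENAMES, p=_FORENAME_W)),
                "surname": surname,
                "dob": _draw_dob(rng, spec.dob_start, spec.dob_end),
                "sex": "M" if rng.random() < 0.5 else "F",
                "postcode": postcode,
                "subgroup": subgroup,
                "twin_group": None,
            })
        hid += 1
    pop = pd.DataFrame(rows)

    n_pairs = int(rng.binomial(n, spec.twin_rate)) if spec.twin_rate > 0 else 0
    n_pairs = min(n_pairs, n // 2)
    if n_pairs:
        chosen = rng.choice(n, size=2 * n_pairs, replace=False)
        for t, (i, j) in enumerate(chosen.reshape(-1, 2)):
            for col in ("household_id", "surname", "dob", "sex", "postcode",
                        "subgroup"):
                pop.at[j, col] = pop.at[i, col]
            # twins must be distinguishable on forename only
            while pop.at[j, "forename"] == pop.at[i, "forename"]:
                pop.at[j, "forename"] = str(rng.choice(FORENAMES, p=_FORENAME_W))
            pop.at[i, "twin_group"] = pop.at[j, "twin_group"] = f"T{t:05d}"

    out_p = pop["subgroup"].map(spec.outcome_model).to_numpy(float)
    pop["outcome"] = (rng.random(n) < out_p).astype(int)
    return pop


# ---------------------------------------------------------------------------
# Corruption and file derivation
# ---------------------------------------------------------------------------

def corrupt_value(
    value: str, kind: str, event: str, rng: np.random.Generator
) -> str | None:
    """Apply one corruption event to a non-missing value.

    typo: single-character substitution, deletion or insertion at a random
    position (edit distance exactly 1). transposition (dates only): swap
    day and month when both are <= 12 and distinct, else shift by one
    adjacent day. update: a genuine change over time — redraw a fresh value
    of the same kind (e.g. a move to a new postcode). missing: drop.
    """
    if value is None:
        raise ValueError("corrupt_value requires a non-missing value")
    if event == "none":
        return value
    if event == "missing":
        return None
    if event == "typo":
        return _typo(value, rng)
    if event == "transposition":
        if kind != "date":
            raise ConfigError("transposition only applies to date fields")
        return _transpose_date(value, rng)
    if event == "update":
        return _redraw(value, kind, rng)
    raise ConfigError(f"unknown corruption event {event!r}")


def _typo(value: str, rng: np.random.Generator) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    op = rng.integers(0, 3) if len(value) > 1 else rng.integers(0, 2)  # no deletion of last char
    pos = int(rng.integers(0, len(value)))
    ch = value[pos]
    alphabet = "0123456789" if ch.isdigit() else letters
    if op == 0:  # substitution: must change the character
        new = ch
        while new == ch:
            new = alphabet[rng.integers(0, len(alphabet))]
        return value[:pos] + new + value[pos + 1:]
    if op == 1:  # insertion
        new = alphabet[rng.integers(0, len(alphabet))]
        return value[:pos] + new + value[pos:]
    return value[:pos] + value[pos + 1:]  # deletion


def _transpose_date(value: str, rng: np.random.Generator) -> str:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError):
        return value
    if ts.day <= 12 and ts.month <= 12 and ts.day != ts.month:
        return ts.replace(month=ts.day, day=ts.month).strftime("%Y-%m-%d")
    shift = 1 if rng.random() < 0.5 else -1
    return (ts + pd.Timedelta(days=shift)).strftime("%Y-%m-%d")


def _redraw(value: str, kind: str, rng: np.random.Generator) -> str:
    if kind == "postcode":
        new = _draw_postcode(rng)
        while new == value:
            new = _draw_postcode(rng)
        return new
    if kind == "name":
        lex, w = SURNAMES, _SURNAME_W
        new = str(rng.choice(lex, p=w))
        while new == value:
            new = str(rng.choice(lex, p=w))
        return new
    if kind == "sex":
        return "F" if value == "M" else "M"
    if kind == "date":
        shift = int(rng.integers(1, 366)) * (1 if rng.random() < 0.5 else -1)
        return (pd.Timestamp(value) + pd.Timedelta(days=shift)).strftime("%Y-%m-%d")
    if kind == "id":
        return _draw_nhs(rng)
    raise ConfigError(f"no update model for field kind {kind!r}")


POPULATION_SCHEMA: dict[str, str] = {
    "nhs": IDENTIFIER, "forename": IDENTIFIER, "surname": IDENTIFIER,
    "dob": IDENTIFIER_DATE, "sex": IDENTIFIER, "postcode": IDENTIFIER,
    "subgroup": ATTRIBUTE, "outcome": ATTRIBUTE, "person_id": TRUTH_ID,
}


@dataclass
class TruthMap:
    """Ground-truth match status between two files.

    Stores each file's row_key -> true person id; a pair is a true match iff
    the person ids agree. ``true_pairs`` enumerates all cross-file matches;
    ``multiplicity`` counts records per person per file.
    """

    left: dict[str, str]
    right: dict[str, str]

    @classmethod
    def from_files(cls, left: RecordFile, right: RecordFile) -> "TruthMap":
        lc, rc = left.truth_column, right.truth_column
        if lc is None or rc is None:
            raise ConfigError("both files need a truth_id column for a TruthMap")
        return cls(left=dict(left.df[lc]), right=dict(right.df[rc]))

    def is_match(self, left_key: str, right_key: str) -> bool:
        lt = self.left.get(left_key)
        rt = self.right.get(right_key)
        if lt is None or rt is None:
            raise KeyError(f"truth unknown for pair ({left_key}, {right_key})")
        return lt == rt

    def true_pairs(self) -> set[tuple[str, str]]:
        by_person: dict[str, list[str]] = {}
        for rk, pid in self.right.items():
            by_person.setdefault(pid, []).append(rk)
        return {
            (lk, rk)
            for lk, pid in self.left.items()
            for rk in by_person.get(pid, ())
        }

    def multiplicity(self) -> pd.DataFrame:
        ml = pd.Series(self.left).value_counts().rename("left_records")
        mr = pd.Series(self.right).value_counts().rename("right_records")
        return pd.concat([ml, mr], axis=1).fillna(0).astype(int)


def derive_file(
    population: pd.DataFrame,
    corruption: CorruptionSpec,
    coverage: float = 1.0,
    duplication_rate: float = 0.0,
    seed: int = 0,
    file_id: str = "file",
    include: pd.Series | None = None,
) -> tuple[RecordFile, TruthMap]:
    """Observe the population through one event-based file.

    Each person (optionally restricted by the boolean ``include`` mask) is
    captured with probability ``coverage``; captured persons emit
    1 + Geometric(duplication_rate) records (duplication as found in
    registries). Each identifier field of each record independently receives
    at most one corruption event, with all rates multiplied by the person's
    subgroup differential multiplier. The returned TruthMap pairs population
    person_ids (left) with derived row keys (right); with no corruption,
    full coverage and no duplication it is the identity pairing.
    """
    if not 0 <= coverage <= 1 or not 0 <= duplication_rate < 1:
        raise ConfigError("coverage in [0,1] and duplication_rate in [0,1) required")
    corruption.validate()
    rng = np.random.default_rng(seed)
    fields = [c for c in population.columns
              if c in corruption.field_kinds and c in POPULATION_SCHEMA]
    events = ("missing", "typo", "transposition", "update", "none")

    sub = population if include is None else population.loc[include.to_numpy(bool)]
    rows: list[dict] = []
    for _, person in sub.iterrows():
        if rng.random() >= coverage:
            continue
        n_rec = 1
        while rng.random() < duplication_rate:
            n_rec += 1
        mult = corruption.differential.get(person["subgroup"], 1.0)
        for _ in range(n_rec):
            rec = {
                "row_key": f"{file_id}-{len(rows)}",
                "person_id": person["person_id"],
                "subgroup": person["subgroup"],
                "outcome": person["outcome"],
            }
            for f in fields:  # schema order, one event draw per field
                value = person[f]
                fc = corruption.fields.get(f)
                if fc is None or value is None:
                    rec[f] = value
                    continue
                event = events[rng.choice(5, p=fc.event_probs(mult))]
                rec[f] = corrupt_value(value, corruption.field_kinds[f], event, rng)
            rows.append(rec)

    cols = ["row_key"] + fields + ["subgroup", "outcome", "person_id"]
    df = pd.DataFrame(rows, columns=cols).set_index("row_key")
    df.index.name = "row_key"
    schema = {c: POPULATION_SCHEMA[c] for c in df.columns}
    rf = RecordFile(file_id=file_id, df=df, schema=schema)
    truth = TruthMap(
        left=dict(zip(population["person_id"], population["person_id"])),
        right=dict(df["person_id"]),
    )
    return rf, truth


def make_control_subsets(
    cohort: RecordFile, register: RecordFile
) -> tuple[list[str], list[str]]:
    """Positive/negative control row keys for a cohort linked to a register.

    Positive controls are cohort records whose true person has at least one
    record in the register (known to have the registered event, so they
    should link); negative controls are cohort records whose person is
    absent from the register by construction (should not link). The sets
    are disjoint. An empty set is a warning, not an error.
    """
    tm = TruthMap.from_files(cohort, register)
    register_persons = set(tm.right.values())
    pos = [k for k, pid in tm.left.items() if pid in register_persons]
    neg = [k for k, pid in tm.left.items() if pid not in register_persons]
    if not pos or not neg:
        logger.warning("empty control subset (pos=%d, neg=%d)", len(pos), len(neg))
    return pos, neg
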