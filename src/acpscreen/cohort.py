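"""Person-level cohort I/O, variable derivation, filtering, stratum codes.

A cohort is held as a pandas DataFrame with canonical column names.  Raw
instrument totals (CES-D score, LSNS-6 score, age, number of cohabiting
family members) are binarized into the six risk factors used for
stratification; pre-derived binaries are accepted and pass through.

Risk-factor coding (1 = the higher-risk category):

    position 1  md_history   history of mental disorder
    position 2  working      working generation (age < 65)
    position 3  female       female sex
    position 4  lives_alone  no cohabiting family
    position 5  isolation    social isolation (LSNS-6 < 12)
    position 6  bereavement  bereavement of a close person

A stratum code is a 6-character string over {0,1,x}: active positions carry
the record's 0/1 value, inactive positions are 'x' (e.g. "0xxxxx" = no MD
history, all other factors unrestricted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    SchemaError,
    StratificationError,
    ValidationError,
)

__all__ = [
    "Thresholds",
    "LedgerEntry",
    "FilterLedger",
    "POSITION_FACTORS",
    "RISK_FACTORS",
    "validate_stratum_code",
    "read_cohort",
    "write_cohort",
    "derive_variables",
    "complete_case_filter",
    "assign_stratum_code",
    "assign_stratum_codes",
]

#: stratum-code digit position -> canonical binary risk column
POSITION_FACTORS = {
    1: "md_history",
    2: "working",
    3: "female",
    4: "lives_alone",
    5: "isolation",
    6: "bereavement",
}
RISK_FACTORS = tuple(POSITION_FACTORS[p] for p in range(1, 7))

_NUMERIC_COLUMNS = (
    "cesd_score", "cesd_positive", "ais", "age", "lsns6", "n_cohabiting",
    "md_history", "isolation", "bereavement", "working", "female",
    "lives_alone", "insomnia",
)
_CATEGORY_COLUMNS = {
    "sex": {"female", "male"},
    "age_group": {"working", "retired"},
    "cohabiting": {"lives_alone", "lives_with_family"},
}
_BINARY_COLUMNS = (
    "cesd_positive", "md_history", "isolation", "bereavement",
    "working", "female", "lives_alone", "insomnia",
)


@dataclass(frozen=True)
class Thresholds:
    """Binarization thresholds for the derived variables.

    Defaults follow the scales' conventional screening cutoffs: CES-D >= 16
    is positive, LSNS-6 < 12 is socially isolated, age < 65 is working
    generation, AIS >= 6 is insomnia.
    """

    cesd_cutoff: int = 16
    lsns_cutoff: int = 12
    age_cutoff: int = 65
    ais_insomnia_cutoff: int = 6

    def __post_init__(self):
        for name in ("cesd_cutoff", "lsns_cutoff", "age_cutoff", "ais_insomnia_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.cesd_cutoff <= 60:
            raise ValueError("cesd_cutoff outside the CES-D range 0..60")


@dataclass(frozen=True)
class LedgerEntry:
    stage: str
    n_before: int
    n_after: int
    fields: tuple[str, ...]

    def __post_init__(self):
        if self.n_after > self.n_before:
            raise ValueError("n_after exceeds n_before")


@dataclass
class FilterLedger:
    """Ordered audit trail of the stepwise complete-case filtering stages."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def append(self, entry: LedgerEntry) -> None:
        self.entries.append(entry)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": e.stage,
                    "n_before": e.n_before,
                    "n_after": e.n_after,
                    "fields_required": ",".join(e.fields),
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def validate_stratum_code(code: str) -> str:
    if len(code) != 6 or any(c not in "01x" for c in code):
        raise ValueError(f"invalid stratum code {code!r} (6 chars over {{0,1,x}})")
    return code


def read_cohort(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a person-level cohort CSV into canonical columns.

    ``schema`` maps canonical column names to the CSV's column names; when
    omitted, columns already bearing canonical names are picked up.  Cells
    that fail to parse become missing; the row count is preserved.

    Raises :class:`SchemaError` for an unmapped column and
    :class:`ValidationError` (naming the first offending row) for AIS values
    outside 0..24 or non-0/1 entries in binary columns.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if schema is None:
        known = set(_NUMERIC_COLUMNS) | set(_CATEGORY_COLUMNS)
        schema = {c: c for c in raw.columns if c in known}
        if not schema:
            raise SchemaError(f"no canonical columns recognized in {list(raw.columns)}")
    out = pd.DataFrame(index=raw.index)
    for canonical, source in schema.items():
        if source not in raw.columns:
            raise SchemaError(f"mapped column {source!r} (for {canonical!r}) not in file")
        col = raw[source]
        if canonical in _CATEGORY_COLUMNS:
            norm = col.str.strip().str.lower()
            out[canonical] = norm.where(norm.isin(_CATEGORY_COLUMNS[canonical]))
        elif canonical in _NUMERIC_COLUMNS:
            out[canonical] = pd.to_numeric(col, errors="coerce")
        else:
            raise SchemaError(f"unknown canonical column {canonical!r}")
    _validate(out)
    return out


def _validate(df: pd.DataFrame) -> None:
    if "ais" in df.columns:
        bad = df.index[df["ais"].notna() & ~df["ais"].between(0, 24)]
        if len(bad):
            raise ValidationError(f"ais outside [0, 24] at row {bad[0]}")
    for col in _BINARY_COLUMNS:
        if col in df.columns:
            bad = df.index[df[col].notna() & ~df[col].isin([0, 1])]
            if len(bad):
                raise ValidationError(f"{col} not in {{0,1}} at row {bad[0]}")


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _derive_binary(out, derived, raw_mask, raw_value, source_name):
    """Set ``derived`` from a raw rule, honoring an existing binary column
    (pre-derived in the input, or derived from an earlier raw source).

    raw_mask: boolean Series, True where the raw field is available.
    raw_value: float Series (0/1, meaningful where raw_mask).
    """
    if derived in out.columns:
        existing = out[derived]
        both = raw_mask & existing.notna()
        clash = both & (existing != raw_value)
        if clash.any():
            row = out.index[clash][0]
            raise ConsistencyError(
                f"{derived} disagrees with {source_name} at row {row}"
            )
        out[derived] = existing.astype(float)
        # fill holes in the binary from the raw field where possible
        fill = raw_mask & existing.isna()
        if fill.any():
            out.loc[fill, derived] = raw_value[fill]
    else:
        out[derived] = np.where(raw_mask, raw_value, np.nan)


def derive_variables(df: pd.DataFrame, t: Thresholds = Thresholds()) -> pd.DataFrame:
    """Binarize raw scores into outcome and risk-factor columns.

    cesd_positive = 1 iff cesd_score >= cesd_cutoff (a score equal to the
    cutoff is positive); isolation = 1 iff lsns6 < lsns_cutoff (strict);
    working = 1 iff age < age_cutoff (65-year-olds are retired);
    insomnia = 1 iff ais >= ais_insomnia_cutoff; lives_alone from the
    ``cohabiting`` category or a raw cohabitant count of 0.  Missing raw
    values yield missing derived values; pre-derived binaries pass through
    unchanged, but a raw/binary contradiction raises ConsistencyError.
    Idempotent.
    """
    out = df.copy()

    if "cesd_score" in df.columns:
        m = df["cesd_score"].notna()
        _derive_binary(out, "cesd_positive", m,
                       (df["cesd_score"] >= t.cesd_cutoff).astype(float), "cesd_score")
    if "lsns6" in df.columns:
        m = df["lsns6"].notna()
        _derive_binary(out, "isolation", m,
                       (df["lsns6"] < t.lsns_cutoff).astype(float), "lsns6")
    if "age" in df.columns:
        m = df["age"].notna()
        _derive_binary(out, "working", m,
                       (df["age"] < t.age_cutoff).astype(float), "age")
    if "age_group" in df.columns:
        m = df["age_group"].notna()
        _derive_binary(out, "working", m,
                       (df["age_group"] == "working").astype(float), "age_group")
    if "sex" in df.columns:
        m = df["sex"].notna()
        _derive_binary(out, "female", m,
                       (df["sex"] == "female").astype(float), "sex")
    if "cohabiting" in df.columns:
        m = df["cohabiting"].notna()
        _derive_binary(out, "lives_alone", m,
                       (df["cohabiting"] == "lives_alone").astype(float), "cohabiting")
    if "n_cohabiting" in df.columns:
        m = df["n_cohabiting"].notna()
        _derive_binary(out, "lives_alone", m,
                       (df["n_cohabiting"] == 0).astype(float), "n_cohabiting")
    if "ais" in df.columns:
        m = df["ais"].notna()
        _derive_binary(out, "insomnia", m,
                       (df["ais"] >= t.ais_insomnia_cutoff).astype(float), "ais")
    return out


def complete_case_filter(
    df: pd.DataFrame, required: list[str], stage_name: str
) -> tuple[pd.DataFrame, LedgerEntry]:
    """Keep records non-missing on every required field; log before/after Ns."""
    if not required:
        raise ValueError("required field list is empty")
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"required fields not in cohort: {missing_cols}")
    mask = df[list(required)].notna().all(axis=1)
    filtered = df.loc[mask].reset_index(drop=True)
    entry = LedgerEntry(stage_name, len(df), len(filtered), tuple(required))
    return filtered, entry


def assign_stratum_code(record, active_positions) -> str:
    """Code one record: active positions get its 0/1 value, others 'x'."""
    active = set(active_positions)
    chars = []
    for pos in range(1, 7):
        if pos not in active:
            chars.append("x")
            continue
        factor = POSITION_FACTORS[pos]
        value = record.get(factor) if hasattr(record, "get") else record[factor]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise StratificationError(f"missing {factor} for active position {pos}")
        if value not in (0, 1, 0.0, 1.0):
            raise StratificationError(f"{factor} is not binary: {value!r}")
        chars.append("1" if value else "0")
    return "".join(chars)


def assign_stratum_codes(df: pd.DataFrame, active_positions) -> pd.Series:
    """Vectorized stratum codes for a complete-case cohort."""
    active = sorted(set(active_positions))
    if not active:
        raise ValueError("active_positions is empty")
    codes = np.full((len(df), 6), "x", dtype="<U1")
    for pos in active:
        factor = POSITION_FACTORS[pos]
        if factor not in df.columns:
            raise SchemaError(f"factor column {factor!r} absent")
        col = df[factor]
        if col.isna().any():
            row = df.index[col.isna()][0]
            raise StratificationError(f"missing {factor} at row {row}")
        codes[:, pos - 1] = np.where(col.to_numpy(dtype=float) == 1.0, "1", "0")
    joined = ["".join(row) for row in codes]
    return pd.Series(joined, index=df.index, name="stratum_code")
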