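"""AIRR rearrangement and participant-metadata I/O.

The pipeline's on-disk interchange formats are

* an AIRR-style Rearrangement table: tab-separated, UTF-8, one row per
  sequenced IGH transcript, with the standard AIRR column names
  (``sequence_id``, ``v_call``, ``j_call``, ``c_call``, ``junction``,
  ``junction_length``, ``duplicate_count``) plus two extra columns,
  ``participant_id`` and ``mutation_count`` (the per-sequence number of
  bases differing from the IMGT germline reference, computed upstream);
* a participant metadata CSV with exposure group, demographics, smoking
  history, GOLD spirometry group, and optional socioeconomic / CT / genetic
  covariates.

Readers validate every row on the way in and fail loudly with the offending
row index; they never silently drop or impute.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .errors import (
    RowValidationError,
    SchemaError,
    UnknownIsotypeError,
)

log = logging.getLogger("ighrep")

# --- isotype subclasses -------------------------------------------------

#: The eight IGH isotype subclasses, in canonical reporting order.
ISOTYPES = ("IgM", "IgD", "IgA1", "IgA2", "IgG1", "IgG2", "IgG3", "IgE")

#: Subclasses produced by class-switch recombination (everything but IgM/IgD).
CLASS_SWITCHED = frozenset({"IgA1", "IgA2", "IgG1", "IgG2", "IgG3", "IgE"})

_C_GENE_TO_ISOTYPE = {
    "IGHM": "IgM",
    "IGHD": "IgD",
    "IGHA1": "IgA1",
    "IGHA2": "IgA2",
    "IGHG1": "IgG1",
    "IGHG2": "IgG2",
    "IGHG3": "IgG3",
    "IGHE": "IgE",
}

#: Inverse mapping, used by the simulator to emit ``c_call`` values.
ISOTYPE_TO_C_CALL = {v: k for k, v in _C_GENE_TO_ISOTYPE.items()}


def first_call(call: str) -> str:
    """Resolve a possibly multi-valued gene call to its first listed entry."""
    return str(call).split(",")[0].strip()


def map_isotype(c_call: str) -> str:
    """Map a constant-region gene call to its isotype subclass label.

    Case-insensitive and tolerant of allele suffixes (``"IGHA2*01"`` -> IgA2)
    and multi-valued calls (first call wins). Raises
    :class:`~ighrep.errors.UnknownIsotypeError` for anything that is not one
    of the 8 IGH constant genes.
    """
    if c_call is None or str(c_call).strip() == "":
        raise UnknownIsotypeError("empty c_call")
    gene = first_call(c_call).split("*")[0].upper()
    try:
        return _C_GENE_TO_ISOTYPE[gene]
    except KeyError:
        raise UnknownIsotypeError(f"not an IGH constant-region gene: {c_call!r}") from None


def is_class_switched(isotype: str) -> bool:
    """True iff *isotype* is produced by class-switch recombination."""
    if isotype not in ISOTYPES:
        raise UnknownIsotypeError(f"unknown isotype subclass: {isotype!r}")
    return isotype in CLASS_SWITCHED


# --- rearrangement tables -----------------------------------------------

REARRANGEMENT_FIELDS = (
    "sequence_id",
    "participant_id",
    "v_call",
    "j_call",
    "c_call",
    "junction",
    "junction_length",
    "mutation_count",
    "duplicate_count",
)

#: Columns that must be present in an input file; ``duplicate_count`` is
#: optional and defaults to 1 (measure definitions count unique sequences,
#: duplicates only matter for clone abundance).
REQUIRED_REARRANGEMENT_FIELDS = tuple(
    f for f in REARRANGEMENT_FIELDS if f != "duplicate_count"
)

_JUNCTION_RE = re.compile(r"[ACGT]+\Z")


def _coerce_int(df: pd.DataFrame, col: str, minimum: int) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals != vals.round())
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowValidationError(f"row {idx}: non-integer {col}={df[col].iloc[idx]!r}")
    vals = vals.astype(np.int64)
    low = vals < minimum
    if low.any():
        idx = int(np.flatnonzero(low.to_numpy())[0])
        raise RowValidationError(f"row {idx}: {col}={vals.iloc[idx]} < {minimum}")
    return vals


def validate_rearrangements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a raw (string-typed) rearrangement table.

    Enforces the row invariants: integer ``mutation_count >= 0``,
    ``duplicate_count >= 1``, junction over {A,C,G,T}, and
    ``junction_length == len(junction)``. Returns a typed copy with
    preserved row order.
    """
    df = df.copy()
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    df["junction_length"] = _coerce_int(df, "junction_length", 0)
    df["mutation_count"] = _coerce_int(df, "mutation_count", 0)
    df["duplicate_count"] = _coerce_int(df, "duplicate_count", 1)
    junction = df["junction"].astype(str)
    bad_alpha = ~junction.str.fullmatch(_JUNCTION_RE.pattern)
    if bad_alpha.any():
        idx = int(np.flatnonzero(bad_alpha.to_numpy())[0])
        raise RowValidationError(
            f"row {idx}: junction {junction.iloc[idx]!r} not over A/C/G/T"
        )
    mismatch = junction.str.len().to_numpy() != df["junction_length"].to_numpy()
    if mismatch.any():
        idx = int(np.flatnonzero(mismatch)[0])
        raise RowValidationError(
            f"row {idx}: junction_length={df['junction_length'].iloc[idx]} "
            f"!= len(junction)={len(junction.iloc[idx])}"
        )
    dup = df["sequence_id"].duplicated()
    if dup.any():
        idx = int(np.flatnonzero(dup.to_numpy())[0])
        raise RowValidationError(
            f"row {idx}: duplicate sequence_id {df['sequence_id'].iloc[idx]!r}"
        )
    for col in ("sequence_id", "participant_id", "v_call", "j_call", "c_call", "junction"):
        df[col] = df[col].astype(str)
    return df[list(REARRANGEMENT_FIELDS)]


def read_rearrangements(
    path, required_fields: tuple[str, ...] = REQUIRED_REARRANGEMENT_FIELDS
) -> pd.DataFrame:
    """Read an AIRR rearrangement TSV into a validated, typed DataFrame.

    An empty file yields an empty (zero-row) table; a missing required
    column raises :class:`~ighrep.errors.SchemaError` naming the column;
    rows failing validation raise :class:`~ighrep.errors.RowValidationError`
    carrying the row index.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        log.info("read 0 rearrangement rows from %s (empty file)", path)
        return validate_rearrangements(
            pd.DataFrame({f: pd.Series(dtype=str) for f in REQUIRED_REARRANGEMENT_FIELDS})
        )
    missing = [c for c in required_fields if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = validate_rearrangements(raw)
    log.info("read %d rearrangement rows from %s (0 rejected)", len(df), path)
    return df


def write_rearrangements(df: pd.DataFrame, path) -> None:
    """Write a rearrangement table in the AIRR TSV dialect."""
    cols = [c for c in REARRANGEMENT_FIELDS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


# --- participant metadata -----------------------------------------------

EXPOSURE_LEVELS = ("never", "former", "cigarette", "vaping", "dual")
GOLD_LEVELS = ("normal", "gold1", "gold2_4", "prism")

REQUIRED_METADATA_FIELDS = (
    "participant_id",
    "exposure_group",
    "age",
    "sex",
    "race",
    "pack_years",
    "gold_group",
    "ics_use",
)

OPTIONAL_METADATA_FIELDS = (
    "income_level",
    "deprivation_index",
    "ct_emphysema_pct",
    "ct_wall_area_pct",
    "ct_scanner",
    "oral_steroids",
)

_SEX_CODES = {"0": 0, "1": 1, "female": 0, "male": 1, "f": 0, "m": 1}
_RACE_CODES = {"0": 0, "1": 1, "aa": 0, "nhw": 1}
_BOOL_CODES = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _map_codes(df: pd.DataFrame, col: str, codes: dict):
    keys = df[col].astype(str).str.strip().str.lower()
    bad = ~keys.isin(codes)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowValidationError(f"row {idx}: invalid {col}={df[col].iloc[idx]!r}")
    return keys.map(codes)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a participant metadata CSV.

    Sex is coded 0=female / 1=male and race 0=AA / 1=NHW (string forms are
    accepted on input). Optional covariates that are absent stay absent —
    they are never imputed. Never-smokers must have ``pack_years == 0``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_METADATA_FIELDS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = raw.copy()
    dups = df["participant_id"][df["participant_id"].duplicated()].unique()
    if len(dups):
        raise RowValidationError(
            "duplicate participant_id(s): " + ", ".join(map(str, dups))
        )
    bad_exp = ~df["exposure_group"].isin(EXPOSURE_LEVELS)
    if bad_exp.any():
        idx = int(np.flatnonzero(bad_exp.to_numpy())[0])
        raise RowValidationError(
            f"row {idx}: unknown exposure_group {df['exposure_group'].iloc[idx]!r}"
        )
    bad_gold = ~df["gold_group"].isin(GOLD_LEVELS)
    if bad_gold.any():
        idx = int(np.flatnonzero(bad_gold.to_numpy())[0])
        raise RowValidationError(
            f"row {idx}: unknown gold_group {df['gold_group'].iloc[idx]!r}"
        )
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
    df["pack_years"] = pd.to_numeric(df["pack_years"], errors="raise").astype(float)
    if (df["pack_years"] < 0).any():
        raise RowValidationError("negative pack_years")
    never_bad = (df["exposure_group"] == "never") & (df["pack_years"] != 0)
    if never_bad.any():
        idx = int(np.flatnonzero(never_bad.to_numpy())[0])
        raise RowValidationError(
            f"row {idx}: never-smoker with pack_years={df['pack_years'].iloc[idx]}"
        )
    df["sex"] = _map_codes(df, "sex", _SEX_CODES).astype(int)
    df["race"] = _map_codes(df, "race", _RACE_CODES).astype(int)
    df["ics_use"] = _map_codes(df, "ics_use", _BOOL_CODES).astype(bool)
    if "oral_steroids" in df.columns:
        df["oral_steroids"] = _map_codes(df, "oral_steroids", _BOOL_CODES).astype(bool)
    numeric_optional = [
        c for c in ("income_level", "deprivation_index", "ct_emphysema_pct",
                    "ct_wall_area_pct")
        if c in df.columns
    ] + [c for c in df.columns if re.fullmatch(r"pc\d+", c)]
    for col in numeric_optional:
        df[col] = pd.to_numeric(df[col].mask(df[col] == ""), errors="coerce")
    log.info("read %d participant metadata rows from %s", len(df), path)
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    """Write a participant metadata CSV."""
    df.to_csv(path, index=False)
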