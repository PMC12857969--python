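"""Reading, validation, filtering and covariate annotation of shelter records.

One row of the canonical record table describes one shelter stay: an intake
date, an outcome date (blank while the animal is still in care), intake and
outcome type codes, a size category, and a date of birth.  ``animal_id`` is
an opaque label and is *not* required to be unique -- an animal returned to
the shelter contributes one row per stay.

Dates are whole calendar days (ISO 8601); all arithmetic is in integer days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

#: Allowed size categories.  PUPPY is treated as a size by shelter software,
#: reflecting uncertainty about a young dog's eventual size.
SIZE_CATEGORIES = ("X-LRG", "LARGE", "MED", "SMALL", "TOY", "PUPPY", "UNKNOWN")

#: Outcome/intake type codes that do not represent regular live admissions
#: (duplicates, expired lost/found reports, surgery scheduling entries, ...).
DEFAULT_DROP_OUTCOME_TYPES = frozenset(
    {"DELETE DUP", "FOUND EXP", "HOME EXP", "LOST EXP", "SURG SCHED", "SURG WAIT"}
)
DEFAULT_DROP_INTAKE_TYPES = frozenset({"DISPO REQ", "EUTH REQ", "WILD"})

#: Canonical column names; a schema mapping renames input headers onto these.
CANONICAL_COLUMNS = (
    "animal_id",
    "intake_date",
    "outcome_date",
    "intake_type",
    "outcome_type",
    "size",
    "date_of_birth",
)

AGE_MIN = 1
AGE_MAX = 15


@dataclass(frozen=True)
class RecordFilterSpec:
    """Which intake/outcome type codes to drop before analysis."""

    drop_outcome_types: frozenset = field(default=DEFAULT_DROP_OUTCOME_TYPES)
    drop_intake_types: frozenset = field(default=DEFAULT_DROP_INTAKE_TYPES)


def read_records(path, schema=None, species="DOG", rejected_report=None):
    """Read a record CSV into the canonical table.

    Parameters
    ----------
    path : str or Path
        CSV file with one row per stay.
    schema : dict, optional
        Mapping from canonical column name to the header used in the file.
        Unmapped canonical names are looked up verbatim.
    species : str or None
        If the file has a ``species`` column, keep only this species
        (case-insensitive).  ``None`` disables the filter.
    rejected_report : str or Path, optional
        Where to write the rejected-rows report.  Defaults to
        ``<path>.rejected.csv``; only written when rows are rejected.

    Returns
    -------
    pandas.DataFrame
        Canonical record table.  Rows with unparseable dates or with an
        outcome before intake are removed and reported.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    schema = dict(schema or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        header = schema.get(canonical, canonical)
        if header not in raw.columns:
            raise SchemaError(f"mapped column {header!r} (for {canonical!r}) not in {path.name}")
        rename[header] = canonical
    if "species" in schema:
        if schema["species"] not in raw.columns:
            raise SchemaError(f"mapped column {schema['species']!r} (for 'species') missing")
        rename[schema["species"]] = "species"
    df = raw.rename(columns=rename)
    keep = [c for c in CANONICAL_COLUMNS + ("species",) if c in df.columns]
    df = df[keep].copy()
    df["_row"] = np.arange(len(df))

    if species is not None and "species" in df.columns:
        df = df[df["species"].str.upper().str.strip() == species.upper()]

    rejects = []

    def _parse_date(col, required):
        blank = df[col].str.strip() == ""
        parsed = pd.to_datetime(df[col].where(~blank), format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & ~blank
        if required:
            bad |= blank
        for idx in df.index[bad]:
            rejects.append({"row": int(df.at[idx, "_row"]), "column": col,
                            "value": df.at[idx, col], "reason": "unparseable or missing date"})
        return parsed, bad

    intake, bad_i = _parse_date("intake_date", required=True)
    outcome, bad_o = _parse_date("outcome_date", required=False)
    dob, bad_d = _parse_date("date_of_birth", required=False)
    df["intake_date"], df["outcome_date"], df["date_of_birth"] = intake, outcome, dob

    inverted = df["outcome_date"].notna() & (df["outcome_date"] < df["intake_date"])
    for idx in df.index[inverted]:
        rejects.append({"row": int(df.at[idx, "_row"]), "column": "outcome_date",
                        "value": str(df.at[idx, "outcome_date"].date()),
                        "reason": "outcome_date before intake_date"})

    bad_rows = bad_i | bad_o | bad_d | inverted
    df = df[~bad_rows].drop(columns="_row").reset_index(drop=True)

    df["size"] = df["size"].str.strip().str.upper().replace("", "UNKNOWN")
    unknown_sizes = ~df["size"].isin(SIZE_CATEGORIES)
    if unknown_sizes.any():
        warnings.warn(
            f"{int(unknown_sizes.sum())} rows with size outside {SIZE_CATEGORIES} set to UNKNOWN"
        )
        df.loc[unknown_sizes, "size"] = "UNKNOWN"

    if rejects:
        report = pd.DataFrame(rejects)
        out = Path(rejected_report) if rejected_report else path.with_suffix(path.suffix + ".rejected.csv")
        report.to_csv(out, index=False)
        warnings.warn(f"{len(rejects)} row problems rejected; report written to {out}")
    return df


def filter_records(records, spec=None):
    """Drop records whose intake or outcome type is on the drop lists.

    Returns ``(kept, removal_counts)`` where ``removal_counts`` maps each
    dropped type code to the number of rows it removed (a row matching both
    an intake and an outcome drop code is counted under the outcome code).
    Idempotent: ``|kept| + sum(counts.values()) == |records|``.
    """
    spec = spec or RecordFilterSpec()
    out_drop = records["outcome_type"].isin(spec.drop_outcome_types)
    in_drop = records["intake_type"].isin(spec.drop_intake_types) & ~out_drop
    counts = {}
    for code, mask_col in (("outcome_type", out_drop), ("intake_type", in_drop)):
        sub = records.loc[mask_col, code].value_counts()
        for key, n in sub.items():
            counts[key] = counts.get(key, 0) + int(n)
    kept = records[~(out_drop | in_drop)].reset_index(drop=True)
    return kept, counts


def _add_years(date, years):
    """date + years calendar years, mapping Feb 29 to Feb 28 off leap years."""
    try:
        return date.replace(year=date.year + years)
    except ValueError:  # Feb 29
        return date.replace(year=date.year + years, day=28)


def _age_one(dob, intake):
    if pd.isna(dob):
        return pd.NA
    if dob > intake:
        warnings.warn(f"date_of_birth {dob.date()} after intake {intake.date()}; age set UNKNOWN")
        return pd.NA
    y = intake.year - dob.year
    if _add_years(dob, y) < intake:
        y += 1
    else:
        while y > 1 and _add_years(dob, y - 1) >= intake:
            y -= 1
    return min(AGE_MAX, max(AGE_MIN, y))


def derive_age(records):
    """Add an ``age`` column: years from birth to intake, rounded up.

    Ages are whole years in {1, ..., 15} (ceiling of the elapsed calendar
    years, floored at 1 and capped at 15 to avoid sparse old-age cells).
    Missing or future dates of birth give a missing age (``pd.NA``), kept
    for unstratified analyses and dropped from age-stratified fits.
    """
    out = records.copy()
    ages = [
        _age_one(dob, intake)
        for dob, intake in zip(out["date_of_birth"], out["intake_date"])
    ]
    out["age"] = pd.array(ages, dtype="Int64")
    return out


def reclassify_size(records):
    """Reclassify PUPPY-sized animals older than 1 year as MED.

    Requires :func:`derive_age` to have run.  Animals with unknown age keep
    the PUPPY label.
    """
    if "age" not in records.columns:
        raise ValidationError("derive_age must run before reclassify_size")
    out = records.copy()
    mask = (out["size"] == "PUPPY") & out["age"].notna() & (out["age"] > 1)
    out.loc[mask, "size"] = "MED"
    return out


def full_los(records, allow_missing=False):
    """Length of stay in days, counting both intake and outcome dates.

    A same-day arrival and departure has LOS 1.  Records without an outcome
    have undefined LOS: an error unless ``allow_missing`` (then ``pd.NA``).
    """
    missing = records["outcome_date"].isna()
    if missing.any() and not allow_missing:
        raise ValidationError(
            f"{int(missing.sum())} records have no outcome_date; LOS undefined"
        )
    days = (records["outcome_date"] - records["intake_date"]).dt.days + 1
    return days.astype("Int64")


def prepare_records(path, schema=None, species="DOG", filter_spec=None):
    """Read + filter + derive age + reclassify size, in the standard order."""
    records = read_records(path, schema=schema, species=species)
    records, counts = filter_records(records, filter_spec)
    records = reclassify_size(derive_age(records))
    return records, counts
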