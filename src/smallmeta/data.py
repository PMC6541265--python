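"""Effect-size tables: row schema, readers/writers, and study-coding rules.

The unit record is one outcome measure of one intervention arm of one primary
study: a correlation-scale effect size ``r`` together with the treatment,
control and total sample sizes behind it.  Five such tables ship with the
package (two study sets on well-being/depression from a 2009 intervention
meta-analysis and three from a 2013 one); they are loaded by name through
:func:`load_dataset`.

Coding rules cover the three data irregularities that occur in practice:
articles that report one overall N only (split equally across groups),
families of articles that report arms of a single underlying study (merged
under one study id), and rows whose statistics are insufficient to compute an
effect size (excluded, with a log line).
"""
from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AVAILABLE_DATA_CODES",
    "DATASET_IDS",
    "EffectRow",
    "StudyEffect",
    "MetaDataset",
    "CodingRules",
    "DEFAULT_CODING_RULES",
    "TableValidationError",
    "CodingConfigError",
    "read_effect_table",
    "write_effect_table",
    "apply_coding_rules",
    "load_dataset",
    "dataset_path",
    "fixture_sha256",
]

#: "available data" codes: which statistics the primary article reported.
AVAILABLE_DATA_CODES = frozenset(
    {
        "post-msds",
        "post-anovaF",
        "post-tpvalue",
        "post-cohend",
        "prepost-msds",
        "prepost-difmsds",
        "prepost-ancovaF",
        "prepost-nomsnosds",
    }
)

#: The five packaged replication study sets.
DATASET_IDS = ("sl2009_wb", "sl2009_dep", "b2013_swb", "b2013_pwb", "b2013_dep")

COLUMNS = ["study_id", "available_data", "measure", "intervention",
           "n_t", "n_c", "n_total", "r"]


class TableValidationError(ValueError):
    """An effect table violates the row schema (named row in the message)."""


class CodingConfigError(ValueError):
    """A coding-rule configuration refers to unknown studies."""


@dataclass(frozen=True)
class EffectRow:
    """One outcome x intervention x study record of an effect table."""

    study_id: str
    available_data: str
    measure: str
    intervention: str
    n_t: int | None
    n_c: int | None
    n_total: int | None
    r: float | None

    def is_missing(self) -> bool:
        return self.r is None or (isinstance(self.r, float) and math.isnan(self.r))


@dataclass(frozen=True)
class StudyEffect:
    """One aggregated effect per study, on both the r and Fisher-z scales.

    ``var_z`` is the large-sample variance 1/(n_eff - 3) of the z transform,
    where ``n_eff`` is the study's effective per-comparison sample size.
    """

    study_id: str
    r: float
    z: float
    var_z: float
    n_eff: float
    n_rows: int

    def __post_init__(self):
        if not self.var_z > 0:
            raise ValueError(f"{self.study_id}: var_z must be positive")
        if self.n_eff < 4:
            raise ValueError(f"{self.study_id}: n_eff must be at least 4")
        if abs(self.z - math.atanh(self.r)) > 1e-8:
            raise ValueError(f"{self.study_id}: z must equal atanh(r)")


def _parse_num(value, row_label: str, column: str, kind=float):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan"):
        return None
    try:
        return kind(float(s))
    except (TypeError, ValueError) as exc:
        raise TableValidationError(
            f"row {row_label}: malformed numeric cell {column}={value!r}"
        ) from exc


def read_effect_table(path) -> pd.DataFrame:
    """Read a per-outcome effect table (CSV) into a validated DataFrame.

    ``NA`` cells parse as missing.  Raises :class:`TableValidationError` when a
    numeric cell is malformed, when ``n_t + n_c != n_total`` on a fully
    reported row, or when a (study_id, measure, intervention) triple repeats.
    Rows are returned in file order.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise TableValidationError(f"missing columns: {missing_cols}")
    records = []
    for i, row in raw.iterrows():
        label = f"{i + 1} ({row['study_id']})"
        n_t = _parse_num(row["n_t"], label, "n_t", int)
        n_c = _parse_num(row["n_c"], label, "n_c", int)
        n_total = _parse_num(row["n_total"], label, "n_total", int)
        r = _parse_num(row["r"], label, "r")
        if r is not None and not -1.0 <= r <= 1.0:
            raise TableValidationError(f"row {label}: r={r} outside [-1, 1]")
        if None not in (n_t, n_c, n_total) and n_t + n_c != n_total:
            raise TableValidationError(
                f"row {label}: n_t + n_c = {n_t + n_c} != n_total = {n_total}"
            )
        records.append(
            {
                "study_id": row["study_id"],
                "available_data": row["available_data"],
                "measure": row["measure"],
                "intervention": row["intervention"],
                "n_t": n_t,
                "n_c": n_c,
                "n_total": n_total,
                "r": np.nan if r is None else r,
            }
        )
    df = pd.DataFrame(records, columns=COLUMNS)
    dup = df.duplicated(subset=["study_id", "measure", "intervention"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise TableValidationError(
            "duplicate (study_id, measure, intervention): "
            f"{first['study_id']}/{first['measure']}/{first['intervention']}"
        )
    for col in ("n_t", "n_c", "n_total"):
        df[col] = df[col].astype("Int64")
    return df


def _format_r(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    s = f"{value:.2f}"
    return s.replace("0.", ".", 1) if abs(value) < 1 else s


def write_effect_table(df: pd.DataFrame, path) -> None:
    """Write an effect table in the canonical fixture format (r as .xx, NA)."""
    out = df.copy()
    out["r"] = [_format_r(v) for v in df["r"]]
    for col in ("n_t", "n_c", "n_total"):
        out[col] = ["NA" if pd.isna(v) else str(int(v)) for v in df[col]]
    out.to_csv(path, index=False)


def iter_rows(df: pd.DataFrame) -> Iterable[EffectRow]:
    """Typed row access for a validated effect table."""
    for _, row in df.iterrows():
        yield EffectRow(
            study_id=row["study_id"],
            available_data=row["available_data"],
            measure=row["measure"],
            intervention=row["intervention"],
            n_t=None if pd.isna(row["n_t"]) else int(row["n_t"]),
            n_c=None if pd.isna(row["n_c"]) else int(row["n_c"]),
            n_total=None if pd.isna(row["n_total"]) else int(row["n_total"]),
            r=None if pd.isna(row["r"]) else float(row["r"]),
        )


# ---------------------------------------------------------------------------
# Coding rules
# ---------------------------------------------------------------------------

#: Four articles that report arms of one underlying study; analysed as one.
DEFAULT_MERGE_MAP: Mapping[str, str] = {
    "Mongrain.2011.1": "Mongrain.2011-2013.1",
    "Mongrain.2012.1": "Mongrain.2011-2013.1",
    "Shapira.2010.1": "Mongrain.2011-2013.1",
    "Sergeant.2011.1": "Mongrain.2011-2013.1",
}


@dataclass(frozen=True)
class CodingRules:
    """How raw table rows are prepared for aggregation.

    merge_map
        original study id -> merged study id, for articles that report arms of
        the same underlying study.  Ids absent from a given table are ignored
        unless ``strict``.
    equal_split
        impute missing group sizes by splitting ``n_total`` equally over the
        treatment and control groups (odd participant to treatment).
    drop_missing
        exclude rows whose effect size is missing and cannot be recovered.
    strict
        raise :class:`CodingConfigError` if the merge map names a study id not
        present in the table.
    """

    merge_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_MERGE_MAP))
    equal_split: bool = True
    drop_missing: bool = True
    strict: bool = False


DEFAULT_CODING_RULES = CodingRules()


def apply_coding_rules(df: pd.DataFrame, rules: CodingRules = DEFAULT_CODING_RULES) -> pd.DataFrame:
    """Apply group-size imputation, study merging and missing-row exclusion.

    Returns a new DataFrame with two extra columns: ``source_id`` (the original
    article id) and ``study_id`` rewritten per the merge map.  Every exclusion
    and imputation is logged.
    """
    if rules.strict:
        unknown = set(rules.merge_map) - set(df["study_id"])
        if unknown:
            raise CodingConfigError(f"merge map names unknown studies: {sorted(unknown)}")
    out = df.copy()
    out["source_id"] = out["study_id"]
    out["study_id"] = out["study_id"].map(lambda s: rules.merge_map.get(s, s))

    if rules.equal_split:
        needs = out["n_t"].isna() & out["n_c"].isna() & out["n_total"].notna()
        for i in out.index[needs]:
            total = int(out.at[i, "n_total"])
            n_c = total // 2
            n_t = total - n_c  # odd participant to treatment
            out.at[i, "n_t"] = n_t
            out.at[i, "n_c"] = n_c
            logger.info(
                "imputed group sizes for %s/%s: n_total=%d -> n_t=%d, n_c=%d",
                out.at[i, "source_id"], out.at[i, "measure"], total, n_t, n_c,
            )

    if rules.drop_missing:
        missing = out["r"].isna()
        for i in out.index[missing]:
            logger.info(
                "excluded %s/%s/%s: no effect size recoverable (%s)",
                out.at[i, "source_id"], out.at[i, "measure"],
                out.at[i, "intervention"], out.at[i, "available_data"],
            )
        out = out[~missing].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Packaged datasets
# ---------------------------------------------------------------------------

def dataset_path(dataset_id: str):
    """Path-like resource handle for a packaged study-set CSV."""
    key = dataset_id.lower()
    if key not in DATASET_IDS:
        raise KeyError(f"unknown dataset {dataset_id!r}; expected one of {DATASET_IDS}")
    return resources.files("smallmeta.datasets") / f"{key}.csv"


def load_dataset(dataset_id: str, rules: CodingRules | None = DEFAULT_CODING_RULES) -> pd.DataFrame:
    """Load a packaged study set; apply coding rules unless ``rules`` is None."""
    with resources.as_file(dataset_path(dataset_id)) as path:
        df = read_effect_table(path)
    if rules is not None:
        df = apply_coding_rules(df, rules)
    return df


def fixture_sha256(dataset_id: str) -> str:
    """Checksum of the shipped fixture, to guard against transcription drift."""
    data = dataset_path(dataset_id).read_bytes()
    return hashlib.sha256(data).hexdigest()


@dataclass
class MetaDataset:
    """A study set: raw rows plus (lazily) the aggregated study-level table."""

    dataset_id: str
    rows: pd.DataFrame
    studies: pd.DataFrame | None = None

    @classmethod
    def from_packaged(cls, dataset_id: str, rules: CodingRules = DEFAULT_CODING_RULES) -> "MetaDataset":
        return cls(dataset_id=dataset_id.lower(), rows=load_dataset(dataset_id, rules))

    def aggregate(self, within_r: float = 0.5, method: str = "composite") -> pd.DataFrame:
        from .aggregate import aggregate_dataset

        self.studies = aggregate_dataset(self.rows, within_r=within_r, method=method)
        return self.studies
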