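"""Reading, validation, standardization and merging of expression and clinical data.

Expression matrices are probes x samples, log2-scale intensities (already
RMA-normalized upstream; this package performs no background correction).
Two on-disk dialects are supported: a plain TSV with a ``probe_id`` first
column, and the GEO series-matrix dialect where the table is delimited by
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` marker lines
and probe ids may be quoted.

Clinical tables are CSV with columns ``sample_id,response,age,er_status,
grade,node``; ``response`` is the binary pathological endpoint (pCR =
complete response, RD = residual disease). Missing values are encoded as
empty cells or ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_PCR = "pCR"
RESPONSE_RD = "RD"

_RESPONSE_TOKENS = {"pcr": RESPONSE_PCR, "rd": RESPONSE_RD}
_ER_TOKENS = {"positive": "positive", "negative": "negative", "pos": "positive", "neg": "negative"}
_NODE_TOKENS = _ER_TOKENS
_MISSING_TOKENS = {"", "na", "nan", "none", "missing"}

CLINICAL_COLUMNS = ["response", "age", "er_status", "grade", "node"]


class ExpressionLoadError(ValueError):
    """Raised when an expression file violates the matrix contract."""


class ClinicalLoadError(ValueError):
    """Raised when a clinical table contains unusable values."""


@dataclass
class ExpressionMatrix:
    """A probes-x-samples real matrix from one cohort.

    ``values`` is a DataFrame indexed by probe id with sample ids as
    columns. ``standardized`` records whether each probe row has been
    z-scored within this dataset; merged multi-cohort matrices keep the
    flag because standardization happened per source dataset.
    """

    cohort_id: str
    values: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ExpressionLoadError(f"duplicate probe id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ExpressionLoadError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ExpressionLoadError(
                f"non-finite value at probe {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ClinicalTable:
    """Per-sample response and covariates, indexed by unique sample id."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ClinicalLoadError(f"duplicate sample id: {dup!r}")
        for col in CLINICAL_COLUMNS:
            if col not in self.data.columns:
                self.data[col] = np.nan
        bad = set(self.data["response"].dropna()) - {RESPONSE_PCR, RESPONSE_RD}
        if bad:
            raise ClinicalLoadError(f"invalid response values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def response(self) -> pd.Series:
        return self.data["response"]

    def response_counts(self) -> dict[str, int]:
        r = self.data["response"]
        return {
            RESPONSE_PCR: int((r == RESPONSE_PCR).sum()),
            RESPONSE_RD: int((r == RESPONSE_RD).sum()),
            "missing": int(r.isna().sum()),
        }

    def with_response(self) -> "ClinicalTable":
        """Subset to samples whose response is known."""
        return ClinicalTable(self.data[self.data["response"].notna()].copy())


def _finalize_expression(df: pd.DataFrame, cohort_id: str, path: Path) -> ExpressionMatrix:
    probe_col = df.columns[0]
    probes = df[probe_col].astype(str).str.strip().str.strip('"')
    dup = probes[probes.duplicated()]
    if len(dup):
        raise ExpressionLoadError(f"{path}: duplicate probe id: {dup.iloc[0]!r}")
    body = df.drop(columns=[probe_col])
    body.index = pd.Index(probes, name="probe_id")
    body.columns = [str(c).strip().strip('"') for c in body.columns]
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            probe = body.index[bad][0]
            raise ExpressionLoadError(
                f"{path}: non-numeric cell at probe {probe!r}, sample {col!r}: "
                f"{body.loc[probe, col]!r}"
            )
        if converted.isna().any():
            probe = body.index[converted.isna()][0]
            raise ExpressionLoadError(f"{path}: missing value at probe {probe!r}, sample {col!r}")
    # astype on the raw strings is correctly-rounded, so repr output round-trips
    m = ExpressionMatrix(cohort_id=cohort_id, values=body.astype(float), standardized=False)
    logger.info("loaded %s: %d probes x %d samples", path, m.n_probes, m.n_samples)
    return m


def read_expression(
    path: str | Path, format: str = "tabular", cohort_id: str | None = None
) -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``format`` is ``"tabular"`` (TSV, first column ``probe_id``) or
    ``"series_matrix"`` (GEO series-matrix dialect). The returned matrix is
    unstandardized; the cohort id defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cohort_id = cohort_id or path.stem
    if format == "tabular":
        df = pd.read_csv(path, sep="\t", dtype=str)
    elif format == "series_matrix":
        lines = []
        inside = False
        for line in path.read_text().splitlines():
            if line.strip() == "!series_matrix_table_begin":
                inside = True
                continue
            if line.strip() == "!series_matrix_table_end":
                inside = False
                break
            if inside:
                lines.append(line)
        if not lines:
            raise ExpressionLoadError(f"{path}: no series_matrix table markers found")
        from io import StringIO

        df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", dtype=str)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tabular' or 'series_matrix'")
    if df.shape[1] < 2:
        raise ExpressionLoadError(f"{path}: expected probe column plus at least one sample")
    return _finalize_expression(df, cohort_id, path)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the tabular TSV dialect; round-trips bit-identically via repr."""
    path = Path(path)
    out = m.values.copy()
    out.index.name = "probe_id"
    # repr formatting preserves float values exactly on reload
    out.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def _norm_token(raw: object, mapping: dict[str, str], what: str, path: Path) -> object:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    token = str(raw).strip()
    if token.lower() in _MISSING_TOKENS:
        return np.nan
    if token.lower() in mapping:
        return mapping[token.lower()]
    raise ClinicalLoadError(
        f"{path}: unknown {what} token {token!r}; accepted: "
        f"{sorted(set(mapping.values()))} or NA/empty"
    )


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical CSV; enum tokens are normalized case-insensitively."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if "sample_id" not in df.columns or "response" not in df.columns:
        raise ClinicalLoadError(f"{path}: required columns sample_id and response")
    out = pd.DataFrame(index=pd.Index(df["sample_id"].astype(str).str.strip(), name="sample_id"))
    out["response"] = [_norm_token(v, _RESPONSE_TOKENS, "response", path) for v in df["response"]]
    if "age" in df.columns:
        ages = []
        for v in df["age"]:
            if str(v).strip().lower() in _MISSING_TOKENS:
                ages.append(np.nan)
            else:
                a = float(v)
                if a < 0:
                    raise ClinicalLoadError(f"{path}: negative age {v!r}")
                ages.append(a)
        out["age"] = ages
    if "er_status" in df.columns:
        out["er_status"] = [_norm_token(v, _ER_TOKENS, "er_status", path) for v in df["er_status"]]
    if "node" in df.columns:
        out["node"] = [_norm_token(v, _NODE_TOKENS, "node", path) for v in df["node"]]
    if "grade" in df.columns:
        grades = []
        for v in df["grade"]:
            if str(v).strip().lower() in _MISSING_TOKENS:
                grades.append(np.nan)
            elif str(v).strip() in {"1", "2", "3"}:
                grades.append(int(str(v).strip()))
            else:
                raise ClinicalLoadError(f"{path}: grade must be 1, 2, 3 or NA; got {v!r}")
        out["grade"] = grades
    table = ClinicalTable(out)
    logger.info("loaded %s: %d samples, response counts %s", path, len(out), table.response_counts())
    return table


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    out = t.data[CLINICAL_COLUMNS].copy()
    out["grade"] = out["grade"].map(lambda g: "" if pd.isna(g) else str(int(g)))
    out.to_csv(path, na_rep="")


def standardize(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Z-score each probe row within this dataset (mean 0, sd 1, ddof=1).

    Zero-variance probes cannot be scaled and are dropped; their ids are
    returned alongside the transformed matrix. Standardizing twice is an
    error because silent double transformation corrupts index scores.
    """
    if m.standardized:
        raise ValueError(f"cohort {m.cohort_id!r} is already standardized")
    if m.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples (sample sd, ddof=1)")
    vals = m.values
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0.0
    dropped = list(vals.index[flat])
    if dropped:
        logger.warning(
            "cohort %s: dropping %d zero-variance probes (first: %s)",
            m.cohort_id, len(dropped), dropped[0],
        )
        vals = vals.loc[~flat]
        sd = sd[~flat]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(cohort_id=m.cohort_id, values=z, standardized=True), dropped


def merge_cohorts(
    matrices: list[ExpressionMatrix], clinicals: list[ClinicalTable]
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Column-concatenate per-dataset-standardized cohorts on common probes.

    Standardization is strictly per dataset and happens before merging; the
    merged matrix is never re-standardized. Samples whose response is
    missing are dropped (their count is logged), matching how validation
    cohorts are pooled.
    """
    if len(matrices) != len(clinicals):
        raise ValueError("need one clinical table per expression matrix")
    if not matrices:
        raise ValueError("nothing to merge")
    for m in matrices:
        if not m.standardized:
            raise ValueError(f"cohort {m.cohort_id!r} must be standardized before merging")
    common = matrices[0].values.index
    for m in matrices[1:]:
        common = common.intersection(m.values.index)
    if len(common) == 0:
        raise ValueError("empty probe intersection across cohorts")
    common = matrices[0].values.index[matrices[0].values.index.isin(common)]

    seen: set[str] = set()
    for m in matrices:
        clash = seen & set(m.sample_ids)
        if clash:
            raise ValueError(f"sample id collision across cohorts: {sorted(clash)[:5]}")
        seen |= set(m.sample_ids)

    expr = pd.concat([m.values.loc[common] for m in matrices], axis=1)
    clin = pd.concat([c.data for c in clinicals], axis=0)
    if clin.index.has_duplicates:
        raise ValueError("sample id collision across clinical tables")
    clin = clin.reindex(expr.columns)

    missing = clin["response"].isna()
    n_dropped = int(missing.sum())
    if n_dropped:
        logger.info("merge: dropping %d samples with missing response", n_dropped)
    keep = clin.index[~missing]
    merged_id = "+".join(m.cohort_id for m in matrices)
    merged = ExpressionMatrix(cohort_id=merged_id, values=expr[keep], standardized=True)
    return merged, ClinicalTable(clin.loc[keep])
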