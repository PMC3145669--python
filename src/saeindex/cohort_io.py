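"""Expression-cohort I/O and per-chip normalization.

The analysis consumes probe-set-level microarray summaries (linear scale,
probes x samples) together with optional Present/Marginal/Absent detection
calls, a phenotype table and a probe -> gene-symbol annotation.  Two text
dialects are supported: a plain TSV matrix (probe rows, sample columns) and
the GEO Series Matrix format (the table between its begin/end marker lines).

Normalization follows the classic MAS5-era convention: floor every
measurement at 0.01, then scale each array so its median equals 1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("saeindex")

#: floor applied to linear expression values before median scaling
EXPRESSION_FLOOR = 0.01

#: recognized phenotype groups
GROUPS = ("nonsmoker", "healthy_smoker", "copd")

#: required phenotype-table columns
PHENOTYPE_COLUMNS = ("sample_id", "subject_id", "group", "set", "timepoint")


class CohortError(ValueError):
    """User-facing error in cohort inputs (malformed file, bad invariant)."""


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise CohortError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Linear-scale expression values, probes x samples.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample-id columns.
    calls
        Optional detection-call DataFrame with identical index/columns,
        entries in ``{"P", "M", "A"}``.
    normalized
        True once :func:`normalize_per_chip` has been applied (floored at
        0.01, per-sample median 1).
    """

    values: pd.DataFrame
    calls: Optional[pd.DataFrame] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        if self.calls is not None:
            if not (
                self.calls.index.equals(self.values.index)
                and self.calls.columns.equals(self.values.columns)
            ):
                raise CohortError(
                    "calls matrix must share the value matrix's probe and "
                    "sample ordering"
                )
            bad = set(np.unique(self.calls.to_numpy())) - {"P", "M", "A"}
            if bad:
                raise CohortError(f"invalid detection-call symbols: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise CohortError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(
            values=self.values.loc[:, list(samples)],
            calls=None if self.calls is None else self.calls.loc[:, list(samples)],
            normalized=self.normalized,
        )

    def log2(self) -> pd.DataFrame:
        """log2-transformed values (used throughout the downstream stats)."""
        return np.log2(self.values)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _finalize_matrix(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    _check_unique(df.index.astype(str), "probe")
    _check_unique(df.columns.astype(str), "sample")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad.to_numpy().argmax()]
            raise CohortError(
                f"non-numeric cell at probe {probe!r}, sample {col!r} in {path}"
            )
        if converted.isna().any():
            probe = df.index[converted.isna().to_numpy().argmax()]
            raise CohortError(
                f"missing cell at probe {probe!r}, sample {col!r} in {path}"
            )
        df[col] = converted
    return df.astype(float)


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=object,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = header[1:]
    df[df == ""] = np.nan
    return _finalize_matrix(df, path)


def _read_series_matrix(path: str | Path, label_source: str = "title") -> pd.DataFrame:
    """Parse the table of a GEO Series Matrix file.

    ``label_source`` picks sample labels from the ``!Sample_title`` line
    (default) or the accession header row (``"accession"``).
    """
    titles: Optional[list[str]] = None
    table: list[list[str]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if in_table:
                table.append(next(csv.reader([stripped], delimiter="\t")))
            elif stripped.startswith("!Sample_title"):
                titles = next(csv.reader([stripped], delimiter="\t"))[1:]
    if not table:
        raise CohortError(f"no series-matrix table found in {path}")
    header, *rows = table
    sample_ids = header[1:]
    if label_source == "title":
        if titles is None:
            logger.warning("series matrix %s has no !Sample_title line; "
                           "falling back to accession ids", path)
        elif len(titles) != len(sample_ids):
            raise CohortError("sample-title count does not match table width")
        else:
            sample_ids = titles
    elif label_source != "accession":
        raise CohortError(f"unknown label_source {label_source!r}")
    _check_unique(sample_ids, "sample")
    df = pd.DataFrame(
        [r[1:] for r in rows],
        index=pd.Index([r[0] for r in rows], name=header[0]),
        columns=sample_ids,
        dtype=object,
    )
    df[df == ""] = np.nan
    return _finalize_matrix(df, path)


def read_expression(
    path: str | Path,
    format: str = "tsv",
    calls_path: Optional[str | Path] = None,
    label_source: str = "title",
) -> ExpressionMatrix:
    """Read an expression matrix; ``format`` is ``"tsv"`` or ``"series_matrix"``.

    The returned matrix is un-normalized; ordering follows the file.
    """
    if format == "tsv":
        values = _read_tsv_matrix(path)
    elif format == "series_matrix":
        values = _read_series_matrix(path, label_source=label_source)
    else:
        raise CohortError(f"unknown expression format {format!r}")
    calls = None
    if calls_path is not None:
        calls = read_calls(calls_path)
        calls = calls.loc[values.index, values.columns]
    return ExpressionMatrix(values=values, calls=calls, normalized=False)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the values as a probe-rows TSV (the package's only orientation)."""
    m.values.to_csv(path, sep="\t", float_format="%.17g")


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    return df


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV and validate its required columns."""
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return validate_phenotypes(pheno)


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise CohortError(f"phenotype table lacks required columns: {missing}")
    if pheno["group"].isna().any() or pheno["set"].isna().any():
        raise CohortError("phenotype group/set must be non-missing")
    bad_groups = set(pheno["group"]) - set(GROUPS)
    if bad_groups:
        raise CohortError(f"unknown phenotype groups: {sorted(bad_groups)}")
    dup = pheno.duplicated(subset=["sample_id"])
    if dup.any():
        raise CohortError(
            f"duplicate sample_id in phenotype table: {pheno.loc[dup, 'sample_id'].iloc[0]!r}"
        )
    pheno = pheno.copy()
    pheno["timepoint"] = pheno["timepoint"].astype(int)
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.Series:
    """Read a probe_id -> gene_symbol TSV; empty symbol means unknown gene."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise CohortError("annotation TSV needs probe_id and gene_symbol columns")
    probe, symbol = df.columns[:2]
    dup = df.duplicated(subset=[probe])
    if dup.any():
        raise CohortError(f"duplicate probe in annotation: {df.loc[dup, probe].iloc[0]!r}")
    ann = pd.Series(df[symbol].to_numpy(), index=pd.Index(df[probe], name="probe_id"),
                    name="gene_symbol")
    return ann.fillna("")


def write_annotation(ann: pd.Series, path: str | Path) -> None:
    ann.rename("gene_symbol").rename_axis("probe_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# normalization and detection-call summaries
# ---------------------------------------------------------------------------

def normalize_per_chip(m: ExpressionMatrix) -> ExpressionMatrix:
    """Floor values at 0.01, then scale each sample to median 1.

    The floor is applied before the median is computed, so an all-zero
    sample normalizes to all-ones (its floored median is the floor itself).
    Re-normalizing an already normalized matrix is an error.
    """
    if m.normalized:
        raise CohortError("matrix is already normalized")
    if m.values.empty:
        raise CohortError("cannot normalize an empty matrix")
    floored = m.values.clip(lower=EXPRESSION_FLOOR)
    medians = floored.median(axis=0)
    out = floored / medians
    return ExpressionMatrix(values=out,
                            calls=None if m.calls is None else m.calls.copy(),
                            normalized=True)


def present_fraction(
    m: ExpressionMatrix,
    samples: Optional[Sequence[str]] = None,
    assume_present: bool = False,
) -> pd.Series:
    """Per-probe fraction of Present detection calls over ``samples``.

    Marginal and Absent both count as not-present.  Without a calls matrix
    the caller must either supply one or opt into ``assume_present`` (every
    probe treated as fully Present), which is logged loudly because it
    disables the detection filter.
    """
    cols = list(m.sample_ids if samples is None else samples)
    if not cols:
        raise CohortError("present_fraction needs at least one sample")
    if m.calls is None:
        if assume_present:
            logger.warning(
                "no detection calls available: ASSUMING every probe Present "
                "in all %d samples (detection filter disabled)", len(cols)
            )
            return pd.Series(1.0, index=m.probe_ids, name="present_fraction")
        raise CohortError(
            "no detection calls on this matrix; supply a calls matrix or "
            "pass assume_present=True (--assume-present) to treat all "
            "probes as Present"
        )
    missing = [c for c in cols if c not in m.calls.columns]
    if missing:
        raise CohortError(f"calls matrix lacks samples: {missing}")
    frac = (m.calls.loc[:, cols] == "P").mean(axis=1)
    frac.name = "present_fraction"
    return frac
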