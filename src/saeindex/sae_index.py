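"""The I_SAE index: per-subject fraction of signature genes out of range.

For every index-eligible signature gene a *normal range* is built from the
nonsmoker reference: the log2 mean and SD of the reference samples define a
one-sided threshold two SDs from the mean **in the smoking-induced
direction** (mean + 2 SD for smoking-induced genes, mean - 2 SD for
smoking-suppressed genes).  A sample scores an abnormality indicator
E_g = 1 for gene g when its log2 value lies strictly beyond the threshold
in that direction, and

    I_SAE = c * sum_g E_g,    c = 100 / N

with N the number of index genes, i.e. the percent of index genes the
subject expresses outside the nonsmoker range.  Healthy smokers at or
below the median I_SAE are "low" responders; those above are "high".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .signature import AnalysisError, SmokingSignature

logger = logging.getLogger("saeindex")

#: number of reference SDs defining the normal range
SD_MULTIPLIER = 2.0


@dataclass
class NormalRangeSet:
    """Per-index-gene reference statistics and directional thresholds.

    ``table`` is indexed by probe_id with columns gene_symbol, mean, sd
    (log2 units, reference samples, n-1 denominator), direction and
    threshold (mean + k*sd for 'up' genes, mean - k*sd for 'down').
    """

    table: pd.DataFrame
    n_reference: int
    sd_multiplier: float = SD_MULTIPLIER

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, n_reference: int = 0,
                 sd_multiplier: float = SD_MULTIPLIER) -> "NormalRangeSet":
        table = pd.read_csv(path, sep="\t", index_col=0,
                            dtype={"gene_symbol": str}, keep_default_na=False)
        for col in ("mean", "sd", "threshold"):
            table[col] = pd.to_numeric(table[col])
        return cls(table=table, n_reference=n_reference, sd_multiplier=sd_multiplier)


@dataclass
class IndexResult:
    """Per-sample abnormality indicators and I_SAE values.

    ``indicators`` is a 0/1 DataFrame (index genes x samples); ``isae`` is
    the per-sample percent of index genes out of range.
    """

    indicators: pd.DataFrame
    n_genes: int

    @property
    def abnormal_counts(self) -> pd.Series:
        return self.indicators.sum(axis=0).rename("abnormal_count")

    @property
    def isae(self) -> pd.Series:
        return (100.0 * self.abnormal_counts / self.n_genes).rename("isae_percent")

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    def summary(self, labels: Optional[pd.Series] = None) -> pd.DataFrame:
        out = pd.DataFrame({
            "abnormal_count": self.abnormal_counts,
            "n_index_genes": self.n_genes,
            "isae_percent": self.isae,
        })
        out.index.name = "sample_id"
        if labels is not None:
            out["label"] = labels.reindex(out.index)
        return out


@dataclass
class ResponderLabels:
    """Low/high responder labels for healthy smokers.

    ``labels`` maps sample_id -> 'low' | 'high' (NaN for the unlabeled
    middle under the quantile rule).  ``boundary`` is the I_SAE value(s)
    actually used: the median under the median rule, a (low_cut, high_cut)
    pair under quantile(alpha).
    """

    labels: pd.Series
    rule: str
    boundary: float | tuple[float, float]

    def samples(self, which: str) -> list[str]:
        return list(self.labels.index[self.labels == which])


def fit_normal_ranges(
    m: ExpressionMatrix,
    sig: SmokingSignature,
    reference: Sequence[str],
    sd_multiplier: float = SD_MULTIPLIER,
    ddof: int = 1,
) -> NormalRangeSet:
    """Fit directional 2-SD normal ranges from reference (nonsmoker) samples.

    The SD uses the n-1 denominator by default (``ddof`` configurable).  A
    zero-SD gene collapses its threshold onto the mean and is logged; any
    strictly more extreme value still counts as abnormal.
    """
    reference = list(reference)
    if len(reference) < 2:
        raise AnalysisError("reference needs >= 2 samples (SD undefined for 1)")
    eligible = sig.table[sig.table["index_eligible"]]
    if eligible.empty:
        raise AnalysisError("signature has no index-eligible genes")
    missing = [p for p in eligible.index if p not in m.values.index]
    if missing:
        raise AnalysisError(f"index genes missing from matrix: {missing[:5]}")
    logv = np.log2(m.values.loc[eligible.index, reference].to_numpy())
    mean = logv.mean(axis=1)
    sd = logv.std(axis=1, ddof=ddof)
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("%d index genes with zero reference SD: threshold = mean",
                       int(zero_sd.sum()))
    sign = np.where(eligible["direction"].to_numpy() == "up", 1.0, -1.0)
    table = pd.DataFrame(
        {
            "gene_symbol": eligible["gene_symbol"].to_numpy(),
            "mean": mean,
            "sd": sd,
            "direction": eligible["direction"].to_numpy(),
            "threshold": mean + sign * sd_multiplier * sd,
        },
        index=eligible.index,
    )
    return NormalRangeSet(table=table, n_reference=len(reference),
                          sd_multiplier=sd_multiplier)


def compute_isae(
    m: ExpressionMatrix,
    ranges: NormalRangeSet,
    samples: Optional[Sequence[str]] = None,
) -> IndexResult:
    """Score samples against the normal ranges.

    E_g = 1 iff log2(value) lies strictly beyond the gene's threshold in
    the smoking direction (above for 'up' genes, below for 'down');
    abnormality is one-sided only.
    """
    cols = list(m.sample_ids if samples is None else samples)
    missing = [p for p in ranges.table.index if p not in m.values.index]
    if missing:
        raise AnalysisError(f"index genes missing from matrix: {missing[:5]}")
    logv = np.log2(m.values.loc[ranges.table.index, cols].to_numpy())
    thr = ranges.table["threshold"].to_numpy()[:, None]
    up = (ranges.table["direction"].to_numpy() == "up")[:, None]
    exceed = np.where(up, logv > thr, logv < thr)
    indicators = pd.DataFrame(exceed.astype(np.int8), index=ranges.table.index,
                              columns=pd.Index(cols, name="sample_id"))
    return IndexResult(indicators=indicators, n_genes=ranges.n_genes)


def classify_responders(
    isae: pd.Series,
    rule: str = "median",
    alpha: Optional[float] = None,
) -> ResponderLabels:
    """Split healthy smokers into low/high responders by I_SAE.

    Median rule: low iff I_SAE <= median (ties go low), high above.
    Quantile rule: the top ``alpha`` fraction are high, the bottom
    ``alpha`` fraction low, the middle unlabeled; counts are
    floor(alpha * n) per side.
    """
    isae = isae.astype(float)
    if rule == "median":
        if len(isae) < 2:
            raise AnalysisError("median split needs >= 2 smokers")
        boundary = float(isae.median())
        labels = pd.Series(np.where(isae <= boundary, "low", "high"),
                           index=isae.index, name="label")
        if isae.nunique() == 1:
            logger.warning("all I_SAE values identical: every smoker labeled low")
        return ResponderLabels(labels=labels, rule="median", boundary=boundary)
    if rule == "quantile":
        if alpha is None or not (0 < alpha <= 0.5):
            raise AnalysisError("quantile rule needs alpha in (0, 0.5]")
        n = len(isae)
        k = int(np.floor(alpha * n + 1e-12))
        if k < 1:
            raise AnalysisError(f"alpha={alpha} selects no samples from n={n}")
        order = isae.sort_values(kind="mergesort")
        low_ids, high_ids = order.index[:k], order.index[-k:]
        labels = pd.Series(np.nan, index=isae.index, dtype=object, name="label")
        labels.loc[low_ids] = "low"
        labels.loc[high_ids] = "high"
        boundary = (float(order.iloc[k - 1]), float(order.iloc[-k]))
        return ResponderLabels(labels=labels, rule=f"quantile({alpha})",
                               boundary=boundary)
    raise AnalysisError(f"unknown split rule {rule!r}")


def label_against_boundary(isae: pd.Series, boundary: float) -> pd.Series:
    """Label samples by the side of a frozen median boundary (<= is low)."""
    return pd.Series(np.where(isae.astype(float) <= boundary, "low", "high"),
                     index=isae.index, name="label")


def range_membership(
    query: pd.Series,
    reference: pd.Series,
    mode: str = "at_least_min",
) -> tuple[pd.Series, float]:
    """Fraction of query samples inside the reference I_SAE range.

    ``interval`` counts min <= value <= max of the reference;
    ``at_least_min`` (default) counts value >= min, so queries exceeding
    the reference maximum still count as range-like.
    """
    if len(reference) == 0:
        raise AnalysisError("reference set is empty")
    lo, hi = float(reference.min()), float(reference.max())
    if mode == "interval":
        member = (query >= lo) & (query <= hi)
    elif mode == "at_least_min":
        member = query >= lo
    else:
        raise AnalysisError(f"unknown membership mode {mode!r}")
    member = member.rename("in_range")
    return member, float(member.mean())


@dataclass
class StabilityReport:
    """Responder-label retention between two bronchoscopy timepoints."""

    table: pd.DataFrame      # subject, isae_t1, isae_t2, label_t1, label_t2, retained
    retention: float
    boundary: float


def stability_over_time(
    isae_t1: pd.Series,
    isae_t2: pd.Series,
    labels_t1: ResponderLabels,
) -> StabilityReport:
    """Label retention across timepoints, keyed by subject.

    Timepoint-2 values must already be scored against the timepoint-1
    ranges; the timepoint-1 median boundary is frozen, so a subject's
    timepoint-2 label is simply which side of that boundary it falls on.
    Subjects missing from either timepoint are excluded with a warning.
    """
    if not isinstance(labels_t1.boundary, (int, float)):
        raise AnalysisError("stability analysis needs a median-rule boundary")
    labeled = labels_t1.labels.dropna()
    paired = [s for s in labeled.index if s in isae_t1.index and s in isae_t2.index]
    dropped = [s for s in labeled.index if s not in paired]
    if dropped:
        logger.warning("excluding %d unpaired subjects: %s", len(dropped), dropped[:5])
    if not paired:
        raise AnalysisError("no paired subjects with labels at both timepoints")
    boundary = float(labels_t1.boundary)
    t2_labels = label_against_boundary(isae_t2.loc[paired], boundary)
    table = pd.DataFrame({
        "isae_t1": isae_t1.loc[paired],
        "isae_t2": isae_t2.loc[paired],
        "label_t1": labeled.loc[paired],
        "label_t2": t2_labels,
    })
    table["retained"] = table["label_t1"] == table["label_t2"]
    table.index.name = "subject_id"
    return StabilityReport(table=table, retention=float(table["retained"].mean()),
                           boundary=boundary)
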