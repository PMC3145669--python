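"""Smoking-responsive signature selection.

The primary selector is the classic three-criterion microarray filter
chain applied to healthy smokers vs nonsmokers:

1. detection: Present call in at least 20% of the samples considered;
2. effect size: fold change of group arithmetic means (linear, normalized
   scale) with magnitude >= 1.5;
3. significance: t-test on log2 values with Benjamini-Hochberg adjusted
   p < 0.01 (the BH universe is the probes surviving the detection filter).

Probes are then collapsed to genes for index construction: only probes
with a known gene symbol are index-eligible, and where several probes
interrogate one gene the lowest-p probe represents it.

Two alternative selectors are provided for cross-method robustness:
an SVD/principal-axis ranking and nearest-shrunken-centroid (the
computation behind "PAM") gene selection with cross-validated shrinkage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import ExpressionMatrix, CohortError, present_fraction

logger = logging.getLogger("saeindex")


class AnalysisError(ValueError):
    """User-facing error in an analysis step."""


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, order-preserving, in [0,1]).

    adjusted[(i)] = min_{j >= i} p[(j)] * n / j  over the ranked p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise AnalysisError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise AnalysisError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# the three-criterion filter chain (shared with subgroup contrasts)
# ---------------------------------------------------------------------------

def filter_chain_stats(
    m: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    present_min: float = 0.20,
    present_samples: Optional[Sequence[str]] = None,
    assume_present: bool = False,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe statistics for an A-vs-B contrast over the present probes.

    Returns a DataFrame (indexed by probe, detection-filter survivors only)
    with columns mean_a, mean_b (linear), fold_change (magnitude >= 1),
    direction ('up' = higher in A), t, p, q.  The t-test is Welch by
    default (pooled when ``equal_var``), computed on log2 values; fold
    change is the ratio of linear-scale arithmetic means.
    """
    if not m.normalized:
        raise AnalysisError("matrix must be normalized (normalize_per_chip)")
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise AnalysisError("each contrasted group needs >= 2 samples")
    if set(samples_a) & set(samples_b):
        raise AnalysisError("contrasted groups share samples")
    if present_samples is None:
        present_samples = samples_a + samples_b
    frac = present_fraction(m, samples=present_samples, assume_present=assume_present)
    keep = frac >= present_min
    if not keep.any():
        raise AnalysisError("no probe passes the detection filter")
    a = m.values.loc[keep, samples_a].to_numpy()
    b = m.values.loc[keep, samples_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ratio = mean_a / mean_b
    fold = np.maximum(ratio, 1.0 / ratio)
    la, lb = np.log2(a), np.log2(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var)
    nan_p = ~np.isfinite(p)
    if nan_p.any():
        logger.warning("%d probes with zero variance in both groups: p set to 1",
                       int(nan_p.sum()))
        p = np.where(nan_p, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
    direction = np.where(la.mean(axis=1) >= lb.mean(axis=1), "up", "down")
    out = pd.DataFrame(
        {
            "present_fraction": frac[keep].to_numpy(),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "direction": direction,
            "t": t,
            "p": p,
            "q": benjamini_hochberg(p),
        },
        index=m.probe_ids[keep.to_numpy()],
    )
    return out


# ---------------------------------------------------------------------------
# signature container
# ---------------------------------------------------------------------------

SIGNATURE_COLUMNS = ["gene_symbol", "direction", "fold_change", "p", "q",
                     "index_eligible"]


@dataclass
class SmokingSignature:
    """Selected smoking-responsive probes with thresholds and provenance.

    ``table`` is indexed by probe_id with columns gene_symbol, direction
    ('up'/'down' for smoker-induced/-suppressed), fold_change, p, q and
    index_eligible (known gene and lowest-p probe for that gene).
    """

    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise AnalysisError(f"duplicate probe in signature: {dup!r}")

    @property
    def probes(self) -> pd.Index:
        return self.table.index

    @property
    def index_genes(self) -> pd.Index:
        """Unique gene symbols carried by the index-eligible probes."""
        return pd.Index(self.table.loc[self.table["index_eligible"], "gene_symbol"])

    @property
    def n_index_genes(self) -> int:
        return int(self.table["index_eligible"].sum())

    def to_tsv(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, thresholds: Optional[dict] = None) -> "SmokingSignature":
        table = pd.read_csv(path, sep="\t", index_col=0,
                            dtype={"gene_symbol": str}, keep_default_na=False)
        table["index_eligible"] = table["index_eligible"].astype(str).isin(
            ("True", "true", "1"))
        for col in ("fold_change", "p", "q"):
            table[col] = pd.to_numeric(table[col])
        return cls(table=table, thresholds=thresholds or {})


def _input_hash(m: ExpressionMatrix, samples: Sequence[str]) -> str:
    h = hashlib.sha256()
    h.update(",".join(samples).encode())
    h.update(np.ascontiguousarray(m.values[list(samples)].to_numpy()).tobytes())
    return h.hexdigest()[:16]


def _mark_eligible(table: pd.DataFrame) -> pd.DataFrame:
    """Known-gene, lowest-p-per-gene eligibility (ties: q, then probe id)."""
    table = table.copy()
    table["index_eligible"] = False
    known = table["gene_symbol"].astype(str) != ""
    sub = table.loc[known, ["gene_symbol", "p", "q"]].copy()
    sub["_probe"] = sub.index.astype(str)
    sub = sub.sort_values(["gene_symbol", "p", "q", "_probe"], kind="mergesort")
    winners = sub.drop_duplicates(subset="gene_symbol", keep="first").index
    table.loc[winners, "index_eligible"] = True
    return table


def select_signature(
    m: ExpressionMatrix,
    pheno: pd.DataFrame,
    ann: Optional[pd.Series] = None,
    present_min: float = 0.20,
    fc_min: float = 1.5,
    q_max: float = 0.01,
    group_a: str = "healthy_smoker",
    group_b: str = "nonsmoker",
    present_samples: Optional[Sequence[str]] = None,
    assume_present: bool = False,
    equal_var: bool = False,
) -> SmokingSignature:
    """Derive the smoking signature via the three-criterion filter chain.

    Filters are conjunctive and applied detection -> fold change ->
    BH-adjusted t-test; both boundary values (fold change exactly 1.5,
    q exactly at the cutoff is excluded: q < q_max mirrors "p < 0.01"
    on adjusted values, while the fold gate is inclusive at 1.5).
    Direction 'up' means higher in ``group_a`` (smokers).
    """
    sa = pheno.loc[pheno["group"] == group_a, "sample_id"].tolist()
    sb = pheno.loc[pheno["group"] == group_b, "sample_id"].tolist()
    if not sa or not sb:
        raise AnalysisError(f"empty group in contrast {group_a} vs {group_b}")
    stats_df = filter_chain_stats(
        m, sa, sb, present_min=present_min, present_samples=present_samples,
        assume_present=assume_present, equal_var=equal_var,
    )
    passing = stats_df[(stats_df["fold_change"] >= fc_min) & (stats_df["q"] < q_max)]
    table = passing[["direction", "fold_change", "p", "q"]].copy()
    if ann is not None:
        table.insert(0, "gene_symbol", ann.reindex(table.index).fillna("").astype(str))
    else:
        table.insert(0, "gene_symbol", "")
    table = _mark_eligible(table)
    sig = SmokingSignature(
        table=table[SIGNATURE_COLUMNS],
        thresholds={
            "present_min": present_min, "fc_min": fc_min, "q_max": q_max,
            "fold_change_scale": "linear arithmetic means",
            "t_test": "pooled" if equal_var else "welch",
        },
        group_sizes={group_a: len(sa), group_b: len(sb)},
        provenance=_input_hash(m, sa + sb),
    )
    logger.info("signature: %d probes, %d index-eligible genes",
                len(sig.table), sig.n_index_genes)
    return sig


def collapse_to_genes(sig: SmokingSignature, ann: pd.Series) -> SmokingSignature:
    """Re-annotate and recompute index eligibility on an existing signature.

    Unknown-gene probes become ineligible; per gene symbol only the
    minimum-p probe is eligible (ties by q, then lexicographic probe id).
    """
    table = sig.table.copy()
    table["gene_symbol"] = ann.reindex(table.index).fillna("").astype(str)
    table = _mark_eligible(table)
    return SmokingSignature(table=table, thresholds=dict(sig.thresholds),
                            group_sizes=dict(sig.group_sizes),
                            provenance=sig.provenance)


# ---------------------------------------------------------------------------
# SVD-based ranking
# ---------------------------------------------------------------------------

def svd_rank_select(
    m: ExpressionMatrix,
    pheno: pd.DataFrame,
    k: int = 300,
    group_a: str = "healthy_smoker",
    group_b: str = "nonsmoker",
    present_min: float = 0.20,
    assume_present: bool = False,
) -> tuple[list[str], dict]:
    """Rank probes by loading on the best group-separating singular axis.

    The detection-filtered matrix (both groups) is log2-transformed and
    gene-centered, decomposed by SVD, and the component whose sample
    scores give the largest absolute two-sample t statistic between the
    groups is taken as the smoking axis.  Returns the k probes with the
    largest absolute loadings (ranked) plus details (component index,
    separation statistic, variance fraction).
    """
    if not m.normalized:
        raise AnalysisError("matrix must be normalized")
    sa = pheno.loc[pheno["group"] == group_a, "sample_id"].tolist()
    sb = pheno.loc[pheno["group"] == group_b, "sample_id"].tolist()
    if len(sa) < 2 or len(sb) < 2:
        raise AnalysisError("each group needs >= 2 samples")
    cols = sa + sb
    frac = present_fraction(m, samples=cols, assume_present=assume_present)
    keep = frac >= present_min
    probes = m.probe_ids[keep.to_numpy()]
    if k > len(probes):
        raise AnalysisError(f"k={k} exceeds {len(probes)} detection-filtered probes")
    X = np.log2(m.values.loc[keep, cols].to_numpy())
    X = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    is_a = np.array([c in set(sa) for c in cols])
    tstats = np.array([
        stats.ttest_ind(scores[is_a], scores[~is_a], equal_var=False).statistic
        if np.ptp(scores) > 0 else 0.0
        for scores in Vt
    ])
    tstats = np.nan_to_num(tstats)
    best = int(np.argmax(np.abs(tstats)))
    order = np.argsort(-np.abs(U[:, best]), kind="mergesort")
    ranked = [str(probes[i]) for i in order[:k]]
    total_var = float((S ** 2).sum())
    details = {
        "component": best,
        "separation_t": float(tstats[best]),
        "variance_fraction": float(S[best] ** 2 / total_var) if total_var else 0.0,
        "n_probes_considered": int(len(probes)),
    }
    return ranked, details


# ---------------------------------------------------------------------------
# nearest shrunken centroids ("PAM")
# ---------------------------------------------------------------------------

@dataclass
class _NSCFit:
    classes: np.ndarray
    overall: np.ndarray          # overall centroid per gene
    shrunken: np.ndarray         # classes x genes shrunken centroids
    s: np.ndarray                # pooled within-class SD per gene
    s0: float                    # fudge constant (median of s)
    priors: np.ndarray
    dprime: np.ndarray           # classes x genes shrunken differences


def _nsc_fit(X: np.ndarray, y: np.ndarray, delta: float) -> _NSCFit:
    """Fit nearest-shrunken-centroid statistics on a genes x samples matrix.

    Per-gene class-vs-overall centroid differences are standardized by the
    pooled within-class deviation plus a fudge constant (the median pooled
    deviation), then soft-thresholded at ``delta``.
    """
    classes, counts = np.unique(y, return_counts=True)
    n = len(y)
    overall = X.mean(axis=1)
    cent = np.stack([X[:, y == c].mean(axis=1) for c in classes])
    within_ss = np.zeros(X.shape[0])
    for i, c in enumerate(classes):
        within_ss += ((X[:, y == c] - cent[i][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(within_ss / max(n - len(classes), 1))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / counts - 1.0 / n)
    d = (cent - overall) / (mk[:, None] * (s + s0)[None, :])
    dprime = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = overall[None, :] + mk[:, None] * (s + s0)[None, :] * dprime
    return _NSCFit(classes=classes, overall=overall, shrunken=shrunken,
                   s=s, s0=s0, priors=counts / n, dprime=dprime)


def _nsc_predict(fit: _NSCFit, X: np.ndarray) -> np.ndarray:
    denom = (fit.s + fit.s0) ** 2
    scores = np.stack([
        (((X - fit.shrunken[i][:, None]) ** 2) / denom[:, None]).sum(axis=0)
        - 2.0 * np.log(fit.priors[i])
        for i in range(len(fit.classes))
    ])
    return fit.classes[np.argmin(scores, axis=0)]


def nsc_max_delta(X: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(_nsc_fit(X, y, 0.0).dprime).max())


@dataclass
class ShrunkenCentroidResult:
    selected_probes: list[str]
    accuracy: float
    delta: float
    cv_table: pd.DataFrame       # delta, accuracy, n_genes


def shrunken_centroid_select(
    m: ExpressionMatrix,
    pheno: pd.DataFrame,
    cv_folds: int = 10,
    group_a: str = "healthy_smoker",
    group_b: str = "nonsmoker",
    labels: Optional[pd.Series] = None,
    gene_subset: Optional[Sequence[str]] = None,
    delta: Optional[float] = None,
    n_deltas: int = 30,
    seed: int = 0,
) -> ShrunkenCentroidResult:
    """Nearest-shrunken-centroid gene selection with CV-chosen shrinkage.

    ``labels`` (sample_id -> class) overrides the phenotype groups, which
    lets the same machinery classify responder subgroups.  The shrinkage
    Delta is chosen as the smallest value whose cross-validated accuracy is
    within one standard error of the best; pass ``delta`` to fix it.
    """
    from sklearn.model_selection import StratifiedKFold

    if labels is not None:
        labels = labels.dropna()
        sample_ids = [s for s in labels.index if s in set(m.sample_ids)]
        y = labels.loc[sample_ids].to_numpy()
    else:
        sel = pheno[pheno["group"].isin([group_a, group_b])]
        sample_ids = sel["sample_id"].tolist()
        y = sel["group"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise AnalysisError("shrunken-centroid selection expects two classes")
    if counts.min() < cv_folds:
        new_folds = int(counts.min())
        logger.warning("class size %d < cv_folds %d: reducing folds to %d",
                       counts.min(), cv_folds, new_folds)
        cv_folds = new_folds
    if cv_folds < 2:
        raise AnalysisError("need >= 2 members per class for cross-validation")
    probes = m.probe_ids if gene_subset is None else pd.Index(gene_subset)
    X = np.log2(m.values.loc[probes, sample_ids].to_numpy())

    dmax = nsc_max_delta(X, y)
    if delta is not None:
        grid = np.array([float(delta)])
    else:
        grid = np.linspace(0.0, dmax, n_deltas)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    hits = np.zeros(len(grid))
    for train, test in skf.split(X.T, y):
        fits = [_nsc_fit(X[:, train], y[train], d) for d in grid]
        for j, f in enumerate(fits):
            hits[j] += (_nsc_predict(f, X[:, test]) == y[test]).sum()
    acc = hits / len(y)
    if delta is None:
        best = float(acc.max())
        se = np.sqrt(best * (1 - best) / len(y))
        chosen_idx = int(np.flatnonzero(acc >= best - se)[0])
    else:
        chosen_idx = 0
    chosen = float(grid[chosen_idx])
    full = _nsc_fit(X, y, chosen)
    selected_mask = np.abs(full.dprime).max(axis=0) > 0
    if not selected_mask.any():
        raise AnalysisError(
            f"shrinkage delta={chosen:.3g} removes every gene (max standardized "
            f"difference {dmax:.3g})"
        )
    n_genes = [int((np.abs(_nsc_fit(X, y, d).dprime).max(axis=0) > 0).sum())
               for d in grid]
    return ShrunkenCentroidResult(
        selected_probes=[str(p) for p in probes[selected_mask]],
        accuracy=float(acc[chosen_idx]),
        delta=chosen,
        cv_table=pd.DataFrame({"delta": grid, "accuracy": acc, "n_genes": n_genes}),
    )


# ---------------------------------------------------------------------------
# overlap accounting
# ---------------------------------------------------------------------------

def overlap_counts(list_a: Sequence[str], list_b: Sequence[str],
                   list_c: Sequence[str]) -> dict:
    """Pairwise and triple intersection sizes of three probe-id sets."""
    a, b, c = set(list_a), set(list_b), set(list_c)
    return {
        "a": len(a), "b": len(b), "c": len(c),
        "ab": len(a & b), "ac": len(a & c), "bc": len(b & c),
        "abc": len(a & b & c),
    }
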