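"""Validation machinery: clustering, PC separation, classifiers, K-fold
range robustness, and a covariate (confounder) screen.

These operations quantify whether a derived signature and the I_SAE-based
responder labels are artifacts of a particular sample or method:
hierarchical clustering of held-out samples on the signature, separation
of groups along principal axes, cross-validated classification accuracy,
sensitivity of I_SAE and labels to resampled nonsmoker reference ranges,
and association of I_SAE with demographic covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort_io import ExpressionMatrix
from .sae_index import (IndexResult, NormalRangeSet, ResponderLabels,
                        compute_isae, fit_normal_ranges)
from .signature import AnalysisError, SmokingSignature, _nsc_fit, _nsc_predict

logger = logging.getLogger("saeindex")


# ---------------------------------------------------------------------------
# unsupervised cluster validation
# ---------------------------------------------------------------------------

def cluster_validate(
    m_heldout: ExpressionMatrix,
    pheno: pd.DataFrame,
    gene_set: Sequence[str],
    method: str = "average",
    metric: str = "correlation",
) -> tuple[pd.Series, float]:
    """Two-cut hierarchical clustering of held-out samples on a gene set.

    Samples are clustered with average linkage on 1 - Pearson correlation
    over per-gene standardized log2 values; the tree is cut at two
    clusters and agreement with the known groups is reported as the
    adjusted Rand index.
    """
    from sklearn.metrics import adjusted_rand_score

    gene_set = list(gene_set)
    if not gene_set:
        raise AnalysisError("gene set is empty")
    samples = [s for s in pheno["sample_id"] if s in set(m_heldout.sample_ids)]
    if len(samples) < 3:
        raise AnalysisError("cluster validation needs >= 3 samples")
    missing = [g for g in gene_set if g not in m_heldout.values.index]
    if missing:
        raise AnalysisError(f"gene set missing from matrix: {missing[:5]}")
    X = np.log2(m_heldout.values.loc[gene_set, samples].to_numpy())
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    if metric != "correlation":
        raise AnalysisError(f"unknown metric {metric!r}")
    corr = np.corrcoef(X.T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    assignment = pd.Series(fcluster(Z, t=2, criterion="maxclust"),
                           index=samples, name="cluster")
    known = pheno.set_index("sample_id").loc[samples, "group"]
    ari = float(adjusted_rand_score(known.to_numpy(), assignment.to_numpy()))
    return assignment, ari


# ---------------------------------------------------------------------------
# principal-component separation
# ---------------------------------------------------------------------------

@dataclass
class SeparationReport:
    """Best group-separating principal component of a gene-set submatrix."""

    component: int               # 0-based index of the separating component
    variance_fraction: float     # share of total variance it captures
    statistic: float             # two-sample t on its scores
    p_value: float
    scores: pd.DataFrame         # samples x [pc1, pc2]
    variance_fractions: np.ndarray  # all components, sums to 1


def pc_separation(
    m: ExpressionMatrix,
    pheno: pd.DataFrame,
    gene_set: Sequence[str],
    groups: tuple[str, str] | None = None,
    labels: Optional[ResponderLabels] = None,
) -> SeparationReport:
    """PCA of the gene-set submatrix (log2, gene-centered) with the
    component best separating two groups identified by a two-sample t test
    on its sample scores.

    Groups come either from phenotype ``group`` values or from responder
    ``labels``.
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in m.values.index]
    if missing:
        raise AnalysisError(f"gene set missing from matrix: {missing[:5]}")
    if labels is not None:
        lab = labels.labels.dropna()
        samples = [s for s in lab.index if s in set(m.sample_ids)]
        y = lab.loc[samples].to_numpy()
    elif groups is not None:
        sel = pheno[pheno["group"].isin(groups)]
        samples = [s for s in sel["sample_id"] if s in set(m.sample_ids)]
        y = sel.set_index("sample_id").loc[samples, "group"].to_numpy()
    else:
        raise AnalysisError("pc_separation needs groups or labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise AnalysisError("need two groups with >= 2 samples each")
    X = np.log2(m.values.loc[gene_set, samples].to_numpy())
    X = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S ** 2
    total = var.sum()
    fractions = var / total if total > 0 else var
    is_a = y == classes[0]
    tvals, pvals = [], []
    for scores in Vt:
        if np.ptp(scores) == 0:
            tvals.append(0.0)
            pvals.append(1.0)
            continue
        t, p = stats.ttest_ind(scores[is_a], scores[~is_a], equal_var=False)
        tvals.append(float(t) if np.isfinite(t) else 0.0)
        pvals.append(float(p) if np.isfinite(p) else 1.0)
    best = int(np.argmax(np.abs(tvals)))
    scores2 = pd.DataFrame(
        {"pc1": Vt[0] * S[0], "pc2": (Vt[1] * S[1]) if len(S) > 1 else 0.0},
        index=pd.Index(samples, name="sample_id"),
    )
    return SeparationReport(
        component=best,
        variance_fraction=float(fractions[best]),
        statistic=float(tvals[best]),
        p_value=float(pvals[best]),
        scores=scores2,
        variance_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# cross-validated classifiers
# ---------------------------------------------------------------------------

def crossval_classifiers(
    m: ExpressionMatrix,
    labels: pd.Series,
    gene_set: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    nsc_delta: float = 0.0,
    svm_c: float = 1.0,
) -> dict[str, float]:
    """Stratified cross-validated accuracy of two classifiers on a gene set.

    ``shrunken_centroid`` is the nearest-shrunken-centroid classifier at a
    fixed recorded shrinkage (default 0 = nearest centroid);
    ``max_margin_linear`` is a maximum-margin linear classifier with hinge
    loss and fixed regularization C (recorded, not tuned).
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import LinearSVC

    labels = labels.dropna()
    samples = [s for s in labels.index if s in set(m.sample_ids)]
    y = labels.loc[samples].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise AnalysisError("classification needs exactly two classes")
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise AnalysisError("need >= 2 members per class")
    X = np.log2(m.values.loc[list(gene_set), samples].to_numpy())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    hits = {"shrunken_centroid": 0, "max_margin_linear": 0}
    for train, test in skf.split(X.T, y):
        fit = _nsc_fit(X[:, train], y[train], nsc_delta)
        hits["shrunken_centroid"] += int(
            (_nsc_predict(fit, X[:, test]) == y[test]).sum())
        svm = LinearSVC(C=svm_c, loss="hinge", max_iter=20000)
        mu = X[:, train].mean(axis=1, keepdims=True)
        sd = X[:, train].std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        svm.fit(((X[:, train] - mu) / sd).T, y[train])
        hits["max_margin_linear"] += int(
            (svm.predict(((X[:, test] - mu) / sd).T) == y[test]).sum())
    return {k: v / len(y) for k, v in hits.items()}


# ---------------------------------------------------------------------------
# K-fold range robustness
# ---------------------------------------------------------------------------

@dataclass
class KFoldReport:
    """Per-sample I_SAE range and label consistency across resampled
    reference ranges.

    ``table``: sample_id, isae_min, isae_max, modal_label, consistency
    (fraction of resamples assigning the modal label; NaN for reference
    samples, which are never labeled).
    """

    table: pd.DataFrame
    k: int
    repetitions: int
    seed: int
    freeze_boundary: bool

    def consistent_fraction(self, samples: Sequence[str],
                            threshold: float = 0.75) -> float:
        """Fraction of the given samples whose modal label holds in more
        than ``threshold`` of resamples."""
        cons = self.table.loc[list(samples), "consistency"]
        return float((cons > threshold).mean())


def kfold_robustness(
    m: ExpressionMatrix,
    pheno: pd.DataFrame,
    sig: SmokingSignature,
    k: int = 10,
    repetitions: int = 100,
    seed: int = 0,
    freeze_boundary: bool = False,
    full_boundary: Optional[float] = None,
    sd_multiplier: float = 2.0,
) -> KFoldReport:
    """Robustness of I_SAE and responder labels to the nonsmoker reference.

    For each repetition the timepoint-1 nonsmokers are partitioned into K
    folds; for each fold the normal ranges are refit on the remaining
    nonsmokers, every sample is rescored, and smokers (and the COPD group)
    are relabeled against the refit healthy-smoker median (or against the
    frozen full-data boundary when ``freeze_boundary``).  Per-sample
    minimum/maximum I_SAE and modal-label consistency are aggregated over
    all K x R resamples.
    """
    t1 = pheno[pheno["timepoint"] == 1]
    reference = t1.loc[t1["group"] == "nonsmoker", "sample_id"].tolist()
    smokers = t1.loc[t1["group"] == "healthy_smoker", "sample_id"].tolist()
    if len(reference) < k:
        new_k = max(len(reference) // 2, 2)
        logger.warning("only %d nonsmokers for K=%d folds: reducing K to %d",
                       len(reference), k, new_k)
        k = new_k
    if len(reference) // k < 1 or len(reference) - (len(reference) + k - 1) // k < 2:
        raise AnalysisError("folds leave < 2 reference samples")
    if freeze_boundary and full_boundary is None:
        raise AnalysisError("freeze_boundary requires full_boundary")
    all_samples = list(m.sample_ids)
    eligible = sig.table[sig.table["index_eligible"]]
    logv = np.log2(m.values.loc[eligible.index, :].to_numpy())
    ref_pos = np.array([all_samples.index(s) for s in reference])
    smoker_pos = np.array([all_samples.index(s) for s in smokers])
    labeled_pos = np.array([i for i, s in enumerate(all_samples) if s not in set(reference)])
    up = (eligible["direction"].to_numpy() == "up")[:, None]
    n_genes = len(eligible)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 41]))
    n_samp = len(all_samples)
    isae_min = np.full(n_samp, np.inf)
    isae_max = np.full(n_samp, -np.inf)
    high_counts = np.zeros(n_samp, dtype=int)
    n_resamples = 0
    for _ in range(repetitions):
        perm = rng.permutation(ref_pos)
        for fold in np.array_split(perm, k):
            train = np.setdiff1d(ref_pos, fold)
            sub = logv[:, train]
            mean = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=1)
            thr = mean + np.where(up[:, 0], 1.0, -1.0) * sd_multiplier * sd
            exceed = np.where(up, logv > thr[:, None], logv < thr[:, None])
            isae = 100.0 * exceed.sum(axis=0) / n_genes
            np.minimum(isae_min, isae, out=isae_min)
            np.maximum(isae_max, isae, out=isae_max)
            if freeze_boundary:
                boundary = float(full_boundary)
            else:
                boundary = float(np.median(isae[smoker_pos]))
            high_counts[labeled_pos] += (isae[labeled_pos] > boundary).astype(int)
            n_resamples += 1
    consistency = np.full(n_samp, np.nan)
    frac_high = high_counts[labeled_pos] / n_resamples
    consistency[labeled_pos] = np.maximum(frac_high, 1.0 - frac_high)
    modal = np.full(n_samp, np.nan, dtype=object)
    modal[labeled_pos] = np.where(frac_high >= 0.5, "high", "low")
    table = pd.DataFrame(
        {
            "isae_min": isae_min,
            "isae_max": isae_max,
            "modal_label": modal,
            "consistency": consistency,
        },
        index=pd.Index(all_samples, name="sample_id"),
    )
    return KFoldReport(table=table, k=k, repetitions=repetitions, seed=seed,
                       freeze_boundary=freeze_boundary)


# ---------------------------------------------------------------------------
# confounder screen
# ---------------------------------------------------------------------------

def confounder_screen(
    isae: pd.Series,
    pheno: pd.DataFrame,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Associate I_SAE with phenotype covariates.

    Categorical covariates use a rank-based K-group (Kruskal-Wallis) test;
    numeric covariates a least-squares regression (slope, p, variance
    explained).  P-values are BH-adjusted across the screened covariates.
    Constant covariates are skipped with a note.
    """
    from .signature import benjamini_hochberg

    ph = pheno.set_index("sample_id").loc[isae.index]
    rows = []
    for cov in covariates:
        if cov not in ph.columns:
            raise AnalysisError(f"covariate {cov!r} not in phenotype table")
        vals = ph[cov]
        mask = vals.notna() & isae.notna()
        v, y = vals[mask], isae[mask]
        if v.nunique() <= 1:
            logger.warning("covariate %r is constant: skipped", cov)
            rows.append((cov, "constant", np.nan, np.nan, np.nan))
            continue
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 5:
            res = stats.linregress(v.astype(float), y.astype(float))
            rows.append((cov, "numeric", float(res.slope), float(res.pvalue),
                         float(res.rvalue ** 2)))
        else:
            groups = [y[v == level].to_numpy() for level in v.unique()]
            groups = [g for g in groups if len(g) > 0]
            stat, p = stats.kruskal(*groups)
            rows.append((cov, "categorical", float(stat), float(p), np.nan))
    out = pd.DataFrame(rows, columns=["covariate", "kind", "statistic", "p",
                                      "variance_explained"]).set_index("covariate")
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    return out
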