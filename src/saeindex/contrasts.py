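"""Genome-wide subgroup contrasts and the combined-group biomarker.

Each contrast reruns the full three-criterion filter chain (detection
recomputed over only the contrasted samples, fold change >= 1.5, BH q
below the cutoff) genome-wide between two subgroups: high vs low
responder smokers, COPD vs either responder subgroup, or the pooled
high-responder + COPD group vs low responders (the biomarker signature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix
from .sae_index import ResponderLabels
from .signature import AnalysisError, SmokingSignature, filter_chain_stats

logger = logging.getLogger("saeindex")

CONTRAST_NAMES = ("high_vs_low", "copd_vs_low", "copd_vs_high", "highcopd_vs_low")


@dataclass
class ContrastResult:
    """Per-probe statistics and significance flags for one contrast.

    ``table`` covers every detection-filtered probe with columns mean_a,
    mean_b, fold_change, direction ('up' = higher in group A), p, q and
    significant; significance means passing all three gates.
    """

    name: str
    table: pd.DataFrame
    thresholds: dict
    group_sizes: dict
    gene_symbols: Optional[pd.Series] = None

    @property
    def significant_probes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_unique_genes(self) -> Optional[int]:
        """Unique known gene symbols among significant probes (needs annotation)."""
        if self.gene_symbols is None:
            return None
        syms = self.gene_symbols.reindex(self.significant_probes).fillna("")
        return int(syms[syms != ""].nunique())

    def summary(self) -> dict:
        out = {
            "contrast": self.name,
            "n_significant_probes": self.n_significant,
            "n_unique_genes": self.n_unique_genes,
            "thresholds": self.thresholds,
            "group_sizes": self.group_sizes,
        }
        return out

    def to_tsv(self, path) -> None:
        self.table.rename_axis("probe_id").to_csv(path, sep="\t")


def run_contrast_samples(
    m: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    name: str = "custom",
    present_min: float = 0.20,
    fc_min: float = 1.5,
    q_max: float = 0.01,
    ann: Optional[pd.Series] = None,
    assume_present: bool = False,
    equal_var: bool = False,
) -> ContrastResult:
    """Genome-wide A-vs-B contrast with the detection filter recomputed
    over only the contrasted samples."""
    samples_a, samples_b = list(samples_a), list(samples_b)
    if set(samples_a) == set(samples_b):
        raise AnalysisError(f"contrast {name!r} compares a group against itself")
    stats_df = filter_chain_stats(
        m, samples_a, samples_b, present_min=present_min,
        assume_present=assume_present, equal_var=equal_var,
    )
    stats_df = stats_df.copy()
    stats_df["significant"] = (stats_df["fold_change"] >= fc_min) & (stats_df["q"] < q_max)
    res = ContrastResult(
        name=name,
        table=stats_df,
        thresholds={"present_min": present_min, "fc_min": fc_min, "q_max": q_max},
        group_sizes={"a": len(samples_a), "b": len(samples_b)},
        gene_symbols=ann,
    )
    logger.info("contrast %s: %d significant probes", name, res.n_significant)
    return res


def resolve_contrast_groups(
    pheno: pd.DataFrame,
    labels: Optional[ResponderLabels],
    contrast: str,
) -> tuple[list[str], list[str]]:
    """Map a named contrast to (samples_a, samples_b)."""
    copd = pheno.loc[pheno["group"] == "copd", "sample_id"].tolist()
    high = labels.samples("high") if labels is not None else []
    low = labels.samples("low") if labels is not None else []
    if contrast == "high_vs_low":
        groups = high, low
    elif contrast == "copd_vs_low":
        groups = copd, low
    elif contrast == "copd_vs_high":
        groups = copd, high
    elif contrast == "highcopd_vs_low":
        groups = high + copd, low
    else:
        raise AnalysisError(
            f"unknown contrast {contrast!r}; expected one of {CONTRAST_NAMES}")
    if not groups[0] or not groups[1]:
        raise AnalysisError(f"contrast {contrast!r} has an empty group")
    return groups


def run_contrast(
    m: ExpressionMatrix,
    pheno: pd.DataFrame,
    labels: Optional[ResponderLabels] = None,
    contrast: str = "high_vs_low",
    q_max: float = 0.01,
    **kwargs,
) -> ContrastResult:
    """Run a named subgroup contrast (see :data:`CONTRAST_NAMES`)."""
    samples_a, samples_b = resolve_contrast_groups(pheno, labels, contrast)
    return run_contrast_samples(m, samples_a, samples_b, name=contrast,
                                q_max=q_max, **kwargs)


def partition_by_signature(
    c: ContrastResult, sig: SmokingSignature,
) -> tuple[list[str], list[str]]:
    """Split significant probes into signature members vs independent."""
    sig_probes = set(sig.probes)
    within = [str(p) for p in c.significant_probes if p in sig_probes]
    independent = [str(p) for p in c.significant_probes if p not in sig_probes]
    return within, independent


def biomarker_signature(
    m: ExpressionMatrix,
    pheno: pd.DataFrame,
    labels: ResponderLabels,
    q_max: float = 0.01,
    **kwargs,
) -> ContrastResult:
    """Combined high-responder + COPD vs low-responder contrast.

    The resulting significant set is the biomarker distinguishing low
    responders from the COPD-like expression phenotype; persist it and
    evaluate on a held-out set with the validation machinery.
    """
    copd = pheno.loc[pheno["group"] == "copd", "sample_id"]
    if len(copd) == 0 or not labels.samples("high") or not labels.samples("low"):
        raise AnalysisError("biomarker contrast needs non-empty high, low and "
                            "copd groups")
    return run_contrast(m, pheno, labels, contrast="highcopd_vs_low",
                        q_max=q_max, **kwargs)
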