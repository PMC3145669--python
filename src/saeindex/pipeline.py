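"""End-to-end orchestration: simulate/load -> normalize -> signature ->
index -> classify -> contrasts -> validation -> report.

A run is driven by a single :class:`RunConfig` (YAML-loadable) holding
either input file paths or a simulation block, plus thresholds, the split
rule, K-fold settings and the seed.  Every artifact is written as TSV/JSON
with a provenance sidecar (config hash, seed, package version), and a run
is idempotent given the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (CohortError, ExpressionMatrix, normalize_per_chip,
                        read_annotation, read_calls, read_expression,
                        read_phenotypes, write_annotation, write_calls,
                        write_expression, write_phenotypes)
from .contrasts import CONTRAST_NAMES, run_contrast, partition_by_signature
from .sae_index import (classify_responders, compute_isae, fit_normal_ranges,
                        range_membership)
from .signature import AnalysisError, SmokingSignature, select_signature
from .synthetic import SimulationConfig, SyntheticTruth, generate_cohort, write_truth
from .validation import confounder_screen, kfold_robustness, pc_separation

logger = logging.getLogger("saeindex")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (exactly one input mode)."""

    output_dir: str = "saeindex_run"
    seed: int = 0
    # input mode A: file paths
    expression_path: Optional[str] = None
    calls_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    annotation_path: Optional[str] = None
    expression_format: str = "tsv"
    # input mode B: simulation block
    simulate: Optional[SimulationConfig] = None
    # thresholds
    present_min: float = 0.20
    fc_min: float = 1.5
    q_max_primary: float = 0.01
    q_max_validation: float = 0.05
    assume_present: bool = False
    # responder split
    split_rule: str = "median"
    split_alpha: Optional[float] = None
    # K-fold settings
    kfold_k: int = 10
    kfold_repetitions: int = 100
    # covariates screened (skipped silently if absent from the phenotypes)
    covariates: tuple[str, ...] = ("age", "sex", "ancestry", "pack_years",
                                   "smoking_years", "fev1_fvc")

    def __post_init__(self) -> None:
        has_paths = self.expression_path is not None
        if has_paths == (self.simulate is not None):
            raise CohortError("config needs exactly one of input paths or a "
                              "simulate block")
        for name in ("present_min",):
            if not 0 <= getattr(self, name) <= 1:
                raise CohortError(f"{name} out of range")
        if self.fc_min < 1 or not (0 < self.q_max_primary <= 1):
            raise CohortError("invalid thresholds")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw, simulate=None if sim is None else SimulationConfig(**sim))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        m, pheno, truth = generate_cohort(cfg.simulate)
        ann = truth.annotation
        return m, pheno, ann, truth
    m = read_expression(cfg.expression_path, format=cfg.expression_format,
                        calls_path=cfg.calls_path)
    pheno = read_phenotypes(cfg.phenotype_path)
    ann = (read_annotation(cfg.annotation_path)
           if cfg.annotation_path is not None else None)
    return m, pheno, ann, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``output_dir``.

    Returns a dict of in-memory results keyed by stage.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    logger.info("stage: load/simulate")
    m_raw, pheno, ann, truth = _load_inputs(cfg)
    t1 = pheno[pheno["timepoint"] == 1]
    if cfg.simulate is not None:
        write_expression(m_raw, out / "expression.tsv")
        if m_raw.calls is not None:
            write_calls(m_raw.calls, out / "calls.tsv")
        write_phenotypes(pheno, out / "phenotypes.tsv")
        write_annotation(ann, out / "annotation.tsv")
        write_truth(truth, out / "truth_genes.tsv", out / "truth_subjects.tsv")

    logger.info("stage: normalize")
    m = normalize_per_chip(m_raw)

    logger.info("stage: signature")
    sig = select_signature(
        m, t1, ann, present_min=cfg.present_min, fc_min=cfg.fc_min,
        q_max=cfg.q_max_primary, assume_present=cfg.assume_present,
    )
    sig.to_tsv(out / "signature.tsv")
    _write_json({"thresholds": sig.thresholds, "group_sizes": sig.group_sizes,
                 "n_probes": len(sig.table), "n_index_genes": sig.n_index_genes,
                 "provenance": sig.provenance}, out / "signature.json")
    results["signature"] = sig
    if sig.n_index_genes == 0:
        raise AnalysisError("empty signature: no index-eligible genes survive "
                            "the filter chain")

    logger.info("stage: index")
    reference = t1.loc[t1["group"] == "nonsmoker", "sample_id"].tolist()
    ranges = fit_normal_ranges(m, sig, reference)
    ranges.to_tsv(out / "normal_ranges.tsv")
    idx = compute_isae(m, ranges)
    results["ranges"], results["index"] = ranges, idx

    logger.info("stage: classify")
    smokers = t1.loc[t1["group"] == "healthy_smoker", "sample_id"].tolist()
    labels = classify_responders(idx.isae.loc[smokers], rule=cfg.split_rule,
                                 alpha=cfg.split_alpha)
    idx.summary(labels.labels).to_csv(out / "index.tsv", sep="\t")
    results["labels"] = labels

    copd = t1.loc[t1["group"] == "copd", "sample_id"].tolist()
    membership = None
    if copd:
        member, frac = range_membership(idx.isae.loc[copd],
                                        idx.isae.loc[labels.samples("high")])
        membership = frac
        results["copd_membership"] = frac

    logger.info("stage: contrasts")
    contrast_summaries = []
    results["contrasts"] = {}
    for name in CONTRAST_NAMES:
        try:
            c = run_contrast(m, t1, labels, contrast=name,
                             present_min=cfg.present_min, fc_min=cfg.fc_min,
                             q_max=cfg.q_max_primary, ann=ann,
                             assume_present=cfg.assume_present)
        except AnalysisError as exc:
            logger.warning("contrast %s skipped: %s", name, exc)
            continue
        c.to_tsv(out / f"contrast_{name}.tsv")
        within, indep = partition_by_signature(c, sig)
        summary = c.summary() | {"n_within_signature": len(within),
                                 "n_independent": len(indep)}
        contrast_summaries.append(summary)
        results["contrasts"][name] = c
    _write_json(contrast_summaries, out / "contrasts.json")

    logger.info("stage: validation")
    kfold = kfold_robustness(m, t1, sig, k=cfg.kfold_k,
                             repetitions=cfg.kfold_repetitions, seed=cfg.seed)
    kfold.table.to_csv(out / "kfold.tsv", sep="\t")
    results["kfold"] = kfold

    sep = pc_separation(m, t1, list(sig.probes), labels=labels)
    _write_json({"component": sep.component,
                 "variance_fraction": sep.variance_fraction,
                 "statistic": sep.statistic, "p_value": sep.p_value},
                out / "pc_separation.json")
    results["pc_separation"] = sep

    covs = [c for c in cfg.covariates if c in pheno.columns]
    non_copd = t1[t1["group"] != "copd"]["sample_id"].tolist()
    screen = confounder_screen(idx.isae.loc[non_copd], t1, covs)
    screen.to_csv(out / "confounders.tsv", sep="\t")
    results["confounders"] = screen

    logger.info("stage: report")
    _write_json({"config_hash": cfg.config_hash(), "seed": cfg.seed,
                 "version": __version__, "config": cfg.to_dict()},
                out / "provenance.json")
    report = _render_report(cfg, sig, idx, labels, membership,
                            contrast_summaries, kfold, sep, screen, pheno)
    (out / "report.md").write_text(report)
    results["report_path"] = str(out / "report.md")
    return results


def _render_report(cfg, sig, idx, labels, membership, contrast_summaries,
                   kfold, sep, screen, pheno) -> str:
    t1 = pheno[pheno["timepoint"] == 1].set_index("sample_id")
    lines = [
        "# Small-airway-epithelium smoking-response run",
        "",
        f"- seed: {cfg.seed}; config hash: {cfg.config_hash()}",
        f"- signature: {len(sig.table)} probe sets, {sig.n_index_genes} "
        f"index-eligible genes "
        f"(present >= {cfg.present_min:.0%}, FC >= {cfg.fc_min}, "
        f"q < {cfg.q_max_primary})",
        "",
        "## I_SAE by group (percent of index genes out of range)",
        "",
    ]
    for group in ("nonsmoker", "healthy_smoker", "copd"):
        ids = t1.index[t1["group"] == group]
        vals = idx.isae.reindex(ids).dropna()
        if len(vals):
            lines.append(
                f"- {group}: n={len(vals)}, median {vals.median():.1f}%, "
                f"range {vals.min():.1f}-{vals.max():.1f}%, "
                f"variance {vals.var():.1f}"
            )
    n_low = len(labels.samples("low"))
    n_high = len(labels.samples("high"))
    lines += ["",
              f"Responder split ({labels.rule}, boundary {labels.boundary}): "
              f"{n_low} low / {n_high} high."]
    if membership is not None:
        lines.append(f"COPD smokers with I_SAE at/above the high-responder "
                     f"minimum: {100 * membership:.1f}%.")
    lines += ["", "## Genome-wide contrasts", ""]
    for s in contrast_summaries:
        lines.append(f"- {s['contrast']}: {s['n_significant_probes']} significant "
                     f"probe sets ({s['n_unique_genes']} unique genes; "
                     f"{s['n_within_signature']} within the smoking signature, "
                     f"{s['n_independent']} independent)")
    labeled = kfold.table["consistency"].dropna()
    lines += [
        "",
        "## Robustness",
        "",
        f"- K-fold ({kfold.k} folds x {kfold.repetitions} repetitions): "
        f"{100 * (labeled > 0.75).mean():.1f}% of labeled samples keep their "
        f"modal label in >75% of resamples.",
        f"- best separating principal component: #{sep.component + 1}, "
        f"{100 * sep.variance_fraction:.1f}% of variance, p = {sep.p_value:.2e}",
        "",
        "## Covariate screen (BH-adjusted)",
        "",
    ]
    for cov, row in screen.iterrows():
        if row["kind"] == "constant":
            lines.append(f"- {cov}: constant, skipped")
        else:
            extra = (f", R^2 = {row['variance_explained']:.3f}"
                     if np.isfinite(row["variance_explained"]) else "")
            lines.append(f"- {cov} ({row['kind']}): p = {row['p']:.3g}, "
                         f"q = {row['q']:.3g}{extra}")
    return "\n".join(lines) + "\n"
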