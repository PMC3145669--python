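"""Synthetic small-airway-epithelium cohorts with planted smoking effects.

The generator emulates the statistical structure the downstream analysis
assumes:

* per-gene log-normal baseline expression (log2 mean drawn uniformly in a
  configurable range, likewise the baseline SD);
* a planted set of smoking-responsive genes with random direction and
  log2 effect sizes of at least log2(1.5);
* a latent per-subject responsiveness ``r in [0, 1]`` that scales every
  planted effect — zero for nonsmokers, a 50/50 Beta(2,8)/Beta(8,2)
  mixture for healthy smokers (the bimodal low/high responder structure),
  Beta(8,2) for the COPD-like group so that COPD vs high-responder is a
  true null;
* smoker-variance inflation: the noise SD is scaled by ``1 + kappa * r``,
  reproducing the inflated log2 variance seen for smoking-responsive genes
  in smokers;
* Present/Absent detection calls drawn with logistic probability in the
  log2 signal.

On the log2 scale the signal is::

    x_gi = mu_g + r_i * d_g * delta_g + eps_gi,
    eps_gi ~ Normal(0, (sigma_g * (1 + kappa * r_i))^2)

and the emitted linear values are ``2**x`` floored at 0.01.  All streams
derive from the single config seed by fixed stage codes, so any stage is
reproducible in isolation and identical seeds give byte-identical cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_io import ExpressionMatrix, CohortError, validate_phenotypes

logger = logging.getLogger("saeindex")

LOG2_15 = float(np.log2(1.5))

# stage codes for deriving independent, documented random streams from the
# single config seed: rng(seed, stage) == default_rng(SeedSequence([seed, code]))
_STAGE_CODES = {
    "baseline": 11,
    "effects": 12,
    "responsiveness": 13,
    "covariates": 14,
    "noise": 15,
    "calls": 16,
    "visit": 17,
    "extend": 18,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Random generator for one named simulation stage of a cohort seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_CODES[stage]]))


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the real study's primary cohort: 47 nonsmokers, 58
    healthy smokers, 22 COPD smokers; planted effects of at least 1.5-fold;
    smoker-noise inflation strong enough that responsive genes show
    severalfold larger log2 variance in smokers than nonsmokers.
    """

    n_genes: int = 2000
    n_responsive: int = 200
    n_nonsmoker: int = 47
    n_smoker: int = 58
    n_copd: int = 22
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)   # log2 units
    baseline_sd_range: tuple[float, float] = (0.2, 0.8)      # log2 units
    effect_range: tuple[float, float] = (LOG2_15, 3.0)       # log2 units
    smoker_noise_inflation: float = 0.5                      # kappa
    low_beta: tuple[float, float] = (2.0, 8.0)
    high_beta: tuple[float, float] = (8.0, 2.0)
    high_weight: float = 0.5
    copd_beta: tuple[float, float] = (8.0, 2.0)
    responsiveness_scale: float = 1.0   # 0 turns every subject into a null
    call_midpoint: float = 5.0          # log2 value of 50% Present probability
    call_slope: float = 1.0
    noise_df: Optional[float] = None    # None = Gaussian; else scaled t (unit var)
    batch_offset_sd: float = 0.0        # optional per-sample log2 scalar offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responsive > self.n_genes:
            raise CohortError("n_responsive cannot exceed n_genes")
        for name in ("baseline_mean_range", "baseline_sd_range", "effect_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise CohortError(f"{name} must be ordered (lo <= hi)")
        if min(self.n_nonsmoker, self.n_smoker, self.n_copd) < 0:
            raise CohortError("group sizes must be non-negative")
        if self.seed is None:
            raise CohortError("seed is mandatory")
        if self.noise_df is not None and self.noise_df <= 2:
            raise CohortError("noise_df must exceed 2 (finite variance)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic cohort.

    ``genes`` is indexed by probe_id with columns gene_symbol, responsive,
    direction (+1/-1, 0 for non-responsive), effect (log2 units, 0 if
    non-responsive), baseline_mean, baseline_sd.  ``subjects`` is indexed by
    subject_id with columns sample_id, group, planted_class, responsiveness.
    """

    genes: pd.DataFrame
    subjects: pd.DataFrame

    @property
    def annotation(self) -> pd.Series:
        return self.genes["gene_symbol"].rename("gene_symbol")

    @property
    def responsive_probes(self) -> pd.Index:
        return self.genes.index[self.genes["responsive"]]

    def realized_effect(self, r_high_mean: float, r_low_mean: float = 0.0) -> pd.Series:
        """Expected log2 mean shift per gene for a given responsiveness gap."""
        return self.genes["effect"] * (r_high_mean - r_low_mean)


def _draw_noise(rng: np.random.Generator, shape: tuple[int, int],
                sd: np.ndarray, df: Optional[float]) -> np.ndarray:
    """Heteroscedastic noise; unit-variance t when df is set (heavier tails)."""
    if df is None:
        return rng.standard_normal(shape) * sd
    scale = np.sqrt((df - 2.0) / df)
    return rng.standard_t(df, size=shape) * scale * sd


def _signal_matrix(genes: pd.DataFrame, r: np.ndarray) -> np.ndarray:
    mu = genes["baseline_mean"].to_numpy()
    d_delta = (genes["direction"] * genes["effect"]).to_numpy()
    return mu[:, None] + np.outer(d_delta, r)


def _emit(cfg: SimulationConfig, genes: pd.DataFrame, r: np.ndarray,
          sample_ids: Sequence[str], noise_rng: np.random.Generator,
          calls_rng: np.random.Generator,
          extra_noise_sd: float = 0.0) -> ExpressionMatrix:
    sigma = genes["baseline_sd"].to_numpy()
    x = _signal_matrix(genes, r)
    sd = sigma[:, None] * (1.0 + cfg.smoker_noise_inflation * r[None, :])
    x = x + _draw_noise(noise_rng, x.shape, sd, cfg.noise_df)
    if extra_noise_sd > 0:
        x = x + noise_rng.standard_normal(x.shape) * extra_noise_sd
    if cfg.batch_offset_sd > 0:
        x = x + noise_rng.standard_normal(len(r))[None, :] * cfg.batch_offset_sd
    p_present = expit((x - cfg.call_midpoint) / cfg.call_slope)
    calls = np.where(calls_rng.random(x.shape) < p_present, "P", "A")
    values = np.maximum(np.exp2(x), 0.01)
    idx = genes.index
    cols = pd.Index(sample_ids, name="sample_id")
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        calls=pd.DataFrame(calls, index=idx, columns=cols),
        normalized=False,
    )


def _draw_genes(cfg: SimulationConfig) -> pd.DataFrame:
    rng_b = stage_rng(cfg.seed, "baseline")
    rng_e = stage_rng(cfg.seed, "effects")
    G = cfg.n_genes
    probe_ids = pd.Index([f"PS{i:05d}_at" for i in range(G)], name="probe_id")
    genes = pd.DataFrame(index=probe_ids)
    genes["gene_symbol"] = [f"GENE{i:05d}" for i in range(G)]
    genes["baseline_mean"] = rng_b.uniform(*cfg.baseline_mean_range, size=G)
    genes["baseline_sd"] = rng_b.uniform(*cfg.baseline_sd_range, size=G)
    responsive = np.zeros(G, dtype=bool)
    responsive[rng_e.choice(G, size=cfg.n_responsive, replace=False)] = True
    genes["responsive"] = responsive
    direction = np.zeros(G, dtype=int)
    direction[responsive] = rng_e.choice([-1, 1], size=cfg.n_responsive)
    genes["direction"] = direction
    effect = np.zeros(G)
    effect[responsive] = rng_e.uniform(*cfg.effect_range, size=cfg.n_responsive)
    genes["effect"] = effect
    return genes


def _draw_subjects(cfg: SimulationConfig, rng: np.random.Generator,
                   sizes: tuple[int, int, int], set_label: str,
                   prefix: str = "") -> pd.DataFrame:
    n_non, n_smk, n_copd = sizes
    rows = []
    counter = 0
    for group, n in (("nonsmoker", n_non), ("healthy_smoker", n_smk), ("copd", n_copd)):
        for _ in range(n):
            sid = f"{prefix}SUBJ{counter:03d}"
            if group == "nonsmoker":
                r, planted = 0.0, "nonsmoker"
            elif group == "healthy_smoker":
                if rng.random() < cfg.high_weight:
                    planted, params = "high", cfg.high_beta
                else:
                    planted, params = "low", cfg.low_beta
                r = rng.beta(*params)
            else:
                planted = "copd"
                r = rng.beta(*cfg.copd_beta)
            rows.append((sid, f"{prefix}S{counter:03d}", group, planted,
                         r * cfg.responsiveness_scale, set_label))
            counter += 1
    df = pd.DataFrame(rows, columns=["subject_id", "sample_id", "group",
                                     "planted_class", "responsiveness", "set"])
    return df.set_index("subject_id")


def _draw_covariates(subjects: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics drawn independently of responsiveness.

    Means/SDs follow the published cohort demographics (age ~42 in
    nonsmokers and smokers, ~51 in COPD; pack-years ~27.5 smokers / 41
    COPD; predominately male), so the confounder screen sees realistic
    but null covariates.
    """
    params = {
        "nonsmoker": dict(age=(42.4, 11.2), male=33 / 47, pack=None, fev1fvc=(82, 6)),
        "healthy_smoker": dict(age=(42.9, 7.2), male=38 / 58, pack=(27.5, 16.7),
                               fev1fvc=(81, 5)),
        "copd": dict(age=(51.5, 8.5), male=18 / 22, pack=(41.0, 28.2), fev1fvc=(61, 8)),
    }
    out = subjects.copy()
    age, sex, pack, years, ff = [], [], [], [], []
    for _, row in subjects.iterrows():
        p = params[row["group"]]
        a = float(np.clip(rng.normal(*p["age"]), 18, 80))
        age.append(round(a, 1))
        sex.append("M" if rng.random() < p["male"] else "F")
        if p["pack"] is None:
            pack.append(np.nan)
            years.append(np.nan)
        else:
            py = float(np.clip(rng.normal(*p["pack"]), 0.5, None))
            pack.append(round(py, 1))
            years.append(round(min(py / rng.uniform(0.5, 2.0), a - 15), 1))
        ff.append(round(float(rng.normal(*p["fev1fvc"])), 1))
    out["age"] = age
    out["sex"] = sex
    out["ancestry"] = rng.choice(["B", "W", "O"], size=len(subjects), p=[0.45, 0.35, 0.2])
    out["pack_years"] = pack
    out["smoking_years"] = years
    out["fev1_fvc"] = ff
    return out


def _phenotype_frame(subjects: pd.DataFrame, timepoint: int = 1) -> pd.DataFrame:
    pheno = subjects.reset_index()[
        ["sample_id", "subject_id", "group", "set", "age", "sex", "ancestry",
         "pack_years", "smoking_years", "fev1_fvc"]
    ].copy()
    pheno.insert(4, "timepoint", timepoint)
    return validate_phenotypes(pheno)


def generate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate the primary cohort: expression + calls, phenotypes, truth.

    Identical seeds give byte-identical outputs; every random stream is
    derived from ``cfg.seed`` by a fixed stage code.
    """
    genes = _draw_genes(cfg)
    subjects = _draw_subjects(cfg, stage_rng(cfg.seed, "responsiveness"),
                              (cfg.n_nonsmoker, cfg.n_smoker, cfg.n_copd), "primary")
    subjects = _draw_covariates(subjects, stage_rng(cfg.seed, "covariates"))
    m = _emit(cfg, genes, subjects["responsiveness"].to_numpy(),
              subjects["sample_id"].tolist(),
              stage_rng(cfg.seed, "noise"), stage_rng(cfg.seed, "calls"))
    truth = SyntheticTruth(genes=genes, subjects=subjects)
    return m, _phenotype_frame(subjects), truth


def plant_repeat_visit(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    subjects: Optional[Sequence[str]] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Second-bronchoscopy draws for a subject subset.

    Baseline means, responsiveness and planted effects are held fixed; the
    measurement noise is redrawn (from ``seed``; default a visit-2 stream
    derived from the cohort seed) and an optional extra between-visit
    perturbation of SD ``noise_sd`` (log2 units) is added.  Passing the
    cohort's own seed with ``noise_sd=0`` and all subjects reproduces the
    first visit exactly.
    """
    all_subjects = truth.subjects.index
    if subjects is None:
        subjects = list(all_subjects)
    unknown = [s for s in subjects if s not in all_subjects]
    if unknown:
        raise CohortError(f"unknown subjects: {unknown}")
    sub = truth.subjects.loc[list(subjects)]
    if seed is None:
        seed = int(np.random.SeedSequence(
            [cfg.seed, _STAGE_CODES["visit"]]).generate_state(1)[0] % (2**31))
    m = _emit(cfg, truth.genes, sub["responsiveness"].to_numpy(),
              [f"{s}_T2" for s in sub["sample_id"]],
              stage_rng(seed, "noise"), stage_rng(seed, "calls"),
              extra_noise_sd=noise_sd)
    pheno = sub.copy()
    pheno["sample_id"] = [f"{s}_T2" for s in sub["sample_id"]]
    return m, _phenotype_frame(pheno, timepoint=2)


def extend_cohort(
    cfg: SimulationConfig,
    truth: SyntheticTruth,
    n_nonsmoker: int = 16,
    n_smoker: int = 14,
    n_copd: int = 14,
    set_label: str = "validation",
    seed: Optional[int] = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw additional subjects (a validation set) against the same genes.

    Returns (matrix, phenotypes, subject truth table).  Default sizes
    mirror the study's validation set (16/14/14).
    """
    if seed is None:
        seed = int(np.random.SeedSequence(
            [cfg.seed, _STAGE_CODES["extend"]]).generate_state(1)[0] % (2**31))
    subjects = _draw_subjects(cfg, stage_rng(seed, "responsiveness"),
                              (n_nonsmoker, n_smoker, n_copd), set_label, prefix="V")
    subjects = _draw_covariates(subjects, stage_rng(seed, "covariates"))
    m = _emit(cfg, truth.genes, subjects["responsiveness"].to_numpy(),
              subjects["sample_id"].tolist(),
              stage_rng(seed, "noise"), stage_rng(seed, "calls"))
    return m, _phenotype_frame(subjects), subjects


# ---------------------------------------------------------------------------
# truth writers (TSV interfaces)
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, gene_path, subject_path) -> None:
    truth.genes.to_csv(gene_path, sep="\t")
    truth.subjects.to_csv(subject_path, sep="\t")


def read_truth(gene_path, subject_path) -> SyntheticTruth:
    genes = pd.read_csv(gene_path, sep="\t", index_col=0)
    subjects = pd.read_csv(subject_path, sep="\t", index_col=0)
    return SyntheticTruth(genes=genes, subjects=subjects)
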