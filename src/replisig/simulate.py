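"""Synthetic two-study case-control expression data with known ground truth.

The generator emulates a pair of independent whole-blood case-control
microarray studies analysed on a common probe set: per-gene linear model
structure (intercept + group + batch + sex + age + anxiety + Gaussian noise),
hierarchical gene variances drawn from a scaled inverse chi-square prior, a
set of differentially expressed (DE) genes shared between the studies with
concordant fold-change sign, study-specific DE genes, and a per-case latent
"inflammation" factor that couples the mean expression of the planted UP
genes to the mean expression of the planted DOWN genes with a configurable
negative correlation.

Default sizes mirror the two study designs the pipeline targets: 113 cases /
57 controls and 94 cases / 100 controls on 18,863 probes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParameterError
from .study import CASE, CONTROL, ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "sample_gene_variances",
    "generate_two_studies",
    "write_fixture_bundle",
]


@dataclass
class SimConfig:
    """Parameters of the two-study simulation.

    Defaults encode the reference study conditions: two studies of 113/57 and
    94/100 cases/controls on 18,863 genes, 200 shared sign-concordant DE
    genes with |log2 fold change| 0.8 (55% overexpressed), 100 study-specific
    DE genes per study, scaled-inverse-chi-square gene variances with prior
    df 4 and prior variance 0.25 log2^2, and a latent per-case factor tuned
    so that the case-level correlation between mean UP and mean DOWN
    expression is -0.8.
    """

    n_genes: int = 18863
    n_cases: tuple[int, int] = (113, 94)
    n_controls: tuple[int, int] = (57, 100)
    n_shared_de: int = 200
    n_specific_de: tuple[int, int] = (100, 100)
    lfc_mean: float = 0.8        # mean |log2 fold change| of DE genes
    lfc_sd: float = 0.0          # sd of |log2 fold change| draws
    frac_up: float = 0.55        # fraction of DE genes overexpressed in cases
    d0: float = 4.0              # prior df of the gene-variance distribution
    s0_sq: float = 0.25          # prior variance, log2^2
    batch_effect_sd: float = 0.2
    sex_effect_sd: float = 0.1
    age_effect_sd: float = 0.005  # per year of age
    anxiety_effect_sd: float = 0.1
    rho_target: float = -0.8     # target case-level corr(meanUP, meanDOWN)
    baseline_mean: float = 7.0   # log2 abundance baseline
    baseline_sd: float = 1.0
    t_noise_df: float | None = None  # optional heavy-tailed noise switch
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        for nc, nk in zip(self.n_cases, self.n_controls):
            if nc < 2 or nk < 2:
                raise ParameterError("each group needs at least 2 samples")
        if self.n_shared_de < 0 or any(k < 0 for k in self.n_specific_de):
            raise ParameterError("DE gene counts must be nonnegative")
        for k in self.n_specific_de:
            if self.n_shared_de + k > self.n_genes:
                raise ParameterError(
                    "more DE genes than genes: "
                    f"{self.n_shared_de}+{k} > {self.n_genes}"
                )
        if not -1.0 <= self.rho_target <= 0.0:
            raise ParameterError("rho_target must lie in [-1, 0]")
        if self.rho_target <= -0.999:
            raise ParameterError(
                "rho_target at or near -1 requires unbounded latent variance"
            )
        if not 0.0 <= self.frac_up <= 1.0:
            raise ParameterError("frac_up must lie in [0, 1]")
        if not (self.d0 > 0 or math.isinf(self.d0)):
            raise ParameterError("d0 must be positive (or infinite)")
        if self.s0_sq <= 0:
            raise ParameterError("s0_sq must be positive")


@dataclass
class SimTruth:
    """Ground truth planted by :func:`generate_two_studies`.

    ``genes`` holds one row per gene id with columns ``shared`` (bool),
    ``specific_study1``/``specific_study2`` (bool), ``sign`` (+1/-1/0),
    ``lfc`` (signed log2 fold change, 0 for non-DE), and per-study true
    residual variances ``sigma2_study1``/``sigma2_study2``. ``latent`` maps
    study name to the per-case latent factor values.
    """

    genes: pd.DataFrame
    latent: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def shared_ids(self) -> pd.Index:
        return self.genes.index[self.genes["shared"]]

    @property
    def up_ids(self) -> pd.Index:
        mask = self.genes["shared"] & (self.genes["sign"] > 0)
        return self.genes.index[mask]

    @property
    def down_ids(self) -> pd.Index:
        mask = self.genes["shared"] & (self.genes["sign"] < 0)
        return self.genes.index[mask]

    def specific_ids(self, study: int) -> pd.Index:
        return self.genes.index[self.genes[f"specific_study{study}"]]

    def sign_of(self, gene_ids: Sequence[str]) -> pd.Series:
        return self.genes.loc[list(gene_ids), "sign"]


def sample_gene_variances(
    n_genes: int,
    d0: float,
    s0_sq: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw per-gene true variances from a scaled inverse chi-square prior.

    sigma_i^2 = d0 * s0_sq / X_i with X_i ~ chi-square(d0). An infinite ``d0``
    collapses the prior to the point mass at ``s0_sq``.
    """
    if s0_sq <= 0:
        raise ParameterError("s0_sq must be positive")
    if not (d0 > 0 or math.isinf(d0)):
        raise ParameterError("d0 must be positive or infinite")
    if math.isinf(d0):
        return np.full(n_genes, float(s0_sq))
    rng = np.random.default_rng(seed)
    return d0 * s0_sq / rng.chisquare(d0, size=n_genes)


def _gene_ids(n: int) -> pd.Index:
    width = max(6, len(str(n)))
    return pd.Index([f"G{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")


def _latent_variance(rho: float, v_up: float, v_down: float) -> float:
    """Latent variance c achieving corr(meanUP, meanDOWN) = -rho among cases.

    With a unit-loading latent g ~ N(0, c) added to UP genes and subtracted
    from DOWN genes, cov(meanUP, meanDOWN) = -c and var(mean) = c + v, where
    v is the averaging-noise variance of each signature mean. Solving
    rho^2 (c + v_up)(c + v_down) = c^2 for the positive root gives c.
    """
    if rho <= 0:
        return 0.0
    a = 1.0 - rho * rho
    b = rho * rho * (v_up + v_down)
    d = rho * rho * v_up * v_down
    return (b + math.sqrt(b * b + 4.0 * a * d)) / (2.0 * a)


def _simulate_study(
    name: str,
    n_cases: int,
    n_controls: int,
    cfg: SimConfig,
    gene_index: pd.Index,
    baseline: np.ndarray,
    lfc: np.ndarray,          # signed planted log2FC for this study (0 = non-DE)
    coupling_sign: np.ndarray,  # +1/-1 on shared DE genes, 0 elsewhere
    ss: np.random.SeedSequence,
) -> tuple[ExpressionStudy, np.ndarray, pd.Series]:
    """Generate one study; returns (study, sigma2, latent factor per case)."""
    rng = np.random.default_rng(ss)
    n = n_cases + n_controls
    n_genes = len(gene_index)

    sample_ids = pd.Index([f"{name}_S{j:04d}" for j in range(1, n + 1)], name="sample_id")
    group = np.array([CASE] * n_cases + [CONTROL] * n_controls)
    samples = pd.DataFrame(
        {
            "group": group,
            "batch": rng.integers(1, 3, size=n),
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.uniform(20.0, 65.0, size=n),
            "anxiety": rng.integers(0, 2, size=n),
        },
        index=sample_ids,
    )

    sigma2 = sample_gene_variances(n_genes, cfg.d0, cfg.s0_sq, rng)
    sigma = np.sqrt(sigma2)

    # per-gene covariate coefficients (additive, as in the per-gene linear model)
    beta_batch = rng.normal(0.0, cfg.batch_effect_sd, size=n_genes)
    beta_sex = rng.normal(0.0, cfg.sex_effect_sd, size=n_genes)
    beta_age = rng.normal(0.0, cfg.age_effect_sd, size=n_genes)
    beta_anx = rng.normal(0.0, cfg.anxiety_effect_sd, size=n_genes)

    x_batch = (samples["batch"].to_numpy() == 2).astype(float)
    x_sex = (samples["sex"].to_numpy() == "female").astype(float)
    x_age = samples["age"].to_numpy() - 42.5  # centred so baseline stays interpretable
    x_anx = samples["anxiety"].to_numpy().astype(float)
    is_case = (group == CASE).astype(float)

    y = (
        baseline[:, None]
        + np.outer(beta_batch, x_batch)
        + np.outer(beta_sex, x_sex)
        + np.outer(beta_age, x_age)
        + np.outer(beta_anx, x_anx)
        + np.outer(lfc, is_case)
    )

    # latent coupling factor: per-case scalar shifting UP genes up, DOWN genes down
    up = coupling_sign > 0
    down = coupling_sign < 0
    latent = pd.Series(0.0, index=sample_ids[group == CASE], name="latent")
    if up.any() and down.any() and cfg.rho_target < 0:
        v_up = sigma2[up].mean() / up.sum()
        v_down = sigma2[down].mean() / down.sum()
        c = _latent_variance(-cfg.rho_target, v_up, v_down)
        g = rng.normal(0.0, math.sqrt(c), size=n_cases)
        latent[:] = g
        y[:, :n_cases] += np.outer(coupling_sign, g)

    if cfg.t_noise_df is not None:
        noise = rng.standard_t(cfg.t_noise_df, size=(n_genes, n))
        noise *= math.sqrt((cfg.t_noise_df - 2) / cfg.t_noise_df)  # unit variance
    else:
        noise = rng.standard_normal((n_genes, n))
    y += sigma[:, None] * noise

    expression = pd.DataFrame(y, index=gene_index, columns=sample_ids)
    return ExpressionStudy(expression, samples, name=name), sigma2, latent


def generate_two_studies(
    config: SimConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, SimTruth]:
    """Generate the paired case-control studies and the planted ground truth.

    Both studies share gene ids and the shared DE genes carry the same signed
    fold change in both. Randomness is split from ``config.seed`` with a
    counter-based :class:`numpy.random.SeedSequence`, so each stage (truth
    assignment, study 1, study 2) draws from an independent stream.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_truth, ss_s1, ss_s2 = root.spawn(3)
    rng = np.random.default_rng(ss_truth)

    genes = _gene_ids(config.n_genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    shared_pos = rng.choice(config.n_genes, size=config.n_shared_de, replace=False)
    pool = np.setdiff1d(np.arange(config.n_genes), shared_pos)
    # study-specific DE genes are drawn per study: disjoint from the shared
    # set within each study, but the two studies' specific sets may overlap
    spec1_pos = rng.choice(pool, size=config.n_specific_de[0], replace=False)
    spec2_pos = rng.choice(pool, size=config.n_specific_de[1], replace=False)

    def planted_signs(k: int) -> np.ndarray:
        n_up = int(round(config.frac_up * k))
        signs = np.concatenate([np.ones(n_up), -np.ones(k - n_up)])
        rng.shuffle(signs)
        return signs

    def planted_magnitudes(k: int) -> np.ndarray:
        return np.abs(rng.normal(config.lfc_mean, config.lfc_sd, size=k))

    shared_sign = planted_signs(config.n_shared_de)
    shared_lfc = shared_sign * planted_magnitudes(config.n_shared_de)
    spec_lfc = [
        planted_signs(k) * planted_magnitudes(k) for k in config.n_specific_de
    ]

    sign = np.zeros(config.n_genes)
    sign[shared_pos] = shared_sign
    lfc_all = np.zeros(config.n_genes)
    lfc_all[shared_pos] = shared_lfc

    coupling_sign = np.zeros(config.n_genes)
    coupling_sign[shared_pos] = shared_sign

    studies: list[ExpressionStudy] = []
    sigma2s: list[np.ndarray] = []
    latents: dict[str, pd.Series] = {}
    for i, (ss, spec_pos, slfc) in enumerate(
        [(ss_s1, spec1_pos, spec_lfc[0]), (ss_s2, spec2_pos, spec_lfc[1])]
    ):
        lfc = lfc_all.copy()
        lfc[spec_pos] = slfc
        study, sigma2, latent = _simulate_study(
            f"study{i + 1}",
            config.n_cases[i],
            config.n_controls[i],
            config,
            genes,
            baseline,
            lfc,
            coupling_sign,
            ss,
        )
        studies.append(study)
        sigma2s.append(sigma2)
        latents[study.name] = latent

    truth_genes = pd.DataFrame(
        {
            "shared": np.zeros(config.n_genes, dtype=bool),
            "specific_study1": np.zeros(config.n_genes, dtype=bool),
            "specific_study2": np.zeros(config.n_genes, dtype=bool),
            "sign": sign.astype(int),
            "lfc": lfc_all,
            "sigma2_study1": sigma2s[0],
            "sigma2_study2": sigma2s[1],
        },
        index=genes,
    )
    truth_genes.iloc[shared_pos, truth_genes.columns.get_loc("shared")] = True
    truth_genes.iloc[spec1_pos, truth_genes.columns.get_loc("specific_study1")] = True
    truth_genes.iloc[spec2_pos, truth_genes.columns.get_loc("specific_study2")] = True

    truth = SimTruth(genes=truth_genes, latent=latents)
    logger.info(
        "simulated %d genes; %d shared DE (%d up / %d down), specific %s",
        config.n_genes,
        config.n_shared_de,
        int((shared_sign > 0).sum()),
        int((shared_sign < 0).sum()),
        config.n_specific_de,
    )
    return studies[0], studies[1], truth


def write_fixture_bundle(
    study_pair: tuple[ExpressionStudy, ExpressionStudy],
    truth: SimTruth,
    directory: str | Path,
    config: SimConfig | None = None,
) -> list[Path]:
    """Write expression/metadata/truth/config files; return the manifest.

    The directory must already exist; a missing path raises before any file
    is written.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    manifest: list[Path] = []
    for study in study_pair:
        expr_path = directory / f"{study.name}_expression.tsv"
        study.expression.to_csv(expr_path, sep="\t", float_format="%.9g")
        manifest.append(expr_path)
        meta_path = directory / f"{study.name}_samples.tsv"
        study.samples.to_csv(meta_path, sep="\t", float_format="%.9g")
        manifest.append(meta_path)
    truth_path = directory / "truth.tsv"
    truth.genes.to_csv(truth_path, sep="\t", float_format="%.9g")
    manifest.append(truth_path)
    for name, latent in truth.latent.items():
        latent_path = directory / f"{name}_latent.tsv"
        latent.to_csv(latent_path, sep="\t", float_format="%.9g")
        manifest.append(latent_path)
    if config is not None:
        cfg_path = directory / "sim_config.yaml"
        cfg = asdict(config)
        cfg["n_cases"] = list(config.n_cases)
        cfg["n_controls"] = list(config.n_controls)
        cfg["n_specific_de"] = list(config.n_specific_de)
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        manifest.append(cfg_path)
    return manifest
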