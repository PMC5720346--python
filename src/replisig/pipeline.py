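"""End-to-end two-study replication pipeline.

Flow: per-study moderated-t differential expression -> overlap profile and
q2 selection -> sign-concordant consensus lists (with Fisher-combination
corroboration) -> optional gene-set enrichment -> per-study coupled UP/DOWN
bioscalar summaries. Inputs are either two on-disk studies or a synthetic
configuration; all intermediate tables are written and a compact summary is
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .bioscalar import CoupledSignatureScorer
from .diffexpr import DEFAULT_COVARIATES, ModeratedTTest
from .enrichment import bonferroni_threshold, fisher_enrichment, load_gene_sets
from .exceptions import ConfigError, ReplisigError
from .io import read_expression_study, write_gene_list, write_results
from .replication import ReplicationSelector
from .simulate import SimConfig, generate_two_studies
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

NO_REPLICATION = "no replicated signal"


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be given: the four study paths, or a
    :class:`SimConfig` for a synthetic run.
    """

    study1_expression: str | None = None
    study1_metadata: str | None = None
    study2_expression: str | None = None
    study2_metadata: str | None = None
    sim: SimConfig | None = None
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    ratio_rule: float = 2.0
    p_max: float = 0.05
    fdr_level: float = 0.10
    n_perm: int = 0
    gmt_path: str | None = None
    alpha: float = 0.05
    standardize_signatures: bool = True
    out_dir: str = "replisig_output"
    seed: int = 0

    def __post_init__(self) -> None:
        paths = [
            self.study1_expression,
            self.study1_metadata,
            self.study2_expression,
            self.study2_metadata,
        ]
        has_paths = any(p is not None for p in paths)
        if has_paths and self.sim is not None:
            raise ConfigError("give either study paths or a simulation config, not both")
        if not has_paths and self.sim is None:
            raise ConfigError("one input source required: study paths or sim config")
        if has_paths and not all(p is not None for p in paths):
            raise ConfigError("all four study paths are required for a real-data run")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            for key in ("n_cases", "n_controls", "n_specific_de"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(sim=sim, **raw)


def _load_studies(config: PipelineConfig) -> tuple[ExpressionStudy, ExpressionStudy, Any]:
    if config.sim is not None:
        s1, s2, truth = generate_two_studies(config.sim)
        return s1, s2, truth
    s1 = read_expression_study(
        config.study1_expression, config.study1_metadata, name="study1"
    )
    s2 = read_expression_study(
        config.study2_expression, config.study2_metadata, name="study2"
    )
    return s1, s2, None


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; write artifacts; return a summary dict.

    On a stage failure a ``FAILED`` marker naming the stage is left in the
    output directory alongside whatever tables were already written.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    summary: dict[str, Any] = {"seed": config.seed}
    stage = "load"
    try:
        study1, study2, truth = _load_studies(config)
        logger.info(
            "loaded %s (%d genes x %d samples) and %s (%d x %d)",
            study1.name, study1.n_genes, study1.n_samples,
            study2.name, study2.n_genes, study2.n_samples,
        )

        stage = "diffexpr"
        stats = {}
        for study in (study1, study2):
            model = ModeratedTTest(
                covariates=config.covariates, n_perm=config.n_perm, seed=config.seed
            ).fit(study)
            stats[study.name] = model.results_
            tables[f"{study.name}_gene_stats"] = model.results_
            summary[f"{study.name}_prior_d0"] = model.prior_.d0
            summary[f"{study.name}_prior_s0_sq"] = model.prior_.s0_sq

        stage = "replication"
        selector = ReplicationSelector(
            ratio_rule=config.ratio_rule,
            p_max=config.p_max,
            fdr_level=config.fdr_level,
        ).fit(stats[study1.name], stats[study2.name])
        tables["overlap_profile"] = selector.profile_.table
        tables["fisher_combined"] = selector.combined_
        summary["q2"] = selector.q2_
        summary["n_fdr_rejected"] = int(selector.combined_["rejected"].sum())
        if selector.q2_ is None:
            summary["status"] = NO_REPLICATION
            write_results(tables, out_dir)
            _write_summary(summary, out_dir)
            return summary
        consensus = selector.consensus_
        summary.update(
            n_replicated=consensus.n_replicated,
            n_up=len(consensus.up),
            n_down=len(consensus.down),
            n_discordant=len(consensus.discordant),
        )
        write_gene_list(consensus.up, out_dir / "consensus_up.txt")
        write_gene_list(consensus.down, out_dir / "consensus_down.txt")
        tables["consensus"] = pd.DataFrame(
            {
                "gene_id": list(consensus.up) + list(consensus.down),
                "direction": ["UP"] * len(consensus.up) + ["DOWN"] * len(consensus.down),
            }
        ).set_index("gene_id")

        if truth is not None:
            stage = "truth-comparison"
            planted = truth.genes.loc[truth.genes["shared"], "sign"]
            recovered = consensus.concordant.intersection(planted.index)
            summary["consensus_sensitivity"] = (
                len(recovered) / len(planted) if len(planted) else None
            )
            if len(recovered):
                rec_sign = pd.Series(1, index=consensus.up).reindex(recovered).fillna(-1)
                summary["sign_concordance_with_truth"] = float(
                    (rec_sign == planted.loc[recovered]).mean()
                )

        if config.gmt_path is not None:
            stage = "enrichment"
            collection = load_gene_sets(
                config.gmt_path, universe=stats[study1.name].index
            )
            enr = fisher_enrichment(
                consensus.concordant, collection, alpha=config.alpha
            )
            tables["enrichment"] = enr
            summary["bonferroni_threshold"] = bonferroni_threshold(
                config.alpha, collection.n_terms
            )
            summary["n_terms_bonferroni_significant"] = int(
                enr["bonferroni_significant"].sum()
            )

        stage = "bioscalar"
        if len(consensus.up) and len(consensus.down):
            for study in (study1, study2):
                scorer = CoupledSignatureScorer(
                    up_ids=consensus.up,
                    down_ids=consensus.down,
                    standardize=config.standardize_signatures,
                ).fit(study)
                tables[f"{study.name}_bioscalar"] = scorer.scores_
                for key, value in scorer.summary_.items():
                    summary[f"{study.name}_{key}"] = value
        else:
            summary["bioscalar"] = "skipped: one-sided consensus set"

        stage = "write"
        manifest = write_results(tables, out_dir)
        summary["status"] = "ok"
        summary["n_tables"] = len(manifest)
        _write_summary(summary, out_dir)
        return summary
    except ReplisigError:
        (out_dir / "FAILED").write_text(f"stage: {stage}\n")
        logger.error("pipeline failed at stage %s", stage)
        raise


def _write_summary(summary: dict[str, Any], out_dir: Path) -> None:
    clean = {
        k: (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v)
        for k, v in summary.items()
    }
    (out_dir / "summary.yaml").write_text(yaml.safe_dump(clean, sort_keys=True))
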