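"""End-to-end orchestration of the three analysis steps.

A single :class:`PipelineConfig` (round-trippable through YAML) drives
Step 1 (per-subject FCN construction), Step 2 (attention classification,
attention-matrix extraction, group representative matrices, top-quartile
lists) and Step 3 (LSIRM per group, alignment, origin proximity,
categorization, summary FCNs and neighbor clusters). Every intermediate
artifact is written under ``output_dir/step{1,2,3}/`` and the run ends with
a deterministic JSON report.

One global seed fans out to per-stage seeds by fixed offsets so stage-level
reruns remain reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from fcnfusion import io as fio
from fcnfusion.attention import AttnConfig, train_and_extract
from fcnfusion.datatypes import RoiTimeSeries
from fcnfusion.fcn import embed_rois, fisher_z, pearson_matrix
from fcnfusion.group_rep import build_group_matrix, top_quartile_rois
from fcnfusion.lsirm import McmcConfig, origin_proximity, rotate_positions, run_mcmc
from fcnfusion.mapper import MapperConfig, mapper_fcn
from fcnfusion.summary import (
    categorize_rois,
    extract_clusters,
    group_summary,
    render_summary,
)
from fcnfusion.synthetic import CohortSpec, simulate_cohort

logger = logging.getLogger("fcnfusion.pipeline")

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"cohort": 1, "embedding": 2, "attention": 3, "lsirm": 5}


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    output_dir: str = "fcnfusion_run"
    seed: int = 0
    manifest: str | None = None          # read an existing cohort ...
    cohort: CohortSpec | None = None     # ... or simulate one
    input_kind: str = "pearson"          # pearson | fisher_z | mapper
    embedding_method: str = "topological"
    embedding_params: dict = field(default_factory=dict)
    mapper: MapperConfig = field(default_factory=MapperConfig)
    attention: AttnConfig = field(default_factory=AttnConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    selection_mode: str = "rank_sum"     # rank_sum | intersection
    summary_threshold: float = 0.2
    render: bool = False

    def __post_init__(self) -> None:
        if self.input_kind not in ("pearson", "fisher_z", "mapper"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.manifest is None and self.cohort is None:
            raise ValueError("either a manifest path or a CohortSpec is required")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = CohortSpec(**d["cohort"])
        if isinstance(d.get("mapper"), dict):
            d["mapper"] = MapperConfig(**d["mapper"])
        if isinstance(d.get("attention"), dict):
            d["attention"] = AttnConfig(**d["attention"])
        if isinstance(d.get("mcmc"), dict):
            d["mcmc"] = McmcConfig(**d["mcmc"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    return int(cfg.seed) + SEED_OFFSETS[stage]


def _load_cohort(cfg: PipelineConfig) -> list[RoiTimeSeries]:
    if cfg.manifest is not None:
        return fio.read_cohort(cfg.manifest)
    spec = dataclasses.replace(cfg.cohort, seed=_stage_seed(cfg, "cohort"))
    return simulate_cohort(spec)


def build_inputs(cfg: PipelineConfig, cohort: list[RoiTimeSeries], step_dir: Path):
    """Step 1: classifier inputs plus binary FCNs for the summary stage."""
    step_dir.mkdir(parents=True, exist_ok=True)
    inputs, fcns = [], []
    emb_seed = _stage_seed(cfg, "embedding")
    for ts in cohort:
        corr = pearson_matrix(ts)
        if cfg.input_kind == "pearson":
            inp = corr
        elif cfg.input_kind == "fisher_z":
            inp = fisher_z(corr)
        emb = embed_rois(ts, cfg.embedding_method, cfg.embedding_params, seed=emb_seed)
        fcn = mapper_fcn(emb, cfg.mapper)
        if cfg.input_kind == "mapper":
            inp = fcn
        inputs.append(inp)
        fcns.append(fcn)
        fio.write_fcn(fcn, step_dir / f"fcn_{ts.subject_id}.csv")
    return inputs, fcns


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all three steps; returns (and writes) the run report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    report: dict = {"seed": cfg.seed, "input_kind": cfg.input_kind}

    stage = "load cohort"
    try:
        cohort = _load_cohort(cfg)
        groups = sorted({ts.group for ts in cohort})
        if len(groups) != 2:
            raise ValueError(f"exactly two groups required, found {groups}")
        report["groups"] = groups
        report["n_subjects"] = {g: sum(ts.group == g for ts in cohort) for g in groups}

        stage = "step1 (FCN construction)"
        logger.info("step1: building inputs for %d subjects", len(cohort))
        inputs, fcns = build_inputs(cfg, cohort, out / "step1")

        stage = "step2 (attention classification)"
        logger.info("step2: training attention classifier")
        attn_cfg = dataclasses.replace(cfg.attention, seed=_stage_seed(cfg, "attention"))
        cv_acc, attn_matrices = train_and_extract(
            inputs,
            [ts.group for ts in cohort],
            attn_cfg,
            subject_ids=[ts.subject_id for ts in cohort],
            roi_labels=cohort[0].roi_labels,
        )
        report["cv_accuracy"] = round(cv_acc, 6)
        if cv_acc < 0.6:
            report["warning"] = (
                "cross-validated accuracy is near chance; attention matrices "
                "may be uninformative"
            )
            logger.warning(report["warning"])
        step2 = out / "step2"
        fio.write_attention_set(attn_matrices, step2)

        report["top_rois"] = {}
        group_matrices, top_lists = {}, {}
        for g in groups:
            mats = [m for m in attn_matrices if m.group == g]
            gm = build_group_matrix(mats)
            top = top_quartile_rois(gm, mats, mode=cfg.selection_mode)
            group_matrices[g], top_lists[g] = gm, top
            fio.write_group_matrix(gm, step2 / f"group_matrix_{g}.csv")
            fio.write_top_list(top, step2 / f"top_rois_{g}.csv")
            report["top_rois"][g] = list(top.labels)

        stage = "step3 (LSIRM + summary networks)"
        step3 = out / "step3"
        step3.mkdir(parents=True, exist_ok=True)
        near_origin, report["lsirm"] = {}, {}
        for k, g in enumerate(groups):
            logger.info("step3: LSIRM for group %s", g)
            mcfg = dataclasses.replace(cfg.mcmc, seed=_stage_seed(cfg, "lsirm") + k)
            post = run_mcmc(group_matrices[g], mcfg)
            rot = rotate_positions(
                (post.aligned_U if post.aligned_U is not None else post.U).mean(axis=0)
            )
            post.rotated_U_mean = rot["rotated"]
            prox = origin_proximity(post)
            near_origin[g] = set(prox.loc[prox.near_origin, "roi"])
            fio.write_posterior(post, step3 / f"posterior_{g}.h5")
            fio.write_position_summary(post, step3 / f"positions_{g}.csv")
            prox.to_csv(step3 / f"origin_proximity_{g}.csv", index=False)
            report["lsirm"][g] = {
                "n_retained": post.n_retained,
                "acceptance_rates": {
                    k2: round(v, 4) for k2, v in post.acceptance_rates.items()
                },
                "near_origin": sorted(near_origin[g]),
            }

        ga, gb = groups
        categories = categorize_rois(
            top_lists[ga], top_lists[gb], near_origin[ga], near_origin[gb],
            cohort[0].roi_labels,
        )
        fio.write_category_map(categories, step3 / "roi_categories.csv")
        counts: dict[str, int] = {}
        for cat in categories.values():
            counts[cat] = counts.get(cat, 0) + 1
        report["category_counts"] = dict(sorted(counts.items()))

        report["clusters"] = {}
        for g in groups:
            fcns_g = [f for f, ts in zip(fcns, cohort) if ts.group == g]
            summary = group_summary(fcns_g, cfg.summary_threshold, group=g)
            fio.write_summary_fcn(summary, step3 / f"summary_fcn_{g}")
            clusters = extract_clusters(summary, categories)
            report["clusters"][g] = [
                {"name": c["name"], "roi": c["roi"], "category": c["category"],
                 "size": len(c["members"])}
                for c in clusters
            ]
            if cfg.render:
                render_summary(summary, categories, step3 / f"summary_{g}.svg")
    except Exception:
        logger.exception("pipeline failed during %s", stage)
        (out / "report_partial.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
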