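"""End-to-end orchestration: cohort -> AI -> group statistics -> prediction.

`analyze_cohort` runs the in-memory pipeline the stages define:
denoising (optional), Fisher-z FC, hemispheric blocks, group gradient
templates, per-subject embedding and Procrustes alignment, asymmetry
indices, ComBat harmonization of the AI features, multivariate
region- and network-level MDD-vs-HC tests, and (optionally) the nested
elastic-net BDI prediction. `run_pipeline` is the file-level wrapper the
CLI uses: it reads a cohort directory, runs `analyze_cohort`, and writes
every stage output plus a machine-readable provenance log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .asymmetry import AsymmetryIndex, ai_feature_matrix, compute_ai, group_ai_maps
from .combat import combat_harmonize
from .connectome import compute_fc, partition_fc
from .gradients import GradientConfig, align_subject, build_templates
from .predict import nested_elasticnet_predict, permutation_pvalue
from .prep import denoise, min_duration_ok
from .stats import network_aggregate, unitwise_group_comparison
from .synth import CohortDataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-level run configuration (paths, thresholds, options, seed)."""

    cohort_dir: str
    out_dir: str
    seed: int = 0
    prep: bool = True
    gsr: bool = False
    fd_thresh: float = 0.35
    dvars_thresh: float = 50.0
    band: tuple = (0.01, 0.1)
    min_seconds: float = 240.0
    gradient: GradientConfig = field(default_factory=GradientConfig)
    template_provenance: str = "all_subjects"
    n_gradients: int = 3
    run_prediction: bool = False
    l1_ratio_intra: float = 0.5
    l1_ratio_inter: float = 0.9
    n_splits: int = 100
    n_perm: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        grad = raw.pop("gradient", None)
        cfg = cls(**raw)
        if grad:
            cfg.gradient = GradientConfig(**grad)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gradient"] = dataclasses.asdict(self.gradient)
        return d


def subject_blocks(dataset: CohortDataset, cfg: RunConfig):
    """Denoise (optionally), estimate FC, and cut blocks for every subject.

    Subjects with less than ``cfg.min_seconds`` of data after scrubbing
    are excluded (with a logged note). Returns (blocks list, kept subject
    indices).
    """
    blocks, kept = [], []
    for i, s in enumerate(dataset.subjects):
        ts = s.timeseries
        if cfg.prep:
            cleaned, mask = denoise(
                ts,
                motion=s.motion,
                band=cfg.band,
                gsr=cfg.gsr,
                fd_thresh=cfg.fd_thresh,
                dvars_thresh=cfg.dvars_thresh,
                tr=s.tr,
            )
            if s.motion is not None and not min_duration_ok(mask, s.tr, cfg.min_seconds):
                logger.info(
                    "excluding %s: %.1f s after scrubbing < %.0f s",
                    s.subject_id, mask.n_kept * s.tr, cfg.min_seconds,
                )
                continue
            ts = cleaned
        fc = compute_fc(ts)
        blocks.append(partition_fc(fc, dataset.parcellation))
        kept.append(i)
    if not blocks:
        raise ValueError("no subject survived preprocessing")
    return blocks, kept


def analyze_cohort(
    dataset: CohortDataset, cfg: RunConfig | None = None
) -> dict:
    """Run the full analysis in memory; returns a result bundle dict.

    Keys: ``subjects`` (kept ids), ``template``, ``ais``, ``ai_intra`` /
    ``ai_inter`` (harmonized feature frames), ``region_<scope>_mv`` /
    ``region_<scope>_posthoc`` / ``network_<scope>_mv`` /
    ``network_<scope>_posthoc`` result frames, ``group_maps_<scope>``,
    and optionally ``prediction_<scope>``.
    """
    cfg = cfg or RunConfig(cohort_dir="", out_dir="")
    blocks, kept = subject_blocks(dataset, cfg)
    subjects = [dataset.subjects[i] for i in kept]
    groups = [s.group for s in subjects]
    sites = np.array([s.site for s in subjects])
    covariates = np.column_stack(
        [
            [s.age for s in subjects],
            [1.0 if s.sex == "M" else 0.0 for s in subjects],
            [s.mean_fd for s in subjects],
        ]
    )
    template = build_templates(
        blocks, cfg.gradient, cfg.template_provenance, groups
    )
    ais: list[AsymmetryIndex] = []
    ok = []
    for j, (s, b) in enumerate(zip(subjects, blocks)):
        try:
            aligned = align_subject(b, template, cfg.gradient)
        except ValueError as exc:
            # QC-style exclusion: a block whose sparsified profiles cannot
            # seed the affinity (e.g. an orphaned region) is unusable
            logger.warning("excluding %s: %s", s.subject_id, exc)
            continue
        ais.append(compute_ai(aligned, cfg.n_gradients, subject_id=s.subject_id))
        ok.append(j)
    subjects = [subjects[j] for j in ok]
    groups = [groups[j] for j in ok]
    sites = sites[ok]
    covariates = covariates[ok]
    out: dict = {
        "subjects": [s.subject_id for s in subjects],
        "groups": groups,
        "template": template,
        "ais": ais,
    }
    n_pairs = dataset.parcellation.n_pairs
    nets = dataset.parcellation.pair_networks
    multi_site = len(np.unique(sites)) > 1
    for scope in ("intra", "inter"):
        feats = ai_feature_matrix(ais, scope)
        if multi_site:
            harmonized, _ = combat_harmonize(feats, sites, covariates)
        else:
            harmonized = feats
        out[f"ai_{scope}"] = harmonized
        # reshape back to subjects x pairs x gradients (columns are
        # gradient-major: G1 pairs, G2 pairs, G3 pairs)
        stack = (
            harmonized.to_numpy()
            .reshape(len(subjects), cfg.n_gradients, n_pairs)
            .transpose(0, 2, 1)
        )
        mv, ph = unitwise_group_comparison(stack, groups, covariates)
        out[f"region_{scope}_mv"] = mv
        out[f"region_{scope}_posthoc"] = ph
        net_stack, net_order = network_aggregate(stack, nets)
        nmv, nph = unitwise_group_comparison(
            net_stack, groups, covariates, unit_ids=net_order
        )
        out[f"network_{scope}_mv"] = nmv
        out[f"network_{scope}_posthoc"] = nph
        out[f"group_maps_{scope}"] = group_ai_maps(ais, groups, scope)
        if cfg.run_prediction:
            l1 = cfg.l1_ratio_intra if scope == "intra" else cfg.l1_ratio_inter
            bdi = np.array([s.bdi for s in subjects], dtype=float)
            raw = ai_feature_matrix(ais, scope)  # prediction harmonizes per split
            if cfg.n_perm > 0:
                res = permutation_pvalue(
                    raw, bdi, sites if multi_site else None, covariates,
                    l1_ratio=l1, n_perm=cfg.n_perm, seed=cfg.seed,
                )
            else:
                res = nested_elasticnet_predict(
                    raw, bdi, sites if multi_site else None, covariates,
                    l1_ratio=l1, n_splits=cfg.n_splits, seed=cfg.seed,
                )
            out[f"prediction_{scope}"] = res
    return out


def write_results(result: dict, cfg: RunConfig) -> Path:
    """Write every stage output of a result bundle plus the provenance log."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the scientific configuration only: where outputs land must not
    # change their content
    h = hio.config_hash(
        {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    )
    # AI long table
    rows = []
    for ai in result["ais"]:
        for scope in ("intra", "inter"):
            m = getattr(ai, scope)
            for i in range(m.shape[0]):
                for k in range(m.shape[1]):
                    rows.append(
                        (ai.subject_id, i, scope, f"G{k + 1}", m[i, k])
                    )
    ai_long = pd.DataFrame(
        rows, columns=["subject_id", "pair_index", "scope", "gradient", "ai"]
    )
    hio.write_table(ai_long, out / "ai_long.tsv", cfg.seed, h, sep="\t")
    tmpl = result["template"]
    for name, mat in (("intra", tmpl.intra), ("inter", tmpl.inter)):
        hio.write_matrix(
            mat, out / f"template_{name}.tsv",
            columns=[f"G{k + 1}" for k in range(mat.shape[1])],
            seed=cfg.seed, cfg_hash=h,
        )
    for key in result:
        if key.startswith(("region_", "network_", "group_maps_")):
            hio.write_table(result[key], out / f"{key}.csv", cfg.seed, h)
    for scope in ("intra", "inter"):
        pk = f"prediction_{scope}"
        if pk in result:
            (out / f"{pk}.json").write_text(
                json.dumps(result[pk].summary(), indent=1)
            )
    provenance = {
        "config": cfg.to_dict(),
        "config_hash": h,
        "seed": cfg.seed,
        "n_subjects": len(result["subjects"]),
        "subjects": result["subjects"],
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Read a cohort directory, analyze it, write all declared outputs."""
    dataset = hio.read_cohort(cfg.cohort_dir)
    result = analyze_cohort(dataset, cfg)
    write_results(result, cfg)
    return result
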