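"""End-to-end pipeline: raw (or simulated) score tables to the full result set.

Stage order mirrors the analysis design: prune missingness -> kNN-impute ->
PCA confounder checks -> hierarchical clustering and type assignment ->
pairwise differential expression with the all-three consensus rule ->
positivity profiles and derived diagnostic panel -> consensus co-clustering
network -> cross-validated internal validation -> survival report.

Every stage writes a self-describing CSV stamped with the configuration
hash; the single run seed fans out into independent per-stage seeds
(stage-name hashed) so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import diffexp as _diffexp
from . import network as _network
from . import panel as _panel
from . import survival as _survival
from . import validate as _validate
from .core_data import (
    PipelineConfig,
    ScoreMatrix,
    prune_missing,
    read_score_table,
    write_score_table,
)
from .impute import knn_impute
from .synthetic import CohortSpec, generate_cohort

__all__ = ["run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "prune",
    "impute",
    "pca",
    "cluster",
    "diffexp",
    "profiles",
    "panel",
    "network",
    "validate",
    "survival",
)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage derived seed (stable, independent across stages)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path,
    score_path: str | Path | None = None,
    clinical_path: str | Path | None = None,
    cohort_spec: CohortSpec | None = None,
    n_network_iterations: int | None = None,
) -> Path:
    """Run every stage and return the run directory.

    Inputs are either files (``score_path`` and optionally
    ``clinical_path``) or a synthetic :class:`CohortSpec`.  When no
    clinical data is available the survival stage is skipped with a
    warning; all other stages still run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    n_iter = n_network_iterations or cfg.n_network_iterations
    log_lines = [f"config_hash={cfg_hash}", f"seed={cfg.seed}", f"config={asdict(cfg)}"]
    t0 = time.time()
    stage = "load"

    try:
        clinical = None
        if score_path is not None:
            m = read_score_table(score_path)
            if clinical_path is not None:
                clinical = pd.read_csv(clinical_path, comment="#")
        else:
            stage = "simulate"
            spec = cohort_spec or CohortSpec(seed=stage_seed(cfg.seed, "simulate"))
            m, truth, clinical = generate_cohort(spec)
            write_score_table(m, out / "scores.csv")
            _write_csv(truth.to_frame(), out / "true_labels.csv", cfg_hash)
            _write_csv(clinical, out / "clinical.csv", cfg_hash, index=False)

        stage = "prune"
        pruned, report = prune_missing(m, cfg)
        write_score_table(pruned, out / "scores_pruned.csv")
        (out / "prune_report.json").write_text(
            json.dumps({"config_hash": cfg_hash, **asdict(report)}, indent=2)
        )

        stage = "impute"
        imputed = knn_impute(pruned, k=cfg.knn_k)
        write_score_table(imputed, out / "scores_imputed.csv")

        stage = "pca"
        pca_rows = []
        probe_check = _cluster.pca_check(imputed, imputed.meta["probe_type"])
        pca_rows.append(
            {
                "check": "probe_type",
                "silhouette": probe_check.silhouette,
                "admixture": probe_check.admixture,
            }
        )
        mask = pruned.observed_mask.astype(float)
        if mask.nunique().gt(1).any():
            mask_check = _cluster.pca_check(mask, imputed.meta["diagnosis"])
            pca_rows.append(
                {
                    "check": "analyzed_marker_mask",
                    "silhouette": mask_check.silhouette,
                    "admixture": mask_check.admixture,
                }
            )
        _write_csv(pd.DataFrame(pca_rows), out / "pca_checks.csv", cfg_hash, index=False)

        stage = "cluster"
        D = _cluster.pearson_distance(imputed)
        dend = _cluster.agglomerative_average(D, sample_ids=imputed.sample_ids)
        assignment = _cluster.assign_types(
            dend, imputed, positivity_threshold=cfg.positivity_threshold
        )
        (out / "dendrogram.newick").write_text(dend.to_newick() + "\n")
        _write_csv(
            pd.DataFrame(
                {"a": dend.merges[:, 0], "b": dend.merges[:, 1], "height": dend.heights}
            ),
            out / "merges.csv",
            cfg_hash,
            index=False,
        )
        _write_csv(assignment.labels.to_frame(), out / "labels.csv", cfg_hash)
        _write_csv(assignment.clusters, out / "clusters.csv", cfg_hash, index=False)

        stage = "diffexp"
        present = set(assignment.labels.unique())
        pairs = [p for p in _diffexp.DEFAULT_PAIRS if set(p) <= present]
        results = _diffexp.run_pairwise(
            imputed,
            assignment.labels,
            pairs=pairs,
            n_perm=cfg.n_permutations,
            alpha=cfg.alpha,
            seed=stage_seed(cfg.seed, "diffexp"),
        )
        consensus_sets = {}
        for pair, res in results.items():
            name = f"diffexp_{pair[0]}_vs_{pair[1]}.csv"
            _write_csv(res.table, out / name, cfg_hash)
            consensus_sets[pair] = res.consensus_markers

        stage = "profiles"
        profile = _diffexp.positivity_profiles(
            imputed, assignment.labels, threshold=cfg.positivity_threshold
        )
        _write_csv(profile.fractions, out / "immunohistogram.csv", cfg_hash)

        stage = "panel"
        panel_markers = [g for g in _panel.PANEL_MARKERS if g in profile.fractions.index]
        derived = _panel.derive_panel(profile.fractions, markers=panel_markers)
        derived.to_json(out / "panel.json")

        stage = "network"
        C = _network.comembership(
            pruned,
            k=assignment.k,
            n_iter=n_iter,
            seed=stage_seed(cfg.seed, "network"),
        )
        _write_csv(C.values, out / "comembership.csv", cfg_hash)
        attrs = pruned.meta.copy()
        attrs["ihc_type"] = assignment.labels
        g = _network.build_graph(C, edge_threshold=0.5, attrs=attrs)
        g.graph["config_hash"] = cfg_hash
        _network.write_graph(g, out / "network.gexf")
        _network.write_graph(g, out / "network_edges.csv")

        stage = "validate"
        metrics = _validate.validation_suite(
            imputed,
            assignment.labels,
            consensus_sets=consensus_sets,
            pairs=pairs,
            seed=stage_seed(cfg.seed, "validate"),
        )
        _write_csv(metrics, out / "validation.csv", cfg_hash, index=False)

        stage = "survival"
        if clinical is None:
            warnings.warn("no clinical records supplied; survival stage skipped")
            log_lines.append("survival: skipped (no clinical input)")
        else:
            joined = _survival.attach_types(clinical, assignment.labels, imputed.meta)
            table = _survival.survival_report(joined)
            _write_csv(table, out / "survival.csv", cfg_hash, index=False)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc

    log_lines.append(f"elapsed_s={time.time() - t0:.1f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    _write_report(out, cfg_hash)
    return out


def _write_report(out: Path, cfg_hash: str) -> None:
    lines = [f"# Pipeline run report", "", f"Config hash: `{cfg_hash}`", ""]
    for f in sorted(out.iterdir()):
        if f.name != "report.md":
            lines.append(f"- `{f.name}`")
    (out / "report.md").write_text("\n".join(lines) + "\n")
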