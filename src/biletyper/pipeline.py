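"""End-to-end orchestration: simulate/load -> normalise -> diversity ->
rank -> lefse -> biletype -> sub-biletype -> genus clusters -> score ROC ->
random-forest selection -> survival, with one master seed and a manifest.

Stage seeds are derived as ``(master_seed + fixed stage offset) mod 2^31``
so toggling one stage never shifts another stage's randomness.  All tabular
outputs are TSV with a header; scalar reports are JSON.  The manifest lists
every output file together with a hash of the resolved configuration and
per-stage wall-clock timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biletype as bt
from . import diversity as dv
from . import markers, rf, survival
from .data import (
    AbundanceTable,
    CohortMetadata,
    check_alignment,
    metadata_frame,
    read_abundance_table,
    read_metadata,
    read_newick,
    to_relative_abundance,
    rarefy_to_min_depth,
    write_abundance_table,
    write_metadata,
)
from .simulate import SyntheticCohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGE_SEED_OFFSETS", "stage_seed"]

logger = logging.getLogger("biletyper")

STAGE_SEED_OFFSETS = {
    "simulate": 1,
    "rarefy": 2,
    "permanova": 3,
    "lefse": 4,
    "biletype": 5,
    "rf_split": 6,
    "rfcv": 7,
}

ALL_STAGES = (
    "normalize",
    "diversity",
    "rank",
    "lefse",
    "biletype",
    "rf",
    "survival",
)


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Exactly one of ``input_paths`` (dict with keys abundance, metadata and
    optionally tree) and ``synthetic`` (SyntheticCohortConfig parameters)
    must be given.
    """

    out_dir: str
    seed: int = 0
    input_paths: dict | None = None
    synthetic: dict | None = None
    stages: tuple[str, ...] = ALL_STAGES
    case_label: str = "CCA"
    control_label: str = "BBD"
    rarefy: bool = True
    k_max: int = 30
    transform: str = "log_z"
    min_cluster_fraction: float = 0.1
    force_k: int | None = None
    n_label_permutations: int = 999
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.0
    permanova_permutations: int = 999
    rf_ratio: float = 0.7
    rf_candidate_counts: tuple[int, ...] = rf.DEFAULT_CANDIDATE_COUNTS
    rf_rule: str = "one_se"
    rf_trees: int = 500
    rf_trees_cv: int = 25

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_paths and synthetic must be configured"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "rf_candidate_counts" in raw:
            raw["rf_candidate_counts"] = tuple(raw["rf_candidate_counts"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (the output location is not
        part of the analysis, so runs into different directories compare
        equal)."""
        fields = asdict(self)
        fields.pop("out_dir")
        blob = json.dumps(fields, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    On a stage failure the exception propagates after the partial manifest is
    written, so completed outputs remain inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_SEED_OFFSETS},
        "files": [],
        "status": "running",
    }
    # wall-clock timings are diagnostics, kept out of the (deterministic)
    # manifest and written to a side file instead
    timings: dict[str, float] = {}
    manifest_path = out / "manifest.json"

    def emit(name: str) -> Path:
        path = out / name
        manifest["files"].append(name)
        return path

    def timed(stage: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", stage)
                return self_inner

            def __exit__(self_inner, *exc):
                timings[stage] = round(time.perf_counter() - self_inner.t0, 3)
                logger.info("stage %s: done in %.2fs", stage, timings[stage])
                return False

        return _T()

    try:
        # ---- inputs -------------------------------------------------------
        tree = None
        if config.synthetic is not None:
            with timed("simulate"):
                params = dict(config.synthetic)
                params.setdefault("seed", stage_seed(config.seed, "simulate"))
                sim_cfg = SyntheticCohortConfig(**params)
                table, records, truth = generate_cohort(sim_cfg)
                write_abundance_table(table, emit("abundance.tsv"))
                write_metadata(records, emit("metadata.tsv"))
                truth.frame().to_csv(emit("truth.tsv"), sep="\t", index=False)
        else:
            with timed("load"):
                table = read_abundance_table(config.input_paths["abundance"])
                records = read_metadata(config.input_paths["metadata"])
                if config.input_paths.get("tree"):
                    tree = read_newick(config.input_paths["tree"])
        check_alignment(table, records)

        # ---- normalise ----------------------------------------------------
        if "normalize" in config.stages and table.kind == "counts":
            with timed("normalize"):
                if config.rarefy:
                    table = rarefy_to_min_depth(
                        table, seed=stage_seed(config.seed, "rarefy")
                    )
                    write_abundance_table(table, emit("rarefied.tsv"))
                rel = to_relative_abundance(table)
        else:
            rel = table.relative()

        # ---- diversity ----------------------------------------------------
        if "diversity" in config.stages:
            with timed("diversity"):
                alpha = dv.alpha_diversity(rel, tree=tree)
                alpha.to_csv(emit("alpha_diversity.tsv"), sep="\t")
                dm = dv.bray_curtis(rel)
                pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                    emit("bray_curtis.tsv"), sep="\t", index_label="sample_id"
                )
                ord_res = dv.pcoa(dm)
                ord_res.coordinates.to_csv(emit("pcoa.tsv"), sep="\t")
                groups = metadata_frame(records).set_index("sample_id")
                labels = groups.loc[list(dm.ids), "group"]
                perm = dv.permanova(
                    dm,
                    labels,
                    n_permutations=config.permanova_permutations,
                    seed=stage_seed(config.seed, "permanova"),
                )
                _write_json(
                    {
                        "pseudo_f": perm.pseudo_f,
                        "p_value": perm.p_value,
                        "n_permutations": perm.n_permutations,
                    },
                    emit("permanova.json"),
                )

        # ---- AUC ranking --------------------------------------------------
        ranking = None
        if "rank" in config.stages or "biletype" in config.stages:
            with timed("rank"):
                ranking = markers.rank_genera_by_auc(
                    rel, records, config.case_label, config.control_label
                )
                ranking.entries.to_csv(emit("auc_ranking.tsv"), sep="\t", index=False)

        # ---- LEfSe-style scan --------------------------------------------
        if "lefse" in config.stages:
            with timed("lefse"):
                lef = markers.lefse_like(
                    rel,
                    records,
                    alpha=config.lefse_alpha,
                    lda_threshold=config.lda_threshold,
                    seed=stage_seed(config.seed, "lefse"),
                )
                entries = lef.entries.copy()
                entries["kw_p_adjusted"] = markers.bh_adjust(entries["kw_p"])
                entries.to_csv(emit("lefse.tsv"), sep="\t", index=False)

        # ---- biletype sweep ----------------------------------------------
        result = None
        if "biletype" in config.stages:
            with timed("biletype"):
                result = bt.biletype_sweep(
                    rel,
                    records,
                    ranking,
                    k_max=config.k_max,
                    min_cluster_fraction=config.min_cluster_fraction,
                    transform=config.transform,
                    n_label_permutations=config.n_label_permutations,
                    seed=stage_seed(config.seed, "biletype"),
                    force_k=config.force_k,
                )
                result.sweep_trace.to_csv(emit("sweep_trace.tsv"), sep="\t", index=False)
                if result.confident:
                    feats = bt.transform_features(
                        rel, result.feature_taxa, config.transform
                    )
                    tree_lk = bt.ward_d2_linkage(feats)
                    pd.DataFrame(
                        tree_lk.merges,
                        columns=["left", "right", "height", "size"],
                    ).to_csv(emit("biletype_merges.tsv"), sep="\t", index=False)
                    b_samples = result.samples_in("B")
                    if len(b_samples) >= 4:
                        result = bt.sub_biletype(rel, records, result)
                    part = pd.DataFrame(
                        {
                            "sample_id": list(result.partition),
                            "biletype": list(result.partition.values()),
                            "sub_biletype": [
                                (result.sub_partition or {}).get(s)
                                for s in result.partition
                            ],
                        }
                    )
                    part.to_csv(emit("biletypes.tsv"), sep="\t", index=False)
                    _write_json(
                        {
                            "chosen_k": result.chosen_k,
                            "feature_taxa": result.feature_taxa,
                            **result.association,
                            "sub_rule": result.sub_rule,
                        },
                        emit("biletype_report.json"),
                    )
                    if len(result.feature_taxa) >= 2:
                        b1 = [
                            s
                            for s, v in (result.sub_partition or {}).items()
                            if v == "B1"
                        ]
                        clusters = bt.genus_coclusters(
                            rel, result.feature_taxa, b1_samples=b1 or None
                        )
                        pd.DataFrame(
                            {
                                "taxon_id": list(clusters),
                                "cluster": list(clusters.values()),
                            }
                        ).to_csv(emit("genus_clusters.tsv"), sep="\t", index=False)
                        cluster1 = [t for t, c in clusters.items() if c == 1]
                        score = bt.cluster_score_roc(
                            rel, records, cluster1, config.case_label
                        )
                        score.scores.to_frame().to_csv(
                            emit("cluster1_scores.tsv"), sep="\t"
                        )
                        score.roc.to_csv(emit("cluster1_roc.tsv"), sep="\t", index=False)
                        _write_json(
                            {"cluster1_taxa": cluster1, "auc": score.auc},
                            emit("cluster1_report.json"),
                        )

        # ---- random forest ------------------------------------------------
        if "rf" in config.stages:
            with timed("rf"):
                labels = metadata_frame(records).set_index("sample_id").loc[
                    rel.sample_ids, "group"
                ]
                train_ids, test_ids = rf.split_train_test(
                    rel.sample_ids,
                    labels,
                    ratio=config.rf_ratio,
                    seed=stage_seed(config.seed, "rf_split"),
                )
                train_tbl = AbundanceTable(rel.data[train_ids], kind=rel.kind)
                test_tbl = AbundanceTable(rel.data[test_ids], kind=rel.kind)
                train_recs = [r for r in records if r.sample_id in set(train_ids)]
                test_recs = [r for r in records if r.sample_id in set(test_ids)]
                report = rf.rfcv_select(
                    train_tbl,
                    train_recs,
                    candidate_counts=config.rf_candidate_counts,
                    rule=config.rf_rule,
                    n_trees=config.rf_trees,
                    n_trees_cv=config.rf_trees_cv,
                    seed=stage_seed(config.seed, "rfcv"),
                )
                report.cv_curve.to_csv(emit("rf_cv_curve.tsv"), sep="\t", index=False)
                report.importance.to_frame().to_csv(
                    emit("rf_importance.tsv"), sep="\t", index_label="taxon_id"
                )
                model = rf.train_classifier(
                    train_tbl,
                    train_recs,
                    report.selected_taxa,
                    config.case_label,
                    n_trees=config.rf_trees,
                    seed=stage_seed(config.seed, "rfcv"),
                )
                ev = rf.evaluate(model, test_tbl, test_recs, config.case_label)
                ev.roc.to_csv(emit("rf_test_roc.tsv"), sep="\t", index=False)
                _write_json(
                    {
                        "chosen_m": report.chosen_m,
                        "selected_taxa": report.selected_taxa,
                        "test_auc": ev.auc,
                        "confusion": {
                            "tp": ev.tp,
                            "fp": ev.fp,
                            "tn": ev.tn,
                            "fn": ev.fn,
                        },
                        "n_train": len(train_ids),
                        "n_test": len(test_ids),
                    },
                    emit("rf_report.json"),
                )

        # ---- survival -----------------------------------------------------
        if "survival" in config.stages:
            with timed("survival"):
                grouping = None
                if result is not None and result.sub_partition:
                    grouping = dict(result.sub_partition)
                    name = "sub_biletype"
                elif result is not None and result.partition:
                    grouping = dict(result.partition)
                    name = "biletype"
                else:
                    grouping = {
                        r.sample_id: r.group
                        for r in records
                        if r.survival_time is not None
                    }
                    name = "group"
                try:
                    res = survival.survival_by_group(records, grouping)
                except ValueError as exc:
                    logger.warning("survival stage skipped: %s", exc)
                else:
                    curves = pd.concat(
                        [c.frame() for c in res["curves"].values()], ignore_index=True
                    )
                    curves.to_csv(emit("km_curves.tsv"), sep="\t", index=False)
                    _write_json(
                        {
                            "stratification": name,
                            "chi_square": res["chi_square"],
                            "p_value": res["p_value"],
                            "groups": res["groups"],
                        },
                        emit("logrank.json"),
                    )

        manifest["status"] = "ok"
        return manifest
    finally:
        _write_json(manifest, manifest_path)
        _write_json(timings, out / "timings.json")
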