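"""End-to-end orchestration of the chromogroup transcriptome analysis.

One call runs: chromogroup assignment -> aneuploidy / frequency summaries
-> per-group DE contrasts (vs the CTRL cancer group and vs normal
tissue) -> transcript taxonomy -> OverT/UnderT and UpT/DownT region
summaries -> NCDI profiles -> strict-DEG modified-FC clustering ->
cross-group set intersections -> GSEA in both metric modes -> lobular
vs ductal DEGs where both histotypes exist.  Every report table is
written as TSV with a stable schema; the run is deterministic given the
seed in the configuration.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_io, chromogroups, classify, clustering, de_engine, ncdi
from . import enrichment, synthetic_data

logger = logging.getLogger(__name__)

ANALYSIS_GROUPS = ("A", "B1", "B2", "C", "D1", "D2")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and scope of one pipeline run."""

    annotation: str | None = None
    arm_calls: str | None = None
    counts: str | None = None
    metadata: str | None = None
    out_dir: str = "chromotx_out"
    seed: int = 0
    groups: tuple[str, ...] = ANALYSIS_GROUPS
    reference_group: str = "A"
    core_groups: tuple[str, ...] = ("A", "B1", "C", "D1")
    histotype_filter: str | None = None
    subtype_filter: str | None = None
    min_group_size: int = 3
    thresholds: classify.ThresholdConfig = field(default_factory=classify.ThresholdConfig)
    de: de_engine.DEConfig = field(default_factory=de_engine.DEConfig)
    gsea_permutations: int = 200
    cluster_k_rows: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        th = classify.ThresholdConfig(**raw.pop("thresholds", {}))
        de = de_engine.DEConfig(**raw.pop("de", {}))
        for key in ("groups", "core_groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(thresholds=th, de=de, **raw)

    def dump(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if not isinstance(v, (classify.ThresholdConfig, de_engine.DEConfig))
        }
        data["thresholds"] = dict(self.thresholds.__dict__)
        data["de"] = dict(self.de.__dict__)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _digest(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(frame, index=True).to_numpy().tobytes()
    ).hexdigest()[:12]


def _log_stage(name: str, t0: float, **info) -> None:
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s wall=%.2fs %s", name, time.time() - t0, extra)


def load_inputs(config: PipelineConfig):
    annotation = annotation_io.read_gene_annotation(config.annotation)
    arm_calls = annotation_io.read_arm_calls(config.arm_calls)
    counts = annotation_io.read_counts(config.counts)
    metadata = pd.read_csv(config.metadata, sep="\t", index_col=0)
    return annotation, arm_calls, counts, metadata


def run_pipeline(
    config: PipelineConfig,
    cohort: synthetic_data.SyntheticCohort | None = None,
) -> dict[str, object]:
    """Execute the full analysis; returns the report bundle in memory and
    writes it under ``config.out_dir``.

    Inputs come either from the file paths in ``config`` or from an
    in-memory synthetic cohort.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / "config_used.yaml")
    if cohort is not None:
        annotation, arm_calls = cohort.annotation, cohort.arm_calls
        counts, metadata = cohort.counts, cohort.metadata
    else:
        annotation, arm_calls, counts, metadata = load_inputs(config)
    bundle: dict[str, object] = {}

    # --- chromogroup assignment and cytogenomic summaries ----------------
    t0 = time.time()
    assignments = chromogroups.assign_cohort(arm_calls)
    scores = chromogroups.cohort_aneuploidy_scores(
        arm_calls, arm_universe=list(arm_calls.columns)
    )
    summary = chromogroups.group_overlap_summary(assignments, scores)
    assignments.join(scores).to_csv(out / "assignments.tsv", sep="\t")
    summary.to_csv(out / "as_summary.tsv", sep="\t")
    bundle.update(assignments=assignments, aneuploidy=scores, group_summary=summary)
    for group in ("all", *config.groups):
        freq = chromogroups.arm_aberration_frequencies(
            arm_calls, assignments, None if group == "all" else group
        )
        freq.round(2).to_csv(out / f"arm_freq_{group}.tsv", sep="\t")
    _log_stage("assign", t0, n=len(assignments), digest=_digest(assignments))

    # --- restrict samples (Analysis II style filters) ---------------------
    meta = metadata.copy()
    tumor_mask = meta["is_tumor"] if "is_tumor" in meta else meta["group"] != "normal"
    if config.histotype_filter:
        tumor_mask &= meta["histotype"] == config.histotype_filter
    if config.subtype_filter and "subtype" in meta:
        tumor_mask &= meta["subtype"] == config.subtype_filter
    normals = list(meta.index[~(meta["is_tumor"] if "is_tumor" in meta else meta["group"] != "normal")])

    def members(group: str) -> list[str]:
        sel = assignments.index[assignments[group]]
        return [s for s in sel if s in meta.index and bool(tumor_mask.get(s, False))]

    ctrl_samples = members("CTRL")

    # --- shared gene universe (one pre-filter across all samples) --------
    t0 = time.time()
    filtered = de_engine.filter_low_counts(counts, config.de.zero_fraction)
    de_cfg = de_engine.DEConfig(**{**config.de.__dict__, "prefilter": False})
    _log_stage("prefilter", t0, genes=len(filtered.genes))

    # --- contrasts and taxonomy -------------------------------------------
    contrasts_ctrl: dict[str, pd.DataFrame] = {}
    contrasts_n: dict[str, pd.DataFrame] = {}
    classifications: dict[str, pd.DataFrame] = {}
    for group in config.groups:
        g_samples = members(group)
        if len(g_samples) < config.min_group_size or len(ctrl_samples) < config.min_group_size:
            logger.info("skip contrast %s vs CTRL (insufficient samples)", group)
            continue
        t0 = time.time()
        vs_ctrl = de_engine.run_contrast(filtered, g_samples, ctrl_samples, de_cfg)
        contrasts_ctrl[group] = vs_ctrl
        vs_ctrl.to_csv(out / f"contrast_{group}_vs_CTRL.tsv", sep="\t")
        vs_n = None
        if len(normals) >= config.min_group_size:
            vs_n = de_engine.run_contrast(filtered, g_samples, normals, de_cfg)
            contrasts_n[group] = vs_n
            vs_n.to_csv(out / f"contrast_{group}_vs_N.tsv", sep="\t")
        flags = classify.classify_transcripts(vs_ctrl, vs_n, config.thresholds)
        classifications[group] = flags
        flags.to_csv(out / f"classes_{group}.tsv", sep="\t")
        _log_stage("contrast", t0, group=group, n=len(g_samples))
    bundle.update(
        contrasts_ctrl=contrasts_ctrl, contrasts_n=contrasts_n,
        classifications=classifications,
    )

    # --- Table 2 / Table 3 style summaries --------------------------------
    ann_arm = (annotation["chrom"].astype(str) + annotation["arm"]).to_numpy()
    arm_of = dict(zip(annotation["gene_id"], ann_arm))
    ref = config.reference_group

    def region_sets(flag_a: str, flag_b: str, region: str):
        per_group = {}
        for group, flags in classifications.items():
            if flag_a not in flags or flag_b not in flags:
                continue
            sel = {
                "OverT": {
                    g for g in flags.index[flags[flag_a]] if arm_of.get(g) == region
                },
                "UnderT": {
                    g for g in flags.index[flags[flag_b]] if arm_of.get(g) == region
                },
            }
            per_group[group] = sel
        return per_group

    tables = []
    if ref in classifications:
        for region in ("1q", "16q"):
            t2 = classify.summarize_over_under(
                region_sets("OverT", "UnderT", region), reference=ref
            )
            t2.insert(0, "region", region)
            tables.append(t2)
        pd.concat(tables).to_csv(out / "table2_like.tsv", sep="\t")
        bundle["table2_like"] = pd.concat(tables)
        tables = []
        if contrasts_n:
            for region in ("1q", "16q"):
                t3 = classify.summarize_up_down(
                    {
                        g: {"UpT": s["OverT"], "DownT": s["UnderT"]}
                        for g, s in region_sets("UpT", "DownT", region).items()
                    },
                    reference=ref,
                )
                t3.insert(0, "region", region)
                tables.append(t3)
            pd.concat(tables).to_csv(out / "table3_like.tsv", sep="\t")
            bundle["table3_like"] = pd.concat(tables)

    # --- NCDI --------------------------------------------------------------
    ann_filtered = annotation[annotation["gene_id"].isin(filtered.genes)]
    for group, flags in classifications.items():
        for cls_name in ("OverT", "UnderT"):
            genes = set(flags.index[flags[cls_name]])
            if not genes:
                continue
            tally = ncdi.tally_regions(genes, ann_filtered, "arms")
            ncdi.ncdi_table(tally).round(4).to_csv(
                out / f"ncdi_{group}_{cls_name}.tsv", sep="\t"
            )
    allt = ncdi.allt_baseline(ann_filtered)
    allt.round(4).to_csv(out / "ncdi_AllT.tsv", sep="\t")
    bundle["ncdi_allt"] = allt

    # --- strict DEGs and clustering ----------------------------------------
    if ref in contrasts_ctrl and len(contrasts_ctrl) >= 2:
        strict = classify.select_strict_degs(
            contrasts_ctrl[ref], annotation, config.thresholds
        )
        per_group_fc = {
            g: pd.Series(
                [classify.modified_fc(v) for v in c.loc[c.index.isin(strict.index), "linear_fc"]],
                index=c.index[c.index.isin(strict.index)],
            )
            for g, c in contrasts_ctrl.items()
        }
        fc_matrix = clustering.build_fc_matrix(per_group_fc).loc[
            [g for g in strict.index if g in set().union(*(set(s.index) for s in per_group_fc.values()))]
        ]
        fc_matrix.to_csv(out / "modfc_matrix.tsv", sep="\t")
        bundle["fc_matrix"] = fc_matrix
        if len(fc_matrix) >= 2 and fc_matrix.shape[1] >= 2:
            scaled = clustering.scale_rows(fc_matrix)
            k = min(config.cluster_k_rows, len(scaled))
            z_rows, row_labels = clustering.upgma_cluster(scaled, "rows", k=k)
            z_cols, col_labels = clustering.upgma_cluster(
                scaled, "columns", k=min(2, scaled.shape[1])
            )
            clustering.linkage_table(z_rows).to_csv(out / "clusters_rows_merges.tsv",
                                                    sep="\t", index=False)
            row_labels.to_csv(out / "clusters.tsv", sep="\t")
            bundle.update(row_clusters=row_labels, col_linkage=z_cols)

    # --- Venn / core sets ---------------------------------------------------
    overupt_sets = {
        g: {
            gene for gene in flags.index[flags["OverUpT"]] if arm_of.get(gene) == "1q"
        }
        for g, flags in classifications.items()
    }
    overupt_sets = {g: s for g, s in overupt_sets.items() if s}
    if len(overupt_sets) >= 2:
        venn = classify.shared_gene_sets(overupt_sets)
        venn.to_csv(out / "venn.tsv", sep="\t")
        bundle["venn"] = venn
        designated = [g for g in config.core_groups if g in overupt_sets]
        if len(designated) >= 2:
            core = classify.core_gene_set(overupt_sets, tuple(designated))
            (out / "core_genes.txt").write_text("\n".join(sorted(core)) + "\n")
            bundle["core_genes"] = core

    # --- GSEA ----------------------------------------------------------------
    arm_sets = {
        f"arm_{arm}": set(annotation.loc[ann_arm == arm, "gene_id"]) & set(filtered.genes)
        for arm in dict.fromkeys(ann_arm)
    }
    tpm_like = filtered  # counts are an acceptable expression proxy for ranking
    for group in config.groups:
        g_samples = members(group)
        if len(g_samples) < 3 or len(ctrl_samples) < 3:
            continue
        for absolute, tag in ((False, "real"), (True, "abs")):
            res = enrichment.nes_fdr(
                tpm_like, g_samples, ctrl_samples, arm_sets,
                n_perm=config.gsea_permutations, seed=config.seed,
                absolute=absolute,
            )
            res.to_csv(out / f"gsea_{group}_{tag}.tsv", sep="\t")
            bundle[f"gsea_{group}_{tag}"] = res

    # --- lobular vs ductal ---------------------------------------------------
    lvsd: dict[str, pd.DataFrame] = {}
    if "histotype" in meta:
        for group in config.groups:
            g_samples = members(group)
            try:
                res = classify.lobular_vs_ductal_degs(
                    filtered, meta["histotype"], g_samples, config.thresholds, de_cfg
                )
            except ValueError as exc:
                logger.info("skip lobular-vs-ductal for %s: %s", group, exc)
                continue
            lvsd[group] = res
            res.to_csv(out / f"lvsd_{group}.tsv", sep="\t")
        if lvsd:
            inter = classify.coherent_lvsd_intersection(lvsd)
            (out / "lvsd_intersection.txt").write_text("\n".join(sorted(inter)) + "\n")
            bundle["lvsd_intersection"] = inter
    bundle["lvsd"] = lvsd
    return bundle
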