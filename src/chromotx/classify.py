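"""Transcript taxonomy and cross-group gene-set summaries.

Two contrasts define the taxonomy of a chromogroup's transcripts:

* versus the CTRL cancer group (FCvsCTRL): **OverT** (FC > 1.3,
  adjp < 0.05) and **UnderT** (FC < -1.3, adjp < 0.05) — the
  dosage-sensitive classes;
* versus normal tissue (FCvsN): **UpT** (FC > 1, adjp < 0.05) and
  **DownT** (FC < -1, adjp < 0.05) — cancer dysregulation;
* their conjunctions **OverUpT** (candidate drivers on gained arms) and
  **OverDownT**.

All threshold comparisons are strict, on signed linear fold-changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .annotation_io import CountsMatrix
from .de_engine import DEConfig, run_contrast

FLAGS = ("OverT", "UnderT", "UpT", "DownT", "OverUpT", "OverDownT")


@dataclass
class ThresholdConfig:
    """Fold-change and significance cut-offs of the taxonomy."""

    fc_vs_ctrl: float = 1.3
    fc_vs_normal: float = 1.0
    adjp_cut: float = 0.05
    strict_adjp_cut: float = 0.001
    lvsd_fc: float = 1.5

    def __post_init__(self) -> None:
        if min(self.fc_vs_ctrl, self.fc_vs_normal, self.lvsd_fc) <= 0:
            raise ValueError("fold-change thresholds must be positive")
        for p in (self.adjp_cut, self.strict_adjp_cut):
            if not (0 < p < 1):
                raise ValueError("adjp cuts must lie in (0, 1)")


def modified_fc(linear_fc: float) -> float:
    """Collapse the (-1, +1) gap of signed linear fold-changes.

    FC - 1 for FC > 1, FC + 1 for FC < -1, 0 at |FC| = 1; undefined (and
    rejected) inside the gap.
    """
    if abs(linear_fc) < 1:
        raise ValueError(f"|linear FC| must be >= 1, got {linear_fc}")
    if linear_fc > 1:
        return linear_fc - 1.0
    if linear_fc < -1:
        return linear_fc + 1.0
    return 0.0


def classify_transcripts(
    vs_ctrl: pd.DataFrame,
    vs_normal: pd.DataFrame | None = None,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Flag every gene of a contrast with its taxonomy classes.

    ``vs_ctrl`` / ``vs_normal`` are contrast tables indexed by gene_id
    with ``linear_fc`` and ``adjp`` columns.  When both contrasts are
    given their gene universes must match.  Returns a boolean DataFrame
    with one column per flag.
    """
    th = thresholds or ThresholdConfig()
    flags = pd.DataFrame(False, index=vs_ctrl.index, columns=list(FLAGS))
    sig_c = vs_ctrl["adjp"] < th.adjp_cut
    flags["OverT"] = (vs_ctrl["linear_fc"] > th.fc_vs_ctrl) & sig_c
    flags["UnderT"] = (vs_ctrl["linear_fc"] < -th.fc_vs_ctrl) & sig_c
    if vs_normal is not None:
        missing = vs_ctrl.index.symmetric_difference(vs_normal.index)
        if len(missing):
            raise ValueError(f"contrast gene universes differ: {list(missing[:10])}")
        vs_normal = vs_normal.loc[vs_ctrl.index]
        sig_n = vs_normal["adjp"] < th.adjp_cut
        flags["UpT"] = (vs_normal["linear_fc"] > th.fc_vs_normal) & sig_n
        flags["DownT"] = (vs_normal["linear_fc"] < -th.fc_vs_normal) & sig_n
        flags["OverUpT"] = flags["OverT"] & flags["UpT"]
        flags["OverDownT"] = flags["OverT"] & flags["DownT"]
    flags.index.name = "gene_id"
    return flags


def select_strict_degs(
    vs_ctrl: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: ThresholdConfig | None = None,
    chrom_filter: tuple[str, ...] = ("1", "16"),
) -> pd.DataFrame:
    """High-confidence DEGs on selected chromosomes, for clustering.

    Keeps genes with |FCvsCTRL| > fc_vs_ctrl at adjp < strict_adjp_cut
    that the annotation places on ``chrom_filter`` chromosomes; attaches
    chromosome/arm and the modified fold-change.
    """
    th = thresholds or ThresholdConfig()
    ann = annotation.set_index("gene_id")
    hits = vs_ctrl[
        (vs_ctrl["linear_fc"].abs() > th.fc_vs_ctrl)
        & (vs_ctrl["adjp"] < th.strict_adjp_cut)
    ]
    hits = hits[hits.index.isin(ann.index)]
    chroms = ann.loc[hits.index, "chrom"].astype(str)
    hits = hits[chroms.isin([str(c) for c in chrom_filter])].copy()
    hits["chrom"] = ann.loc[hits.index, "chrom"]
    hits["arm"] = ann.loc[hits.index, "arm"]
    hits["modified_fc"] = [modified_fc(v) for v in hits["linear_fc"]]
    return hits


def shared_gene_sets(per_group_sets: dict[str, set[str]]) -> pd.DataFrame:
    """All Venn regions of a family of gene sets.

    For every non-empty subset S of groups reports the exclusive region
    ``|intersection(S) - union(others)|`` and the inclusive intersection
    ``|intersection(S)|`` with its members.
    """
    if len(per_group_sets) < 2:
        raise ValueError("need at least two gene sets")
    groups = list(per_group_sets)
    rows = []
    for k in range(1, len(groups) + 1):
        for subset in combinations(groups, k):
            inter = set.intersection(*(per_group_sets[g] for g in subset))
            others = [per_group_sets[g] for g in groups if g not in subset]
            excl = inter - set.union(*others) if others else set(inter)
            rows.append(
                {
                    "groups": "&".join(subset),
                    "n_inclusive": len(inter),
                    "n_exclusive": len(excl),
                    "members_inclusive": ";".join(sorted(inter)),
                }
            )
    return pd.DataFrame(rows).set_index("groups")


def core_gene_set(
    per_group_sets: dict[str, set[str]],
    designated: tuple[str, ...] = ("A", "B", "C", "D"),
) -> set[str]:
    """Inclusive intersection over the designated group list (the "core"
    genes shared by every 1q-gain group and the 16q-loss-only group)."""
    missing = [g for g in designated if g not in per_group_sets]
    if missing:
        raise ValueError(f"designated groups without a gene set: {missing}")
    return set.intersection(*(per_group_sets[g] for g in designated))


def summarize_over_under(
    per_group_sets: dict[str, dict[str, set[str]]],
    reference: str = "A",
) -> pd.DataFrame:
    """Per-group OverT/UnderT counts, overlap with the reference group,
    and the OverT/UnderT ratio (2 decimals; NA when UnderT is empty).

    ``per_group_sets[group]`` maps "OverT"/"UnderT" to gene-id sets,
    already restricted to the chromosomal region of interest.  "Shared
    with reference" is the inclusive intersection with the reference
    group's same-class set, so the reference row reads 100%.
    """
    if reference not in per_group_sets:
        raise ValueError(f"reference group {reference!r} missing")
    ref_over = per_group_sets[reference]["OverT"]
    ref_under = per_group_sets[reference]["UnderT"]
    rows = []
    for group, sets in per_group_sets.items():
        over, under = sets["OverT"], sets["UnderT"]
        sh_over = len(over & ref_over)
        sh_under = len(under & ref_under)
        rows.append(
            {
                "group": group,
                "n_overt": len(over),
                "shared_overt": sh_over,
                "pct_overt_of_ref": round(100.0 * sh_over / len(ref_over), 2)
                if ref_over
                else np.nan,
                "n_undert": len(under),
                "shared_undert": sh_under,
                "pct_undert_of_ref": round(100.0 * sh_under / len(ref_under), 2)
                if ref_under
                else np.nan,
                "ratio": round(len(over) / len(under), 2) if under else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def summarize_up_down(
    per_group_sets: dict[str, dict[str, set[str]]],
    reference: str = "A",
) -> pd.DataFrame:
    """UpT/DownT analogue of :func:`summarize_over_under`."""
    renamed = {
        g: {"OverT": s["UpT"], "UnderT": s["DownT"]} for g, s in per_group_sets.items()
    }
    out = summarize_over_under(renamed, reference=reference)
    out.columns = [
        c.replace("overt", "upt").replace("undert", "downt") for c in out.columns
    ]
    return out


def lobular_vs_ductal_degs(
    counts: CountsMatrix,
    histotypes: pd.Series,
    group_samples: list[str],
    thresholds: ThresholdConfig | None = None,
    de_config: DEConfig | None = None,
) -> pd.DataFrame:
    """Genes differentially expressed between lobular and ductal samples
    of one chromogroup.

    Runs the DE engine lobular vs ductal within the group and flags genes
    at |FC| > lvsd_fc with adjp < adjp_cut; ``direction`` is "decreased"
    (lower in lobular) or "increased".
    """
    th = thresholds or ThresholdConfig()
    members = [s for s in group_samples if s in histotypes.index]
    lob = [s for s in members if histotypes[s] == "lobular"]
    duc = [s for s in members if histotypes[s] == "ductal"]
    if len(lob) < 2 or len(duc) < 2:
        raise ValueError(
            f"need >=2 lobular and >=2 ductal samples (got {len(lob)}/{len(duc)})"
        )
    res = run_contrast(counts, lob, duc, config=de_config)
    sig = res[(res["linear_fc"].abs() > th.lvsd_fc) & (res["adjp"] < th.adjp_cut)].copy()
    sig["direction"] = np.where(sig["linear_fc"] > 0, "increased", "decreased")
    return sig


def coherent_lvsd_intersection(
    per_group_degs: dict[str, pd.DataFrame], direction: str = "decreased"
) -> set[str]:
    """Genes called in the same direction in every group's
    lobular-vs-ductal list."""
    sets = [
        set(df.index[df["direction"] == direction]) for df in per_group_degs.values()
    ]
    return set.intersection(*sets) if sets else set()
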