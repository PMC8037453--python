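"""Normalized chromosomal distribution index (NCDI).

The NCDI expresses how a transcript class (e.g. the overexpressed
transcripts of one chromogroup) distributes over a system of chromosomal
regions — all arms genome-wide, or the cytobands of a single arm.  With
x_n class members among the X_n transcripts of region n,

    NCDI_n = (x_n / X_n) / sum_i (x_i / X_i) * 100

so the values are region densities normalized to sum to 100.  Regions
encoding no transcripts are dropped (the density is undefined there).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class RegionTally:
    """Class-member counts x and transcript totals X per region."""

    regions: list[str]
    x: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=np.int64)
        if not (len(self.regions) == self.x.size == self.X.size):
            raise ValueError("regions, x and X must have equal length")
        if self.x.size < 1:
            raise ValueError("at least one region required")
        if (self.x < 0).any() or (self.x > self.X).any():
            raise ValueError("need 0 <= x_n <= X_n in every region")


def tally_regions(
    genes: list[str] | set[str],
    annotation: pd.DataFrame,
    region_system: str = "arms",
    arm: str | None = None,
) -> RegionTally:
    """Tally a gene list over chromosome arms or over the cytobands of
    one arm.

    ``region_system`` is ``"arms"`` (regions = chrom+arm genome-wide) or
    ``"cytobands"`` with ``arm`` naming the arm (e.g. ``"1q"``).  X_n is
    the number of annotated transcripts per region; genes absent from the
    annotation are logged and skipped; regions with X_n = 0 cannot occur
    (regions are derived from the annotation itself).
    """
    ann = annotation.copy()
    if region_system == "arms":
        ann["region"] = ann["chrom"].astype(str) + ann["arm"].astype(str)
    elif region_system == "cytobands":
        if arm is None:
            raise ValueError("cytoband tallies need an arm, e.g. arm='1q'")
        ann["region"] = ann["cytoband"].astype(str)
        ann = ann[(ann["chrom"].astype(str) + ann["arm"].astype(str)) == arm]
    else:
        raise ValueError(f"unknown region system {region_system!r}")

    universe = set(ann["gene_id"])
    genes = set(genes)
    skipped = genes - universe
    if skipped:
        logger.warning("tally_regions: %d gene(s) not in annotation, skipped", len(skipped))
    totals = ann.groupby("region", sort=True)["gene_id"].count()
    hits = (
        ann[ann["gene_id"].isin(genes)].groupby("region", sort=True)["gene_id"].count()
    )
    hits = hits.reindex(totals.index, fill_value=0)
    return RegionTally(list(totals.index), hits.to_numpy(), totals.to_numpy())


def ncdi(tally: RegionTally) -> pd.Series:
    """NCDI values of a tally (sum exactly 100; zero iff x_n = 0)."""
    density = tally.x / tally.X
    total = density.sum()
    if total <= 0:
        raise ValueError("all region densities are zero; NCDI undefined")
    values = density / total * 100.0
    return pd.Series(values, index=tally.regions, name="ncdi")


def ncdi_table(tally: RegionTally) -> pd.DataFrame:
    """Report table: region, x, X, density, ncdi."""
    values = ncdi(tally)
    return pd.DataFrame(
        {
            "x": tally.x,
            "X": tally.X,
            "density": tally.x / tally.X,
            "ncdi": values.to_numpy(),
        },
        index=pd.Index(tally.regions, name="region"),
    )


def allt_baseline(annotation: pd.DataFrame, region_system: str = "arms",
                  arm: str | None = None) -> pd.Series:
    """NCDI of the full transcript universe (x_n = X_n), the comparison
    baseline shown alongside class-specific profiles."""
    tally = tally_regions(set(annotation["gene_id"]), annotation, region_system, arm)
    return ncdi(tally)
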