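"""File formats and unit conversions.

Readers/writers for the four tabular inputs of the pipeline: gene
annotation, counts matrices (TSV or MatrixMarket), SEG-format copy-number
segments, and per-sample arm-call grids.  All genomic coordinates are
0-based half-open internally; the SEG reader converts from the 1-based
inclusive convention of that dialect at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

logger = logging.getLogger(__name__)

AUTOSOMES = [str(c) for c in range(1, 23)]

#: Chromosome arms used throughout; acrocentric p-arms (13p, 14p, 15p,
#: 21p, 22p) carry essentially no annotated genes and are excluded from
#: the default universe.
ACROCENTRIC_P = {"13p", "14p", "15p", "21p", "22p"}
ALL_ARMS_44 = [f"{c}{a}" for c in AUTOSOMES for a in ("p", "q")]
DEFAULT_ARMS_39 = [a for a in ALL_ARMS_44 if a not in ACROCENTRIC_P]

ANNOTATION_COLUMNS = ["gene_id", "gene_name", "chrom", "arm", "cytoband", "start", "end"]


class FormatError(ValueError):
    """Malformed file: missing columns, ragged rows, wrong dtypes."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-annotation table against its invariants.

    Required columns: gene_id, gene_name, chrom, arm, cytoband, start, end.
    Returns a clean copy with string chrom and integer coordinates.
    Raises :class:`ValidationError` on duplicate gene ids; rows with an
    invalid chromosome, arm/cytoband mismatch, or an empty interval are
    dropped with a logged count.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"annotation missing required columns: {missing}")
    tab = table.loc[:, ANNOTATION_COLUMNS].copy()
    tab["chrom"] = tab["chrom"].astype(str)
    tab["arm"] = tab["arm"].astype(str)
    tab["start"] = tab["start"].astype(np.int64)
    tab["end"] = tab["end"].astype(np.int64)

    dup = tab["gene_id"][tab["gene_id"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate gene_id values: {sorted(map(str, dup))[:10]}")

    band_ok = [
        str(band).startswith(chrom + arm)
        for band, chrom, arm in zip(tab["cytoband"], tab["chrom"], tab["arm"])
    ]
    ok = (
        tab["chrom"].isin(AUTOSOMES)
        & tab["arm"].isin(["p", "q"])
        & (tab["start"] < tab["end"])
        & pd.Series(band_ok, index=tab.index)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("annotation: rejected %d row(s) failing invariants", n_bad)
    return tab.loc[ok].reset_index(drop=True)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited gene-annotation table and validate it."""
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_annotation(tab)


def write_gene_annotation(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts matrices
# ---------------------------------------------------------------------------

VALID_UNITS = ("counts", "FPKM", "TPM", "CPM")


@dataclass
class CountsMatrix:
    """A gene x sample expression matrix with an explicit unit tag.

    ``values`` is a dense pandas DataFrame indexed by gene_id with sample
    ids as columns.  ``unit`` is one of ``counts`` (non-negative
    integers), ``FPKM``, ``TPM`` or ``CPM`` (non-negative reals).
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit tag {self.unit!r}")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in counts matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts matrix contains non-numeric values")
        if np.isnan(arr).any():
            raise FormatError("counts matrix contains missing values")
        if (arr < 0).any():
            raise ValidationError("negative values in counts matrix")
        if self.unit == "counts":
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("unit 'counts' requires integer values")
            self.values = self.values.astype(np.int64)
        self.values.index = self.values.index.rename("gene_id")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: list[str]) -> "CountsMatrix":
        return CountsMatrix(self.values.loc[:, list(samples)], unit=self.unit)

    def subset_genes(self, genes: list[str]) -> "CountsMatrix":
        return CountsMatrix(self.values.loc[list(genes)], unit=self.unit)


def read_counts(path: str | Path, unit: str = "counts") -> CountsMatrix:
    """Read a counts matrix from TSV (first column = gene ids) or MTX.

    An ``.mtx`` file is read with its sidecar index files
    ``<stem>.genes.txt`` / ``<stem>.samples.txt`` (one id per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = mmread(path)
        genes = Path(str(path)[: -len(".mtx")] + ".genes.txt").read_text().split()
        samples = Path(str(path)[: -len(".mtx")] + ".samples.txt").read_text().split()
        frame = pd.DataFrame(np.asarray(mat.todense()), index=genes, columns=samples)
        return CountsMatrix(frame, unit=unit)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(str(exc)) from exc
    if frame.shape[1] == 0:
        raise FormatError("counts table has no sample columns")
    if not all(np.issubdtype(d, np.number) for d in frame.dtypes):
        raise FormatError("non-numeric sample column in counts table")
    return CountsMatrix(frame, unit=unit)


def write_counts(matrix: CountsMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, csr_matrix(matrix.values.to_numpy()))
        stem = str(path)[: -len(".mtx")]
        Path(stem + ".genes.txt").write_text("\n".join(matrix.genes) + "\n")
        Path(stem + ".samples.txt").write_text("\n".join(matrix.samples) + "\n")
    else:
        out = matrix.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def fpkm_to_tpm(matrix: CountsMatrix) -> CountsMatrix:
    """Convert per-sample FPKM columns to TPM.

    TPM_g = FPKM_g / sum_g FPKM_g * 1e6, per sample; rank order within a
    sample is unchanged and every column sums to one million.
    """
    if matrix.unit != "FPKM":
        raise ValidationError(f"fpkm_to_tpm requires FPKM input, got {matrix.unit}")
    colsums = matrix.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValidationError(f"all-zero FPKM column(s): {list(zero.index)}")
    tpm = matrix.values.div(colsums, axis=1) * 1e6
    return CountsMatrix(tpm, unit="TPM")


# ---------------------------------------------------------------------------
# SEG segments and arm calls
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "seg_value"]


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-like table; converts 1-based inclusive coordinates to
    0-based half-open.  Accepts the common header synonyms (``ID``,
    ``loc.start``, ``seg.mean`` ...)."""
    tab = pd.read_csv(path, sep="\t", dtype={1: str})
    rename = {}
    for col in tab.columns:
        key = col.lower().replace(".", "_")
        if key in ("id", "sample", "sample_id"):
            rename[col] = "sample_id"
        elif key in ("chrom", "chromosome", "chr"):
            rename[col] = "chrom"
        elif key in ("loc_start", "start"):
            rename[col] = "start"
        elif key in ("loc_end", "end"):
            rename[col] = "end"
        elif key in ("seg_mean", "seg_value"):
            rename[col] = "seg_value"
    tab = tab.rename(columns=rename)
    missing = [c for c in SEG_COLUMNS if c not in tab.columns]
    if missing:
        raise FormatError(f"segment table missing columns: {missing}")
    tab = tab.loc[:, SEG_COLUMNS].copy()
    tab["chrom"] = tab["chrom"].astype(str).str.removeprefix("chr")
    tab["start"] = tab["start"].astype(np.int64) - 1  # to 0-based half-open
    tab["end"] = tab["end"].astype(np.int64)
    bad = tab["start"] >= tab["end"]
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} segment(s) with start >= end")
    return tab


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    out = segments.loc[:, SEG_COLUMNS].copy()
    out["start"] = out["start"] + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


@dataclass
class ArmModel:
    """Base-pair intervals (0-based half-open) of each autosomal arm."""

    intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    @classmethod
    def synthetic(cls, arm_length: int = 100_000_000, arms: list[str] | None = None) -> "ArmModel":
        """A schematic equal-length arm model (synthetic stand-in for a
        genome-build cytoband table): p occupies the first half of each
        chromosome, q the second."""
        arms = arms if arms is not None else ALL_ARMS_44
        iv = {}
        for arm in arms:
            chrom, pq = arm[:-1], arm[-1]
            if pq == "p":
                iv[arm] = (chrom, 0, arm_length)
            else:
                iv[arm] = (chrom, arm_length, 2 * arm_length)
        return cls(iv)

    def arms(self) -> list[str]:
        return list(self.intervals)


def segments_to_arm_calls(
    segments: pd.DataFrame,
    arm_model: ArmModel,
    gain_thresh: float = 0.2,
    loss_thresh: float = -0.2,
    min_fraction: float = 0.5,
) -> pd.DataFrame:
    """Reduce mean log2 copy-ratio segments to categorical arm calls.

    An arm is called *gain* when the length-weighted fraction of the arm
    covered by segments with ``seg_value > gain_thresh`` is at least
    ``min_fraction``; *loss* symmetrically below ``loss_thresh``; else
    *disomy*.  If both qualify the larger covered fraction wins, ties go
    to disomy.  Uncovered arm territory counts as disomic.  Returns a
    sample x arm DataFrame of {gain, disomy, loss}.
    """
    calls: dict[str, dict[str, str]] = {}
    for sample_id, seg in segments.groupby("sample_id"):
        row: dict[str, str] = {}
        for arm, (chrom, a_start, a_end) in arm_model.intervals.items():
            sub = seg[seg["chrom"] == chrom]
            ov_start = np.maximum(sub["start"].to_numpy(), a_start)
            ov_end = np.minimum(sub["end"].to_numpy(), a_end)
            ov = np.maximum(ov_end - ov_start, 0).astype(float)
            vals = sub["seg_value"].to_numpy()
            arm_len = a_end - a_start
            gain_frac = ov[vals > gain_thresh].sum() / arm_len
            loss_frac = ov[vals < loss_thresh].sum() / arm_len
            if gain_frac >= min_fraction and gain_frac > loss_frac:
                row[arm] = "gain"
            elif loss_frac >= min_fraction and loss_frac > gain_frac:
                row[arm] = "loss"
            else:
                row[arm] = "disomy"
        calls[str(sample_id)] = row
    table = pd.DataFrame.from_dict(calls, orient="index")
    table.index.name = "sample_id"
    return table.loc[:, arm_model.arms()]


def read_arm_calls(path: str | Path) -> pd.DataFrame:
    """Read a sample x arm grid of {gain, disomy, loss}."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    bad = set(np.unique(tab.to_numpy().astype(str))) - {"gain", "disomy", "loss"}
    if bad:
        raise ValidationError(f"unknown arm states: {sorted(bad)}")
    return tab


def write_arm_calls(calls: pd.DataFrame, path: str | Path) -> None:
    out = calls.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
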