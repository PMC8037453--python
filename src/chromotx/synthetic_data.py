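"""Synthetic breast-cancer cohorts with gene-dosage cis-effects.

The generator emits everything the pipeline consumes — gene annotation,
per-sample arm-level copy-number calls, an NB count matrix for tumors
plus normal-tissue samples, and sample metadata — with the statistical
structure the analysis assumes:

* each tumor's 1p/1q/16p/16q states follow its chromogroup's rule, and
  unconstrained arms acquire independent extra gains/losses at a
  per-group rate that shapes the aneuploidy-score distribution (low in
  the der(1;16)-like and del(16q)-like groups, high in the i(1q)+del(16q)
  group, lowest in CTRL);
* expected counts scale with copy number as (copies/2)**beta — the gene
  dosage transcriptional cis-effect; beta=1 is pure proportionality,
  beta<1 models dosage compensation;
* a configurable fraction of genes is up-/down-dysregulated in all
  tumors relative to normal tissue (the UpT/DownT signal);
* one 16q marker gene is additionally downregulated in lobular samples
  (the CDH1-like pattern), and lobular histotype frequency is enriched
  in 16q-loss groups.

Counts are gamma-Poisson (negative binomial) with common dispersion phi.
Each consumer draws from its own child stream of the master seed, so
enabling one feature never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (
    DEFAULT_ARMS_39,
    CountsMatrix,
    write_arm_calls,
    write_counts,
    write_gene_annotation,
)

#: rule-conforming arm states per truth chromogroup (a concrete choice
#: within each group's allowed states; 16p kept disomic except D2 where
#: the rule requires a gain)
GROUP_ARM_STATES: dict[str, dict[str, str]] = {
    "A": {"1p": "disomy", "1q": "gain", "16p": "disomy", "16q": "loss"},
    "B1": {"1p": "loss", "1q": "gain", "16p": "disomy", "16q": "loss"},
    "B2": {"1p": "loss", "1q": "gain", "16p": "disomy", "16q": "disomy"},
    "C": {"1p": "disomy", "1q": "gain", "16p": "disomy", "16q": "disomy"},
    "D1": {"1p": "disomy", "1q": "disomy", "16p": "disomy", "16q": "loss"},
    "D2": {"1p": "disomy", "1q": "disomy", "16p": "gain", "16q": "loss"},
    "CTRL": {"1p": "disomy", "1q": "disomy", "16p": "disomy", "16q": "disomy"},
}

CONSTRAINED_ARMS = ("1p", "1q", "16p", "16q")
STATE_COPIES = {"gain": 3, "disomy": 2, "loss": 1}

#: TCGA-derived cohort composition (samples with RNA-seq per group).
DEFAULT_GROUP_SIZES = {
    "A": 175, "B1": 98, "B2": 17, "C": 89, "D1": 27, "D2": 45, "CTRL": 68,
}

#: per-group rate of extra aberrations on unconstrained arms, shaping the
#: aneuploidy-score ordering seen in the cohort (CTRL lowest; A and D1
#: low; B1 highest).
DEFAULT_EXTRA_RATES = {
    "A": 0.10, "B1": 0.40, "B2": 0.30, "C": 0.25, "D1": 0.10, "D2": 0.15,
    "CTRL": 0.05,
}

#: lobular histotype frequency per group: enriched with 16q-loss, absent
#: or rare in the 1q-gain/16q-disomic groups.
DEFAULT_LOBULAR_FRACTIONS = {
    "A": 0.30, "B1": 0.15, "B2": 0.0, "C": 0.01, "D1": 0.25, "D2": 0.20,
    "CTRL": 0.20,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults model the study conditions: paper-scale group sizes, NB
    dispersion 0.1, proportional dosage effect (beta = 1), 5% of genes
    up- and 5% down-dysregulated two-fold in tumors, and a 3-fold
    lobular marker knock-down on 16q.
    """

    seed: int = 0
    genes_per_arm: int = 50
    arms: tuple[str, ...] = tuple(DEFAULT_ARMS_39)
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_normals: int = 99
    library_size: int = 500_000
    baseline_logmean_mu: float = 4.0
    baseline_logmean_sigma: float = 1.0
    dispersion: float = 0.1
    dosage_exponent: float = 1.0
    extra_aberration_rate: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXTRA_RATES)
    )
    frac_tumor_up: float = 0.05
    frac_tumor_down: float = 0.05
    tumor_up_fc: float = 2.0
    tumor_down_fc: float = 0.5
    lobular_fraction: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOBULAR_FRACTIONS)
    )
    lobular_marker_fc: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.dosage_exponent < 0:
            raise ValueError("dosage exponent must be non-negative")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        for r in self._rates().values():
            if not (0 <= r <= 1):
                raise ValueError("extra aberration rates must lie in [0, 1]")
        for r in self._lobular().values():
            if not (0 <= r <= 1):
                raise ValueError("lobular fractions must lie in [0, 1]")
        unknown = set(self.group_sizes) - set(GROUP_ARM_STATES)
        if unknown:
            raise ValueError(f"unknown truth groups: {sorted(unknown)}")

    def _rates(self) -> dict[str, float]:
        if isinstance(self.extra_aberration_rate, dict):
            return {g: self.extra_aberration_rate.get(g, 0.0) for g in self.group_sizes}
        return {g: float(self.extra_aberration_rate) for g in self.group_sizes}

    def _lobular(self) -> dict[str, float]:
        if isinstance(self.lobular_fraction, dict):
            return {g: self.lobular_fraction.get(g, 0.0) for g in self.group_sizes}
        return {g: float(self.lobular_fraction) for g in self.group_sizes}


@dataclass
class SyntheticCohort:
    annotation: pd.DataFrame
    arm_calls: pd.DataFrame
    counts: CountsMatrix
    metadata: pd.DataFrame
    gene_truth: pd.DataFrame
    config: SimConfig

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.metadata.index[self.metadata["is_tumor"]])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.metadata.index[~self.metadata["is_tumor"]])

    def group_samples(self, group: str) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == group])


# four synthetic sub-bands per arm, labelled like real cytobands
_BAND_SUFFIXES = ("11", "12", "21", "22")
_ARM_LENGTH = 100_000_000


def _make_annotation(config: SimConfig) -> pd.DataFrame:
    rows = []
    for arm in config.arms:
        chrom, pq = arm[:-1], arm[-1]
        offset = 0 if pq == "p" else _ARM_LENGTH
        spacing = _ARM_LENGTH // (config.genes_per_arm + 1)
        for i in range(config.genes_per_arm):
            start = offset + (i + 1) * spacing
            band = _BAND_SUFFIXES[(i * len(_BAND_SUFFIXES)) // config.genes_per_arm]
            rows.append(
                {
                    "gene_id": f"SYN{arm}G{i:04d}",
                    "gene_name": f"Syn-{arm}-{i:04d}",
                    "chrom": chrom,
                    "arm": pq,
                    "cytoband": f"{arm}{band}",
                    "start": start,
                    "end": start + 2000,
                }
            )
    return pd.DataFrame(rows)


def truth_arm_state(group: str, arm: str) -> str:
    """Rule-conforming copy-number state of an arm in a truth group
    (unconstrained arms are disomic in expectation)."""
    return GROUP_ARM_STATES[group].get(arm, "disomy")


def expected_fold_change(config: SimConfig, arm: str, group: str,
                         ref_group: str = "CTRL") -> float:
    """Analytic expected mean-count ratio of a gene on ``arm`` between
    ``group`` and ``ref_group`` — the dosage-effect oracle
    ((copies/2) ** beta ratio)."""
    c_g = STATE_COPIES[truth_arm_state(group, arm)]
    c_r = STATE_COPIES[truth_arm_state(ref_group, arm)]
    return (c_g / 2.0) ** config.dosage_exponent / (c_r / 2.0) ** config.dosage_exponent


def expected_signed_fc(config: SimConfig, arm: str, group: str,
                       ref_group: str = "CTRL") -> float:
    """Expected ratio in the signed linear-FC convention (|FC| >= 1)."""
    r = expected_fold_change(config, arm, group, ref_group)
    return r if r >= 1 else -1.0 / r


def generate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Generate a fully reproducible synthetic cohort from a config."""
    config = config or SimConfig()
    n_tumors = sum(config.group_sizes.values())
    n_genes = len(config.arms) * config.genes_per_arm
    if n_genes == 0 or n_tumors + config.n_normals == 0:
        raise ValueError("cohort must contain at least one gene and one sample")

    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_base = np.random.default_rng(streams[0])   # baseline expression
    rng_arms = np.random.default_rng(streams[1])   # extra aberrations
    rng_hist = np.random.default_rng(streams[2])   # histotypes
    rng_counts = np.random.default_rng(streams[3])  # NB sampling
    rng_truth = np.random.default_rng(streams[4])  # dysregulated gene choice

    annotation = _make_annotation(config)
    gene_arms = (annotation["chrom"] + annotation["arm"]).to_numpy()
    gene_ids = annotation["gene_id"].to_numpy()

    # baseline relative abundance per gene (log-normal weights)
    weights = np.exp(
        rng_base.normal(config.baseline_logmean_mu, config.baseline_logmean_sigma, n_genes)
    )
    baseline_p = weights / weights.sum()

    # tumor-vs-normal dysregulation and the lobular marker
    t_mult = np.ones(n_genes)
    n_up = int(round(config.frac_tumor_up * n_genes))
    n_down = int(round(config.frac_tumor_down * n_genes))
    dysreg = rng_truth.choice(n_genes, size=n_up + n_down, replace=False)
    t_mult[dysreg[:n_up]] = config.tumor_up_fc
    t_mult[dysreg[n_up:]] = config.tumor_down_fc
    marker_idx = None
    on_16q = np.flatnonzero(gene_arms == "16q")
    if on_16q.size:
        marker_idx = int(on_16q[0])

    # samples: arm calls, groups, histotypes
    rates = config._rates()
    lob = config._lobular()
    free_arms = [a for a in config.arms if a not in CONSTRAINED_ARMS]
    sample_ids: list[str] = []
    groups: list[str] = []
    histotypes: list[str] = []
    call_rows: list[dict[str, str]] = []
    for group in sorted(config.group_sizes):
        for i in range(config.group_sizes[group]):
            sid = f"T-{group}-{i:04d}"
            sample_ids.append(sid)
            groups.append(group)
            row = {arm: truth_arm_state(group, arm) for arm in config.arms}
            aberrant = rng_arms.random(len(free_arms)) < rates[group]
            direction = rng_arms.random(len(free_arms)) < 0.5
            for j, arm in enumerate(free_arms):
                if aberrant[j]:
                    row[arm] = "gain" if direction[j] else "loss"
            call_rows.append(row)
            histotypes.append(
                "lobular" if rng_hist.random() < lob[group] else "ductal"
            )
    arm_calls = pd.DataFrame(call_rows, index=sample_ids, columns=list(config.arms))
    arm_calls.index.name = "sample_id"

    normal_ids = [f"N-{i:04d}" for i in range(config.n_normals)]

    # expected counts and NB sampling
    beta = config.dosage_exponent
    arm_index = {arm: np.flatnonzero(gene_arms == arm) for arm in config.arms}
    n_total = n_tumors + config.n_normals
    mean = np.empty((n_genes, n_total))
    base_mean = config.library_size * baseline_p
    for k, sid in enumerate(sample_ids):
        copies = np.full(n_genes, 2.0)
        for arm in config.arms:
            state = arm_calls.iloc[k][arm]
            if state != "disomy":
                copies[arm_index[arm]] = STATE_COPIES[state]
        m = base_mean * (copies / 2.0) ** beta * t_mult
        if marker_idx is not None and histotypes[k] == "lobular":
            m = m.copy()
            m[marker_idx] *= config.lobular_marker_fc
        mean[:, k] = m
    for k in range(config.n_normals):
        mean[:, n_tumors + k] = base_mean

    shape = 1.0 / config.dispersion
    lam = rng_counts.gamma(shape, mean / shape)
    counts = rng_counts.poisson(lam).astype(np.int64)
    all_ids = sample_ids + normal_ids
    counts_matrix = CountsMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=all_ids), unit="counts"
    )

    metadata = pd.DataFrame(
        {
            "group": groups + ["normal"] * config.n_normals,
            "histotype": histotypes + ["normal"] * config.n_normals,
            "is_tumor": [True] * n_tumors + [False] * config.n_normals,
        },
        index=pd.Index(all_ids, name="sample_id"),
    )

    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "arm": gene_arms,
            "tumor_multiplier": t_mult,
            "lobular_marker": [i == marker_idx for i in range(n_genes)],
        }
    ).set_index("gene_id")

    return SyntheticCohort(
        annotation=annotation,
        arm_calls=arm_calls,
        counts=counts_matrix,
        metadata=metadata,
        gene_truth=gene_truth,
        config=config,
    )


def small_config(**overrides) -> SimConfig:
    """A desk-scale configuration (reduced group sizes and gene count)
    for fast exploratory runs; all structural features retained."""
    base = dict(
        genes_per_arm=25,
        arms=("1p", "1q", "16p", "16q", "2p", "2q", "5q", "8q"),
        group_sizes={"A": 40, "B1": 40, "B2": 12, "C": 40, "D1": 16, "D2": 24, "CTRL": 40},
        n_normals=30,
        library_size=200_000,
    )
    base.update(overrides)
    return SimConfig(**base)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four standard files plus truth tables; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.tsv",
        "arm_calls": out / "arm_calls.tsv",
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "gene_truth": out / "gene_truth.tsv",
    }
    write_gene_annotation(cohort.annotation, paths["annotation"])
    write_arm_calls(cohort.arm_calls, paths["arm_calls"])
    write_counts(cohort.counts, paths["counts"])
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    cohort.gene_truth.to_csv(paths["gene_truth"], sep="\t")
    return paths
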