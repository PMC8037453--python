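"""Gene-set enrichment with Signal2Noise ranking.

Two-class GSEA in the classic running-sum form: genes are ranked by the
Signal2Noise metric s = (mu_A - mu_B) / (sigma_A + sigma_B) (each sigma
floored at max(0.2 |mu|, 0.2)); a weighted Kolmogorov-Smirnov walk over
the ranked list yields the enrichment score; phenotype (or gene-set)
permutations yield NES, nominal p and a ratio-of-tails FDR q.

The *absolute* metric variant ranks by |s| instead of s, so genes driven
in either direction by a copy-number dosage effect — increased on a
gained arm, decreased on a lost arm — reach the top of the list
together; this is what lets a single set mixing 1q and 16q genes score.

A hypergeometric over-representation test is included for threshold-
selected gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation_io import CountsMatrix
from .de_engine import bh_adjust

logger = logging.getLogger(__name__)

SIGMA_FLOOR_FRACTION = 0.2
SIGMA_FLOOR_MIN = 0.2


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def signal2noise_values(
    expr: pd.DataFrame, group_samples: list[str], ref_samples: list[str]
) -> pd.Series:
    """Raw Signal2Noise value per gene (no ordering)."""
    if len(group_samples) < 3 or len(ref_samples) < 3:
        raise ValueError(
            "Signal2Noise needs >=3 samples per side; "
            "use gene-set permutation GSEA for smaller groups"
        )
    a = expr.loc[:, list(group_samples)].to_numpy(dtype=float)
    b = expr.loc[:, list(ref_samples)].to_numpy(dtype=float)
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1),
                      np.maximum(SIGMA_FLOOR_FRACTION * np.abs(mu_a), SIGMA_FLOOR_MIN))
    sd_b = np.maximum(b.std(axis=1, ddof=1),
                      np.maximum(SIGMA_FLOOR_FRACTION * np.abs(mu_b), SIGMA_FLOOR_MIN))
    return pd.Series((mu_a - mu_b) / (sd_a + sd_b), index=expr.index, name="s2n")


def rank_genes(values: pd.Series, absolute: bool = False) -> pd.DataFrame:
    """Order genes by the metric (or its absolute value), descending.

    Ties are broken by gene id (lexicographic) for determinism.  Returns
    a DataFrame with columns ``s2n`` and ``rank_metric`` in list order.
    """
    metric = values.abs() if absolute else values
    frame = pd.DataFrame({"s2n": values, "rank_metric": metric})
    order = np.lexsort((np.asarray(frame.index).astype(str), -metric.to_numpy()))
    frame = frame.iloc[order]
    frame.attrs["metric"] = "abs_signal2noise" if absolute else "signal2noise"
    return frame


def signal2noise(
    expr: CountsMatrix | pd.DataFrame,
    group_samples: list[str],
    ref_samples: list[str],
    absolute: bool = False,
) -> pd.DataFrame:
    """Signal2Noise-ranked gene list (the GSEA input)."""
    frame = expr.values if isinstance(expr, CountsMatrix) else expr
    return rank_genes(signal2noise_values(frame, group_samples, ref_samples), absolute)


# ---------------------------------------------------------------------------
# Running-sum enrichment score
# ---------------------------------------------------------------------------

def _es_walk(metric: np.ndarray, hit: np.ndarray, weight: float) -> tuple[float, np.ndarray]:
    """ES and full running sum for one ranked list / hit mask."""
    n = metric.size
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(metric) ** weight
    hit_sum = w[hit].sum()
    steps = np.where(hit, np.where(hit_sum > 0, w / max(hit_sum, 1e-300), 1.0 / n_hit),
                     -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def enrichment_score(
    ranked: pd.DataFrame, gene_set: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a set against a ranked list.

    Hits increment the running sum by |metric|^weight normalized over
    hits, misses decrement by 1/(N - N_hit); the ES is the extremum of
    largest magnitude.  The leading edge contains the set members at or
    before the extremum (at or after, for negative ES).
    """
    metric = ranked["rank_metric"].to_numpy(dtype=float)
    genes = np.asarray(ranked.index)
    hit = np.isin(genes, list(gene_set))
    es, running = _es_walk(metric, hit, weight)
    idx = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = genes[: idx + 1][hit[: idx + 1]]
    else:
        leading = genes[idx:][hit[idx:]]
    return es, running, list(leading)


# ---------------------------------------------------------------------------
# Permutation NES / FDR
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)


def _nes(es: float, perm: np.ndarray) -> float:
    same = perm[perm >= 0] if es >= 0 else -perm[perm < 0]
    if same.size == 0 or same.mean() == 0:
        return 0.0
    return float(es / same.mean())


def _nominal_p(es: float, perm: np.ndarray) -> float:
    if es >= 0:
        same = perm[perm >= 0]
        return float((same >= es).sum()) / max(same.size, 1)
    same = perm[perm < 0]
    return float((same <= es).sum()) / max(same.size, 1)


def nes_fdr(
    expr: CountsMatrix | pd.DataFrame,
    group_samples: list[str],
    ref_samples: list[str],
    gene_sets: dict[str, set[str]],
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int = 0,
    absolute: bool = False,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation GSEA over a collection of gene sets.

    Phenotype mode permutes sample labels (needs >= 7 per side, else the
    run auto-switches to gene-set mode with a warning); gene-set mode
    draws random same-size sets from the universe.  NES divides the ES by
    the mean magnitude of same-sign permuted scores; FDR q follows the
    ratio-of-tails scheme over the pooled sign-matched NES null.
    Deterministic for a fixed seed.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-values will be coarse", n_perm)
    frame = expr.values if isinstance(expr, CountsMatrix) else expr
    rng = np.random.default_rng(seed)
    if mode == "phenotype" and (len(group_samples) < 7 or len(ref_samples) < 7):
        logger.warning("groups too small for phenotype permutation; using gene_set mode")
        mode = "gene_set"
    if mode not in ("phenotype", "gene_set"):
        raise ValueError(f"unknown permutation mode {mode!r}")

    ranked = signal2noise(frame, group_samples, ref_samples, absolute=absolute)
    universe = np.asarray(ranked.index)
    sets = {
        name: set(members) & set(universe) for name, members in gene_sets.items()
    }
    sets = {n: s for n, s in sets.items() if min_size <= len(s) <= max_size}
    if not sets:
        return pd.DataFrame(
            columns=["size", "es", "nes", "nominal_p", "fdr_q", "leading_edge"]
        )

    observed: dict[str, tuple[float, list[str]]] = {}
    for name, members in sets.items():
        es, _, leading = enrichment_score(ranked, members, weight)
        observed[name] = (es, leading)

    perm_es = {name: np.empty(n_perm) for name in sets}
    if mode == "phenotype":
        pool = list(group_samples) + list(ref_samples)
        n_a = len(group_samples)
        metric_order_cache = None
        for j in range(n_perm):
            perm = rng.permutation(pool)
            r = signal2noise(frame, list(perm[:n_a]), list(perm[n_a:]), absolute=absolute)
            metric = r["rank_metric"].to_numpy(dtype=float)
            genes_order = np.asarray(r.index)
            for name, members in sets.items():
                hit = np.isin(genes_order, list(members))
                perm_es[name][j], _ = _es_walk(metric, hit, weight)
    else:
        metric = ranked["rank_metric"].to_numpy(dtype=float)
        for name, members in sets.items():
            k = len(members)
            for j in range(n_perm):
                hit = np.zeros(universe.size, dtype=bool)
                hit[rng.choice(universe.size, size=k, replace=False)] = True
                perm_es[name][j], _ = _es_walk(metric, hit, weight)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes: dict[str, float] = {}
    for name in sets:
        es, leading = observed[name]
        perm = perm_es[name]
        obs_nes[name] = _nes(es, perm)
        pos_mean = perm[perm >= 0].mean() if (perm >= 0).any() else np.nan
        neg_mean = (-perm[perm < 0]).mean() if (perm < 0).any() else np.nan
        norm = np.where(perm >= 0, perm / pos_mean, perm / neg_mean)
        null_nes_pool.append(norm[np.isfinite(norm)])
    pooled = np.concatenate(null_nes_pool)
    all_obs = np.array(list(obs_nes.values()))

    for name in sets:
        es, leading = observed[name]
        nes = obs_nes[name]
        if nes >= 0:
            tail_null = (pooled >= nes).sum() / max((pooled >= 0).sum(), 1)
            tail_obs = (all_obs >= nes).sum() / max((all_obs >= 0).sum(), 1)
        else:
            tail_null = (pooled <= nes).sum() / max((pooled < 0).sum(), 1)
            tail_obs = (all_obs <= nes).sum() / max((all_obs < 0).sum(), 1)
        q = 1.0 if tail_obs == 0 else min(1.0, tail_null / tail_obs)
        rows.append(
            {
                "name": name,
                "size": len(sets[name]),
                "es": es,
                "nes": nes,
                "nominal_p": _nominal_p(es, perm_es[name]),
                "fdr_q": q,
                "leading_edge": ";".join(leading),
                "mode": mode,
            }
        )
    out = pd.DataFrame(rows).set_index("name")
    return out.sort_values("nes", ascending=False)


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------

def hypergeometric_ora(
    query: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene list.

    A desk-scale replacement for web-service pathway enrichment: per set,
    P(overlap >= observed) under sampling |query| genes from the universe
    without replacement, BH-corrected across sets.
    """
    universe = set(universe)
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:10]}")
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append(
            {
                "name": name,
                "set_size": len(members),
                "overlap": k,
                "p": min(p, 1.0),
                "members": ";".join(sorted(query & members)),
            }
        )
    out = pd.DataFrame(rows).set_index("name")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, members in gene_sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")
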