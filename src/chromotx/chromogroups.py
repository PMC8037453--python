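"""1,16-chromogroup assignment and cohort-level cytogenomic summaries.

Breast cancers are grouped by the categorical copy-number state of four
chromosome arms (1p, 1q, 16p, 16q) into chromogroups that mirror the
classical cytogenetic aberrations producing 1q-gain and/or 16q-loss:

====== ==== ==== ======== ==== =================================
group   1p   1q    16p     16q  inspiring aberration
====== ==== ==== ======== ==== =================================
A       Dis   G   G/Dis     L   der(1;16)(q10;p10)
B        L    G    any     any  i(1q)
B1       L    G   G/Dis     L   i(1q) + 16q-loss
B2       L    G    Dis     Dis  i(1q), intact chr16
C       any   G    Dis     Dis  1q-gain, intact chr16
D       Dis  Dis  G/Dis     L   16q-loss, intact chr1
D1      Dis  Dis   Dis      L   del(16q)
D2      Dis  Dis    G       L   16q-loss with 16p-gain
CTRL    Dis  Dis   Dis     Dis  no chr1/chr16 aberration
====== ==== ==== ======== ==== =================================

"any" means the arm state is ignored (gain and loss both allowed).  A
sample may match several rules (B2 = B intersect C); samples matching no
rule receive the empty label set.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation_io import DEFAULT_ARMS_39

logger = logging.getLogger(__name__)

STATES = ("gain", "disomy", "loss")
REQUIRED_ARMS = ("1p", "1q", "16p", "16q")
GROUP_LABELS = ("A", "B", "B1", "B2", "C", "D", "D1", "D2", "CTRL")

_G = frozenset({"gain"})
_D = frozenset({"disomy"})
_L = frozenset({"loss"})
_GD = frozenset({"gain", "disomy"})
_ANY = frozenset(STATES)

#: allowed-state sets per (group, arm); "any" arms impose no constraint.
RULES: dict[str, dict[str, frozenset[str]]] = {
    "A": {"1p": _D, "1q": _G, "16p": _GD, "16q": _L},
    "B": {"1p": _L, "1q": _G, "16p": _ANY, "16q": _ANY},
    "B1": {"1p": _L, "1q": _G, "16p": _GD, "16q": _L},
    "B2": {"1p": _L, "1q": _G, "16p": _D, "16q": _D},
    "C": {"1p": _ANY, "1q": _G, "16p": _D, "16q": _D},
    "D": {"1p": _D, "1q": _D, "16p": _GD, "16q": _L},
    "D1": {"1p": _D, "1q": _D, "16p": _D, "16q": _L},
    "D2": {"1p": _D, "1q": _D, "16p": _G, "16q": _L},
    "CTRL": {"1p": _D, "1q": _D, "16p": _D, "16q": _D},
}


def assign_chromogroups(calls: Mapping[str, str]) -> frozenset[str]:
    """Return every chromogroup whose arm-state rule matches ``calls``.

    ``calls`` maps arm labels to states in {gain, disomy, loss} and must
    include 1p, 1q, 16p and 16q.  May return the empty set (the rule
    table does not cover every state combination).
    """
    for arm in REQUIRED_ARMS:
        if arm not in calls:
            raise ValueError(f"missing required arm call: {arm}")
        if calls[arm] not in STATES:
            raise ValueError(f"invalid state {calls[arm]!r} for arm {arm}")
    labels = {
        group
        for group, rule in RULES.items()
        if all(calls[arm] in allowed for arm, allowed in rule.items())
    }
    return frozenset(labels)


def assign_cohort(arm_calls: pd.DataFrame) -> pd.DataFrame:
    """Assign every sample of a sample x arm call table.

    Returns a DataFrame indexed by sample with one boolean column per
    group label plus a semicolon-joined ``labels`` column.
    """
    records = {}
    for sample, row in arm_calls.iterrows():
        labels = assign_chromogroups(row.to_dict())
        rec = {g: (g in labels) for g in GROUP_LABELS}
        rec["labels"] = ";".join(g for g in GROUP_LABELS if g in labels)
        records[sample] = rec
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


def aneuploidy_score(
    calls: Mapping[str, str], arm_universe: Iterable[str] = DEFAULT_ARMS_39
) -> int:
    """Number of arms in ``arm_universe`` with a non-disomic state.

    Arms missing from ``calls`` are treated as disomic (logged once per
    call at debug level).
    """
    score = 0
    missing = []
    for arm in arm_universe:
        state = calls.get(arm)
        if state is None:
            missing.append(arm)
        elif state != "disomy":
            score += 1
    if missing:
        logger.debug("aneuploidy_score: %d arm(s) missing, treated as disomy", len(missing))
    return score


def cohort_aneuploidy_scores(
    arm_calls: pd.DataFrame, arm_universe: Iterable[str] = DEFAULT_ARMS_39
) -> pd.Series:
    universe = [a for a in arm_universe]
    present = [a for a in universe if a in arm_calls.columns]
    scores = (arm_calls.loc[:, present] != "disomy").sum(axis=1)
    return scores.astype(int).rename("aneuploidy_score")


def arm_aberration_frequencies(
    arm_calls: pd.DataFrame,
    assignments: pd.DataFrame | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Percentage of samples with gain / loss per arm.

    With ``group`` given, restricts to samples assigned that chromogroup
    (requires ``assignments`` from :func:`assign_cohort`).
    """
    sel = arm_calls
    if group is not None:
        if assignments is None:
            raise ValueError("group selection requires assignments")
        members = assignments.index[assignments[group]]
        sel = arm_calls.loc[members]
    n = len(sel)
    if n == 0:
        raise ValueError("empty sample selection")
    freq = pd.DataFrame(
        {
            "gain_pct": 100.0 * (sel == "gain").sum(axis=0) / n,
            "loss_pct": 100.0 * (sel == "loss").sum(axis=0) / n,
        }
    )
    freq.index.name = "arm"
    return freq


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def group_overlap_summary(
    assignments: pd.DataFrame,
    aneuploidy: pd.Series | None = None,
    union_groups: tuple[str, ...] = ("A", "B", "C", "D"),
) -> pd.DataFrame:
    """Per-group sample counts, share of the aberrant union, and
    aneuploidy-score statistics.

    The union counts unique samples across ``union_groups`` (a sample in
    both B and C is counted once); shares are percentages of that union
    rounded to the nearest integer, half away from zero.
    """
    if len(assignments) == 0:
        raise ValueError("no assignments given")
    union_mask = assignments.loc[:, list(union_groups)].any(axis=1)
    n_union = int(union_mask.sum())
    rows = []
    for group in GROUP_LABELS:
        members = assignments.index[assignments[group]]
        rec: dict[str, object] = {"group": group, "n": len(members)}
        rec["pct_of_union"] = (
            _round_half_away(100.0 * len(members) / n_union)
            if group in union_groups and n_union
            else np.nan
        )
        if aneuploidy is not None and len(members):
            a_s = aneuploidy.loc[members]
            rec.update(
                as_mean=round(float(a_s.mean()), 2),
                as_sd=round(float(a_s.std(ddof=1)), 2) if len(a_s) > 1 else np.nan,
                as_median=float(a_s.median()),
                as_iqr_low=float(a_s.quantile(0.25)),
                as_iqr_high=float(a_s.quantile(0.75)),
            )
        rows.append(rec)
    summary = pd.DataFrame(rows).set_index("group")
    summary.attrs["n_union"] = n_union
    return summary
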