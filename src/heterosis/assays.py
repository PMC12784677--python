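"""Phenotype and assay statistics for aquaculture growth trials.

Covers the arithmetic behind a hybrid-vigor grow-out experiment: specific
growth rates for length and weight, survival, enzyme specific activity,
intestinal histomorphometry indices, relative qPCR expression by the
2^-ddCT method, one-way ANOVA and Tukey's HSD post-hoc test with a compact
letter display. Growth-curve description is deliberately non-parametric:
group mean +/- SD per timepoint.
"""

from __future__ import annotations

import itertools
import math
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROWTH_COLUMNS = ["fish_id", "group", "timepoint_days", "length_mm", "weight_g"]

__all__ = [
    "specific_growth_rate",
    "survival_rate",
    "specific_activity",
    "villus_density",
    "fold_crypt_ratio",
    "relative_expression_ddct",
    "AnovaResult",
    "anova_oneway",
    "tukey_hsd",
    "studentized_range_pvalue",
    "compact_letter_display",
    "read_growth_records",
    "write_growth_records",
    "summarize_growth",
    "group_sgr",
]


def specific_growth_rate(x1: float, x2: float, days: float) -> float:
    """SGR in %/day: (ln x2 - ln x1) / T * 100, for length or weight."""
    if x1 <= 0 or x2 <= 0:
        raise ValueError("measurements must be strictly positive")
    if days <= 0:
        raise ValueError("culture period must be positive")
    return (math.log(x2) - math.log(x1)) / days * 100.0


def survival_rate(final_n: int, initial_n: int) -> float:
    """Survival in %: 100 * final / initial."""
    if initial_n <= 0:
        raise ValueError("initial count must be positive")
    if not 0 <= final_n <= initial_n:
        raise ValueError("final count must lie in [0, initial]")
    return 100.0 * final_n / initial_n


def specific_activity(total_units: float, protein_mg: float) -> float:
    """Enzyme specific activity in U/mg protein."""
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    return total_units / protein_mg


def villus_density(n_villi: int, mucosal_length_mm: float) -> float:
    """Villi per millimetre of mucosa."""
    if mucosal_length_mm <= 0:
        raise ValueError("mucosal length must be positive")
    return n_villi / mucosal_length_mm


def fold_crypt_ratio(fold_height_um: float, crypt_depth_um: float) -> float:
    """Intestinal fold length / crypt depth (dimensionless)."""
    if fold_height_um <= 0 or crypt_depth_um <= 0:
        raise ValueError("fold height and crypt depth must be positive")
    return fold_height_um / crypt_depth_um


def relative_expression_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    ddCT = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator).
    """
    for ct in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return 2.0 ** (-ddct)


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        arrays[name] = arr
    return arrays


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (between/within sums of squares).

    All-identical observations yield F = 0, p = 1 by convention; zero
    within-group variance with distinct group means yields F = inf, p = 0.
    """
    arrays = _check_groups(groups)
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df1 = len(arrays) - 1
    df2 = all_values.size - len(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(float("inf"), df1, df2, 0.0)
    F = (ssb / df1) / (ssw / df2)
    return AnovaResult(float(F), df1, df2, float(stats.f.sf(F, df1, df2)))


def studentized_range_pvalue(q: float, k: int, df: int) -> float:
    """Upper-tail p of the studentized range distribution (k groups, df error)."""
    if q <= 0:
        return 1.0
    return float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All-pairs Tukey HSD with a compact letter display.

    Unbalanced designs use the Tukey-Kramer standard error. Returns the
    pairwise table (``group1, group2, diff, q_stat, p_adj, significant``) and
    a dict mapping group -> letters; groups sharing a letter do not differ at
    level ``alpha``. Letters follow descending group means.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    df_err = n_total - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err
    means = {name: a.mean() for name, a in arrays.items()}

    rows = []
    for g1, g2 in itertools.combinations(arrays, 2):
        diff = means[g2] - means[g1]
        se = math.sqrt(
            msw / 2.0 * (1.0 / arrays[g1].size + 1.0 / arrays[g2].size)
        )
        if se == 0.0:
            q = 0.0 if diff == 0.0 else float("inf")
        else:
            q = abs(diff) / se
        p_adj = 0.0 if math.isinf(q) else studentized_range_pvalue(q, k, df_err)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "diff": diff,
                "q_stat": q,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    table = pd.DataFrame(rows)
    sig_pairs = [
        (r["group1"], r["group2"]) for r in rows if r["significant"]
    ]
    letters = compact_letter_display(means, sig_pairs)
    return table, letters


def compact_letter_display(
    means: Mapping[str, float], significant_pairs: Sequence[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one set holding all groups; every significantly different
    pair splits the sets containing both; sets absorbed by supersets are
    dropped. Letters are assigned in order of descending group mean.
    """
    order = sorted(means, key=lambda g: -means[g])
    sets: list[set[str]] = [set(order)]
    for g1, g2 in significant_pairs:
        for s in [s for s in sets if g1 in s and g2 in s]:
            sets.remove(s)
            for candidate in (s - {g1}, s - {g2}):
                if candidate and not any(candidate <= other for other in sets):
                    sets.append(candidate)
            sets = [
                s2 for s2 in sets
                if not any(s2 < other for other in sets)
            ]
    for g in order:  # safety: every group must carry a letter
        if not any(g in s for s in sets):
            sets.append({g})
    # letter order: sets ranked by their best (highest-mean) member
    sets.sort(key=lambda s: min(order.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter, s in zip(alphabet, sets):
        for g in order:
            if g in s:
                letters[g] += letter
    return letters


def read_growth_records(path: str | Path) -> pd.DataFrame:
    """CSV with columns fish_id, group, timepoint_days, length_mm, weight_g."""
    df = pd.read_csv(Path(path))
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth file missing columns: {sorted(missing)}")
    if (df["length_mm"] <= 0).any() or (df["weight_g"] <= 0).any():
        raise ValueError("lengths and weights must be strictly positive")
    return df[GROWTH_COLUMNS]


def write_growth_records(records: pd.DataFrame, path: str | Path) -> None:
    records[GROWTH_COLUMNS].to_csv(Path(path), index=False)


def summarize_growth(records: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD of length and weight per timepoint."""
    out = (
        records.groupby(["group", "timepoint_days"], sort=True)
        .agg(
            n=("fish_id", "count"),
            length_mean=("length_mm", "mean"),
            length_sd=("length_mm", "std"),
            weight_mean=("weight_g", "mean"),
            weight_sd=("weight_g", "std"),
        )
        .reset_index()
    )
    return out


def group_sgr(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group SGR for length and weight between first and last timepoint."""
    rows = []
    for group, sub in records.groupby("group", sort=True):
        t0, t1 = sub["timepoint_days"].min(), sub["timepoint_days"].max()
        if t0 == t1:
            raise ValueError(f"group {group!r} has a single timepoint")
        first = sub[sub["timepoint_days"] == t0]
        last = sub[sub["timepoint_days"] == t1]
        days = float(t1 - t0)
        rows.append(
            {
                "group": group,
                "days": days,
                "sgr_length": specific_growth_rate(
                    first["length_mm"].mean(), last["length_mm"].mean(), days
                ),
                "sgr_weight": specific_growth_rate(
                    first["weight_g"].mean(), last["weight_g"].mean(), days
                ),
            }
        )
    return pd.DataFrame(rows)
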