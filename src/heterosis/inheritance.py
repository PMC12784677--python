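"""Inheritance-pattern classification of hybrid gene expression.

Each gene that is differentially expressed in at least one of the three
pairwise comparisons (hybrid vs parent1, hybrid vs parent2, parent2 vs
parent1) is assigned one of twelve expression patterns, or a ``conserved`` /
``ambiguous`` bin:

* **conserved** — |log2FC| < 1.25 between the hybrid and *both* parents
  (strict), checked first;
* **additive** (classes I and II) — the parents differ (c != 0), the hybrid's
  replicates do not significantly deviate from the mid-parent value (MPV, the
  arithmetic mean of the two parental means), and the hybrid mean lies inside
  the parental interval; class I when parent2 is the high parent, II when
  parent1 is;
* **expression-level dominance** (III-VI) — the hybrid significantly deviates
  from the MPV (or sits outside the parental range) while matching one parent:
  III/IV hybrid ~ parent1 (low/high parent respectively), V/VI hybrid ~
  parent2 (high/low);
* **transgressive** (VII-XII) — the hybrid is significantly above or below
  both parents: IX/X parents equal, XI/XII up beyond the high parent, VII/VIII
  down beyond the low parent;
* **ambiguous** — any remaining sign combination (e.g. hybrid between parents
  yet significantly off-MPV with no dominance signature).

Each pairwise comparison contributes a sign in {-1, 0, +1}: the sign of the
log2 fold change when the comparison is a DEG, 0 otherwise. Making additivity
hinge on the MPV test rather than on both hybrid-parent comparisons being
significant is deliberate: a hybrid at the exact arithmetic MPV of two parents
can never differ from the high parent by more than one log2 unit
(|log2((1+R)/(2R))| < 1 for every parent ratio R), so a DEG-threshold-based
rule would, by construction, label every truly additive gene as dominant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, SampleDesign, normalize_counts, size_factors

logger = logging.getLogger(__name__)

CLASS_LABELS = (
    "I", "II", "III", "IV", "V", "VI",
    "VII", "VIII", "IX", "X", "XI", "XII",
    "conserved", "ambiguous",
)

ADDITIVE_CLASSES = frozenset({"I", "II"})
NONADDITIVE_CLASSES = frozenset(
    {"III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"}
)

# transgressive patterns keyed by (sign of hybrid-vs-both-parents, sign of c)
_TRANSGRESSIVE = {
    (1, 0): "IX",
    (-1, 0): "X",
    (1, 1): "XI",
    (1, -1): "XII",
    (-1, 1): "VII",
    (-1, -1): "VIII",
}

# expression-level dominance patterns keyed by (c, a, b)
_DOMINANCE = {
    (1, 0, -1): "III",
    (-1, 0, 1): "IV",
    (1, 1, 0): "V",
    (-1, -1, 0): "VI",
}

__all__ = [
    "ComparisonTriple",
    "mid_parent_value",
    "mpv_deviation_test",
    "conserved_call",
    "classify_gene",
    "classify_all",
    "summarize_patterns",
    "additivity_of",
    "write_calls",
    "CLASS_LABELS",
    "ADDITIVE_CLASSES",
    "NONADDITIVE_CLASSES",
]


@dataclass(frozen=True)
class ComparisonTriple:
    """Signs of the three pairwise DE calls for one gene.

    ``a``: hybrid vs parent1; ``b``: hybrid vs parent2; ``c``: parent2 vs
    parent1. Each is the sign of the log2 fold change when the comparison is a
    DEG, and 0 exactly when it is not.
    """

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) not in (-1, 0, 1):
                raise ValueError(f"sign {name} must be -1, 0 or +1")

    def parent_swapped(self) -> "ComparisonTriple":
        """The triple after relabeling parent1 <-> parent2."""
        return ComparisonTriple(a=self.b, b=self.a, c=-self.c)


def mid_parent_value(mean_p1: float, mean_p2: float) -> float:
    """Arithmetic mean of the two parental expression means."""
    if mean_p1 < 0 or mean_p2 < 0:
        raise ValueError("parental means must be non-negative")
    return (mean_p1 + mean_p2) / 2.0


def mpv_deviation_test(
    hybrid_reps: np.ndarray,
    mpv: float,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two-sided one-sample t-test of log2(rep + 1) against log2(MPV + 1).

    Returns ``(p, deviates)`` with ``deviates`` true when p < alpha. For
    zero-variance replicates the p-value is set to 0 or 1 by convention,
    depending on whether the replicate mean differs from the MPV beyond 1e-9
    relative tolerance.
    """
    y = np.log2(np.asarray(hybrid_reps, dtype=float) + 1.0)
    if y.size < 2:
        raise ValueError("need at least 2 hybrid replicates")
    if mpv < 0:
        raise ValueError("MPV must be non-negative")
    target = np.log2(mpv + 1.0)
    if np.ptp(y) == 0.0:
        same = np.isclose(y[0], target, rtol=1e-9, atol=1e-12)
        p = 1.0 if same else 0.0
        return p, p < alpha
    t_res = stats.ttest_1samp(y, popmean=target)
    p = float(t_res.pvalue)
    return p, p < alpha


def conserved_call(
    lfc_h_vs_p1: float, lfc_h_vs_p2: float, threshold: float = 1.25
) -> bool:
    """Conserved expression: |log2FC| strictly below threshold vs both parents."""
    if not (np.isfinite(lfc_h_vs_p1) and np.isfinite(lfc_h_vs_p2)):
        raise ValueError("log2 fold changes must be finite")
    return abs(lfc_h_vs_p1) < threshold and abs(lfc_h_vs_p2) < threshold


def classify_gene(
    triple: ComparisonTriple,
    mpv_deviates: bool,
    conserved: bool,
    hybrid_between: bool | None = None,
) -> str:
    """Assign one of the 12 pattern labels, ``conserved`` or ``ambiguous``.

    ``hybrid_between`` optionally supplies whether the hybrid mean lies inside
    the closed parental interval; when ``None`` the additive call relies on
    the MPV test alone. Total function: every input gets a label.
    """
    if conserved:
        return "conserved"
    a, b, c = triple.a, triple.b, triple.c
    if a == b and a != 0:
        return _TRANSGRESSIVE[(a, c)]
    if c != 0 and not mpv_deviates and hybrid_between is not False:
        return "I" if c == 1 else "II"
    return _DOMINANCE.get((c, a, b), "ambiguous")


def additivity_of(class_label: str) -> str:
    if class_label in ADDITIVE_CLASSES:
        return "additive"
    if class_label in NONADDITIVE_CLASSES:
        return "non-additive"
    return class_label  # conserved / ambiguous


def _signs(table: pd.DataFrame) -> np.ndarray:
    return np.where(
        table["is_deg"].to_numpy(),
        np.sign(table["log2fc"].to_numpy()).astype(int),
        0,
    )


def _vectorized_mpv_test(
    hybrid: np.ndarray, mpv: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-sample t of log2(rep+1) vs log2(mpv+1) with the
    zero-variance convention of :func:`mpv_deviation_test`."""
    y = np.log2(hybrid + 1.0)
    n = y.shape[1]
    target = np.log2(mpv + 1.0)
    mean = y.mean(axis=1)
    sd = y.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - target) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero_var = sd == 0.0
    same = np.isclose(mean, target, rtol=1e-9, atol=1e-12)
    p = np.where(zero_var, np.where(same, 1.0, 0.0), p)
    return p, p < alpha


def classify_all(
    counts: CountMatrix,
    design: SampleDesign,
    de_h_p1: pd.DataFrame,
    de_h_p2: pd.DataFrame,
    de_p2_p1: pd.DataFrame,
    alpha: float = 0.05,
    conserved_threshold: float = 1.25,
    hybrid_group: str | None = None,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify every gene that is a DEG in >= 1 of the three comparisons.

    The DE tables must be oriented hybrid-over-parent (``de_h_p1``,
    ``de_h_p2``) and parent2-over-parent1 (``de_p2_p1``) and share one gene
    universe. Returns a DataFrame with columns ``gene_id, class_label,
    additivity, mpv, mpv_p, lfc_h_p1, lfc_h_p2, lfc_p2_p1``; genes that are
    DEGs nowhere are omitted.
    """
    universe_sets = [set(t["gene_id"]) for t in (de_h_p1, de_h_p2, de_p2_p1)]
    if not (universe_sets[0] == universe_sets[1] == universe_sets[2]):
        diff = sorted(
            universe_sets[0] ^ universe_sets[1] | universe_sets[0] ^ universe_sets[2]
        )
        raise ValueError(
            f"DE tables cover different gene universes; symmetric difference "
            f"(up to 20 shown): {diff[:20]}"
        )
    t_hp1 = de_h_p1.set_index("gene_id")
    t_hp2 = de_h_p2.reindex(
        columns=de_h_p2.columns
    ).set_index("gene_id").reindex(t_hp1.index)
    t_p21 = de_p2_p1.set_index("gene_id").reindex(t_hp1.index)

    a = _signs(t_hp1.reset_index())
    b = _signs(t_hp2.reset_index())
    c = _signs(t_p21.reset_index())
    in_universe = (a != 0) | (b != 0) | (c != 0)

    p1_group, p2_group, hyb_group = design.analysis_groups(hybrid_group)
    if factors is None:
        factors = size_factors(counts)
    normalized = normalize_counts(counts, factors).values.reindex(t_hp1.index)

    mean_p1 = normalized[design.samples_in_group(p1_group)].mean(axis=1).to_numpy()
    mean_p2 = normalized[design.samples_in_group(p2_group)].mean(axis=1).to_numpy()
    hybrid = normalized[design.samples_in_group(hyb_group)].to_numpy(dtype=float)
    mean_h = hybrid.mean(axis=1)

    mpv = (mean_p1 + mean_p2) / 2.0
    mpv_p, deviates = _vectorized_mpv_test(hybrid, mpv, alpha)
    lo = np.minimum(mean_p1, mean_p2)
    hi = np.maximum(mean_p1, mean_p2)
    between = (mean_h >= lo) & (mean_h <= hi)

    lfc_hp1 = t_hp1["log2fc"].to_numpy()
    lfc_hp2 = t_hp2["log2fc"].to_numpy()
    lfc_p21 = t_p21["log2fc"].to_numpy()
    conserved = (np.abs(lfc_hp1) < conserved_threshold) & (
        np.abs(lfc_hp2) < conserved_threshold
    )

    rows = []
    gene_ids = list(t_hp1.index)
    for i in np.flatnonzero(in_universe):
        label = classify_gene(
            ComparisonTriple(a=int(a[i]), b=int(b[i]), c=int(c[i])),
            mpv_deviates=bool(deviates[i]),
            conserved=bool(conserved[i]),
            hybrid_between=bool(between[i]),
        )
        rows.append(
            {
                "gene_id": gene_ids[i],
                "class_label": label,
                "additivity": additivity_of(label),
                "mpv": mpv[i],
                "mpv_p": mpv_p[i],
                "lfc_h_p1": lfc_hp1[i],
                "lfc_h_p2": lfc_hp2[i],
                "lfc_p2_p1": lfc_p21[i],
            }
        )
    columns = [
        "gene_id", "class_label", "additivity",
        "mpv", "mpv_p", "lfc_h_p1", "lfc_h_p2", "lfc_p2_p1",
    ]
    return pd.DataFrame(rows, columns=columns)


def summarize_patterns(calls: pd.DataFrame) -> dict:
    """Per-class counts plus additive/non-additive percentages.

    Percentages use only additive + non-additive calls as the denominator;
    conserved and ambiguous genes are reported separately. Percentages are
    rounded half-up to one decimal.
    """
    if len(calls) == 0:
        raise ValueError("empty call list")
    per_class = {
        label: int((calls["class_label"] == label).sum()) for label in CLASS_LABELS
    }
    additive = int(calls["additivity"].eq("additive").sum())
    nonadditive = int(calls["additivity"].eq("non-additive").sum())
    classified = additive + nonadditive
    summary = {
        "classified": classified,
        "per_class": per_class,
        "additive_count": additive,
        "nonadditive_count": nonadditive,
        "conserved": per_class["conserved"],
        "ambiguous": per_class["ambiguous"],
    }
    if classified == 0:
        logger.warning("no additive or non-additive calls; percentages undefined")
        summary["additive_pct"] = None
        summary["nonadditive_pct"] = None
    else:
        summary["additive_pct"] = float(
            (Decimal(100 * additive) / Decimal(classified)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        summary["nonadditive_pct"] = float(
            (Decimal(100 * nonadditive) / Decimal(classified)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
    return summary


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(Path(path), sep="\t", index=False)
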