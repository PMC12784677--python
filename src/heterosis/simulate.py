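"""Seeded generators for hybrid-vs-parent count data with planted truth.

The count generator emulates the downstream structure of a reciprocal-cross
liver RNA-seq experiment: two purebred parental groups and two reciprocal
hybrid groups, four biological replicates each, negative-binomial counts at a
target library depth. Each gene is planted with one inheritance mode:

* ``conserved`` — both parents and the hybrid share the baseline mean;
* ``additive`` — parents differ by ``parent_lfc`` log2 units, hybrid at the
  arithmetic mid-parent value;
* ``dominant_p1`` / ``dominant_p2`` — hybrid mean equals the named parent;
* ``overdominant`` / ``underdominant`` — hybrid one log2 unit beyond the
  higher / below the lower parent.

All generators are pure functions of their arguments including ``seed``: the
same call yields bitwise-identical output.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet, GeneSetCollection
from .io import CountMatrix, SampleDesign

MODES = (
    "conserved",
    "additive",
    "dominant_p1",
    "dominant_p2",
    "overdominant",
    "underdominant",
)

#: study-condition defaults: 20% conserved, 20% additive, 30% dominant split
#: evenly between parents, 30% transgressive split evenly over/under
DEFAULT_MODE_PROPORTIONS: dict[str, float] = {
    "conserved": 0.20,
    "additive": 0.20,
    "dominant_p1": 0.15,
    "dominant_p2": 0.15,
    "overdominant": 0.15,
    "underdominant": 0.15,
}

#: log2 offset of over-/under-dominant hybrids beyond the extreme parent
TRANSGRESSIVE_OFFSET = 1.0

__all__ = [
    "MODES",
    "DEFAULT_MODE_PROPORTIONS",
    "simulate_hybrid_counts",
    "simulate_growth_cohort",
    "simulate_gene_sets",
    "default_growth_means",
]


def _mode_assignment(
    n_genes: int, proportions: Mapping[str, float], rng: np.random.Generator
) -> np.ndarray:
    unknown = set(proportions) - set(MODES)
    if unknown:
        raise ValueError(f"unknown mode(s): {sorted(unknown)}")
    total = sum(proportions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"mode proportions must sum to 1, got {total}")
    # largest-remainder apportionment, then a seeded shuffle
    quotas = {m: proportions.get(m, 0.0) * n_genes for m in MODES}
    counts = {m: int(math.floor(q)) for m, q in quotas.items()}
    short = n_genes - sum(counts.values())
    for m in sorted(MODES, key=lambda m: quotas[m] - counts[m], reverse=True)[:short]:
        counts[m] += 1
    modes = np.repeat(
        np.array(list(counts), dtype=object), list(counts.values())
    )
    rng.shuffle(modes)
    return modes


def _hybrid_mean(mode: str, mu_p1: float, mu_p2: float) -> float:
    if mode in ("conserved", "additive"):
        return (mu_p1 + mu_p2) / 2.0
    if mode == "dominant_p1":
        return mu_p1
    if mode == "dominant_p2":
        return mu_p2
    if mode == "overdominant":
        return max(mu_p1, mu_p2) * 2.0**TRANSGRESSIVE_OFFSET
    if mode == "underdominant":
        return min(mu_p1, mu_p2) / 2.0**TRANSGRESSIVE_OFFSET
    raise ValueError(f"unknown mode {mode!r}")


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0.0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # NB as gamma-mixed Poisson; exact for mean 0
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_hybrid_counts(
    n_genes: int,
    reps_per_group: int = 4,
    depth: float = 1e6,
    dispersion: float = 0.05,
    mode_proportions: Mapping[str, float] | None = None,
    parent_lfc: float = 2.0,
    seed: int | None = None,
    n_hybrid_groups: int = 2,
    baseline_log2_mean: float = 6.0,
    baseline_log2_sd: float = 1.5,
) -> tuple[CountMatrix, SampleDesign, pd.DataFrame]:
    """Simulate NB counts for parents and hybrid(s) with planted modes.

    Returns ``(counts, design, truth)`` where ``truth`` has columns
    ``gene_id, mode, parent_log2fc, hybrid_log2_offset`` (the offset is
    log2(hybrid mean / mid-parent value)). Groups are ``P1``, ``P2`` and
    ``H1`` .. ``H{n_hybrid_groups}`` with ``reps_per_group`` replicates each;
    reciprocal hybrids share the planted truth and differ only in sampling
    noise. Baseline expression is log-normal on the log2 scale; every library
    is scaled to the target ``depth`` (``truth.attrs["group_scale"]`` records
    the planted-mean-to-raw-count factor per group).
    """
    if seed is None:
        raise ValueError("seed is required")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if n_genes < 1 or reps_per_group < 1 or n_hybrid_groups < 1:
        raise ValueError("n_genes, reps_per_group, n_hybrid_groups must be >= 1")
    proportions = dict(
        DEFAULT_MODE_PROPORTIONS if mode_proportions is None else mode_proportions
    )
    rng = np.random.default_rng(seed)

    modes = _mode_assignment(n_genes, proportions, rng)
    baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_genes)

    mu_p1 = baseline.copy()
    mu_p2 = np.where(
        modes == "conserved", baseline, baseline * 2.0 ** (signs * parent_lfc)
    )
    mu_h = np.array(
        [_hybrid_mean(m, p1, p2) for m, p1, p2 in zip(modes, mu_p1, mu_p2)]
    )

    group_means = {"P1": mu_p1, "P2": mu_p2}
    roles = {"P1": "parent1", "P2": "parent2"}
    for h in range(1, n_hybrid_groups + 1):
        group_means[f"H{h}"] = mu_h
        roles[f"H{h}"] = "hybrid"

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    group_scale: dict[str, float] = {}
    for group, mu in group_means.items():
        group_scale[group] = depth / mu.sum()
        scaled = mu * group_scale[group]
        for rep in range(1, reps_per_group + 1):
            sample = f"{group}_r{rep}"
            columns[sample] = _nb_draw(rng, scaled, dispersion)
            design_rows.append(
                {"sample": sample, "group": group, "role": roles[group]}
            )

    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    counts = CountMatrix(pd.DataFrame(columns, index=gene_ids))
    design = SampleDesign(pd.DataFrame.from_records(design_rows))
    mpv = (mu_p1 + mu_p2) / 2.0
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mode": modes.astype(str),
            "parent_log2fc": np.where(
                modes == "conserved", 0.0, signs * parent_lfc
            ),
            "hybrid_log2_offset": np.log2(mu_h / mpv),
        }
    )
    # per-group factor mapping planted means to expected raw counts
    truth.attrs["group_scale"] = group_scale
    truth.attrs["depth"] = depth
    return counts, design, truth


def default_growth_means() -> dict[str, dict[int, tuple[float, float]]]:
    """Stylized (length mm, weight g) trajectories at 30/60/90 days.

    Emulates the reported ranking of a reciprocal-cross grow-out: both
    hybrids outgrow both purebreds, with one purebred clearly slowest.
    """
    return {
        "TJ": {30: (45.0, 0.8), 60: (65.0, 2.2), 90: (82.0, 4.5)},
        "LC": {30: (55.0, 1.4), 60: (88.0, 5.0), 90: (120.0, 11.5)},
        "LT": {30: (60.0, 1.7), 60: (95.0, 6.0), 90: (130.0, 14.5)},
        "TL": {30: (58.0, 1.6), 60: (92.0, 5.6), 90: (126.0, 13.5)},
    }


def simulate_growth_cohort(
    group_means: Mapping[str, Mapping[int, tuple[float, float]]] | None = None,
    n_fish: int = 30,
    cv: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-fish growth records with log-normal individual noise.

    ``group_means`` maps group -> timepoint (days) -> (length mm, weight g);
    defaults to :func:`default_growth_means`. ``cv`` is the coefficient of
    variation of the multiplicative noise; ``cv = 0`` reproduces the group
    means exactly. Returns a DataFrame with columns
    ``fish_id, group, timepoint_days, length_mm, weight_g``.
    """
    if seed is None:
        raise ValueError("seed is required")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    if group_means is None:
        group_means = default_growth_means()
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    rows = []
    for group, trajectory in group_means.items():
        for timepoint in sorted(trajectory):
            length_mean, weight_mean = trajectory[timepoint]
            if length_mean <= 0 or weight_mean <= 0:
                raise ValueError("trajectory means must be strictly positive")
            for i in range(1, n_fish + 1):
                noise_l, noise_w = (
                    (1.0, 1.0)
                    if sigma == 0.0
                    else np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=2))
                )
                rows.append(
                    {
                        "fish_id": f"{group}_t{timepoint}_f{i:03d}",
                        "group": group,
                        "timepoint_days": timepoint,
                        "length_mm": length_mean * noise_l,
                        "weight_g": weight_mean * noise_w,
                    }
                )
    return pd.DataFrame(rows)


def simulate_gene_sets(
    universe: Sequence[str],
    query: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 100),
    planted_term_size: int = 60,
    planted_overlap: int = 40,
    seed: int | None = None,
) -> tuple[GeneSetCollection, str]:
    """Random gene-set collection plus one term engineered to overlap the query.

    The planted term draws ``planted_overlap`` genes from ``query`` and the
    rest from the remaining universe. Returns ``(collection, planted_term_id)``.
    """
    if seed is None:
        raise ValueError("seed is required")
    universe = list(dict.fromkeys(universe))
    query = list(dict.fromkeys(query))
    if not set(query) <= set(universe):
        raise ValueError("query must be a subset of the universe")
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("term sizes must satisfy 1 <= lo <= hi <= |universe|")
    if planted_term_size > len(universe):
        raise ValueError("planted term larger than universe")
    if planted_overlap > planted_term_size:
        raise ValueError("planted overlap exceeds planted term size")
    if planted_overlap > len(query):
        raise ValueError("planted overlap exceeds query size")
    rng = np.random.default_rng(seed)
    sets: dict[str, GeneSet] = {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"T{i:04d}"] = GeneSet(
            name=f"random term {i}", genes=frozenset(members.tolist())
        )
    in_query = rng.choice(query, size=planted_overlap, replace=False).tolist()
    outside_pool = [g for g in universe if g not in set(query)]
    n_outside = planted_term_size - planted_overlap
    if n_outside > len(outside_pool):
        raise ValueError("not enough non-query genes for the planted term")
    outside = rng.choice(outside_pool, size=n_outside, replace=False).tolist()
    planted_id = f"T{n_terms + 1:04d}"
    sets[planted_id] = GeneSet(
        name="planted enriched term", genes=frozenset(in_query + outside)
    )
    return GeneSetCollection(sets), planted_id
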