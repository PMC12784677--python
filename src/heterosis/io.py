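"""Count-matrix, sample-design and gene-length I/O plus normalization.

The on-disk dialects are deliberately plain:

* count matrix — tab-separated, UTF-8, header ``gene_id\\t<sample...>``,
  ``#``-prefixed comment lines skipped, integer cells;
* sample design — CSV with header ``sample,group,role`` where role is one of
  ``parent1``, ``parent2``, ``hybrid``;
* gene lengths — tab-separated ``gene_id\\tlength_bp``.

Gene and sample order are file order; nothing is silently sorted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ROLES = ("parent1", "parent2", "hybrid")

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "read_sample_design",
    "write_sample_design",
    "read_gene_lengths",
    "write_gene_lengths",
    "size_factors",
    "normalize_counts",
    "to_expression_units",
]


@dataclass(frozen=True)
class CountMatrix:
    """Integer gene x sample expression counts.

    ``counts`` is a genes-by-samples DataFrame with unique gene identifiers on
    the index and unique sample identifiers on the columns. Counts must be
    non-negative integers; at least one gene and two samples are required.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValueError(
                f"count matrix needs >=1 gene and >=2 samples, got shape {df.shape}"
            )
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0, rtol=0):
                raise ValueError("counts must be integral")
            object.__setattr__(self, "counts", df.astype(np.int64))
            values = self.counts.to_numpy()
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count {values[g, s]} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(samples)])


@dataclass(frozen=True)
class SampleDesign:
    """Maps samples to groups and groups to roles (parent1/parent2/hybrid).

    Multiple groups may share the ``hybrid`` role (reciprocal crosses); an
    analysis that needs one hybrid group must designate it via
    :meth:`analysis_groups`.
    """

    table: pd.DataFrame  # columns: sample, group, role

    def __post_init__(self) -> None:
        df = self.table
        missing = {"sample", "group", "role"} - set(df.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if df["sample"].duplicated().any():
            dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample in design: {dup!r}")
        bad = sorted(set(df["role"]) - set(VALID_ROLES))
        if bad:
            raise ValueError(
                f"invalid role(s) {bad}; must be one of {list(VALID_ROLES)}"
            )
        roles_per_group = df.groupby("group", sort=False)["role"].nunique()
        if (roles_per_group > 1).any():
            g = roles_per_group.index[roles_per_group > 1][0]
            raise ValueError(f"group {g!r} is assigned more than one role")

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def role_of(self, group: str) -> str:
        rows = self.table.loc[self.table["group"] == group, "role"]
        if rows.empty:
            raise KeyError(f"group {group!r} not in design")
        return rows.iloc[0]

    def samples_in_group(self, group: str) -> list[str]:
        out = list(self.table.loc[self.table["group"] == group, "sample"])
        if not out:
            raise KeyError(f"group {group!r} not in design")
        return out

    def replicate_counts(self) -> dict[str, int]:
        return self.table.groupby("group", sort=False)["sample"].count().to_dict()

    def groups_with_role(self, role: str) -> list[str]:
        if role not in VALID_ROLES:
            raise ValueError(f"invalid role {role!r}")
        sub = self.table.loc[self.table["role"] == role, "group"]
        return list(dict.fromkeys(sub))

    def analysis_groups(self, hybrid_group: str | None = None) -> tuple[str, str, str]:
        """Return the (parent1, parent2, hybrid) group triple for one analysis.

        Errors if either parent role is claimed by more than one group, or if
        several hybrid groups exist and none was designated.
        """
        triple = []
        for role in ("parent1", "parent2"):
            cand = self.groups_with_role(role)
            if not cand:
                raise ValueError(f"no group with role {role!r}")
            if len(cand) > 1:
                raise ValueError(
                    f"two groups claiming role {role!r} in one analysis: {cand}"
                )
            triple.append(cand[0])
        hybrids = self.groups_with_role("hybrid")
        if not hybrids:
            raise ValueError("no group with role 'hybrid'")
        if hybrid_group is None:
            if len(hybrids) > 1:
                raise ValueError(
                    f"multiple hybrid groups {hybrids}; designate one explicitly"
                )
            hybrid_group = hybrids[0]
        elif hybrid_group not in hybrids:
            raise ValueError(f"{hybrid_group!r} is not a hybrid group ({hybrids})")
        triple.append(hybrid_group)
        return tuple(triple)  # type: ignore[return-value]

    def validate_matrix(self, matrix: CountMatrix) -> None:
        """Every sample in the matrix must be covered by the design."""
        missing = [s for s in matrix.sample_ids if s not in set(self.samples)]
        if missing:
            raise ValueError(f"samples in matrix but absent from design: {missing}")
        extra = [s for s in self.samples if s not in set(matrix.sample_ids)]
        if extra:
            logger.warning("design samples absent from matrix (ignored): %s", extra)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Real-valued expression matrix in a declared unit.

    ``unit`` is one of ``normalized-count``, ``FPKM``, ``TPM``. TPM columns
    sum to 1e6 (checked at construction within 1e-6 relative tolerance).
    """

    values: pd.DataFrame
    unit: str

    _UNITS = ("normalized-count", "FPKM", "TPM")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValueError(f"unit must be one of {self._UNITS}, got {self.unit!r}")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit == "TPM":
            sums = arr.sum(axis=0)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValueError("TPM columns must each sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-separated count matrix (header ``gene_id\\t<sample...>``).

    Raises ``ValueError`` naming the offending gene for duplicate identifiers,
    giving (row, column) coordinates for negative or non-integer cells, and
    flagging ragged rows.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [
            row
            for row in csv.reader(fh, delimiter="\t")
            if row and not row[0].startswith("#")
        ]
    if not rows:
        raise ValueError(f"{path}: empty count matrix file")
    header = rows[0]
    sample_ids = header[1:]
    if len(sample_ids) < 2:
        raise ValueError(f"{path}: need at least 2 sample columns")
    gene_ids: list[str] = []
    seen: set[str] = set()
    data = np.empty((len(rows) - 1, len(sample_ids)), dtype=np.int64)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}: ragged row at line {i} "
                f"({len(row)} fields, expected {len(header)})"
            )
        gid = row[0]
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene identifier {gid!r} at line {i}")
        seen.add(gid)
        gene_ids.append(gid)
        for j, cell in enumerate(row[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at line {i}, "
                    f"column {sample_ids[j]!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"{path}: negative count {value} at line {i}, "
                    f"column {sample_ids[j]!r}"
                )
            data[i - 2, j] = value
    return CountMatrix(pd.DataFrame(data, index=gene_ids, columns=sample_ids))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", *matrix.sample_ids])
        for gid, row in zip(matrix.gene_ids, matrix.counts.to_numpy()):
            writer.writerow([gid, *row.tolist()])


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read a CSV sample sheet with columns ``sample,group,role``."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"sample", "group", "role"} <= set(
            reader.fieldnames
        ):
            raise ValueError(
                f"{path}: header must contain sample,group,role "
                f"(got {reader.fieldnames})"
            )
        records = [
            {"sample": r["sample"], "group": r["group"], "role": r["role"]}
            for r in reader
        ]
    if not records:
        raise ValueError(f"{path}: empty design file")
    return SampleDesign(pd.DataFrame.from_records(records))


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table[["sample", "group", "role"]].to_csv(Path(path), index=False)


def read_gene_lengths(path: str | Path) -> pd.Series:
    """Read tab-separated ``gene_id\\tlength_bp``; lengths must be > 0."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=0, names=["gene_id", "length_bp"]
    )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    lengths = pd.Series(
        df["length_bp"].to_numpy(dtype=float), index=df["gene_id"], name="length_bp"
    )
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"{path}: non-positive length for gene {bad!r}")
    return lengths


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").rename_axis("gene_id").to_csv(Path(path), sep="\t")


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios library-size factors, geometric mean 1.

    Genes with a zero count in any sample are excluded from the geometric-mean
    reference. If no gene is expressed in every sample, falls back to
    total-count scaling (factors proportional to column sums) with a warning.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if all_nonzero.any():
        ref = counts[all_nonzero]
        log_geomean = np.log(ref).mean(axis=1, keepdims=True)
        ratios = np.log(ref) - log_geomean
        factors = np.exp(np.median(ratios, axis=0))
    else:
        logger.warning(
            "no gene expressed in all samples; falling back to total-count scaling"
        )
        colsums = counts.sum(axis=0)
        if (colsums == 0).any():
            bad = matrix.sample_ids[int(np.argmax(colsums == 0))]
            raise ValueError(f"sample {bad!r} has zero total counts")
        factors = colsums
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def normalize_counts(
    matrix: CountMatrix, factors: pd.Series | None = None
) -> ExpressionMatrix:
    """Divide each column by its size factor; unit becomes ``normalized-count``."""
    if factors is None:
        factors = size_factors(matrix)
    factors = factors.reindex(matrix.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    values = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids),
        unit="normalized-count",
    )


def to_expression_units(
    matrix: CountMatrix,
    lengths: pd.Series | Mapping[str, float],
    unit: str,
) -> ExpressionMatrix:
    """Convert raw counts to FPKM or TPM given gene lengths in bp.

    FPKM_gs = counts_gs * 1e9 / (length_g * colsum_s).
    TPM_gs = rate_gs * 1e6 / sum_g rate_gs with rate = counts / length.
    """
    if unit not in ("FPKM", "TPM"):
        raise ValueError(f"unit must be 'FPKM' or 'TPM', got {unit!r}")
    lengths = pd.Series(lengths, dtype=float)
    missing = [g for g in matrix.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing}")
    length = lengths.reindex(matrix.gene_ids).to_numpy()
    if (length <= 0).any():
        bad = matrix.gene_ids[int(np.argmax(length <= 0))]
        raise ValueError(f"non-positive length for gene {bad!r}")
    counts = matrix.counts.to_numpy(dtype=float)
    colsums = counts.sum(axis=0)
    if (colsums == 0).any():
        bad = matrix.sample_ids[int(np.argmax(colsums == 0))]
        raise ValueError(f"sample {bad!r} has zero total counts")
    if unit == "FPKM":
        values = counts * 1e9 / (length[:, None] * colsums[None, :])
    else:
        rate = counts / length[:, None]
        values = rate * 1e6 / rate.sum(axis=0, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.sample_ids),
        unit=unit,
    )
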