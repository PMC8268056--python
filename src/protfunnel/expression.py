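"""Expression-matrix I/O and the pipeline's canonical in-memory dataset.

One study = one gene-by-sample abundance matrix plus per-sample metadata
and a platform tag. The canonical internal scale is linear: fold changes
("1.5 times higher in tumor") are only meaningful on linear scale, so
log2-served array data is converted on ingest via ``scale_declared``.
Missing values are rejected rather than imputed — the downstream cascade
is threshold set-logic with no principled missing-data semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sample group labels recognized in metadata files.
SAMPLE_GROUPS = frozenset(
    {"cell_line", "tumor", "adjacent_normal", "leukocyte", "organ"}
)


class ExpressionError(ValueError):
    """Raised for malformed expression matrices or metadata."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample column.

    ``subject_label`` carries the cell-line name, organ name or patient id;
    ``paired_with`` links a tumor sample to its adjacent-normal (or vice
    versa) from the same resection.
    """

    sample_id: str
    group: str
    subject_label: str = ""
    paired_with: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in SAMPLE_GROUPS:
            raise ExpressionError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"expected one of {sorted(SAMPLE_GROUPS)}"
            )


@dataclass(frozen=True)
class ExpressionDataset:
    """One study's gene-by-sample abundance matrix, linear scale.

    ``matrix`` is a pandas DataFrame indexed by unique uppercased gene
    symbols with one column per sample, all values finite and >= 0.
    """

    dataset_id: str
    platform_id: str
    matrix: pd.DataFrame
    samples: tuple[SampleMeta, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ExpressionError(f"{self.dataset_id}: duplicate sample ids")
        if list(self.matrix.columns) != ids:
            raise ExpressionError(
                f"{self.dataset_id}: matrix columns do not match sample metadata"
            )
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ExpressionError(
                f"{self.dataset_id}: duplicate gene symbols {list(dupes)[:5]}"
            )
        values = self.matrix.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            gi, si = np.argwhere(~np.isfinite(values))[0]
            raise ExpressionError(
                f"{self.dataset_id}: non-finite value at gene "
                f"{self.matrix.index[gi]!r}, sample {self.matrix.columns[si]!r}"
            )
        if (values < 0).any():
            gi, si = np.argwhere(values < 0)[0]
            raise ExpressionError(
                f"{self.dataset_id}: negative abundance at gene "
                f"{self.matrix.index[gi]!r}, sample {self.matrix.columns[si]!r}"
            )
        by_id = {s.sample_id: s for s in self.samples}
        complementary = {"tumor": "adjacent_normal", "adjacent_normal": "tumor"}
        for s in self.samples:
            if s.paired_with is None:
                continue
            partner = by_id.get(s.paired_with)
            if partner is None:
                raise ExpressionError(
                    f"{self.dataset_id}: sample {s.sample_id} paired with unknown "
                    f"sample {s.paired_with!r}"
                )
            if partner.group != complementary.get(s.group):
                raise ExpressionError(
                    f"{self.dataset_id}: pairing {s.sample_id} ({s.group}) <-> "
                    f"{partner.sample_id} ({partner.group}) is not tumor/adjacent_normal"
                )

    @property
    def gene_index(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def sample_ids_in_groups(self, groups: Iterable[str]) -> list[str]:
        wanted = set(groups)
        return [s.sample_id for s in self.samples if s.group in wanted]

    def groups_present(self) -> set[str]:
        return {s.group for s in self.samples}


def collapse_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated gene-symbol rows to one row per symbol.

    Keeps, per symbol, the row with the highest mean across samples
    (max-mean rule, a common microarray probe-collapse convention); ties
    break deterministically to the first occurrence in file order.
    """
    if not matrix.index.duplicated().any():
        return matrix
    means = matrix.mean(axis=1).to_numpy()
    keep_pos: dict[str, int] = {}
    for pos, symbol in enumerate(matrix.index):
        best = keep_pos.get(symbol)
        if best is None or means[pos] > means[best]:
            keep_pos[symbol] = pos
    return matrix.iloc[sorted(keep_pos.values())]


def read_expression_table(
    matrix_path: str | Path,
    meta_path: str | Path,
    *,
    dataset_id: str | None = None,
    platform_id: str = "unknown",
    scale_declared: str = "linear",
) -> ExpressionDataset:
    """Read a TSV matrix/metadata pair into a validated linear-scale dataset.

    Matrix: header ``gene_symbol<TAB><sample ids...>``, one gene per row.
    Metadata: TSV with header ``sample_id, group, subject_label,
    paired_with`` (the last two optional). ``scale_declared`` is ``linear``
    or ``log2``; log2 values are transformed by ``2**x`` before storage.
    Duplicate gene rows are collapsed by :func:`collapse_probes`.
    """
    matrix_path = Path(matrix_path)
    meta_path = Path(meta_path)
    if scale_declared not in ("linear", "log2"):
        raise ExpressionError(
            f"scale_declared must be 'linear' or 'log2', got {scale_declared!r}"
        )
    matrix = pd.read_csv(
        matrix_path, sep="\t", index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    matrix.index = matrix.index.astype(str).str.upper()
    matrix.index.name = "gene_symbol"
    matrix.columns = matrix.columns.astype(str)
    try:
        matrix = matrix.astype(float)
    except ValueError as exc:
        raise ExpressionError(f"{matrix_path}: non-numeric cell ({exc})") from exc
    if matrix.isna().any().any():
        gene = matrix.index[matrix.isna().any(axis=1)][0]
        sample = matrix.columns[matrix.isna().any(axis=0)][0]
        raise ExpressionError(
            f"{matrix_path}: missing value at gene {gene!r}, sample {sample!r}"
        )
    if scale_declared == "log2":
        matrix = np.exp2(matrix)
    elif (matrix.to_numpy() < 0).any():
        raise ExpressionError(
            f"{matrix_path}: negative values in a linear-scale matrix"
        )
    matrix = collapse_probes(matrix)

    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "group"}
    if not required <= set(meta.columns):
        raise ExpressionError(
            f"{meta_path}: metadata must have columns sample_id and group"
        )
    samples = tuple(
        SampleMeta(
            sample_id=row["sample_id"],
            group=row["group"],
            subject_label=row.get("subject_label", ""),
            paired_with=row.get("paired_with") or None,
        )
        for _, row in meta.iterrows()
    )
    meta_ids = [s.sample_id for s in samples]
    missing = sorted(set(meta_ids) - set(matrix.columns))
    extra = sorted(set(matrix.columns) - set(meta_ids))
    if missing or extra:
        raise ExpressionError(
            f"sample id mismatch between {matrix_path.name} and {meta_path.name}: "
            f"metadata-only={missing}, matrix-only={extra}"
        )
    matrix = matrix.loc[:, meta_ids]
    return ExpressionDataset(
        dataset_id=dataset_id or matrix_path.stem,
        platform_id=platform_id,
        matrix=matrix,
        samples=samples,
    )


def write_expression_table(
    dataset: ExpressionDataset, matrix_path: str | Path, meta_path: str | Path
) -> None:
    """Write the canonical TSV matrix/metadata pair (linear scale).

    Uses repr-roundtrip float formatting so read -> write -> read is
    bit-identical for linear tables.
    """
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    with matrix_path.open("w", encoding="utf-8") as fh:
        fh.write("gene_symbol\t" + "\t".join(dataset.sample_ids) + "\n")
        values = dataset.matrix.to_numpy(dtype=float)
        for gene, row in zip(dataset.gene_index, values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with meta_path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\tsubject_label\tpaired_with\n")
        for s in dataset.samples:
            fh.write(
                f"{s.sample_id}\t{s.group}\t{s.subject_label}\t{s.paired_with or ''}\n"
            )


def subset_genes(
    dataset: ExpressionDataset, symbols: Sequence[str]
) -> tuple[ExpressionDataset, set[str]]:
    """Restrict a dataset to the requested genes, in request order.

    Returns the subset dataset and the set of requested-but-absent symbols.
    Raises :class:`ExpressionError` when no requested gene is present.
    """
    if not symbols:
        raise ExpressionError("subset_genes: empty symbol request")
    wanted = [s.upper() for s in symbols]
    present = [s for s in wanted if s in dataset.matrix.index]
    absent = set(wanted) - set(present)
    if not present:
        raise ExpressionError(
            f"{dataset.dataset_id}: none of the {len(wanted)} requested genes present"
        )
    if absent:
        logger.info(
            "%s: %d requested genes absent: %s",
            dataset.dataset_id,
            len(absent),
            sorted(absent)[:10],
        )
    sub = replace(dataset, matrix=dataset.matrix.loc[present])
    return sub, absent
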