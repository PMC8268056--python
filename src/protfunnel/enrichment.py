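"""Panel statistics, overexpression calls, consensus rules and fold changes.

The cascade's statistics are deliberately simple threshold set-logic, not
differential-expression modeling. The baseline for every "above-average"
call is the panel average: the mean expression of ALL panel proteases over
the samples of one dataset. A gene is called overexpressed when it exceeds
that panel mean — strictly, so a gene exactly at the mean is never called.
All quantities are computed on linear abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .catalog import ProteaseCatalog
from .expression import ExpressionDataset


class EnrichmentError(ValueError):
    """Raised for invalid enrichment computations (empty selections, zeros)."""


@dataclass(frozen=True)
class PanelStats:
    """Panel mean/SD of one dataset: the baseline for overexpression calls.

    ``panel_mean`` and ``panel_sd`` are taken over all (panel gene, sample)
    values; the SD uses the n-1 (sample) denominator. ``n_values`` is the
    number of values pooled.
    """

    dataset_id: str
    panel_mean: float
    panel_sd: float
    n_values: int


@dataclass(frozen=True)
class CallSet:
    """Genes called by one rule in one dataset, with provenance."""

    dataset_id: str
    rule: str
    genes: frozenset[str] = field(default_factory=frozenset)


def _panel_values(
    dataset: ExpressionDataset,
    panel: ProteaseCatalog,
    sample_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Pool all (panel gene, sample) values; genes × selected samples."""
    genes = [g for g in dataset.gene_index if g in panel.entries]
    if len(genes) < 2:
        raise EnrichmentError(
            f"{dataset.dataset_id}: need >=2 panel genes present, found {len(genes)}"
        )
    cols = list(sample_ids) if sample_ids is not None else dataset.sample_ids
    if not cols:
        raise EnrichmentError(f"{dataset.dataset_id}: empty sample selection")
    return dataset.matrix.loc[genes, cols].to_numpy(dtype=float)


def panel_stats(
    dataset: ExpressionDataset,
    panel: ProteaseCatalog,
    sample_ids: Optional[Sequence[str]] = None,
) -> PanelStats:
    """Mean and SD of all panel-protease values in (a sample subset of) a dataset."""
    values = _panel_values(dataset, panel, sample_ids)
    flat = values.ravel()
    return PanelStats(
        dataset_id=dataset.dataset_id,
        panel_mean=float(np.mean(flat)),
        panel_sd=float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0,
        n_values=int(flat.size),
    )


def high_expression_cutoff(stats: PanelStats, k: float = 1.5) -> float:
    """High-expression threshold: panel mean + k x panel SD (default k = 1.5)."""
    if k < 0:
        raise EnrichmentError(f"sd multiplier must be >= 0, got {k}")
    return stats.panel_mean + k * stats.panel_sd


def call_above_average_all_samples(
    dataset: ExpressionDataset, panel: ProteaseCatalog
) -> CallSet:
    """Call genes strictly above the panel mean in EVERY sample.

    The strictest reading of "above-average expression in every cell line":
    a dataset with replicate samples of one line requires all replicates to
    clear the panel mean.
    """
    values = _panel_values(dataset, panel)
    genes = [g for g in dataset.gene_index if g in panel.entries]
    mean = float(np.mean(values))
    called = frozenset(
        g for g, row in zip(genes, values) if bool(np.all(row > mean))
    )
    return CallSet(
        dataset_id=dataset.dataset_id,
        rule="above_average_all_samples",
        genes=called,
    )


def call_above_average_dataset_mean(
    dataset: ExpressionDataset,
    panel: ProteaseCatalog,
    groups_used: Iterable[str] = ("tumor",),
) -> CallSet:
    """Call genes whose mean over selected samples exceeds the panel mean.

    The per-dataset-summary reading used for patient cohorts: the call
    compares the gene's mean abundance over the selected samples (default:
    tumor samples only, so adjacent normals do not dilute the panel mean)
    with the panel mean computed over the same selection.
    """
    cols = dataset.sample_ids_in_groups(groups_used)
    if not cols:
        raise EnrichmentError(
            f"{dataset.dataset_id}: no samples in groups {sorted(set(groups_used))}"
        )
    values = _panel_values(dataset, panel, cols)
    genes = [g for g in dataset.gene_index if g in panel.entries]
    mean = float(np.mean(values))
    called = frozenset(
        g for g, row in zip(genes, values) if float(np.mean(row)) > mean
    )
    return CallSet(
        dataset_id=dataset.dataset_id,
        rule="above_average_dataset_mean",
        genes=called,
    )


def venn_regions(callsets: Sequence[CallSet]) -> dict[str, int]:
    """Cardinality of every Venn region over the callsets' gene sets.

    Keys are membership bitmasks like ``"101"`` (in set 1 and 3, not 2),
    in callset order; only regions over the union are counted, so the
    region counts sum to the size of the union.
    """
    union = set().union(*(cs.genes for cs in callsets))
    regions: dict[str, int] = {}
    for gene in union:
        key = "".join("1" if gene in cs.genes else "0" for cs in callsets)
        regions[key] = regions.get(key, 0) + 1
    return dict(sorted(regions.items()))


def consensus_intersection(
    callsets: Sequence[CallSet],
) -> tuple[set[str], dict[str, int]]:
    """Genes called in every dataset, plus all Venn region cardinalities."""
    if len(callsets) < 2:
        raise EnrichmentError("consensus_intersection needs >=2 callsets")
    shared = set(callsets[0].genes)
    for cs in callsets[1:]:
        shared &= cs.genes
    return shared, venn_regions(callsets)


def consensus_k_of_n(callsets: Sequence[CallSet], k: int) -> set[str]:
    """Genes called in at least k of the n callsets (e.g. 5 of 6 cohorts)."""
    n = len(callsets)
    if not 1 <= k <= n:
        raise EnrichmentError(f"k must satisfy 1 <= k <= {n}, got {k}")
    counts: dict[str, int] = {}
    for cs in callsets:
        for gene in cs.genes:
            counts[gene] = counts.get(gene, 0) + 1
    return {gene for gene, c in counts.items() if c >= k}


def fold_change_tumor_vs_normal(dataset: ExpressionDataset, gene: str) -> float:
    """Linear fold change: mean tumor abundance over mean adjacent-normal."""
    gene = gene.upper()
    if gene not in dataset.matrix.index:
        raise EnrichmentError(f"{dataset.dataset_id}: gene {gene!r} not present")
    tumor = dataset.sample_ids_in_groups(["tumor"])
    normal = dataset.sample_ids_in_groups(["adjacent_normal"])
    if not tumor or not normal:
        raise EnrichmentError(
            f"{dataset.dataset_id}: needs >=1 tumor and >=1 adjacent_normal sample"
        )
    t = float(dataset.matrix.loc[gene, tumor].mean())
    n = float(dataset.matrix.loc[gene, normal].mean())
    if n <= 0:
        raise EnrichmentError(
            f"{dataset.dataset_id}: zero mean normal abundance for {gene}"
        )
    return t / n


def aggregate_fold_change(
    per_dataset_fc: Sequence[float], method: str = "arithmetic"
) -> float:
    """Average per-dataset fold changes (arithmetic default, geometric optional)."""
    if len(per_dataset_fc) == 0:
        raise EnrichmentError("aggregate_fold_change: empty list")
    fc = np.asarray(per_dataset_fc, dtype=float)
    if (fc <= 0).any():
        raise EnrichmentError("fold changes must be positive")
    if method == "arithmetic":
        return float(np.mean(fc))
    if method == "geometric":
        return float(np.exp(np.mean(np.log(fc))))
    raise EnrichmentError(f"unknown aggregation method {method!r}")


def relative_to_reference_tissue(
    target: ExpressionDataset,
    reference: ExpressionDataset,
    gene: str,
    normalizer_gene: Optional[str] = None,
    *,
    target_groups: Optional[Iterable[str]] = None,
    reference_groups: Optional[Iterable[str]] = None,
) -> float:
    """Ratio of a gene's mean abundance in a target vs a reference tissue.

    With ``normalizer_gene`` set (a housekeeping symbol, typically ACTB),
    each side is first divided by that dataset's mean normalizer abundance,
    which cancels per-platform scale factors and makes cross-platform
    comparisons meaningful. Within-platform comparisons pass no normalizer;
    ``target`` and ``reference`` may then be the same dataset with
    different group selections (e.g. leukocyte vs tumor columns).
    """
    gene = gene.upper()

    def _mean(ds: ExpressionDataset, sym: str, groups: Optional[Iterable[str]]) -> float:
        if sym not in ds.matrix.index:
            raise EnrichmentError(f"{ds.dataset_id}: gene {sym!r} not present")
        cols = ds.sample_ids_in_groups(groups) if groups is not None else ds.sample_ids
        if not cols:
            raise EnrichmentError(
                f"{ds.dataset_id}: no samples in groups {sorted(set(groups))}"
            )
        return float(ds.matrix.loc[sym, cols].mean())

    t = _mean(target, gene, target_groups)
    r = _mean(reference, gene, reference_groups)
    if normalizer_gene is not None:
        norm = normalizer_gene.upper()
        tn = _mean(target, norm, target_groups)
        rn = _mean(reference, norm, reference_groups)
        if tn <= 0 or rn <= 0:
            raise EnrichmentError(
                f"normalizer {norm} has non-positive mean in "
                f"{target.dataset_id if tn <= 0 else reference.dataset_id}"
            )
        t, r = t / tn, r / rn
    if r <= 0:
        raise EnrichmentError(
            f"{reference.dataset_id}: zero reference mean for {gene}"
        )
    return t / r
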