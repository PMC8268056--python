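"""The prioritization funnel: six ordered filters from catalog to candidates.

Stage order is fixed: localization -> cell-line consensus -> patient
k-of-n consensus -> tumor/normal fold change -> leukocyte screen -> organ
screen. Every stage consumes the previous stage's survivor set, so
survivor counts are non-increasing; the report records every stage even
when nothing is eliminated. The final output is a ranking by descending
mean fold change (ties alphabetical), not a single winner — picking one
candidate is a reporting concern.

The leukocyte screen is a within-platform comparison: each leukocyte
dataset must carry tumor-group reference samples on its own platform, and
the candidate's leukocyte/tumor abundance ratio must fall below the
low-ratio threshold in every leukocyte dataset. The organ screen crosses
platforms, so both sides are first normalized to a housekeeping gene
(beta-actin by default); the candidate must be low in every organ.
A gene absent from any required dataset cannot be verified low (or high)
there and fails the stage; the absence is logged.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .catalog import (
    CONTROLLED_VOCABULARY,
    DEFAULT_SURFACE_TERMS,
    ProteaseCatalog,
    filter_by_localization,
)
from .enrichment import (
    CallSet,
    EnrichmentError,
    aggregate_fold_change,
    call_above_average_all_samples,
    call_above_average_dataset_mean,
    consensus_intersection,
    consensus_k_of_n,
    fold_change_tumor_vs_normal,
    relative_to_reference_tissue,
)
from .expression import ExpressionDataset

logger = logging.getLogger(__name__)

STAGE_NAMES = (
    "localization",
    "cell_line_consensus",
    "patient_k_of_n",
    "fold_change",
    "leukocyte_screen",
    "organ_screen",
)


class FunnelError(ValueError):
    """Raised when a funnel stage cannot run on the supplied inputs."""


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and dataset roles for one funnel run.

    Defaults mirror the published cascade: keep proteases with any
    surface-accessible localization term; require above-average expression
    in every cell-line sample of every cell-line dataset; above-average
    mean expression in at least 5 of 6 patient cohorts; mean tumor/normal
    fold change of at least 1.5; and a leukocyte/tumor and organ/tumor
    abundance ratio below ``low_ratio_threshold`` (a documented choice —
    no printed threshold exists for "low") in every leukocyte dataset and
    every organ.
    """

    cell_line_dataset_ids: tuple[str, ...] = ()
    patient_dataset_ids: tuple[str, ...] = ()
    paired_patient_dataset_ids: tuple[str, ...] = ()
    leukocyte_dataset_ids: tuple[str, ...] = ()
    organ_dataset_id: str = ""
    organ_reference_dataset_id: str = ""
    allowed_localizations: frozenset[str] = DEFAULT_SURFACE_TERMS
    k_of_n: int = 5
    fc_cutoff: float = 1.5
    sd_multiplier: float = 1.5
    low_ratio_threshold: float = 0.5
    normalizer_gene: str = "ACTB"
    fc_aggregation: str = "arithmetic"
    patient_call_rule: str = "dataset_mean"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cell_line_dataset_ids", tuple(self.cell_line_dataset_ids)
        )
        object.__setattr__(
            self, "patient_dataset_ids", tuple(self.patient_dataset_ids)
        )
        object.__setattr__(
            self,
            "paired_patient_dataset_ids",
            tuple(self.paired_patient_dataset_ids),
        )
        object.__setattr__(
            self, "leukocyte_dataset_ids", tuple(self.leukocyte_dataset_ids)
        )
        object.__setattr__(
            self, "allowed_localizations", frozenset(self.allowed_localizations)
        )
        if self.patient_dataset_ids and not (
            1 <= self.k_of_n <= len(self.patient_dataset_ids)
        ):
            raise FunnelError(
                f"k_of_n={self.k_of_n} out of range for "
                f"{len(self.patient_dataset_ids)} patient datasets"
            )
        if self.fc_cutoff < 0 or self.sd_multiplier < 0:
            raise FunnelError("fc_cutoff and sd_multiplier must be >= 0")
        if self.low_ratio_threshold <= 0:
            raise FunnelError("low_ratio_threshold must be > 0")
        unknown = self.allowed_localizations - CONTROLLED_VOCABULARY
        if unknown:
            raise FunnelError(f"unknown localization terms: {sorted(unknown)}")
        if not set(self.paired_patient_dataset_ids) <= set(self.patient_dataset_ids):
            raise FunnelError(
                "paired_patient_dataset_ids must be a subset of patient_dataset_ids"
            )
        roles = [
            set(self.cell_line_dataset_ids),
            set(self.patient_dataset_ids),
            set(self.leukocyte_dataset_ids),
            {self.organ_dataset_id} if self.organ_dataset_id else set(),
        ]
        seen: set[str] = set()
        for role in roles:
            clash = role & seen
            if clash:
                raise FunnelError(f"dataset ids assigned to multiple roles: {sorted(clash)}")
            seen |= role
        if self.patient_call_rule not in ("dataset_mean", "all_samples"):
            raise FunnelError(f"unknown patient_call_rule {self.patient_call_rule!r}")
        if self.fc_aggregation not in ("arithmetic", "geometric"):
            raise FunnelError(f"unknown fc_aggregation {self.fc_aggregation!r}")

    @property
    def organ_reference(self) -> str:
        if self.organ_reference_dataset_id:
            return self.organ_reference_dataset_id
        if self.paired_patient_dataset_ids:
            return self.paired_patient_dataset_ids[0]
        if self.patient_dataset_ids:
            return self.patient_dataset_ids[0]
        return ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_localizations"] = sorted(self.allowed_localizations)
        for key in (
            "cell_line_dataset_ids",
            "patient_dataset_ids",
            "paired_patient_dataset_ids",
            "leukocyte_dataset_ids",
        ):
            d[key] = list(d[key])
        if math.isinf(d["low_ratio_threshold"]):
            d["low_ratio_threshold"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("low_ratio_threshold") in ("inf", ".inf", "Infinity"):
            d["low_ratio_threshold"] = math.inf
        if "allowed_localizations" in d:
            d["allowed_localizations"] = frozenset(d["allowed_localizations"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        return cls.from_dict({k: v for k, v in raw.items() if k in known})


@dataclass(frozen=True)
class StageResult:
    stage_name: str
    input_count: int
    output_count: int
    surviving_symbols: tuple[str, ...]


@dataclass(frozen=True)
class FunnelReport:
    """Stage-by-stage survivor counts plus the per-candidate evidence table.

    ``per_candidate`` rows cover every gene that reached the fold-change
    stage: its mean fold change, per-leukocyte-dataset ratios, per-organ
    ratios, and pass/fail flags for the last three stages. ``candidates``
    is the final ranking (descending mean fold change, ties alphabetical).
    """

    config: dict
    stages: tuple[StageResult, ...]
    per_candidate: tuple[dict, ...]
    candidates: tuple[str, ...]
    venn_regions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stages": [asdict(s) | {"surviving_symbols": sorted(s.surviving_symbols)}
                       for s in self.stages],
            "per_candidate": [dict(row) for row in self.per_candidate],
            "candidates": list(self.candidates),
            "venn_regions": dict(self.venn_regions),
        }


def _require(datasets: Mapping[str, ExpressionDataset], ds_id: str, stage: str
             ) -> ExpressionDataset:
    if ds_id not in datasets:
        raise FunnelError(f"stage {stage}: dataset {ds_id!r} not supplied")
    return datasets[ds_id]


def _subject_columns(ds: ExpressionDataset, group: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for s in ds.samples:
        if s.group == group:
            out.setdefault(s.subject_label or s.sample_id, []).append(s.sample_id)
    return out


def run_funnel(
    config: PipelineConfig,
    datasets: Mapping[str, ExpressionDataset],
    catalog: ProteaseCatalog,
) -> FunnelReport:
    """Run all six funnel stages and return the stage-by-stage report."""
    if catalog.panel_size == 0:
        raise FunnelError("catalog is empty")
    stages: list[StageResult] = []

    # Stage 1 — localization: restrict the degradome to surface-accessible members.
    panel = filter_by_localization(catalog, config.allowed_localizations)
    survivors = set(panel.symbols)
    stages.append(StageResult(
        "localization", catalog.panel_size, len(survivors),
        tuple(sorted(survivors)),
    ))

    # Stage 2 — cell-line consensus: above panel average in every sample,
    # intersected across all cell-line datasets.
    venn: dict = {}
    if config.cell_line_dataset_ids:
        callsets = []
        for ds_id in config.cell_line_dataset_ids:
            ds = _require(datasets, ds_id, "cell_line_consensus")
            try:
                callsets.append(call_above_average_all_samples(ds, panel))
            except EnrichmentError as exc:
                raise FunnelError(f"stage cell_line_consensus, dataset {ds_id}: {exc}")
        if len(callsets) >= 2:
            shared, venn = consensus_intersection(callsets)
        else:
            shared = set(callsets[0].genes)
        survivors &= shared
    stages.append(StageResult(
        "cell_line_consensus", stages[-1].output_count, len(survivors),
        tuple(sorted(survivors)),
    ))

    # Stage 3 — patient consensus: called in >= k of n patient cohorts.
    if config.patient_dataset_ids:
        callsets = []
        for ds_id in config.patient_dataset_ids:
            ds = _require(datasets, ds_id, "patient_k_of_n")
            groups = (
                ("tumor",) if "tumor" in ds.groups_present() else ("cell_line",)
            )
            try:
                if config.patient_call_rule == "dataset_mean":
                    callsets.append(
                        call_above_average_dataset_mean(ds, panel, groups)
                    )
                else:
                    callsets.append(call_above_average_all_samples(ds, panel))
            except EnrichmentError as exc:
                raise FunnelError(f"stage patient_k_of_n, dataset {ds_id}: {exc}")
        survivors &= consensus_k_of_n(callsets, config.k_of_n)
    stages.append(StageResult(
        "patient_k_of_n", stages[-1].output_count, len(survivors),
        tuple(sorted(survivors)),
    ))

    # Stage 4 — fold change: mean tumor/adjacent-normal ratio across paired
    # cohorts must reach the cutoff; absence from any paired cohort fails.
    per_candidate: list[dict] = []
    fc_survivors: set[str] = set()
    mean_fc: dict[str, float] = {}
    paired = [
        _require(datasets, ds_id, "fold_change")
        for ds_id in config.paired_patient_dataset_ids
    ]
    for gene in sorted(survivors):
        row: dict = {"symbol": gene, "mean_fold_change": None,
                     "per_dataset_fold_change": {}, "leukocyte_ratios": {},
                     "organ_ratios": {}, "passes": {}}
        fcs = []
        ok = bool(paired)
        for ds in paired:
            try:
                fc = fold_change_tumor_vs_normal(ds, gene)
            except EnrichmentError as exc:
                logger.info("fold_change: %s fails in %s (%s)", gene, ds.dataset_id, exc)
                ok = False
                break
            fcs.append(fc)
            row["per_dataset_fold_change"][ds.dataset_id] = fc
        if ok:
            row["mean_fold_change"] = aggregate_fold_change(fcs, config.fc_aggregation)
            mean_fc[gene] = row["mean_fold_change"]
            ok = row["mean_fold_change"] >= config.fc_cutoff
        elif not paired:
            ok = True  # no paired cohorts configured: stage is vacuous
        row["passes"]["fold_change"] = ok
        if ok:
            fc_survivors.add(gene)
        per_candidate.append(row)
    survivors = fc_survivors
    stages.append(StageResult(
        "fold_change", stages[-1].output_count, len(survivors),
        tuple(sorted(survivors)),
    ))
    by_symbol = {row["symbol"]: row for row in per_candidate}

    # Stage 5 — leukocyte screen: low relative to same-platform tumor
    # reference samples in EVERY leukocyte dataset.
    leuk_survivors: set[str] = set()
    for gene in sorted(survivors):
        row = by_symbol[gene]
        ok = True
        for ds_id in config.leukocyte_dataset_ids:
            ds = _require(datasets, ds_id, "leukocyte_screen")
            try:
                ratio = relative_to_reference_tissue(
                    ds, ds, gene,
                    target_groups=("leukocyte",), reference_groups=("tumor",),
                )
            except EnrichmentError as exc:
                logger.info("leukocyte_screen: %s fails in %s (%s)", gene, ds_id, exc)
                ok = False
                break
            row["leukocyte_ratios"][ds_id] = ratio
            if not ratio < config.low_ratio_threshold:
                ok = False
        row["passes"]["leukocyte_screen"] = ok
        if ok:
            leuk_survivors.add(gene)
    survivors = leuk_survivors
    stages.append(StageResult(
        "leukocyte_screen", stages[-1].output_count, len(survivors),
        tuple(sorted(survivors)),
    ))

    # Stage 6 — organ screen: housekeeping-normalized abundance low
    # relative to the tumor reference cohort in EVERY healthy organ.
    organ_survivors: set[str] = set()
    organ_ds = (
        _require(datasets, config.organ_dataset_id, "organ_screen")
        if config.organ_dataset_id else None
    )
    ref_ds = (
        _require(datasets, config.organ_reference, "organ_screen")
        if organ_ds is not None and config.organ_reference else None
    )
    if organ_ds is not None and ref_ds is None:
        raise FunnelError("stage organ_screen: no tumor reference dataset configured")
    for gene in sorted(survivors):
        row = by_symbol[gene]
        ok = True
        if organ_ds is not None:
            for organ, cols in sorted(_subject_columns(organ_ds, "organ").items()):
                sub = replace(
                    organ_ds,
                    matrix=organ_ds.matrix.loc[:, cols],
                    samples=tuple(s for s in organ_ds.samples if s.sample_id in cols),
                )
                try:
                    ratio = relative_to_reference_tissue(
                        sub, ref_ds, gene, config.normalizer_gene,
                        reference_groups=("tumor",),
                    )
                except EnrichmentError as exc:
                    logger.info("organ_screen: %s fails for organ %s (%s)",
                                gene, organ, exc)
                    ok = False
                    break
                row["organ_ratios"][organ] = ratio
                if not ratio < config.low_ratio_threshold:
                    ok = False
        row["passes"]["organ_screen"] = ok
        if ok:
            organ_survivors.add(gene)
    survivors = organ_survivors
    stages.append(StageResult(
        "organ_screen", stages[-1].output_count, len(survivors),
        tuple(sorted(survivors)),
    ))

    ranking = sorted(survivors, key=lambda g: (-mean_fc.get(g, 0.0), g))
    return FunnelReport(
        config=config.to_dict(),
        stages=tuple(stages),
        per_candidate=tuple(per_candidate),
        candidates=tuple(ranking),
        venn_regions=venn,
    )


def write_report(report: FunnelReport, path: str | Path) -> None:
    """Serialize a report as JSON with stable key order (byte-deterministic)."""
    path = Path(path)
    text = json.dumps(report.to_dict(), indent=2, sort_keys=True, allow_nan=False)
    path.write_text(text + "\n", encoding="utf-8")


def read_report(path: str | Path) -> FunnelReport:
    """Read a report written by :func:`write_report`."""
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return FunnelReport(
        config=d["config"],
        stages=tuple(
            StageResult(
                s["stage_name"], s["input_count"], s["output_count"],
                tuple(s["surviving_symbols"]),
            )
            for s in d["stages"]
        ),
        per_candidate=tuple(d["per_candidate"]),
        candidates=tuple(d["candidates"]),
        venn_regions=d.get("venn_regions", {}),
    )
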