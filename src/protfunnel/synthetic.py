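"""Synthetic multi-dataset expression studies with planted ground truth.

The generator emulates the structure of the real study panel: several
cell-line cohorts, several patient cohorts (a subset with paired
adjacent-normal samples), leukocyte cohorts that carry same-platform tumor
reference samples, and one healthy-organ cohort with a housekeeping gene.
Abundances are log-normal baselines with multiplicative (log2-unit)
noise and a per-dataset platform scale factor; planted effects multiply
group means, so true ratios are exact in expectation and exactly
recovered at zero noise.

Planted tumor-enriched genes are given a high baseline (well above the
panel distribution) so that, noise aside, they clear every above-average
call by construction; whether a planted gene should survive the full
funnel is then decided by its localization flag and its three planted
ratios against the paired pipeline thresholds, and checked for
consistency at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional
import json

import numpy as np
import pandas as pd

from .catalog import ProteaseCatalog, write_protease_catalog
from .expression import ExpressionDataset, SampleMeta, write_expression_table
from .funnel import FunnelReport, PipelineConfig, run_funnel

_ORGANS = (
    "pancreas", "liver", "lung", "brain", "heart", "kidney", "spleen", "colon",
)

_INTRACELLULAR_TERMS = ("cytoplasm", "nucleus", "lysosome", "mitochondrion")
_SURFACE_TERMS = ("extracellular", "transmembrane", "secreted", "plasma_membrane")


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one planted protease.

    ``tumor_fc`` is the true tumor/adjacent-normal abundance ratio (also
    applied to cell-line samples, emulating a tumor-cell-intrinsic gene);
    ``leukocyte_ratio`` and ``organ_ratio`` are the true leukocyte/tumor
    and organ/tumor ratios. ``should_pass_funnel`` must be consistent with
    the thresholds of the paired pipeline config.
    """

    symbol: str
    is_extracellular: bool = True
    tumor_fc: float = 3.0
    leukocyte_ratio: float = 0.1
    organ_ratio: float = 0.2
    should_pass_funnel: bool = True

    def __post_init__(self) -> None:
        if min(self.tumor_fc, self.leukocyte_ratio, self.organ_ratio) <= 0:
            raise SimulationError(f"{self.symbol}: planted ratios must be > 0")

    def would_pass(self, config: PipelineConfig) -> bool:
        return (
            self.is_extracellular
            and self.tumor_fc >= config.fc_cutoff
            and self.leukocyte_ratio < config.low_ratio_threshold
            and self.organ_ratio < config.low_ratio_threshold
        )


def adam9_like_planted(symbol: str = "ADAM9") -> PlantedGene:
    """The full-pass profile: high tumor fold change, low everywhere else."""
    return PlantedGene(symbol, True, 3.0, 0.1, 0.2, True)


def default_planted_genes() -> tuple[PlantedGene, ...]:
    """One full-pass candidate plus decoys failing exactly one screen each."""
    return (
        adam9_like_planted("ADAM9"),
        # tumor-enriched but abundant in leukocytes (a CTSB-like profile)
        PlantedGene("CTSB", True, 2.5, 2.0, 0.3, False),
        # tumor-enriched but broadly expressed in healthy organs
        PlantedGene("ADAM10", True, 2.0, 0.2, 1.5, False),
        # perfect expression profile but intracellular
        PlantedGene("CAPN1", False, 3.0, 0.1, 0.2, False),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and noise of a synthetic study.

    Defaults mirror the real panel: 3 cell-line cohorts, 6 patient cohorts
    of which 3 are tumor/adjacent-normal paired, 4 leukocyte cohorts and
    one organ cohort covering 8 organs; 60 proteases (45% surface-
    accessible, echoing 258 of 571) among 40 non-protease background
    genes; log2 baselines N(6, 1.5), multiplicative noise sigma 0.5 in
    log2 units, and per-dataset platform scales in (0.5, 2.0).
    """

    n_proteases: int = 60
    n_background_genes: int = 40
    frac_extracellular: float = 0.45
    n_cell_line_datasets: int = 3
    n_patient_datasets: int = 6
    n_paired_patient_datasets: int = 3
    n_leukocyte_datasets: int = 4
    samples_per_dataset: int = 8
    planted: tuple[PlantedGene, ...] = field(default_factory=default_planted_genes)
    noise_sigma: float = 0.5
    platform_scale_range: tuple[float, float] = (0.5, 2.0)
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    normalizer_gene: str = "ACTB"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be >= 0")
        lo, hi = self.platform_scale_range
        if not 0 < lo <= hi:
            raise SimulationError("platform_scale_range must satisfy 0 < low <= high")
        if not 0 < self.frac_extracellular < 1:
            raise SimulationError("frac_extracellular must be in (0, 1)")
        if self.n_paired_patient_datasets > self.n_patient_datasets:
            raise SimulationError("more paired than total patient datasets")
        if min(self.n_proteases, self.samples_per_dataset,
               self.n_cell_line_datasets, self.n_patient_datasets,
               self.n_leukocyte_datasets) < 1:
            raise SimulationError("all dataset/sample counts must be >= 1")
        if self.n_proteases < len(self.planted):
            raise SimulationError("n_proteases smaller than the planted list")


@dataclass(frozen=True)
class SyntheticTruth:
    """What was planted, for recovery scoring against funnel output."""

    planted: tuple[PlantedGene, ...]
    should_pass: frozenset[str]
    protease_symbols: tuple[str, ...]
    pipeline_config: PipelineConfig

    def to_dict(self) -> dict:
        return {
            "planted": [
                {
                    "symbol": g.symbol,
                    "is_extracellular": g.is_extracellular,
                    "tumor_fc": g.tumor_fc,
                    "leukocyte_ratio": g.leukocyte_ratio,
                    "organ_ratio": g.organ_ratio,
                    "should_pass_funnel": g.should_pass_funnel,
                }
                for g in self.planted
            ],
            "should_pass": sorted(self.should_pass),
            "protease_symbols": list(self.protease_symbols),
        }


def default_pipeline_config(sim: SimulationConfig) -> PipelineConfig:
    """The funnel configuration matching a simulated study's dataset ids."""
    return PipelineConfig(
        cell_line_dataset_ids=tuple(
            f"CL{i + 1:02d}" for i in range(sim.n_cell_line_datasets)
        ),
        patient_dataset_ids=tuple(
            f"PT{i + 1:02d}" for i in range(sim.n_patient_datasets)
        ),
        paired_patient_dataset_ids=tuple(
            f"PT{i + 1:02d}" for i in range(sim.n_paired_patient_datasets)
        ),
        leukocyte_dataset_ids=tuple(
            f"LK{i + 1:02d}" for i in range(sim.n_leukocyte_datasets)
        ),
        organ_dataset_id="ORG",
        k_of_n=min(5, sim.n_patient_datasets),
        normalizer_gene=sim.normalizer_gene,
    )


def _gene_table(sim: SimulationConfig, rng: np.random.Generator):
    """Symbols, localization terms and group-effect multipliers per gene."""
    planted_by_symbol = {g.symbol.upper(): g for g in sim.planted}
    symbols: list[str] = list(planted_by_symbol)
    n_free = sim.n_proteases - len(symbols)
    symbols += [f"PRT{i + 1:03d}" for i in range(n_free)]
    background = [f"BKG{i + 1:03d}" for i in range(sim.n_background_genes)]

    entries: dict[str, frozenset[str]] = {}
    for sym in symbols:
        planted = planted_by_symbol.get(sym)
        if planted is not None:
            surface = planted.is_extracellular
        else:
            surface = bool(rng.random() < sim.frac_extracellular)
        if surface:
            terms = set(rng.choice(_SURFACE_TERMS, size=rng.integers(1, 3),
                                   replace=False))
        else:
            terms = {str(rng.choice(_INTRACELLULAR_TERMS))}
        entries[sym] = frozenset(str(t) for t in terms)

    # Baselines: background distribution for unplanted genes; planted
    # tumor-enriched genes sit 2.5 SD above the log2 mean so every
    # above-average call is cleared by construction in the noiseless limit.
    baselines: dict[str, float] = {}
    for sym in symbols + background:
        planted = planted_by_symbol.get(sym)
        if planted is not None:
            log2_b = sim.baseline_log2_mean + 2.5 * sim.baseline_log2_sd
        else:
            log2_b = rng.normal(sim.baseline_log2_mean, sim.baseline_log2_sd)
        baselines[sym] = float(2.0 ** log2_b)

    def effect(sym: str, group: str, organ: bool = False) -> float:
        planted = planted_by_symbol.get(sym)
        if planted is None:
            return 1.0
        if group in ("tumor", "cell_line"):
            return planted.tumor_fc
        if group == "leukocyte":
            return planted.tumor_fc * planted.leukocyte_ratio
        if group == "organ":
            return planted.tumor_fc * planted.organ_ratio
        return 1.0  # adjacent_normal

    return symbols, background, entries, baselines, effect


def generate_study(
    sim: SimulationConfig,
    pipeline_config: Optional[PipelineConfig] = None,
) -> tuple[dict[str, ExpressionDataset], ProteaseCatalog, SyntheticTruth]:
    """Generate one seeded multi-dataset study with planted ground truth.

    Identical ``sim`` (including seed) gives identical matrices. Raises
    :class:`SimulationError` at generation time if any planted gene's
    ``should_pass_funnel`` flag contradicts the pipeline thresholds.
    """
    config = pipeline_config or default_pipeline_config(sim)
    for g in sim.planted:
        if g.should_pass_funnel != g.would_pass(config):
            raise SimulationError(
                f"planted gene {g.symbol}: should_pass_funnel="
                f"{g.should_pass_funnel} contradicts the pipeline thresholds"
            )
    rng = np.random.default_rng(sim.seed)
    symbols, background, entries, baselines, effect = _gene_table(sim, rng)
    catalog = ProteaseCatalog(entries=entries)
    all_genes = symbols + background + [sim.normalizer_gene.upper()]
    actb_baseline = float(2.0 ** (sim.baseline_log2_mean + 4.0))  # stable housekeeper

    def make_dataset(ds_id: str, platform: str,
                     samples: list[SampleMeta]) -> ExpressionDataset:
        scale = float(rng.uniform(*sim.platform_scale_range))
        cols = {}
        for s in samples:
            noise = 2.0 ** rng.normal(0.0, sim.noise_sigma, size=len(all_genes))
            vals = np.empty(len(all_genes))
            for i, sym in enumerate(all_genes):
                if sym == sim.normalizer_gene.upper():
                    # housekeeping normalizer: stable by construction —
                    # platform scale only, no biological noise
                    vals[i] = actb_baseline * scale
                else:
                    base = baselines[sym] * effect(sym, s.group)
                    vals[i] = base * scale * noise[i]
            cols[s.sample_id] = vals
        matrix = pd.DataFrame(cols, index=all_genes)
        matrix.index.name = "gene_symbol"
        return ExpressionDataset(ds_id, platform, matrix, tuple(samples))

    datasets: dict[str, ExpressionDataset] = {}
    for d in range(sim.n_cell_line_datasets):
        ds_id = f"CL{d + 1:02d}"
        samples = [
            SampleMeta(f"{ds_id}_S{j + 1}", "cell_line", f"LINE{j + 1:02d}")
            for j in range(sim.samples_per_dataset)
        ]
        datasets[ds_id] = make_dataset(ds_id, f"GPL_CL{d + 1}", samples)

    for d in range(sim.n_patient_datasets):
        ds_id = f"PT{d + 1:02d}"
        paired = d < sim.n_paired_patient_datasets
        samples = []
        if paired:
            half = max(1, sim.samples_per_dataset // 2)
            for j in range(half):
                samples.append(SampleMeta(
                    f"{ds_id}_T{j + 1}", "tumor", f"PAT{j + 1:02d}",
                    paired_with=f"{ds_id}_N{j + 1}",
                ))
            for j in range(half):
                samples.append(SampleMeta(
                    f"{ds_id}_N{j + 1}", "adjacent_normal", f"PAT{j + 1:02d}",
                    paired_with=f"{ds_id}_T{j + 1}",
                ))
        else:
            samples = [
                SampleMeta(f"{ds_id}_T{j + 1}", "tumor", f"PAT{j + 1:02d}")
                for j in range(sim.samples_per_dataset)
            ]
        datasets[ds_id] = make_dataset(ds_id, f"GPL_PT{d + 1}", samples)

    for d in range(sim.n_leukocyte_datasets):
        ds_id = f"LK{d + 1:02d}"
        half = max(1, sim.samples_per_dataset // 2)
        samples = [
            SampleMeta(f"{ds_id}_L{j + 1}", "leukocyte", f"SUBSET{j + 1:02d}")
            for j in range(half)
        ] + [
            # same-platform tumor reference profiles for the within-dataset screen
            SampleMeta(f"{ds_id}_T{j + 1}", "tumor", f"REF{j + 1:02d}")
            for j in range(half)
        ]
        datasets[ds_id] = make_dataset(ds_id, f"GPL_LK{d + 1}", samples)

    # GTEx-like organ cohort: several donors per organ, matching the
    # replicate depth of the other group-mean comparisons.
    donors = max(1, sim.samples_per_dataset // 2)
    organ_samples = [
        SampleMeta(f"ORG_{organ}_{j + 1}", "organ", organ)
        for organ in _ORGANS
        for j in range(donors)
    ]
    datasets["ORG"] = make_dataset("ORG", "GPL_ORG", organ_samples)

    truth = SyntheticTruth(
        planted=sim.planted,
        should_pass=frozenset(
            g.symbol.upper() for g in sim.planted if g.should_pass_funnel
        ),
        protease_symbols=tuple(symbols),
        pipeline_config=config,
    )
    return datasets, catalog, truth


def write_study(
    datasets: dict[str, ExpressionDataset],
    catalog: ProteaseCatalog,
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> None:
    """Write a study as canonical TSV pairs, a catalog table and a truth JSON,
    so a synthetic study is indistinguishable from real inputs to the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds_id, ds in sorted(datasets.items()):
        write_expression_table(
            ds, out / f"{ds_id}_matrix.tsv", out / f"{ds_id}_meta.tsv"
        )
    write_protease_catalog(catalog, out / "catalog.tsv")
    (out / "truth.json").write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def recovery_experiment(
    sim: SimulationConfig,
    pipeline_config: Optional[PipelineConfig] = None,
    n_replicates: int = 20,
) -> tuple[float, float]:
    """Monte-Carlo recovery of the planted truth over seeded replicates.

    Replicate ``i`` uses seed ``sim.seed + i``. Returns (sensitivity,
    false-positive rate): sensitivity is the average fraction of
    should-pass planted genes present in the final survivor set, and the
    false-positive rate is the average fraction of the remaining proteases
    that nonetheless survive.
    """
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    sens, fpr = [], []
    for i in range(n_replicates):
        rep = replace(sim, seed=sim.seed + i)
        datasets, catalog, truth = generate_study(rep, pipeline_config)
        report: FunnelReport = run_funnel(
            truth.pipeline_config, datasets, catalog
        )
        survivors = set(report.candidates)
        positives = set(truth.should_pass)
        negatives = set(truth.protease_symbols) - positives
        sens.append(
            len(survivors & positives) / len(positives) if positives else 1.0
        )
        fpr.append(
            len(survivors & negatives) / len(negatives) if negatives else 0.0
        )
    return float(np.mean(sens)), float(np.mean(fpr))
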