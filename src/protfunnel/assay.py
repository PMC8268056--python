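"""FRET-substrate cleavage arithmetic and nanoparticle loading efficiency.

A quenched fluorogenic peptide substrate (fluorophore/quencher flanked)
reports proteolysis as a fluorescence rise, read on a plate reader at a
coarse fixed interval (typically every 15 min). Cleavage activity is
expressed as fold change over a time-matched no-enzyme control well — not
over the t = 0 baseline — optionally after subtracting a buffer blank.
No interpolation or smoothing is applied: threshold times are reported on
the measured grid. Kinetic model fitting (Michaelis–Menten, IC50) is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class AssayError(ValueError):
    """Raised for malformed traces or undefined assay arithmetic."""


@dataclass(frozen=True)
class CleavageTimeSeries:
    """One well's fluorescence-vs-time trace (arbitrary units, minutes)."""

    times: tuple[float, ...]
    fluorescence: tuple[float, ...]
    label: str = ""
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.role not in ("sample", "control", "blank"):
            raise AssayError(f"unknown role {self.role!r}")
        if len(self.times) != len(self.fluorescence):
            raise AssayError(f"{self.label}: times and fluorescence differ in length")
        if len(self.times) == 0:
            raise AssayError(f"{self.label}: empty trace")
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if not (np.diff(t) > 0).all():
            raise AssayError(f"{self.label}: times must be strictly increasing")
        if not np.isfinite(f).all():
            raise AssayError(f"{self.label}: non-finite fluorescence")


@dataclass(frozen=True)
class FoldChangeCurve:
    """Sample fluorescence relative to control at matched times."""

    times: tuple[float, ...]
    fold: tuple[float, ...]


def average_replicates(traces: Sequence[CleavageTimeSeries]) -> CleavageTimeSeries:
    """Average replicate wells pointwise (all must share role and time grid)."""
    if not traces:
        raise AssayError("no traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if tr.times != first.times:
            raise AssayError("replicate wells measured on different time grids")
        if tr.role != first.role:
            raise AssayError("replicate wells with different roles")
    mean = np.mean([tr.fluorescence for tr in traces], axis=0)
    return CleavageTimeSeries(
        times=first.times,
        fluorescence=tuple(float(v) for v in mean),
        label=first.label,
        role=first.role,
    )


def fold_change_curve(
    sample: CleavageTimeSeries,
    control: CleavageTimeSeries,
    blank: Optional[CleavageTimeSeries] = None,
) -> FoldChangeCurve:
    """Pointwise fold change of sample over a time-matched control well.

    fold(t) = (sample(t) - blank(t)) / (control(t) - blank(t)); the blank
    is treated as zero when absent. Time grids must match exactly.
    """
    if sample.times != control.times or (blank is not None and blank.times != sample.times):
        raise AssayError("sample/control/blank time grids do not match")
    s = np.asarray(sample.fluorescence, dtype=float)
    c = np.asarray(control.fluorescence, dtype=float)
    b = np.asarray(blank.fluorescence, dtype=float) if blank is not None else 0.0
    denom = c - b
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise AssayError(
            f"non-positive control signal at t = {sample.times[bad[0]]} min"
        )
    fold = (s - b) / denom
    return FoldChangeCurve(times=sample.times, fold=tuple(float(v) for v in fold))


def time_to_fraction_of_max(curve: FoldChangeCurve, fraction: float = 0.95) -> float:
    """Earliest measured time at which fold reaches ``fraction`` of its maximum.

    No interpolation between measured points. With the default 0.95 this
    is the "time to maximum cleavage" read on a coarse plate-reader grid.
    """
    if not 0 < fraction <= 1:
        raise AssayError(f"fraction must be in (0, 1], got {fraction}")
    if len(curve.fold) == 0:
        raise AssayError("empty curve")
    fold = np.asarray(curve.fold, dtype=float)
    peak = float(fold.max())
    if peak <= 0:
        raise AssayError("no cleavage signal: curve maximum is not positive")
    idx = int(np.nonzero(fold >= fraction * peak)[0][0])
    return float(curve.times[idx])


def dose_monotonicity(
    curves: Mapping[float, FoldChangeCurve], at_time: float
) -> bool:
    """True iff fold change at ``at_time`` is non-decreasing in dose."""
    if len(curves) < 2:
        raise AssayError("dose_monotonicity needs >= 2 doses")
    folds = []
    for dose in sorted(curves):
        curve = curves[dose]
        try:
            i = curve.times.index(at_time)
        except ValueError:
            raise AssayError(f"dose {dose}: no measurement at t = {at_time} min")
        folds.append(curve.fold[i])
    return all(b >= a for a, b in zip(folds, folds[1:]))


def entrapment_efficiency(initial_mass: float, loaded_mass: float) -> float:
    """Fraction of initially added drug retained in the particles."""
    if initial_mass <= 0:
        raise AssayError("initial mass must be > 0")
    if not 0 <= loaded_mass <= initial_mass:
        raise AssayError("loaded mass must be between 0 and the initial mass")
    return loaded_mass / initial_mass


def read_plate_table(path: str | Path) -> dict[tuple[str, float], CleavageTimeSeries]:
    """Read a long-format plate-reader TSV into replicate-averaged traces.

    Expected header: ``well, role, dose, time_min, fluorescence``. Wells
    sharing a (role, dose) condition are replicates and are averaged;
    the returned dict maps (role, dose) to one trace per condition.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"well", "role", "dose", "time_min", "fluorescence"}
    if not required <= set(df.columns):
        raise AssayError(f"{path}: expected columns {sorted(required)}")
    out: dict[tuple[str, float], CleavageTimeSeries] = {}
    for (role, dose), cond in df.groupby(["role", "dose"], sort=True):
        wells = []
        for well, grp in cond.groupby("well", sort=True):
            grp = grp.sort_values("time_min")
            wells.append(CleavageTimeSeries(
                times=tuple(float(t) for t in grp["time_min"]),
                fluorescence=tuple(float(v) for v in grp["fluorescence"]),
                label=str(well),
                role=str(role),
            ))
        out[(str(role), float(dose))] = average_replicates(wells)
    return out


def summarize_cleavage(
    conditions: Mapping[tuple[str, float], CleavageTimeSeries],
    fraction: float = 0.95,
    use_blank: bool = True,
) -> dict:
    """Per-dose cleavage summary against the plate's control condition.

    For each sample dose: maximum fold change, time to reach ``fraction``
    of that maximum, and a dose-monotonicity flag at the final time point.
    A blank condition is subtracted when present and ``use_blank`` is set
    (whether a buffer blank should be subtracted is assay-dependent, so
    both paths are exposed).
    """
    controls = {d: tr for (role, d), tr in conditions.items() if role == "control"}
    if not controls:
        raise AssayError("no control condition in plate")
    control = next(iter(controls.values()))
    blanks = {d: tr for (role, d), tr in conditions.items() if role == "blank"}
    blank = next(iter(blanks.values())) if (blanks and use_blank) else None
    per_dose: dict[float, FoldChangeCurve] = {}
    summary: dict = {"doses": {}}
    for (role, dose), trace in sorted(conditions.items()):
        if role != "sample":
            continue
        curve = fold_change_curve(trace, control, blank)
        per_dose[dose] = curve
        summary["doses"][dose] = {
            "max_fold": max(curve.fold),
            "time_to_fraction_of_max_min": time_to_fraction_of_max(curve, fraction),
        }
    if len(per_dose) >= 2:
        last_t = next(iter(per_dose.values())).times[-1]
        summary["dose_monotonic"] = dose_monotonicity(per_dose, last_t)
    return summary
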