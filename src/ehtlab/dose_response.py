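"""Cumulative-concentration experiments and threshold determination.

A compound is added to the same EHT wells at cumulatively increasing
concentrations; each well is recorded at baseline and after each step.
Contractility parameters are expressed per well as percent of that well's
baseline.  Two significance procedures are run against baseline:

* paired two-tailed Student's t-test on a contractility parameter
  (relaxation velocity being the most sensitive hERG-block surrogate);
* exact Mann-Whitney U on per-well beat-interval interdecile ranges
  (RR-scatter) for the irregular-beating phenotype.

The threshold concentration is read under the monotone-read rule: the
lowest ladder concentration at which the effect is significant (p < alpha
and in the pharmacologically expected direction) *and stays significant at
every higher concentration*.  Cumulative dosing makes true effects
monotone, so isolated one-off significances — the expected byproduct of
testing an uncorrected ladder — do not produce a threshold.  No
multiple-testing correction is applied across the ladder (flagged in the
result as a caveat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rhythm import interdecile_range, mann_whitney_u
from .twitch import RecordingSummary

__all__ = [
    "DoseResponseExperiment",
    "ThresholdResult",
    "normalize_to_baseline",
    "paired_t_test",
    "threshold_concentration",
    "build_concentration_response",
    "PARAMETERS",
]

BASELINE = "baseline"

#: parameter name -> (RecordingSummary attribute, expected direction of a
#: drug effect: -1 decrease, +1 increase)
PARAMETERS: dict[str, tuple[str, int]] = {
    "force": ("mean_force", -1),
    "contraction_velocity": ("mean_contraction_velocity", -1),
    "relaxation_velocity": ("mean_relaxation_velocity", -1),
    "frequency": ("frequency_bpm", -1),
    "idr": ("", +1),  # computed from beat intervals, not an attribute
}


@dataclass
class DoseResponseExperiment:
    """Baseline + ladder recordings for replicate wells of one compound."""

    compound: str
    ladder: list            # strictly increasing concentrations
    summaries: dict         # (well_id, condition) -> RecordingSummary,
                            # condition is BASELINE or a ladder value
    concentration_unit: str = ""
    equilibration_min: float = 30.0

    def __post_init__(self) -> None:
        lad = list(self.ladder)
        if any(b <= a for a, b in zip(lad, lad[1:])):
            raise ValueError("concentration ladder must be strictly increasing")
        for well in self.wells:
            if (well, BASELINE) not in self.summaries:
                raise ValueError(f"well {well!r} lacks a baseline recording")

    @property
    def wells(self) -> list:
        return sorted({w for (w, _c) in self.summaries})

    def value(self, well, condition, parameter: str) -> float:
        """One parameter for one (well, condition); NaN when unavailable."""
        summary = self.summaries.get((well, condition))
        if summary is None:
            return float("nan")
        return _extract(summary, parameter)


def _extract(summary: RecordingSummary, parameter: str) -> float:
    if parameter == "idr":
        iv = np.asarray(summary.beat_intervals)
        if iv.size < 2:
            return float("nan")
        return interdecile_range(iv).idr
    attr, _ = PARAMETERS[parameter]
    return float(getattr(summary, attr))


def normalize_to_baseline(experiment: DoseResponseExperiment,
                          parameters: Optional[Sequence[str]] = None
                          ) -> pd.DataFrame:
    """Percent-of-baseline table, one row per (well, condition).

    Each value is divided by the same well's baseline value x 100; the
    baseline rows are exactly 100.  A zero (or undefined) baseline leaves
    that well/parameter as NaN rather than fabricating a percentage.
    Normalizing an already-normalized experiment is the identity (every
    baseline becomes 100, and x/100*100 = x).
    """
    if parameters is None:
        parameters = [p for p in PARAMETERS if p != "idr"]
    conditions = [BASELINE] + list(experiment.ladder)
    rows = []
    for well in experiment.wells:
        base = {p: experiment.value(well, BASELINE, p) for p in parameters}
        for cond in conditions:
            if (well, cond) not in experiment.summaries:
                continue
            row = {"well": well, "condition": cond}
            for p in parameters:
                v = experiment.value(well, cond, p)
                b = base[p]
                row[p] = 100.0 * v / b if b and math.isfinite(b) else float("nan")
            rows.append(row)
    return pd.DataFrame(rows).set_index(["well", "condition"])


def paired_t_test(baseline: Sequence[float], treated: Sequence[float]
                  ) -> tuple[float, float]:
    """Classical paired two-tailed t-test on treated - baseline differences.

    Returns (t, p) with p from the t distribution on n-1 df.  All-zero
    differences give p = 1; zero-variance nonzero differences give the
    0-limit (t = +-inf, p = 0).
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs equal-length samples, n >= 2")
    d = b - a
    mean = d.mean()
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(min(1.0, p))


@dataclass
class ThresholdResult:
    """Threshold concentration of one compound/parameter/procedure."""

    compound: str
    parameter: str
    procedure: str
    threshold: Optional[float]      # member of the ladder, or None
    p_values: dict = field(default_factory=dict)   # conc -> two-sided p
    effects: dict = field(default_factory=dict)    # conc -> mean effect size
    alpha: float = 0.05
    caveat: str = "no multiple-testing correction across the ladder"


def threshold_concentration(experiment: DoseResponseExperiment,
                            parameter: str = "relaxation_velocity",
                            procedure: str = "t",
                            alpha: float = 0.05) -> ThresholdResult:
    """Lowest ladder concentration with a sustained significant effect.

    procedure="t": paired t-test per concentration on the raw per-well
    parameter values vs the same wells' baseline.
    procedure="mannwhitney": exact Mann-Whitney U on per-well IDR values,
    baseline group vs concentration group (``parameter`` is forced to
    "idr").

    Significance requires the two-sided p < alpha *and* the group effect in
    the expected direction (decrease for force/velocities, increase for
    IDR); the threshold must remain significant at every higher ladder
    concentration (monotone-read rule).
    """
    if procedure == "mannwhitney":
        parameter = "idr"
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    _, direction = PARAMETERS[parameter]
    wells = experiment.wells
    if len(wells) < 2:
        raise ValueError("threshold determination needs >= 2 replicate wells")

    base_vals = np.array([experiment.value(w, BASELINE, parameter)
                          for w in wells])
    p_values: dict = {}
    significant: dict = {}
    effects: dict = {}
    for conc in experiment.ladder:
        treat_vals = np.array([experiment.value(w, conc, parameter)
                               for w in wells])
        ok = np.isfinite(base_vals) & np.isfinite(treat_vals)
        if ok.sum() < 2:
            p_values[conc] = float("nan")
            significant[conc] = False
            effects[conc] = float("nan")
            continue
        bv, tv = base_vals[ok], treat_vals[ok]
        if procedure == "t":
            _, p = paired_t_test(bv, tv)
            effect = float(np.mean(tv - bv))
        elif procedure == "mannwhitney":
            _, p = mann_whitney_u(bv, tv, mode="exact")
            effect = float(np.median(tv) - np.median(bv))
        else:
            raise ValueError(f"unknown procedure {procedure!r}")
        p_values[conc] = p
        effects[conc] = effect
        significant[conc] = bool(p < alpha and effect * direction > 0)

    threshold = None
    for i, conc in enumerate(experiment.ladder):
        if all(significant[c] for c in experiment.ladder[i:]):
            threshold = conc
            break
    return ThresholdResult(compound=experiment.compound, parameter=parameter,
                           procedure=procedure, threshold=threshold,
                           p_values=p_values, effects=effects, alpha=alpha)


def build_concentration_response(experiment: DoseResponseExperiment,
                                 parameters: Sequence[str] = ("force",
                                                              "frequency")
                                 ) -> pd.DataFrame:
    """Per-concentration mean +- sd table (e.g. the calcium curve).

    Ordered by concentration, baseline first.  A missing level simply does
    not appear (never interpolated).
    """
    rows = []
    for cond in [BASELINE] + list(experiment.ladder):
        vals = {p: [experiment.value(w, cond, p) for w in experiment.wells
                    if (w, cond) in experiment.summaries]
                for p in parameters}
        if not any(len(v) for v in vals.values()):
            continue
        row: dict = {"condition": cond}
        for p in parameters:
            arr = np.asarray(vals[p], dtype=float)
            arr = arr[np.isfinite(arr)]
            row[f"{p}_mean"] = arr.mean() if arr.size else float("nan")
            row[f"{p}_sd"] = arr.std(ddof=1) if arr.size > 1 else float("nan")
            row[f"{p}_n"] = int(arr.size)
        rows.append(row)
    return pd.DataFrame(rows)
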