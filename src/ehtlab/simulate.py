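"""Experiment-level simulators: generate recordings, analyze them, and
assemble the containers the statistics stages consume.

These wire the twitch generator to the analysis chain so that whole
pharmacology experiments (cumulative drug ladders, calcium series,
chronotropy interventions) can be simulated and pushed through the exact
pipeline used for real recordings.  Per-recording seeds are derived
deterministically from one root seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import synthetic
from .dose_response import BASELINE, DoseResponseExperiment
from .synthetic import (BeatSchedule, ChronotropyModel, DrugEffectModel,
                        TwitchParams, apply_calcium, apply_chronotropy,
                        apply_drug_effect, generate_trace)
from .twitch import DetectionConfig, RecordingSummary, analyze_trace

__all__ = [
    "child_seeds",
    "simulate_recording",
    "simulate_dose_response_experiment",
    "simulate_calcium_experiment",
    "simulate_chronotropy",
]


def child_seeds(root_seed: int, n: int) -> np.ndarray:
    """``n`` independent sub-seeds derived from one root seed (< 2**31)."""
    rng = np.random.default_rng(np.random.SeedSequence(root_seed))
    return rng.integers(0, 2 ** 31 - 1, size=n)


def simulate_recording(params: TwitchParams = synthetic.DEFAULT_TWITCH,
                       schedule: BeatSchedule = synthetic.DEFAULT_SCHEDULE,
                       duration: float = 60.0,
                       dt: float = synthetic.DEFAULT_DT,
                       noise_sd: float = synthetic.DEFAULT_NOISE_SD,
                       seed: int = 0, well_id: str = "well",
                       condition: Optional[dict] = None,
                       cfg: DetectionConfig = DetectionConfig()
                       ) -> RecordingSummary:
    """Generate one recording and run the analysis chain on it."""
    trace, _truth = generate_trace(schedule, params, duration=duration, dt=dt,
                                   noise_sd=noise_sd, seed=seed,
                                   well_id=well_id, condition=condition)
    return analyze_trace(trace, cfg)


def simulate_dose_response_experiment(
        model: DrugEffectModel, ladder: Sequence[float], n_wells: int = 4,
        seed: int = 0, params: TwitchParams = synthetic.DEFAULT_TWITCH,
        schedule: BeatSchedule = synthetic.DEFAULT_SCHEDULE,
        duration: float = 60.0, dt: float = synthetic.DEFAULT_DT,
        noise_sd: float = synthetic.DEFAULT_NOISE_SD,
        cfg: DetectionConfig = DetectionConfig()) -> DoseResponseExperiment:
    """Simulated cumulative-concentration experiment for one compound.

    Each of ``n_wells`` wells is recorded at baseline and at every ladder
    step with the drug-effect model applied; every recording is an
    independent 60-s observation analyzed through the standard chain.
    """
    ladder = list(ladder)
    conditions = [BASELINE] + ladder
    seeds = child_seeds(seed, n_wells * len(conditions))
    summaries = {}
    k = 0
    for w in range(n_wells):
        well = f"well{w + 1}"
        for cond in conditions:
            conc = 0.0 if cond == BASELINE else float(cond)
            p, s = apply_drug_effect(params, schedule, model, conc)
            summaries[(well, cond)] = simulate_recording(
                p, s, duration=duration, dt=dt, noise_sd=noise_sd,
                seed=int(seeds[k]), well_id=well,
                condition={"compound": model.compound, "conc": conc}, cfg=cfg)
            k += 1
    return DoseResponseExperiment(compound=model.compound, ladder=ladder,
                                  summaries=summaries)


def simulate_calcium_experiment(
        levels: Sequence[float] = (0.2, 0.6, 1.0, 1.4, 1.8, 2.2, 3.0),
        n_wells: int = 4, seed: int = 0,
        model: synthetic.CalciumResponseModel = synthetic.DEFAULT_CALCIUM_MODEL,
        params: TwitchParams = synthetic.DEFAULT_TWITCH,
        schedule: BeatSchedule = synthetic.DEFAULT_SCHEDULE,
        duration: float = 60.0, dt: float = synthetic.DEFAULT_DT,
        noise_sd: float = synthetic.DEFAULT_NOISE_SD,
        cfg: DetectionConfig = DetectionConfig()) -> DoseResponseExperiment:
    """Calcium concentration-response series (baseline = model.baseline_ca)."""
    levels = sorted(levels)
    conditions = [BASELINE] + levels
    seeds = child_seeds(seed, n_wells * len(conditions))
    summaries = {}
    k = 0
    for w in range(n_wells):
        well = f"well{w + 1}"
        for cond in conditions:
            ca = model.baseline_ca if cond == BASELINE else float(cond)
            p = apply_calcium(params, ca, model)
            summaries[(well, cond)] = simulate_recording(
                p, schedule, duration=duration, dt=dt, noise_sd=noise_sd,
                seed=int(seeds[k]), well_id=well,
                condition={"calcium_mm": ca}, cfg=cfg)
            k += 1
    return DoseResponseExperiment(compound="calcium", ladder=levels,
                                  summaries=summaries,
                                  concentration_unit="mM")


def simulate_chronotropy(model: ChronotropyModel = ChronotropyModel(),
                         schedule: BeatSchedule = synthetic.DEFAULT_SCHEDULE,
                         params: TwitchParams = synthetic.DEFAULT_TWITCH,
                         duration: float = 60.0, seed: int = 0,
                         noise_sd: float = synthetic.DEFAULT_NOISE_SD
                         ) -> dict[str, float]:
    """Measured beating frequency (Hz) at baseline, under isoprenaline,
    and after adding carbachol on top."""
    seeds = child_seeds(seed, 3)
    out = {}
    for name, (iso, car), s in zip(
            ("baseline", "isoprenaline", "isoprenaline+carbachol"),
            ((False, False), (True, False), (True, True)), seeds):
        sched = apply_chronotropy(schedule, model, isoprenaline=iso,
                                  carbachol=car)
        summary = simulate_recording(params, sched, duration=duration,
                                     seed=int(s), noise_sd=noise_sd,
                                     condition={"intervention": name})
        out[name] = summary.frequency_hz
    return out
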