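"""Synthetic spontaneously-beating EHT recordings with ground truth.

The generator renders force traces made of single-peaked twitches on a
diastolic offset, beating at a controlled mean frequency with lognormal
beat-to-beat intervals, plus additive Gaussian sensor noise.  Effect
models scale the twitch parameters the way the pharmacology experiments
modulate real tissue:

* calcium — Hill-type amplitude dependence on extracellular [Ca2+],
  constrained so that 0.2 mM yields 10 % of the 1.8 mM baseline force and
  the curve plateaus between 2.2 and 3.0 mM;
* proarrhythmic compounds — concentration-dependent slowing of relaxation
  and decline of force (separate Hill terms), with beat-interval scatter
  (cv inflation plus skipped beats) above a scatter-onset concentration;
* isoprenaline / carbachol — positive chronotropy and its muscarinic
  reversal.

Every random draw flows from one user-supplied integer seed through
numpy's splittable SeedSequence, so identical (seed, parameters) give
bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, asdict
from typing import Optional

import numpy as np

from .trace import ContractionTrace

__all__ = [
    "TwitchParams",
    "BeatSchedule",
    "CalciumResponseModel",
    "DrugEffectModel",
    "ChronotropyModel",
    "GroundTruth",
    "generate_twitch_waveform",
    "generate_trace",
    "apply_drug_effect",
    "apply_calcium",
    "apply_chronotropy",
    "calcium_scale",
    "DEFAULT_TWITCH",
    "DEFAULT_SCHEDULE",
    "DEFAULT_NOISE_SD",
    "DEFAULT_DT",
    "DEFAULT_CALCIUM_MODEL",
    "DRUG_MODELS",
    "preset_registry",
]


@dataclass(frozen=True)
class TwitchParams:
    """Shape of one contraction twitch.

    peak_force : twitch amplitude above diastole, uN
    time_to_peak : baseline-to-peak duration, s
    relaxation_time : peak-to-baseline duration, s
    diastolic_force : resting offset, uN
    """

    peak_force: float = 61.0
    time_to_peak: float = 0.25
    relaxation_time: float = 0.35
    diastolic_force: float = 5.0

    def __post_init__(self) -> None:
        if self.peak_force < 0:
            raise ValueError("peak_force must be >= 0")
        if self.time_to_peak <= 0 or self.relaxation_time <= 0:
            raise ValueError("twitch durations must be positive")
        if self.diastolic_force < 0:
            raise ValueError("diastolic_force must be >= 0")

    @property
    def twitch_duration(self) -> float:
        return self.time_to_peak + self.relaxation_time


@dataclass(frozen=True)
class BeatSchedule:
    """Spontaneous beating rhythm.

    base_frequency : mean beat rate, Hz
    interval_cv : coefficient of variation of beat-to-beat intervals
    irregularity_mode : "regular" or "scattered"
    skip_prob : probability that a beat is skipped (its interval doubles);
        the mechanistic stand-in for the irregular-beating phenotype
    """

    base_frequency: float = 0.5
    interval_cv: float = 0.05
    irregularity_mode: str = "regular"
    skip_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be positive")
        if self.interval_cv < 0:
            raise ValueError("interval_cv must be >= 0")
        if not 0.0 <= self.skip_prob < 1.0:
            raise ValueError("skip_prob must be in [0, 1)")
        if self.irregularity_mode not in ("regular", "scattered"):
            raise ValueError("irregularity_mode must be 'regular' or 'scattered'")


@dataclass
class GroundTruth:
    """Per-trace annotation: what the generator actually rendered."""

    event_times: np.ndarray     # peak times, s, strictly increasing
    peak_forces: np.ndarray     # amplitude above diastole per event, uN
    condition: dict
    overlap: bool = False       # some interval < twitch duration

    def to_dict(self) -> dict:
        return {
            "event_times_s": [float(t) for t in self.event_times],
            "peak_forces_un": [float(f) for f in self.peak_forces],
            "condition": self.condition,
            "overlap": bool(self.overlap),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(event_times=np.asarray(d["event_times_s"], dtype=float),
                   peak_forces=np.asarray(d["peak_forces_un"], dtype=float),
                   condition=dict(d.get("condition", {})),
                   overlap=bool(d.get("overlap", False)))


# ---------------------------------------------------------------------------
# waveform

def generate_twitch_waveform(params: TwitchParams, dt: float) -> np.ndarray:
    """Sample one twitch on a grid of spacing ``dt``.

    The template is a two-phase raised cosine: a half-cosine rise over
    ``time_to_peak`` and a half-cosine fall over ``relaxation_time``.  It
    starts and ends exactly at ``diastolic_force``, has a single maximum of
    ``diastolic_force + peak_force``, and a continuous first derivative
    (zero at both feet and at the peak), so maximal contraction and
    relaxation slopes are well defined:  max dF/dt = pi*A/(2*ttp) on the
    rise and pi*A/(2*rt) on the fall.
    """
    if not (dt > 0 and dt <= params.time_to_peak / 10.0):
        raise ValueError("dt must satisfy 0 < dt <= time_to_peak/10")
    t = np.arange(0.0, params.twitch_duration + dt / 2, dt)
    return params.diastolic_force + _twitch_bump(t, params)


def _twitch_bump(t: np.ndarray, params: TwitchParams) -> np.ndarray:
    """Twitch shape above diastole, zero outside [0, twitch_duration]."""
    a, ttp, rt = params.peak_force, params.time_to_peak, params.relaxation_time
    out = np.zeros_like(t, dtype=float)
    rising = (t >= 0) & (t <= ttp)
    falling = (t > ttp) & (t <= ttp + rt)
    out[rising] = 0.5 * a * (1.0 - np.cos(np.pi * t[rising] / ttp))
    out[falling] = 0.5 * a * (1.0 + np.cos(np.pi * (t[falling] - ttp) / rt))
    return out


# ---------------------------------------------------------------------------
# beat schedule sampling

def _sample_intervals(schedule: BeatSchedule, horizon: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Beat intervals whose cumulative sum first exceeds ``horizon``.

    Lognormal with mean 1/base_frequency and cv = interval_cv (degenerate
    at cv = 0); skipped beats double their interval.
    """
    mean = 1.0 / schedule.base_frequency
    cv = schedule.interval_cv
    if cv > 0:
        sigma2 = math.log1p(cv * cv)
        mu = math.log(mean) - sigma2 / 2.0
        sigma = math.sqrt(sigma2)
    out: list[float] = []
    total = 0.0
    while total <= horizon:
        iv = mean if cv == 0 else float(rng.lognormal(mu, sigma))
        if schedule.skip_prob > 0 and rng.random() < schedule.skip_prob:
            iv *= 2.0  # skipped beat
        out.append(iv)
        total += iv
    return np.asarray(out)


def generate_trace(schedule: BeatSchedule, params: TwitchParams,
                   duration: float = 60.0, dt: float = 0.01,
                   noise_sd: float = 1.0, seed: int = 0,
                   well_id: str = "synthetic",
                   condition: Optional[dict] = None
                   ) -> tuple[ContractionTrace, GroundTruth]:
    """Render one spontaneously beating force recording (uN).

    Beats start one interval after t = 0; only twitches that fit entirely
    inside the recording are rendered (and annotated), so the ground-truth
    event count is ~ base_frequency * duration.  Overlapping twitches (an
    interval shorter than the twitch duration) are summed additively and
    flagged in the ground truth.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    n = int(round(duration / dt)) + 1
    time = np.arange(n) * dt
    value = np.full(n, params.diastolic_force, dtype=float)

    intervals = _sample_intervals(schedule, duration, rng)
    peak_times = np.cumsum(intervals)
    # keep twitches that fit entirely within the recording
    keep = (peak_times >= params.time_to_peak) & \
           (peak_times + params.relaxation_time <= duration)
    peak_times = peak_times[keep]
    overlap = bool(np.any(np.diff(peak_times) < params.twitch_duration))

    for tp in peak_times:
        start = tp - params.time_to_peak
        i0 = max(0, int(math.ceil(start / dt)))
        i1 = min(n - 1, int(math.floor((tp + params.relaxation_time) / dt)))
        seg = time[i0:i1 + 1] - start
        value[i0:i1 + 1] += _twitch_bump(seg, params)

    if noise_sd > 0:
        value = value + rng.normal(0.0, noise_sd, size=n)

    cond = dict(condition or {})
    cond.setdefault("seed", int(seed))
    truth = GroundTruth(
        event_times=peak_times,
        peak_forces=np.full(peak_times.size, params.peak_force),
        condition=cond,
        overlap=overlap,
    )
    trace = ContractionTrace(time=time, value=value, unit="uN", well_id=well_id)
    return trace, truth


# ---------------------------------------------------------------------------
# effect models

def _hill(conc: float, ic50: float, n: float) -> float:
    """Occupancy-style Hill term in [0, 1); 0 at conc = 0."""
    if conc == 0 or math.isinf(ic50):
        return 0.0
    cn = conc ** n
    return cn / (cn + ic50 ** n)


@dataclass(frozen=True)
class CalciumResponseModel:
    """Hill dependence of twitch amplitude on extracellular calcium (mM)."""

    ec50: float
    hill_n: float = 2.0
    baseline_ca: float = 1.8

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill_n <= 0 or self.baseline_ca <= 0:
            raise ValueError("calcium model parameters must be positive")

    @classmethod
    def from_constraints(cls, hill_n: float = 2.0, baseline_ca: float = 1.8,
                         low_ca: float = 0.2, low_fraction: float = 0.10,
                         plateau_lo: float = 2.2, plateau_hi: float = 3.0,
                         plateau_ratio: float = 0.95) -> "CalciumResponseModel":
        """Solve EC50 so that scale(low_ca)/scale(baseline_ca) = low_fraction.

        With f(c) = c^n / (c^n + K^n) the constraint has the closed-form
        solution K^n = (1 - r) a b / (r b - a) for a = low_ca^n,
        b = baseline_ca^n, r = low_fraction.  The resulting curve is checked
        against the required plateau (scale(2.2)/scale(3.0) >= 0.95).
        """
        a = low_ca ** hill_n
        b = baseline_ca ** hill_n
        r = low_fraction
        denom = r * b - a
        if denom <= 0:
            raise ValueError("constraints unsatisfiable at this Hill exponent")
        kn = (1.0 - r) * a * b / denom
        model = cls(ec50=kn ** (1.0 / hill_n), hill_n=hill_n,
                    baseline_ca=baseline_ca)
        ratio = calcium_scale(plateau_lo, model) / calcium_scale(plateau_hi, model)
        if ratio < plateau_ratio:
            raise ValueError(
                f"plateau constraint violated: scale({plateau_lo})/scale({plateau_hi})"
                f" = {ratio:.3f} < {plateau_ratio}")
        return model


def calcium_scale(ca: float, model: CalciumResponseModel) -> float:
    """Amplitude multiplier in (0, 1): the Hill occupancy at ``ca`` mM.

    Monotone non-decreasing in ``ca``.  The generator normalizes by
    ``calcium_scale(model.baseline_ca, model)`` so the preset amplitude
    applies at baseline calcium.
    """
    if ca <= 0:
        raise ValueError("calcium concentration must be positive")
    return _hill(ca, model.ec50, model.hill_n)


def apply_calcium(params: TwitchParams, ca: float,
                  model: CalciumResponseModel) -> TwitchParams:
    """Twitch parameters with amplitude rescaled for calcium ``ca`` (mM)."""
    factor = calcium_scale(ca, model) / calcium_scale(model.baseline_ca, model)
    return replace(params, peak_force=params.peak_force * factor)


@dataclass(frozen=True)
class DrugEffectModel:
    """Phenomenological concentration-effect map of a proarrhythmic compound.

    Relaxation velocity and force each follow their own descending Hill
    curve bounded below by 1 - max_reduction; interval scatter (cv
    inflation + skipped beats) switches on above ``scatter_onset``.
    Concentration units are whatever the dosing ladder uses.
    """

    compound: str
    ic50_relax: float
    ic50_force: float
    scatter_onset: float
    hill_relax: float = 1.5
    hill_force: float = 1.5
    max_reduction: float = 0.4
    cv_gain: float = 6.0
    skip_gain: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_reduction <= 1.0:
            raise ValueError("max_reduction must be in [0, 1]")

    def relaxation_scale(self, conc: float) -> float:
        """Multiplier on measured relaxation velocity, in (1-max_reduction, 1]."""
        return 1.0 - self.max_reduction * _hill(conc, self.ic50_relax,
                                                self.hill_relax)

    def force_scale(self, conc: float) -> float:
        return 1.0 - self.max_reduction * _hill(conc, self.ic50_force,
                                                self.hill_force)

    def scatter_fraction(self, conc: float) -> float:
        """0 at/below scatter_onset, monotone toward 1 far above it."""
        if not math.isfinite(self.scatter_onset) or conc <= self.scatter_onset:
            return 0.0
        return (conc - self.scatter_onset) / (conc + self.scatter_onset)


def apply_drug_effect(params: TwitchParams, schedule: BeatSchedule,
                      model: DrugEffectModel, conc: float
                      ) -> tuple[TwitchParams, BeatSchedule]:
    """Twitch/schedule parameters under ``conc`` of the compound.

    Peak force scales by the force Hill factor; relaxation_time is
    stretched by force_scale/relaxation_scale so that the *measured*
    maximal relaxation slope (proportional to amplitude/relaxation_time)
    scales exactly by the relaxation Hill factor.  Above scatter_onset the
    beat schedule's cv inflates and beats start being skipped.
    conc = 0 returns the inputs unchanged.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if conc == 0:
        return params, schedule
    g_force = model.force_scale(conc)
    g_relax = model.relaxation_scale(conc)
    new_params = replace(
        params,
        peak_force=params.peak_force * g_force,
        relaxation_time=params.relaxation_time * g_force / g_relax,
    )
    s = model.scatter_fraction(conc)
    if s > 0:
        new_schedule = replace(
            schedule,
            interval_cv=schedule.interval_cv * (1.0 + model.cv_gain * s),
            skip_prob=min(0.9, schedule.skip_prob + model.skip_gain * s),
            irregularity_mode="scattered",
        )
    else:
        new_schedule = schedule
    return new_params, new_schedule


@dataclass(frozen=True)
class ChronotropyModel:
    """Beta-adrenergic / muscarinic frequency modulation."""

    isoprenaline_freq_gain: float = 1.3
    carbachol_reversal: bool = True

    def __post_init__(self) -> None:
        if self.isoprenaline_freq_gain <= 1.0:
            raise ValueError("isoprenaline must raise frequency (gain > 1)")


def apply_chronotropy(schedule: BeatSchedule, model: ChronotropyModel,
                      isoprenaline: bool = False,
                      carbachol: bool = False) -> BeatSchedule:
    """Schedule under isoprenaline and/or subsequent carbachol.

    Isoprenaline multiplies the beat frequency by its gain; carbachol on
    top of isoprenaline reverses the effect back to baseline.
    """
    if isoprenaline and not (carbachol and model.carbachol_reversal):
        return replace(schedule,
                       base_frequency=schedule.base_frequency
                       * model.isoprenaline_freq_gain)
    return schedule


# ---------------------------------------------------------------------------
# presets

DEFAULT_TWITCH = TwitchParams()        # 61 uN, 0.25 s up, 0.35 s down
DEFAULT_SCHEDULE = BeatSchedule()      # 0.5 Hz, cv 0.05, regular
DEFAULT_NOISE_SD = 1.0                 # uN
DEFAULT_DT = 0.01                      # s (100 Hz sampling)
DEFAULT_CALCIUM_MODEL = CalciumResponseModel.from_constraints()

#: phenomenological compound presets; concentrations in nM except where noted
DRUG_MODELS: dict[str, DrugEffectModel] = {
    # hERG-blocker-like reference compound: relaxation slows first, force
    # and rhythm follow at ~10x the concentration
    "e4031_like": DrugEffectModel(
        compound="e4031_like", ic50_relax=5.0, ic50_force=50.0,
        scatter_onset=8.0),
    # inert negative control: no effect at any concentration
    "inactive_control": DrugEffectModel(
        compound="inactive_control", ic50_relax=math.inf,
        ic50_force=math.inf, scatter_onset=math.inf, max_reduction=0.0),
}


def preset_registry() -> dict:
    """JSON-serializable registry of every built-in preset."""
    return {
        "twitch": {"default": asdict(DEFAULT_TWITCH)},
        "schedule": {"default": asdict(DEFAULT_SCHEDULE)},
        "noise_sd_un": DEFAULT_NOISE_SD,
        "dt_s": DEFAULT_DT,
        "calcium": asdict(DEFAULT_CALCIUM_MODEL),
        "drugs": {name: asdict(m) for name, m in DRUG_MODELS.items()},
    }
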