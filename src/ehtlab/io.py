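"""File formats, manifests and the end-to-end pipeline.

Traces are CSV with columns ``time_s, value, value_unit`` (inspectable and
language-neutral); configs, manifests, ground-truth sidecars and reports
are JSON.  A run's report embeds the software version and a hash of the
manifest so any synthetic input can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .dose_response import (BASELINE, DoseResponseExperiment,
                            normalize_to_baseline, threshold_concentration)
from .mechanics import PostGeometry, TissueGeometry
from .rhythm import interdecile_range
from .trace import ContractionTrace
from .twitch import DetectionConfig, RecordingSummary, analyze_trace

__all__ = [
    "read_trace",
    "write_trace",
    "load_geometry",
    "load_manifest",
    "run_pipeline",
    "summary_to_dict",
]

#: relative timing jitter above which a grid is resampled instead of trusted
JITTER_TOLERANCE = 0.01


def write_trace(trace: ContractionTrace, path) -> None:
    df = pd.DataFrame({"time_s": trace.time, "value": trace.value,
                       "value_unit": trace.unit})
    df.to_csv(path, index=False)


def read_trace(path, unit: Optional[str] = None,
               well_id: Optional[str] = None) -> ContractionTrace:
    """Load a trace CSV, validating the uniform time grid.

    The unit comes from the ``value_unit`` column (or the ``unit``
    argument, which overrides).  Time grids with up to 1 % jitter are
    resampled onto a uniform grid and flagged; non-monotone time or a
    missing unit is a format error.
    """
    df = pd.read_csv(path)
    required = {"time_s", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"trace CSV needs columns {sorted(required)}")
    if unit is None:
        if "value_unit" not in df.columns or df["value_unit"].isna().all():
            raise ValueError("no unit declared (value_unit column missing)")
        unit = str(df["value_unit"].iloc[0])
    time = df["time_s"].to_numpy(dtype=float)
    value = df["value"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("time column must be strictly increasing")
    dt_med = float(np.median(np.diff(time)))
    flags = []
    jitter = np.max(np.abs(np.diff(time) - dt_med)) / dt_med
    if jitter > JITTER_TOLERANCE:
        raise ValueError(f"time grid jitter {jitter:.1%} is too large")
    if jitter > 1e-6:
        uniform = time[0] + dt_med * np.arange(time.size)
        value = np.interp(uniform, time, value)
        time = uniform
        flags.append("resampled_jittered_grid")
    name = well_id if well_id is not None else Path(path).stem
    return ContractionTrace(time=time, value=value, unit=unit,
                            well_id=name, flags=flags)


def load_geometry(path) -> tuple[PostGeometry, TissueGeometry]:
    """Geometry JSON block: elastic_modulus_pa, post_radius_mm,
    post_length_mm, tissue_diameter_mm."""
    with open(path) as fh:
        cfg = json.load(fh)
    post = PostGeometry.from_mm(cfg["elastic_modulus_pa"],
                                cfg["post_radius_mm"], cfg["post_length_mm"])
    tissue = TissueGeometry(cfg.get("tissue_diameter_mm", 0.72))
    return post, tissue


def summary_to_dict(summary: RecordingSummary) -> dict:
    d = {
        "well_id": summary.well_id,
        "n_twitches": summary.n_twitches,
        "mean_force": summary.mean_force,
        "mean_contraction_velocity": summary.mean_contraction_velocity,
        "mean_relaxation_velocity": summary.mean_relaxation_velocity,
        "mean_contraction_time": summary.mean_contraction_time,
        "mean_relaxation_time": summary.mean_relaxation_time,
        "frequency_hz": summary.frequency_hz,
        "frequency_bpm": summary.frequency_bpm,
        "frequency_defined": summary.frequency_defined,
        "beat_intervals_s": [float(x) for x in summary.beat_intervals],
        "flags": list(summary.flags),
    }
    if len(summary.beat_intervals) >= 2:
        sc = interdecile_range(summary.beat_intervals)
        d["rr_scatter"] = {"idr_s": sc.idr, "n": sc.n,
                           "decile_10_s": sc.decile_10,
                           "decile_90_s": sc.decile_90}
    return d


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def load_manifest(path) -> dict:
    with open(path) as fh:
        manifest = json.load(fh)
    manifest.setdefault("baseline", BASELINE)
    manifest.setdefault("recordings", [])
    root = Path(path).parent
    for rec in manifest["recordings"]:
        rec["path"] = str((root / rec["path"]).resolve())
        if not Path(rec["path"]).exists():
            raise FileNotFoundError(rec["path"])
    return manifest


def run_pipeline(manifest: dict, alpha: float = 0.05,
                 cfg: DetectionConfig = DetectionConfig()) -> dict:
    """Analyze every recording in a manifest and assemble the report.

    Per-well failures are recorded under ``errors`` and do not abort the
    run.  When the manifest declares a concentration ladder, the report
    additionally carries the percent-of-baseline table and the threshold
    concentrations for relaxation velocity (paired t) and RR-scatter
    (exact Mann-Whitney).
    """
    geometry = None
    if manifest.get("geometry"):
        g = manifest["geometry"]
        geometry = PostGeometry.from_mm(g["elastic_modulus_pa"],
                                        g["post_radius_mm"],
                                        g["post_length_mm"])
    report: dict = {
        "software": {"name": "ehtlab", "version": __version__},
        "config_hash": _config_hash(manifest),
        "compound": manifest.get("compound"),
        "wells": {},
        "errors": {},
    }
    summaries = {}
    for rec in manifest.get("recordings", []):
        well, cond = rec["well"], rec["condition"]
        try:
            trace = read_trace(rec["path"], unit=rec.get("unit"), well_id=well)
            if not trace.is_force:
                if geometry is None:
                    raise ValueError("deflection trace needs geometry")
                trace = trace.to_force(geometry)
            summary = analyze_trace(trace, cfg)
            if cond != manifest["baseline"]:
                cond = float(cond)
            summaries[(well, cond)] = summary
            report["wells"].setdefault(well, {})[str(cond)] = \
                summary_to_dict(summary)
        except Exception as exc:  # isolate per-well failures
            report["errors"][f"{well}/{cond}"] = str(exc)

    ladder = manifest.get("ladder")
    if ladder and summaries:
        try:
            _add_dose_response(report, manifest, ladder, summaries, alpha)
        except Exception as exc:
            report["errors"]["dose_response"] = str(exc)
    if not manifest.get("recordings"):
        report["warning"] = "empty manifest: nothing to analyze"
    return report


def _add_dose_response(report: dict, manifest: dict, ladder, summaries,
                       alpha: float) -> None:
    # wells whose baseline failed cannot be normalized; drop them here
    with_baseline = {w for (w, c) in summaries if c == manifest["baseline"]}
    summaries = {(w, c): s for (w, c), s in summaries.items()
                 if w in with_baseline}
    exp = DoseResponseExperiment(
        compound=manifest.get("compound", "compound"),
        ladder=[float(c) for c in ladder], summaries=summaries,
        concentration_unit=manifest.get("concentration_unit", ""))
    percent = normalize_to_baseline(exp)
    report["percent_of_baseline"] = {
        f"{w}/{c}": {k: (None if not np.isfinite(v) else v)
                     for k, v in row.items()}
        for (w, c), row in percent.iterrows()}
    thr_t = threshold_concentration(exp, "relaxation_velocity",
                                    procedure="t", alpha=alpha)
    thr_mw = threshold_concentration(exp, procedure="mannwhitney",
                                     alpha=alpha)
    report["thresholds"] = {
        "relaxation_velocity_t": {
            "threshold": thr_t.threshold,
            "p_values": {str(c): p for c, p in thr_t.p_values.items()},
            "caveat": thr_t.caveat},
        "rr_scatter_mannwhitney": {
            "threshold": thr_mw.threshold,
            "p_values": {str(c): p for c, p in thr_mw.p_values.items()},
            "caveat": thr_mw.caveat},
    }
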