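"""Core time-series container for one EHT recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ContractionTrace"]

#: unit tags understood by the I/O layer
FORCE_UNITS = {"uN", "mN", "N"}
DEFLECTION_UNITS = {"um", "mm", "m"}

_TO_UN = {"uN": 1.0, "mN": 1e3, "N": 1e6}
_TO_UM = {"um": 1.0, "mm": 1e3, "m": 1e6}


@dataclass
class ContractionTrace:
    """Uniformly sampled post-deflection or force signal for one well.

    ``value`` carries either force or deflection; ``unit`` says which
    ("uN"/"mN"/"N" or "um"/"mm"/"m").
    """

    time: np.ndarray
    value: np.ndarray
    unit: str = "uN"
    well_id: str = "well"
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.value.shape:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("a trace needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-3, atol=0.0):
            raise ValueError("time grid must be uniform (resample first)")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("trace values must be finite")
        if self.unit not in FORCE_UNITS | DEFLECTION_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def is_force(self) -> bool:
        return self.unit in FORCE_UNITS

    def in_unit(self, unit: str) -> "ContractionTrace":
        """Same trace converted to another unit of the same kind."""
        if self.is_force:
            if unit not in FORCE_UNITS:
                raise ValueError(f"cannot convert force trace to {unit!r}")
            factor = _TO_UN[self.unit] / _TO_UN[unit]
        else:
            if unit not in DEFLECTION_UNITS:
                raise ValueError(f"cannot convert deflection trace to {unit!r}")
            factor = _TO_UM[self.unit] / _TO_UM[unit]
        return replace(self, value=self.value * factor, unit=unit,
                       flags=list(self.flags))

    def to_force(self, geom) -> "ContractionTrace":
        """Deflection trace -> force trace (uN) through the beam formula."""
        from . import mechanics

        if self.is_force:
            return self.in_unit("uN")
        delta_m = self.in_unit("um").value * 1e-6
        force_un = mechanics.force_from_deflection(delta_m, geom) * 1e6
        return replace(self, value=force_un, unit="uN", flags=list(self.flags))

    def to_deflection(self, geom) -> "ContractionTrace":
        """Force trace -> deflection trace (um) through the inverse formula."""
        from . import mechanics

        if not self.is_force:
            return self.in_unit("um")
        force_n = self.in_unit("uN").value * 1e-6
        delta_um = mechanics.deflection_from_force(force_n, geom) * 1e6
        return replace(self, value=delta_um, unit="um", flags=list(self.flags))
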