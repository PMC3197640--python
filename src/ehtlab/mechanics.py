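"""Cantilever-post mechanics for engineered heart tissue (EHT).

An EHT is cast between two elastic silicone posts; contraction bends the
posts toward each other.  For a cylindrical cantilever of elastic modulus
``E``, radius ``R`` and length ``L``, a tip deflection ``delta`` corresponds
to a tip force

    F = 3 * pi * E * R**4 * delta / (4 * L**3)

(small-deflection Euler-Bernoulli beam).  All functions here work in SI
units (N, m, Pa); convenience constructors accept the mm/um scales used in
practice.  Positive deflection means the posts bend toward each other
(contraction), so force traces are non-negative at rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PostGeometry",
    "TissueGeometry",
    "force_from_deflection",
    "deflection_from_force",
    "cross_sectional_stress",
]


@dataclass(frozen=True)
class PostGeometry:
    """Silicone post as a cylindrical cantilever (SI units).

    Attributes
    ----------
    elastic_modulus : float
        Young's modulus E of the silicone, Pa.
    post_radius : float
        Post radius R, m.
    post_length : float
        Post length L (anchor to tissue plane), m.
    """

    elastic_modulus: float
    post_radius: float
    post_length: float

    def __post_init__(self) -> None:
        for name in ("elastic_modulus", "post_radius", "post_length"):
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")

    @classmethod
    def from_mm(cls, elastic_modulus_pa: float, post_radius_mm: float,
                post_length_mm: float) -> "PostGeometry":
        """Build from the mm-scale numbers a lab protocol quotes."""
        return cls(elastic_modulus_pa, post_radius_mm * 1e-3, post_length_mm * 1e-3)

    @property
    def stiffness(self) -> float:
        """Tip stiffness F/delta in N/m: 3*pi*E*R^4 / (4*L^3)."""
        return (3.0 * math.pi * self.elastic_modulus * self.post_radius ** 4
                / (4.0 * self.post_length ** 3))


# Illustrative default; post geometry for human-EHT racks is lab-specific and
# must normally come from the experiment config.
DEFAULT_GEOMETRY = PostGeometry.from_mm(
    elastic_modulus_pa=1.0e6, post_radius_mm=0.5, post_length_mm=10.0
)


@dataclass(frozen=True)
class TissueGeometry:
    """EHT approximated as a circular cylinder; diameter in mm."""

    diameter_mm: float = 0.72

    def __post_init__(self) -> None:
        if not (self.diameter_mm > 0.0 and math.isfinite(self.diameter_mm)):
            raise ValueError(f"diameter must be positive, got {self.diameter_mm!r}")

    @property
    def cross_section_mm2(self) -> float:
        return math.pi * (self.diameter_mm / 2.0) ** 2


def force_from_deflection(delta_m, geom: PostGeometry):
    """Tip force (N) from post deflection (m).

    Accepts scalars or numpy arrays; linear in ``delta_m``, so sign and
    shape pass through.
    """
    return geom.stiffness * delta_m


def deflection_from_force(force_n, geom: PostGeometry):
    """Post deflection (m) from tip force (N) — exact algebraic inverse."""
    return force_n / geom.stiffness


def cross_sectional_stress(force_mn: float, tissue: TissueGeometry) -> float:
    """Force (mN) per tissue cross section, mN/mm^2."""
    return force_mn / tissue.cross_section_mm2
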