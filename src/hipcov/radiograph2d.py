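"""The six radiographic measures of acetabular morphology from named
AP-pelvis landmarks, plus the obturator-index exclusion screen.

Measures: extrusion index (EI), lateral center edge angle (LCEA),
acetabular index (AI), acetabular angle (AA), crossover ratio, and
posterior wall distance (PWD). All are computed relative to an explicit
horizontal reference direction carried with the landmarks; by convention
the reference points from the contralateral toward the ipsilateral side,
so the lateral direction is positive along it for either hip. The
superior direction is the reference rotated +90 degrees (image +y up).

Angles are in degrees, distances in mm. Sign conventions:

* LCEA positive when the lateral sourcil is lateral to the vertical
  through the head center;
* AI / AA positive when the lateral end of the sourcil line is superior
  to its medial anchor (up-sloping);
* PWD positive when the posterior wall crosses the horizontal through
  the head center lateral to it, negative when medial.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._geom import fit_circle, polyline_first_intersection, unit

__all__ = [
    "RadiographLandmarks",
    "RadiographicMeasures",
    "fit_circle",
    "extrusion_index",
    "lcea",
    "acetabular_index",
    "acetabular_angle",
    "crossover_ratio",
    "posterior_wall_distance",
    "obturator_index",
    "measure_all",
]

MEASURE_NAMES = (
    "extrusion_index",
    "crossover_ratio",
    "acetabular_angle",
    "acetabular_index",
    "lcea",
    "posterior_wall_distance",
)


@dataclass
class RadiographLandmarks:
    """Named 2D landmarks (mm) digitized or simulated on an AP pelvis film."""

    head_center: np.ndarray
    head_radius: float
    lateral_sourcil: np.ndarray
    medial_sourcil: np.ndarray
    teardrop: np.ndarray
    teardrop_contralateral: np.ndarray
    lateral_rim: np.ndarray
    anterior_wall: np.ndarray  # polyline, ordered lateral -> medial
    posterior_wall: np.ndarray  # polyline, ordered lateral -> medial
    obturator_width_ipsi: float
    obturator_width_contra: float
    horizontal_ref: np.ndarray  # unit, contralateral -> ipsilateral
    side: str = "right"

    def __post_init__(self):
        for name in (
            "head_center",
            "lateral_sourcil",
            "medial_sourcil",
            "teardrop",
            "teardrop_contralateral",
            "lateral_rim",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.anterior_wall = np.asarray(self.anterior_wall, dtype=float)
        self.posterior_wall = np.asarray(self.posterior_wall, dtype=float)
        self.horizontal_ref = unit(np.asarray(self.horizontal_ref, dtype=float))
        if self.head_radius <= 0:
            raise ValueError("head radius must be positive")
        if len(self.anterior_wall) < 2 or len(self.posterior_wall) < 2:
            raise ValueError("wall polylines need at least 2 points")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    # -- frame helpers ----------------------------------------------------
    @property
    def lateral(self) -> np.ndarray:
        """Unit in-image direction pointing laterally for this hip."""
        return self.horizontal_ref

    @property
    def superior(self) -> np.ndarray:
        """Unit in-image superior direction: the horizontal reference
        rotated a quarter turn, with the sense set by ``side`` (for a
        right hip, lateral-to-superior is counterclockwise; a mirrored
        left-hip image has the opposite handedness)."""
        h = self.horizontal_ref
        v = np.array([-h[1], h[0]])
        return v if self.side == "right" else -v

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "head_circle": {
                "center": self.head_center.tolist(),
                "radius": float(self.head_radius),
            },
            "lateral_sourcil": self.lateral_sourcil.tolist(),
            "medial_sourcil": self.medial_sourcil.tolist(),
            "teardrop": self.teardrop.tolist(),
            "teardrop_contralateral": self.teardrop_contralateral.tolist(),
            "lateral_rim": self.lateral_rim.tolist(),
            "anterior_wall": self.anterior_wall.tolist(),
            "posterior_wall": self.posterior_wall.tolist(),
            "obturator_width_ipsi": float(self.obturator_width_ipsi),
            "obturator_width_contra": float(self.obturator_width_contra),
            "horizontal_ref": self.horizontal_ref.tolist(),
            "side": self.side,
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RadiographLandmarks":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(
            head_center=obj["head_circle"]["center"],
            head_radius=obj["head_circle"]["radius"],
            lateral_sourcil=obj["lateral_sourcil"],
            medial_sourcil=obj["medial_sourcil"],
            teardrop=obj["teardrop"],
            teardrop_contralateral=obj["teardrop_contralateral"],
            lateral_rim=obj["lateral_rim"],
            anterior_wall=obj["anterior_wall"],
            posterior_wall=obj["posterior_wall"],
            obturator_width_ipsi=obj["obturator_width_ipsi"],
            obturator_width_contra=obj["obturator_width_contra"],
            horizontal_ref=obj["horizontal_ref"],
            side=obj.get("side", "right"),
        )


@dataclass
class RadiographicMeasures:
    extrusion_index: float
    crossover_ratio: Optional[float]
    acetabular_angle: float
    acetabular_index: float
    lcea: float
    posterior_wall_distance: float
    obturator_index: float
    obturator_pass: bool

    def as_dict(self) -> dict:
        return {
            "extrusion_index": self.extrusion_index,
            "crossover_ratio": self.crossover_ratio,
            "acetabular_angle": self.acetabular_angle,
            "acetabular_index": self.acetabular_index,
            "lcea": self.lcea,
            "posterior_wall_distance": self.posterior_wall_distance,
            "obturator_index": self.obturator_index,
            "obturator_pass": self.obturator_pass,
        }


# ---------------------------------------------------------------------------


def extrusion_index(lm: RadiographLandmarks) -> float:
    """Uncovered lateral head width divided by the head diameter.

    ``a`` is the horizontal distance from the lateral sourcil to the
    lateral edge of the femoral head (clamped at zero when the sourcil
    overhangs the head)."""
    h = lm.lateral
    edge = lm.head_center @ h + lm.head_radius
    a = max(0.0, edge - lm.lateral_sourcil @ h)
    return a / (2.0 * lm.head_radius)


def lcea(lm: RadiographLandmarks) -> float:
    """Lateral center edge angle (degrees).

    Angle between the vertical through the head center and the ray from
    the head center to the lateral sourcil; positive laterally."""
    w = lm.lateral_sourcil - lm.head_center
    if np.linalg.norm(w) < 1e-12:
        raise ValueError("lateral sourcil coincides with head center")
    return float(np.degrees(np.arctan2(w @ lm.lateral, w @ lm.superior)))


def _elevation_angle(lm: RadiographLandmarks, anchor, tip) -> float:
    w = np.asarray(tip, float) - np.asarray(anchor, float)
    if np.linalg.norm(w) < 1e-12:
        raise ValueError("coincident landmark points")
    return float(np.degrees(np.arctan2(w @ lm.superior, w @ lm.lateral)))


def acetabular_index(lm: RadiographLandmarks) -> float:
    """Slope (degrees) of the medial-to-lateral sourcil line relative to
    the horizontal reference; positive when up-sloping laterally."""
    return _elevation_angle(lm, lm.medial_sourcil, lm.lateral_sourcil)


def acetabular_angle(lm: RadiographLandmarks) -> float:
    """Slope (degrees) of the teardrop-to-lateral-sourcil line relative to
    the horizontal reference; positive superiorly."""
    return _elevation_angle(lm, lm.teardrop, lm.lateral_sourcil)


def crossover_ratio(lm: RadiographLandmarks) -> Optional[float]:
    """Crossover ratio, or None when the walls do not cross.

    The first intersection of the anterior and posterior wall polylines,
    walking the anterior wall from its lateral end, marks the crossover
    point; the ratio is its distance from the lateral rim over the
    acetabular diameter (lateral rim to teardrop)."""
    if len(lm.anterior_wall) < 2 or len(lm.posterior_wall) < 2:
        raise ValueError("wall polylines need at least 2 points")
    xpt = polyline_first_intersection(lm.anterior_wall, lm.posterior_wall)
    if xpt is None:
        return None
    a = float(np.linalg.norm(lm.lateral_rim - xpt))
    b = float(np.linalg.norm(lm.lateral_rim - lm.teardrop))
    if b == 0:
        raise ValueError("degenerate acetabular diameter")
    return a / b


def posterior_wall_distance(lm: RadiographLandmarks) -> float:
    """Signed horizontal distance (mm) from the head center to the point
    where the posterior wall crosses the horizontal line through the head
    center; lateral positive. With several crossings the most lateral one
    is used."""
    h = lm.lateral
    v = lm.superior
    wall = lm.posterior_wall
    y = (wall - lm.head_center) @ v
    x = (wall - lm.head_center) @ h
    crossings = []
    for i in range(len(wall) - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 == y1 == 0.0:
            crossings.extend([x[i], x[i + 1]])
        elif (y0 <= 0.0 <= y1) or (y1 <= 0.0 <= y0):
            t = y0 / (y0 - y1) if y0 != y1 else 0.0
            crossings.append(x[i] + t * (x[i + 1] - x[i]))
    if not crossings:
        raise ValueError(
            "posterior wall does not cross the horizontal through the head center"
        )
    return float(max(crossings))


def obturator_index(lm: RadiographLandmarks) -> tuple[float, bool]:
    """Ratio of ipsilateral to contralateral obturator foramen width and
    whether the film passes the 0.8--1.2 adequacy screen (inclusive)."""
    if lm.obturator_width_ipsi <= 0 or lm.obturator_width_contra <= 0:
        raise ValueError("obturator widths must be positive")
    ratio = float(lm.obturator_width_ipsi / lm.obturator_width_contra)
    return ratio, bool(0.8 <= ratio <= 1.2)


def measure_all(lm: RadiographLandmarks) -> RadiographicMeasures:
    """All six measures plus the obturator screen for one hip."""
    oi, ok = obturator_index(lm)
    return RadiographicMeasures(
        extrusion_index=extrusion_index(lm),
        crossover_ratio=crossover_ratio(lm),
        acetabular_angle=acetabular_angle(lm),
        acetabular_index=acetabular_index(lm),
        lcea=lcea(lm),
        posterior_wall_distance=posterior_wall_distance(lm),
        obturator_index=oi,
        obturator_pass=ok,
    )
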