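"""Insole sensor-array geometry.

The insole carries 16 discrete pressure cells grouped into four functional
zones: rearfoot (sensors 1-4, initial contact and lateral stability), midfoot
(5-8, transition), forefoot (9-13, the five metatarsal heads, propulsion) and
toes (14-16, end of propulsion).

Coordinate convention
---------------------
Origin at the posterior-medial corner of the insole bounding box; X (mm)
increases anteriorly, i.e. heel -> toe, and Y (mm) increases laterally.
Areas are in cm^2 so that pressure (N cm^-2) times area gives force in N.

Right insoles use a strictly mirrored numbering convention: sensor *i* on a
right insole sits at the medio-laterally mirrored position of sensor *i* on
the left insole. :func:`mirror_layout` converts between the two, so a single
left-handed coordinate frame can govern all pooled analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

ZONES = ("rearfoot", "midfoot", "forefoot", "toes")

#: Sensor id -> functional zone (ids 1-4 rearfoot, 5-8 midfoot,
#: 9-13 forefoot / metatarsal heads, 14-16 toes).
ZONE_OF_SENSOR = {
    **{i: "rearfoot" for i in range(1, 5)},
    **{i: "midfoot" for i in range(5, 9)},
    **{i: "forefoot" for i in range(9, 14)},
    **{i: "toes" for i in range(14, 17)},
}

N_SENSORS = 16

_DEFAULT_LAYOUT_RESOURCE = "left_layout_synthetic.yaml"


class LayoutError(ValueError):
    """Raised when a sensor layout violates its structural invariants."""


@dataclass(frozen=True)
class SensorSpec:
    """One pressure cell: identity, anatomy and geometry."""

    sensor_id: int
    label: str
    zone: str
    centroid_x: float  # mm, antero-posterior axis
    centroid_y: float  # mm, medio-lateral axis
    area: float  # cm^2

    def __post_init__(self) -> None:
        if not 1 <= self.sensor_id <= N_SENSORS:
            raise LayoutError(f"sensor_id {self.sensor_id} outside 1..{N_SENSORS}")
        if self.zone not in ZONES:
            raise LayoutError(f"unknown zone {self.zone!r}")
        if self.zone != ZONE_OF_SENSOR[self.sensor_id]:
            raise LayoutError(
                f"sensor {self.sensor_id} assigned zone {self.zone!r}, "
                f"expected {ZONE_OF_SENSOR[self.sensor_id]!r}"
            )
        if not self.area > 0:
            raise LayoutError(f"sensor {self.sensor_id}: area must be > 0")


@dataclass(frozen=True)
class InsoleLayout:
    """A complete 16-sensor insole, one physical size and side."""

    side: str  # "left" or "right"
    size_variant: str  # e.g. "42-43" (EU)
    length: float  # mm, antero-posterior extent of the bounding box
    width: float  # mm, medio-lateral extent
    sensors: tuple[SensorSpec, ...]

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise LayoutError(f"side must be 'left' or 'right', got {self.side!r}")
        if not (self.length > self.width > 0):
            raise LayoutError("require length > width > 0")
        ids = [s.sensor_id for s in self.sensors]
        if sorted(ids) != list(range(1, N_SENSORS + 1)):
            raise LayoutError(
                f"layout must contain exactly sensors 1..{N_SENSORS}, got ids {sorted(ids)}"
            )
        for s in self.sensors:
            if not (0 <= s.centroid_x <= self.length and 0 <= s.centroid_y <= self.width):
                raise LayoutError(
                    f"sensor {s.sensor_id} centroid ({s.centroid_x}, {s.centroid_y}) "
                    "outside the insole bounding box"
                )
        # canonical storage order: by sensor id
        object.__setattr__(
            self, "sensors", tuple(sorted(self.sensors, key=lambda s: s.sensor_id))
        )

    # -- array views (ordered by sensor id 1..16) ---------------------------

    def centroids(self) -> np.ndarray:
        """(16, 2) array of (x, y) centroids in mm."""
        return np.array(
            [[s.centroid_x, s.centroid_y] for s in self.sensors], dtype=float
        )

    def areas(self) -> np.ndarray:
        """(16,) array of areas in cm^2."""
        return np.array([s.area for s in self.sensors], dtype=float)

    def sensor(self, sensor_id: int) -> SensorSpec:
        return self.sensors[sensor_id - 1]

    def zone_ids(self, zone: str) -> tuple[int, ...]:
        return tuple(s.sensor_id for s in self.sensors if s.zone == zone)


def load_layout(path: str | Path | None = None) -> InsoleLayout:
    """Read an insole layout from a YAML file and validate it.

    With ``path=None`` the bundled default left layout is loaded. The bundled
    geometry is a synthetic but anatomically plausible fixture (the vendor
    does not publish cell coordinates); zones follow the standard 4/4/5/3
    rearfoot/midfoot/forefoot/toes partition.
    """
    if path is None:
        ref = resources.files("solecop.data") / _DEFAULT_LAYOUT_RESOURCE
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        rows = raw["sensors"]
        sensors = tuple(
            SensorSpec(
                sensor_id=int(r["id"]),
                label=str(r["label"]),
                zone=str(r["zone"]),
                centroid_x=float(r["x_mm"]),
                centroid_y=float(r["y_mm"]),
                area=float(r["area_cm2"]),
            )
            for r in rows
        )
        return InsoleLayout(
            side=str(raw["side"]),
            size_variant=str(raw["size_variant"]),
            length=float(raw["length_mm"]),
            width=float(raw["width_mm"]),
            sensors=sensors,
        )
    except (KeyError, TypeError) as exc:
        raise LayoutError(f"malformed layout file: {exc}") from exc


def default_layout(side: str = "left") -> InsoleLayout:
    """Bundled default layout, mirrored on demand for the right foot."""
    left = load_layout(None)
    return left if side == "left" else mirror_layout(left)


def mirror_layout(layout: InsoleLayout) -> InsoleLayout:
    """Reflect a layout across the insole midline (left <-> right).

    Sensor ids, labels, X coordinates and areas are preserved; every
    centroid_y maps to ``width - centroid_y``. The operation is an involution.
    """
    flipped = tuple(
        dataclasses.replace(s, centroid_y=layout.width - s.centroid_y)
        for s in layout.sensors
    )
    other = "right" if layout.side == "left" else "left"
    return dataclasses.replace(layout, side=other, sensors=flipped)


def posterior_anterior_thirds(layout: InsoleLayout) -> tuple[float, float]:
    """X boundaries (mm) splitting the insole into posterior/middle/anterior
    thirds; a physiological roll-over starts below the first and ends above
    the second."""
    return layout.length / 3.0, 2.0 * layout.length / 3.0


def sensor_ids(subset: Iterable[int] | None = None) -> tuple[int, ...]:
    """Normalized, sorted tuple of sensor ids (all 16 when ``subset`` is None)."""
    if subset is None:
        return tuple(range(1, N_SENSORS + 1))
    ids = tuple(sorted(set(int(i) for i in subset)))
    if not ids or ids[0] < 1 or ids[-1] > N_SENSORS:
        raise LayoutError(f"sensor ids must be a non-empty subset of 1..{N_SENSORS}")
    return ids
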