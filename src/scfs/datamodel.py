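"""Domain types: force curves, force maps, rupture events, pooled datasets.

A force curve is one approach/dwell/retract cycle of the piezo with the
cantilever deflection sampled at constant rate.  Sign conventions:

* deflection is positive when the cantilever is pushed away from the surface
  (repulsive); adhesive deflection during retract is negative;
* ``z_position`` is piezo extension, larger = closer to the sample, so it
  increases during approach and decreases during retract;
* rupture step heights and forces are reported as positive magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K
from .errors import ValidationError

__all__ = [
    "CurveMetadata",
    "ForceCurve",
    "ForceMap",
    "RuptureEvent",
    "ConditionDataset",
    "pool_condition",
    "SEGMENTS",
]

SEGMENTS = ("approach", "dwell", "retract")


@dataclass
class CurveMetadata:
    """Acquisition settings attached to one force curve.

    Units: ``spring_constant_k`` pN/nm, ``velocity_v`` um/s, ``max_load`` pN,
    ``dwell_time`` s, ``sampling_rate`` Hz, ``temperature`` K.
    """

    spring_constant_k: float = 60.0
    velocity_v: float = 3.0
    max_load: float = 3000.0
    dwell_time: float = 2.0
    sampling_rate: float = 2000.0
    temperature: float = DEFAULT_TEMPERATURE_K
    condition_label: str = "NF-NF"
    treatment_label: str = "none"
    curve_id: str = "curve0"

    def validate(self) -> None:
        if not self.spring_constant_k > 0:
            raise ValidationError("spring_constant_k must be > 0")
        if not self.velocity_v > 0:
            raise ValidationError("velocity_v must be > 0")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.dwell_time < 0:
            raise ValidationError("dwell_time must be >= 0")


@dataclass
class ForceCurve:
    """One sampled approach/dwell/retract cycle.

    ``segment_labels`` holds one of ``approach``/``dwell``/``retract`` per
    sample.  All arrays have equal length and ``time`` is strictly increasing.
    """

    time: np.ndarray
    z_position: np.ndarray
    deflection: np.ndarray
    segment_labels: np.ndarray
    metadata: CurveMetadata

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z_position = np.asarray(self.z_position, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        self.segment_labels = np.asarray(self.segment_labels, dtype=object)

    def validate(self) -> None:
        n = len(self.time)
        for name in ("z_position", "deflection", "segment_labels"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"array length mismatch: {name} has {len(getattr(self, name))}, time has {n}"
                )
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time must be strictly increasing")
        unknown = set(np.unique(self.segment_labels)) - set(SEGMENTS)
        if unknown:
            raise ValidationError(f"unknown segment labels: {sorted(unknown)}")
        if not np.any(self.segment_labels == "retract"):
            raise ValidationError("retract segment is empty")
        zr = self.z_position[self.segment_labels == "retract"]
        if len(zr) > 1 and np.any(np.diff(zr) > 0):
            raise ValidationError("z_position must be non-increasing during retract")
        self.metadata.validate()

    def segment(self, label: str) -> np.ndarray:
        """Boolean mask selecting one segment."""
        return self.segment_labels == label

    @property
    def retract_indices(self) -> np.ndarray:
        return np.flatnonzero(self.segment_labels == "retract")

    def force(self) -> np.ndarray:
        """Deflection converted to force, pN (F = k * d)."""
        return self.metadata.spring_constant_k * self.deflection


@dataclass
class ForceMap:
    """An ordered collection of force curves recorded over one region.

    One map holds 24 curves by default and all curves share a condition label.
    """

    curves: list[ForceCurve] = field(default_factory=list)
    map_id: str = "map0"

    def validate(self) -> None:
        labels = {c.metadata.condition_label for c in self.curves}
        if len(labels) > 1:
            raise ValidationError(f"curves in one map must share a condition label, got {sorted(labels)}")
        for c in self.curves:
            c.validate()

    def __len__(self) -> int:
        return len(self.curves)


@dataclass(frozen=True)
class RuptureEvent:
    """A detected (or ground-truth) discontinuity in a retract curve.

    ``index`` is the sample index *within the retract segment* of the first
    post-step sample.  ``force_F`` equals ``step_height_d`` times the parent
    curve's spring constant, exactly.  ``event_class`` is ``jump`` (loaded
    ramp before the drop: a receptor-bond rupture) or ``tether`` (flat force
    plateau before the drop: a membrane tether detaching).
    """

    curve_id: str
    index: int
    separation_nm: float
    step_height_d: float
    force_F: float
    event_class: str
    loading_rate_r: float
    pre_slope: float

    def __post_init__(self) -> None:
        if self.event_class not in ("jump", "tether"):
            raise ValidationError(f"event_class must be jump|tether, got {self.event_class!r}")


@dataclass
class ConditionDataset:
    """Pooled jump rupture forces for one pairing x velocity x treatment."""

    condition_label: str
    treatment_label: str
    velocity_v: float
    rupture_forces: np.ndarray
    n_curves: int = 0
    n_maps: int = 0

    def __post_init__(self) -> None:
        self.rupture_forces = np.asarray(self.rupture_forces, dtype=float)

    def validate(self) -> None:
        if self.rupture_forces.size and not np.all(self.rupture_forces > 0):
            raise ValidationError("rupture forces must all be > 0")

    @property
    def n(self) -> int:
        return int(self.rupture_forces.size)


def pool_condition(
    events: Iterable[RuptureEvent],
    label: str,
    treatment: str,
    v: float,
    n_maps: int = 0,
) -> ConditionDataset:
    """Pool the jump-class rupture forces of a condition into one dataset.

    Tether-class events are excluded: rupture-force statistics are computed
    from bond-rupture jumps only.  An empty pool is allowed (it models the
    calcium-depleted regime where specific binding is abolished).
    """
    events = list(events)
    jumps = [e for e in events if e.event_class == "jump"]
    forces = np.array([e.force_F for e in jumps], dtype=float)
    n_curves = len({e.curve_id for e in events})
    ds = ConditionDataset(
        condition_label=label,
        treatment_label=treatment,
        velocity_v=v,
        rupture_forces=forces,
        n_curves=n_curves,
        n_maps=n_maps,
    )
    ds.validate()
    return ds
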