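"""Domain containers: sagittal anatomy, shift vectors, fractions and cohorts.

A *fraction* pairs a patient's planning anatomy with one pretreatment
anatomy and the reference clinical-target-volume (CTV) translation between
them, which is the quantity the regression models learn to predict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Contour, GeometryError

ORGAN_NAMES = ("bladder", "rectum", "prostate", "ctv", "bone")


@dataclass(frozen=True)
class ShiftVector:
    """Translation in mm; positive = left (LR), superior (SI), anterior (AP).

    LR is carried for completeness but excluded from modelling: on bone-
    registered sagittal imaging lateral target motion is negligible.
    """

    lr: float
    si: float
    ap: float

    def __post_init__(self) -> None:
        for v in (self.lr, self.si, self.ap):
            if not math.isfinite(v):
                raise ValueError("shift components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.lr, self.si, self.ap])


@dataclass
class SagittalAnatomy:
    """Closed organ contours in a common sagittal frame (mm, isocenter origin).

    The CTV is the prostate plus the seminal-vesicle region, so the
    prostate contour must lie inside it.  The rectum sits posterior to the
    pubic bone; this is asserted against the bone's superior-posterior
    vertex.  ``gas_region`` is an optional pocket of rectal gas (affects
    only rasterized grey values, never the wall contours).
    """

    bladder: Contour
    rectum: Contour
    prostate: Contour
    ctv: Contour
    bone: Contour
    gas_region: Optional[Contour] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.ctv.polygon.buffer(1e-9).contains(self.prostate.polygon):
            raise GeometryError("prostate contour must lie inside the CTV contour")
        # superior-posterior bone edge: vertex maximizing s - a
        verts = self.bone.vertices
        s_vertex = verts[np.argmax(verts[:, 1] - verts[:, 0])]
        if self.rectum.centroid().a >= s_vertex[0]:
            raise GeometryError("rectum centroid must be posterior to bone landmark S")
        for name in ORGAN_NAMES:
            if getattr(self, name).area <= 1.0:
                raise GeometryError(f"{name} contour is degenerate")

    def organs(self) -> dict[str, Contour]:
        d = {name: getattr(self, name) for name in ORGAN_NAMES}
        if self.gas_region is not None:
            d["gas_region"] = self.gas_region
        return d

    def translated(self, da: float, ds: float) -> "SagittalAnatomy":
        """Rigidly translate every contour (bone included)."""
        return SagittalAnatomy(
            **{k: c.translated(da, ds) for k, c in self.organs().items()}
        )


@dataclass
class LatentState:
    """Unobserved anatomical drivers of one fraction's variation.

    u: upper-rectal filling, v: lower-rectal filling, w: bladder filling
    (all unitless standard-normal draws); ``gas`` flags a rectal gas pocket.
    """

    u: float = 0.0
    v: float = 0.0
    w: float = 0.0
    gas: bool = False


@dataclass
class FractionRecord:
    """One treatment fraction: planning vs pretreatment anatomy + reference shift.

    ``reference_shift`` is, by generator bookkeeping, exactly the rigid
    translation applied to the CTV between the two anatomies.
    """

    patient_id: str
    fraction_index: int
    planning: SagittalAnatomy
    pretreatment: SagittalAnatomy
    reference_shift: ShiftVector
    latent_state: LatentState = field(default_factory=LatentState)


@dataclass
class Patient:
    patient_id: str
    planning: SagittalAnatomy
    fractions: list[FractionRecord]


@dataclass
class Cohort:
    """Patients x fractions of paired anatomies with reference shifts."""

    patients: list[Patient]
    seed: Optional[int] = None
    params_digest: Optional[str] = None

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_fractions(self) -> int:
        return sum(len(p.fractions) for p in self.patients)

    def all_fractions(self) -> list[FractionRecord]:
        return [f for p in self.patients for f in p.fractions]
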