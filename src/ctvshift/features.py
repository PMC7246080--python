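"""Pubic-bone-relative anatomical features for CTV-shift prediction.

All measurements are made on the sagittal plane relative to two fixed
skeletal landmarks: feature point S, the superior-posterior edge of the
pubic bone, and feature point I, its inferior-posterior edge.  Because the
planning and pretreatment images are bone-registered before measurement,
distances taken from S and I are invariant to patient setup and only
reflect soft-tissue change.

Seven distances d1-d7 are measured per image:

  d1  S to the top of the bladder's posterior convexity (Euclidean)
  d2  S to the bladder superior wall along the SI axis through S
  d3  S to the rectal anterior wall along the AP axis through S
  d4  rectal diameter on that same AP axis
  d5  I to the rectal anterior wall along the AP axis through I
  d6  rectal diameter on that same AP axis
  d7  d6 - d4 (a rectal-shape index)

The nine between-image features are f_l = d_l(pretreatment) - d_l(planning)
for l = 1..7, plus f8/f9: the SI and AP displacement of the prostate
center, taken as the midpoint of the prostate's SI and AP extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .anatomy import Cohort, FractionRecord, SagittalAnatomy
from .geometry import (
    Contour,
    GeometryError,
    Point2D,
    horizontal_line_crossings,
    vertical_line_crossings,
)

FEATURE_COLUMNS = [f"f{i}" for i in range(1, 10)]


class FeatureNotMeasurable(GeometryError):
    """A required line-organ intersection does not exist; names the distance."""

    def __init__(self, distance: str, detail: str):
        super().__init__(f"{distance} not measurable: {detail}")
        self.distance = distance


@dataclass(frozen=True)
class FeaturePoints:
    """Skeletal landmarks: S (superior-posterior) and I (inferior-posterior) bone edges."""

    S: Point2D
    I: Point2D


@dataclass(frozen=True)
class DistanceSet:
    """The seven per-image distances in mm; d7 = d6 - d4 may be negative."""

    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    d6: float
    d7: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("distances must be finite")
        if np.any(vals[:6] < 0):
            raise ValueError("d1-d6 must be non-negative")
        if abs(self.d7 - (self.d6 - self.d4)) > 1e-9:
            raise ValueError("d7 must equal d6 - d4")

    def as_array(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3, self.d4, self.d5, self.d6, self.d7])


@dataclass(frozen=True)
class FeatureVector:
    """The nine between-image features in mm (pretreatment minus planning)."""

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: float
    f9: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in FEATURE_COLUMNS])


def locate_feature_points(bone: Contour) -> FeaturePoints:
    """Locate landmarks S and I on the pubic-bone contour.

    S is the vertex maximizing (s - a), i.e. the most superior-posterior
    corner; I maximizes (-s - a).  Ties prefer the more superior vertex for
    S, the more inferior vertex for I, then the more posterior (smaller a).
    """
    v = bone.vertices
    S = _argbest(v, primary=v[:, 1] - v[:, 0], tie1=v[:, 1], tie2=-v[:, 0])
    I = _argbest(v, primary=-v[:, 1] - v[:, 0], tie1=-v[:, 1], tie2=-v[:, 0])
    return FeaturePoints(S=Point2D(*S), I=Point2D(*I))


def _argbest(vertices: np.ndarray, primary: np.ndarray, tie1: np.ndarray,
             tie2: np.ndarray) -> np.ndarray:
    order = np.lexsort((tie2, tie1, primary))
    return vertices[order[-1]]


def prostate_center(prostate: Contour) -> Point2D:
    """Midpoint of the prostate's axis-aligned AP and SI extents (the COP)."""
    min_a, min_s, max_a, max_s = prostate.bounds()
    return Point2D((min_a + max_a) / 2.0, (min_s + max_s) / 2.0)


def _posterior_bladder_point(bladder: Contour) -> Point2D:
    """Most-posterior bladder boundary vertex; ties broken toward superior."""
    v = bladder.vertices
    best = _argbest(v, primary=-v[:, 0], tie1=v[:, 1], tie2=np.zeros(len(v)))
    return Point2D(*best)


def _rectal_wall_and_diameter(rectum: Contour, point: Point2D, label: str) -> tuple[float, float]:
    """(distance point->anterior wall, rectal diameter) on the AP line through ``point``.

    With more than two crossings (non-convex wall) the outermost pair is
    used: the anterior wall is the outer anterior boundary and the diameter
    the full AP span, matching how a reader would place calipers.
    """
    crossings = horizontal_line_crossings(rectum, point.s)
    if crossings.size < 2:
        raise FeatureNotMeasurable(label, f"AP line s={point.s:.2f} misses the rectum")
    anterior, posterior = crossings.max(), crossings.min()
    dist = point.a - anterior
    if dist < 0:
        raise FeatureNotMeasurable(label, "rectal anterior wall lies anterior to the landmark")
    return dist, anterior - posterior


def measure_distances(anatomy: SagittalAnatomy, points: FeaturePoints,
                      click_noise_sd: float = 0.0,
                      rng: Optional[np.random.Generator] = None) -> DistanceSet:
    """Measure d1-d7 on one anatomy relative to landmarks S and I.

    ``click_noise_sd`` adds i.i.d. Gaussian noise (mm, per coordinate) to
    each measured soft-tissue point, mimicking manual caliper placement by
    different professionals; the skeletal landmarks themselves are exact
    because they are fixed by the bone registration.
    """
    S, I = points.S, points.I
    if click_noise_sd < 0:
        raise ValueError("click_noise_sd must be >= 0")
    if click_noise_sd > 0 and rng is None:
        rng = np.random.default_rng()

    def jitter(value: float) -> float:
        return value + (rng.normal(0.0, click_noise_sd) if click_noise_sd > 0 else 0.0)

    # d1: S to top of the bladder posterior convexity (Euclidean)
    p_post = _posterior_bladder_point(anatomy.bladder)
    d1 = math.hypot(jitter(p_post.a) - S.a, jitter(p_post.s) - S.s)

    # d2: SI line through S up to the bladder superior wall
    cross = vertical_line_crossings(anatomy.bladder, S.a)
    if cross.size == 0:
        raise FeatureNotMeasurable("d2", f"SI line a={S.a:.2f} misses the bladder")
    top = cross.max()
    if top < S.s:
        raise FeatureNotMeasurable("d2", "bladder superior wall lies inferior to S")
    d2 = jitter(top) - S.s
    d2 = max(d2, 0.0)

    d3, d4 = _rectal_wall_and_diameter(anatomy.rectum, S, "d3/d4")
    d5, d6 = _rectal_wall_and_diameter(anatomy.rectum, I, "d5/d6")
    if click_noise_sd > 0:
        d3 = max(jitter(d3), 0.0)
        d4 = max(jitter(d4), 0.0)
        d5 = max(jitter(d5), 0.0)
        d6 = max(jitter(d6), 0.0)
    return DistanceSet(d1=d1, d2=d2, d3=d3, d4=d4, d5=d5, d6=d6, d7=d6 - d4)


def compute_features(planning_d: DistanceSet, pretreatment_d: DistanceSet,
                     cop_planning: Point2D, cop_pretreatment: Point2D) -> FeatureVector:
    """f_l = d_l(pretreatment) - d_l(planning), plus prostate-center offsets f8 (SI), f9 (AP)."""
    diff = pretreatment_d.as_array() - planning_d.as_array()
    # f7 recomputed from f6 - f4 so the identity holds to the last bit
    diff[6] = diff[5] - diff[3]
    return FeatureVector(*diff,
                         f8=cop_pretreatment.s - cop_planning.s,
                         f9=cop_pretreatment.a - cop_planning.a)


def extract_fraction_features(record: FractionRecord, click_noise_sd: float = 0.0,
                              rng: Optional[np.random.Generator] = None,
                              cop_click_noise_sd: Optional[float] = None) -> FeatureVector:
    """Extract the nine features for one fraction.

    Landmarks are located on each image's own bone contour; after bone
    registration these coincide, so the distances are directly comparable.
    ``cop_click_noise_sd`` (default: same as ``click_noise_sd``) governs the
    prostate-center click, which is markedly less reproducible than wall
    clicks on low-contrast pretreatment images.
    """
    if cop_click_noise_sd is None:
        cop_click_noise_sd = click_noise_sd
    if (click_noise_sd > 0 or cop_click_noise_sd > 0) and rng is None:
        rng = np.random.default_rng()
    pts_p = locate_feature_points(record.planning.bone)
    pts_c = locate_feature_points(record.pretreatment.bone)
    d_p = measure_distances(record.planning, pts_p, click_noise_sd, rng)
    d_c = measure_distances(record.pretreatment, pts_c, click_noise_sd, rng)
    cop_p = prostate_center(record.planning.prostate)
    cop_c = prostate_center(record.pretreatment.prostate)
    if cop_click_noise_sd > 0:
        cop_p = Point2D(cop_p.a + rng.normal(0, cop_click_noise_sd),
                        cop_p.s + rng.normal(0, cop_click_noise_sd))
        cop_c = Point2D(cop_c.a + rng.normal(0, cop_click_noise_sd),
                        cop_c.s + rng.normal(0, cop_click_noise_sd))
    return compute_features(d_p, d_c, cop_p, cop_c)


def extract_cohort_features(cohort: Cohort, click_noise_sd: float = 0.0,
                            seed: Optional[int] = None,
                            cop_click_noise_sd: Optional[float] = None) -> pd.DataFrame:
    """Feature table for a whole cohort.

    Returns one row per fraction with columns ``patient_id, fraction,
    f1..f9, si, ap`` (reference shift components in mm).
    """
    if cop_click_noise_sd is None:
        cop_click_noise_sd = click_noise_sd
    rng = np.random.default_rng(seed) if (click_noise_sd > 0 or cop_click_noise_sd > 0) else None
    rows = []
    for rec in cohort.all_fractions():
        fv = extract_fraction_features(rec, click_noise_sd, rng, cop_click_noise_sd)
        row = {"patient_id": rec.patient_id, "fraction": rec.fraction_index}
        row.update(dict(zip(FEATURE_COLUMNS, fv.as_array())))
        row["si"] = rec.reference_shift.si
        row["ap"] = rec.reference_shift.ap
        rows.append(row)
    return pd.DataFrame(rows)
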