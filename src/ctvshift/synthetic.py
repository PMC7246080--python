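"""Synthetic sagittal pelvic-anatomy cohorts.

The generator emulates the statistical structure that pubic-bone-relative
anatomical features exploit on real bone-registered planning/pretreatment
image pairs:

* per-patient baseline organ geometry (bladder, rectum, prostate, CTV,
  pubic bone) drawn once per patient;
* per-fraction latent state (u, v, w): upper-rectal filling, lower-rectal
  filling and bladder filling, drawn from centered normals;
* the rectal anterior wall displaces anteriorly with filling, the bladder
  scales with its filling, and the CTV translates rigidly along a
  superior-anterior / inferior-posterior diagonal coupled to the same
  latents, plus small isotropic noise;
* the applied CTV translation is recorded exactly as the reference shift.

Default couplings are calibrated so that pooled cohorts show mean absolute
shifts of roughly 0.9 mm (SI) and 1.3 mm (AP), lateral shifts that are
pure sub-half-millimetre noise, and the upper-rectal-wall feature (f3) as
the strongest -- and negative -- correlate of both shift components.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .anatomy import Cohort, FractionRecord, LatentState, Patient, SagittalAnatomy, ShiftVector
from .features import locate_feature_points
from .geometry import Contour, GeometryError, Point2D, horizontal_line_crossings, superellipse

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Range:
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable generator parameters (all lengths in mm, latents unitless).

    Couplings: the SI shift is alpha_u * u + alpha_w * w + noise, the AP
    shift beta_u * u + beta_v * v + beta_w * w + noise; the rectal anterior
    wall moves anteriorly by k_u * u at the upper (S) level and k_v * v at
    the lower (I) level, the posterior wall follows a fraction
    ``posterior_follow`` of that plus an independent diameter disturbance
    with SD k_r * sigma_r.
    """

    # per-patient baseline ranges
    prostate_ra: Range = Range(17.0, 22.0)
    prostate_rs: Range = Range(15.0, 19.0)
    prostate_center_jitter: float = 2.0
    ctv_margin_a: float = 4.0
    ctv_margin_s: float = 8.0
    ctv_offset: tuple[float, float] = (-2.0, 4.0)  # (a, s) toward posterior-superior
    bladder_offset_a: Range = Range(6.0, 14.0)
    bladder_offset_s: Range = Range(36.0, 44.0)
    bladder_ra: Range = Range(25.0, 32.0)
    bladder_rs: Range = Range(26.0, 34.0)
    rectum_center_a: Range = Range(-38.0, -32.0)
    rectum_center_s: Range = Range(-18.0, -12.0)
    rectum_ra: Range = Range(10.0, 13.0)
    rectum_rs: Range = Range(46.0, 54.0)
    bone_s_a: Range = Range(15.5, 18.5)
    bone_s_s: Range = Range(-2.0, 2.0)
    bone_i_drop: Range = Range(38.0, 42.0)

    # latent SDs (unitless)
    sigma_u: float = 1.0
    sigma_v: float = 1.0
    sigma_w: float = 1.0
    sigma_r: float = 1.0

    # wall/organ couplings (mm per latent unit)
    k_u: float = 4.0
    k_v: float = 3.0
    k_r: float = 2.0
    posterior_follow: float = 0.5
    bladder_scale_per_w: float = 0.05
    bladder_jitter_sd: float = 1.0

    # shift couplings (mm per latent unit) and noise SDs (mm)
    alpha_u: float = 1.0
    alpha_w: float = 0.4
    beta_u: float = 1.4
    beta_v: float = 0.6
    beta_w: float = 0.4
    eps_si: float = 0.3
    eps_ap: float = 0.3
    eps_lr: float = 0.1

    # measurement / gas.  The prostate-center click is far less reproducible
    # than wall clicks (the gland boundary is low-contrast), so it carries
    # its own, larger noise.
    click_noise_sd: float = 0.5
    cop_click_noise_sd: float = 2.0
    gas_probability: float = 0.25
    gas_ra: Range = Range(4.0, 7.0)
    gas_rs: Range = Range(8.0, 14.0)

    def __post_init__(self) -> None:
        for name in ("sigma_u", "sigma_v", "sigma_w", "sigma_r",
                     "eps_si", "eps_ap", "eps_lr", "click_noise_sd",
                     "cop_click_noise_sd", "bladder_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gas_probability <= 1.0:
            raise ValueError("gas_probability must be in [0, 1]")
        if self.eps_lr > 0.5:
            raise ValueError("eps_lr above 0.5 mm contradicts negligible lateral motion")

    @classmethod
    def zero_variance(cls, **overrides) -> "GeneratorParams":
        """Params with every random fraction-to-fraction source switched off."""
        base = dict(sigma_u=0.0, sigma_v=0.0, sigma_w=0.0, sigma_r=0.0,
                    eps_si=0.0, eps_ap=0.0, eps_lr=0.0, bladder_jitter_sd=0.0,
                    click_noise_sd=0.0, cop_click_noise_sd=0.0, gas_probability=0.0)
        base.update(overrides)
        return cls(**base)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def make_patient_baseline(params: GeneratorParams, patient_id: str,
                          seed: int | np.random.SeedSequence) -> SagittalAnatomy:
    """Draw one patient's planning anatomy from the allowed geometry ranges."""
    rng = np.random.default_rng(seed)
    pc = Point2D(rng.uniform(-params.prostate_center_jitter, params.prostate_center_jitter),
                 rng.uniform(-params.prostate_center_jitter, params.prostate_center_jitter))
    ra, rs = params.prostate_ra.draw(rng), params.prostate_rs.draw(rng)
    prostate = superellipse(pc, ra, rs, exponent=2.2, n_vertices=64)
    ctv = superellipse(Point2D(pc.a + params.ctv_offset[0], pc.s + params.ctv_offset[1]),
                       ra + params.ctv_margin_a, rs + params.ctv_margin_s,
                       exponent=2.2, n_vertices=64)
    bladder = superellipse(
        Point2D(pc.a + params.bladder_offset_a.draw(rng), pc.s + params.bladder_offset_s.draw(rng)),
        params.bladder_ra.draw(rng), params.bladder_rs.draw(rng),
        exponent=2.3, n_vertices=64)
    rectum = superellipse(
        Point2D(params.rectum_center_a.draw(rng), params.rectum_center_s.draw(rng)),
        params.rectum_ra.draw(rng), params.rectum_rs.draw(rng),
        exponent=2.5, n_vertices=64)
    sa, ss = params.bone_s_a.draw(rng), params.bone_s_s.draw(rng)
    drop = params.bone_i_drop.draw(rng)
    bone = Contour([
        (sa, ss),                       # landmark S: superior-posterior edge
        (sa + 16.0, ss - 4.0),
        (sa + 14.0, ss - drop + 2.0),
        (sa - 2.0, ss - drop),          # landmark I: inferior-posterior edge
    ])
    return SagittalAnatomy(bladder=bladder, rectum=rectum, prostate=prostate,
                           ctv=ctv, bone=bone)


def _deform_rectum(rectum: Contour, s_top: float, s_bottom: float,
                   delta_ant_top: float, delta_ant_bot: float,
                   delta_post_top: float, delta_post_bot: float) -> Contour:
    """Displace the rectal walls anteriorly, tapered by anterior/posterior weight.

    The displacement interpolates linearly in s between the upper (S) and
    lower (I) measurement levels and is scaled by how anterior (resp.
    posterior) each vertex sits, so the bulge moves while the flanks stay.
    """
    v = rectum.vertices.copy()
    a_c = float(v[:, 0].mean())
    a_max, a_min = v[:, 0].max(), v[:, 0].min()
    t = np.clip((v[:, 1] - s_bottom) / max(s_top - s_bottom, 1e-9), 0.0, 1.0)
    w_ant = np.clip((v[:, 0] - a_c) / max(a_max - a_c, 1e-9), 0.0, 1.0)
    w_post = np.clip((a_c - v[:, 0]) / max(a_c - a_min, 1e-9), 0.0, 1.0)
    disp = (w_ant * (delta_ant_top * t + delta_ant_bot * (1.0 - t))
            + w_post * (delta_post_top * t + delta_post_bot * (1.0 - t)))
    if not np.any(disp):
        return rectum
    v[:, 0] += disp
    return Contour(v)


def _scale_contour(c: Contour, scale: float, jitter: tuple[float, float]) -> Contour:
    if scale == 1.0 and jitter == (0.0, 0.0):
        return c
    ctr = c.vertices.mean(axis=0)
    return Contour((c.vertices - ctr) * scale + ctr + np.asarray(jitter))


def add_gas_pocket(anatomy: SagittalAnatomy, rng: np.random.Generator,
                   params: GeneratorParams, s_level: float | None = None) -> SagittalAnatomy:
    """Insert an elliptical gas pocket hugging the upper anterior rectal wall.

    The pocket only adds a low-intensity region to rasterized images; the
    rectal wall contour -- and therefore every measured distance -- is
    unchanged.  Returns the anatomy unchanged if no admissible pocket fits.
    """
    if s_level is None:
        s_level = float(rng.uniform(-5.0, 10.0))
    crossings = horizontal_line_crossings(anatomy.rectum, s_level)
    if crossings.size < 2:
        return anatomy
    wall_a = crossings.max()
    ra = params.gas_ra.draw(rng)
    rs = params.gas_rs.draw(rng)
    for _ in range(4):
        pocket = superellipse(Point2D(wall_a - ra - 0.5, s_level), ra, rs,
                              exponent=2.0, n_vertices=32)
        if anatomy.rectum.polygon.contains(pocket.polygon):
            return SagittalAnatomy(bladder=anatomy.bladder, rectum=anatomy.rectum,
                                   prostate=anatomy.prostate, ctv=anatomy.ctv,
                                   bone=anatomy.bone, gas_region=pocket)
        ra *= 0.75
        rs *= 0.75
    return anatomy


def sample_fraction(baseline: SagittalAnatomy, params: GeneratorParams,
                    fraction_index: int, seed: int | np.random.SeedSequence,
                    patient_id: str = "patient") -> FractionRecord:
    """Draw one fraction's latent state, deform the anatomy and record the shift.

    If a deformation yields a self-intersecting contour the draw is retried
    with a fresh sub-seed (logged); in the default regime this is rare.
    """
    rng = np.random.default_rng(seed)
    pts = locate_feature_points(baseline.bone)
    for attempt in range(20):
        try:
            u = rng.normal(0.0, params.sigma_u) if params.sigma_u > 0 else 0.0
            v = rng.normal(0.0, params.sigma_v) if params.sigma_v > 0 else 0.0
            w = rng.normal(0.0, params.sigma_w) if params.sigma_w > 0 else 0.0
            r_u = rng.normal(0.0, params.sigma_r) if params.sigma_r > 0 else 0.0
            r_l = rng.normal(0.0, params.sigma_r) if params.sigma_r > 0 else 0.0

            rectum = _deform_rectum(
                baseline.rectum, s_top=pts.S.s, s_bottom=pts.I.s,
                delta_ant_top=params.k_u * u,
                delta_ant_bot=params.k_v * v,
                delta_post_top=params.posterior_follow * params.k_u * u + params.k_r * r_u,
                delta_post_bot=params.posterior_follow * params.k_v * v + params.k_r * r_l,
            )
            jitter = (rng.normal(0.0, params.bladder_jitter_sd),
                      rng.normal(0.0, params.bladder_jitter_sd)) \
                if params.bladder_jitter_sd > 0 else (0.0, 0.0)
            scale = max(1.0 + params.bladder_scale_per_w * w, 0.5)
            bladder = _scale_contour(baseline.bladder, scale, jitter)

            si = params.alpha_u * u + params.alpha_w * w \
                + (rng.normal(0.0, params.eps_si) if params.eps_si > 0 else 0.0)
            ap = params.beta_u * u + params.beta_v * v + params.beta_w * w \
                + (rng.normal(0.0, params.eps_ap) if params.eps_ap > 0 else 0.0)
            lr = rng.normal(0.0, params.eps_lr) if params.eps_lr > 0 else 0.0

            pretreatment = SagittalAnatomy(
                bladder=bladder,
                rectum=rectum,
                prostate=baseline.prostate.translated(ap, si),
                ctv=baseline.ctv.translated(ap, si),
                bone=baseline.bone,
            )
            gas = params.gas_probability > 0 and rng.random() < params.gas_probability
            if gas:
                pretreatment = add_gas_pocket(pretreatment, rng, params)
                gas = pretreatment.gas_region is not None
            return FractionRecord(
                patient_id=patient_id, fraction_index=fraction_index,
                planning=baseline, pretreatment=pretreatment,
                reference_shift=ShiftVector(lr=lr, si=si, ap=ap),
                latent_state=LatentState(u=u, v=v, w=w, gas=gas),
            )
        except GeometryError as exc:  # retry with the already-advanced rng
            logger.warning("fraction %s/%d attempt %d rejected: %s",
                           patient_id, fraction_index, attempt, exc)
    raise GeometryError(
        f"could not draw a valid fraction for {patient_id}/{fraction_index}")


def simulate_cohort(params: GeneratorParams, n_patients: int,
                    n_fractions_per_patient: int, seed: int) -> Cohort:
    """Simulate a full cohort; deterministic given (params, sizes, seed)."""
    if n_patients < 2:
        raise ValueError("a cohort needs at least 2 patients")
    if n_fractions_per_patient < 1:
        raise ValueError("each patient needs at least 1 fraction")
    master = np.random.default_rng(seed)
    patients = []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        base_seed = int(master.integers(0, 2**31 - 1))
        baseline = make_patient_baseline(params, pid, base_seed)
        fractions = []
        for k in range(n_fractions_per_patient):
            frac_seed = int(master.integers(0, 2**31 - 1))
            fractions.append(sample_fraction(baseline, params, k + 1, frac_seed, pid))
        patients.append(Patient(patient_id=pid, planning=baseline, fractions=fractions))
    return Cohort(patients=patients, seed=seed, params_digest=params.digest())
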