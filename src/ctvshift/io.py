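"""Readers, writers, run configuration and the end-to-end pipeline.

On-disk formats are all plain text: anatomies as JSON (one file per image,
coordinates in mm), feature tables as CSV, trained models and evaluation
reports as JSON.  Every artifact embeds the master seed and a digest of
the generator parameters so deleting intermediates and re-running
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anatomy import (ORGAN_NAMES, Cohort, FractionRecord, LatentState, Patient,
                      SagittalAnatomy, ShiftVector)
from .evaluation import rank_features, residual_summary, run_lcv, run_validation
from .features import FEATURE_COLUMNS, extract_cohort_features, locate_feature_points
from .geometry import Contour
from .regressors import TrainedRegressor, ModelSpec
from .synthetic import GeneratorParams, Range, simulate_cohort

FEATURE_TABLE_COLUMNS = ["patient_id", "fraction"] + FEATURE_COLUMNS + ["si", "ap"]


class SchemaError(ValueError):
    """A file does not match the expected on-disk schema."""


# --------------------------------------------------------------------------
# anatomy / cohort JSON
# --------------------------------------------------------------------------

_KNOWN_ANATOMY_KEYS = {"patient_id", "fraction", "organs", "landmarks", "shift", "latent"}


def anatomy_to_dict(anatomy: SagittalAnatomy, patient_id: str, fraction: int,
                    shift: ShiftVector | None = None,
                    latent: LatentState | None = None) -> dict:
    pts = locate_feature_points(anatomy.bone)
    d = {
        "patient_id": patient_id,
        "fraction": fraction,
        "organs": {name: c.vertices.tolist() for name, c in anatomy.organs().items()},
        "landmarks": {"S": [pts.S.a, pts.S.s], "I": [pts.I.a, pts.I.s]},
    }
    if shift is not None:
        d["shift"] = {"lr": shift.lr, "si": shift.si, "ap": shift.ap}
    if latent is not None:
        d["latent"] = {"u": latent.u, "v": latent.v, "w": latent.w, "gas": latent.gas}
    return d


def anatomy_from_dict(d: dict) -> tuple[SagittalAnatomy, dict]:
    """Parse an anatomy record; returns (anatomy, unknown-key dict)."""
    if "organs" not in d:
        raise SchemaError("anatomy record lacks an 'organs' mapping")
    organs = d["organs"]
    for name in ORGAN_NAMES:
        if name not in organs:
            raise SchemaError(f"anatomy record is missing organ {name!r}")
    extras = {k: v for k, v in d.items() if k not in _KNOWN_ANATOMY_KEYS}
    if extras:
        warnings.warn(f"unknown keys preserved in anatomy record: {sorted(extras)}",
                      stacklevel=2)
    kwargs = {name: Contour(np.asarray(organs[name], dtype=float))
              for name in ORGAN_NAMES}
    if "gas_region" in organs:
        kwargs["gas_region"] = Contour(np.asarray(organs["gas_region"], dtype=float))
    return SagittalAnatomy(**kwargs), extras


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write one JSON per image under ``path`` plus a cohort manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.seed, "params_digest": cohort.params_digest,
                "patients": []}
    for patient in cohort.patients:
        pdir = root / patient.patient_id
        pdir.mkdir(exist_ok=True)
        plan = anatomy_to_dict(patient.planning, patient.patient_id, 0)
        (pdir / "planning.json").write_text(json.dumps(plan))
        entry = {"patient_id": patient.patient_id, "fractions": []}
        for rec in patient.fractions:
            d = anatomy_to_dict(rec.pretreatment, rec.patient_id, rec.fraction_index,
                                rec.reference_shift, rec.latent_state)
            d.update(getattr(rec, "extras", {}))
            name = f"fraction_{rec.fraction_index:03d}.json"
            (pdir / name).write_text(json.dumps(d))
            entry["fractions"].append(name)
        manifest["patients"].append(entry)
    (root / "cohort.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(path: str | Path) -> Cohort:
    root = Path(path)
    manifest = json.loads((root / "cohort.json").read_text())
    patients = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        pdir = root / pid
        planning, _ = anatomy_from_dict(json.loads((pdir / "planning.json").read_text()))
        fractions = []
        for name in entry["fractions"]:
            d = json.loads((pdir / name).read_text())
            pretreatment, extras = anatomy_from_dict(d)
            shift = d.get("shift")
            if shift is None:
                raise SchemaError(f"{name}: fraction record lacks a 'shift'")
            latent = d.get("latent", {})
            rec = FractionRecord(
                patient_id=pid, fraction_index=int(d["fraction"]),
                planning=planning, pretreatment=pretreatment,
                reference_shift=ShiftVector(**shift),
                latent_state=LatentState(u=latent.get("u", 0.0), v=latent.get("v", 0.0),
                                         w=latent.get("w", 0.0),
                                         gas=latent.get("gas", False)))
            rec.extras = extras  # type: ignore[attr-defined]
            fractions.append(rec)
        patients.append(Patient(patient_id=pid, planning=planning, fractions=fractions))
    return Cohort(patients=patients, seed=manifest.get("seed"),
                  params_digest=manifest.get("params_digest"))


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in features.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns {missing}")
    features[FEATURE_TABLE_COLUMNS].to_csv(path, index=False,
                                           float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str)
    if list(raw.columns) != FEATURE_TABLE_COLUMNS:
        raise SchemaError(
            f"feature table header mismatch: expected {FEATURE_TABLE_COLUMNS}, "
            f"got {list(raw.columns)}")
    out = raw.copy()
    for col in FEATURE_TABLE_COLUMNS:
        if col == "patient_id":
            continue
        for i, val in enumerate(raw[col]):
            try:
                float(val)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"non-numeric value {val!r} in column {col!r}, row {i + 2}") from None
        out[col] = raw[col].astype(float)
    out["fraction"] = out["fraction"].astype(int)
    return out


# --------------------------------------------------------------------------
# model JSON
# --------------------------------------------------------------------------

def save_model(model: TrainedRegressor, path: str | Path) -> None:
    """Serialize a trained model (weights + standardization + spec) to JSON."""
    spec = model.spec
    d = {"spec": {"architecture": spec.architecture, "direction": spec.direction,
                  "n_features": spec.n_features,
                  "hyperparameters": spec.hyperparameters, "seed": spec.seed},
         "x_mean": model.x_mean.tolist(), "x_scale": model.x_scale.tolist(),
         "y_mean": model.y_mean, "y_scale": model.y_scale}
    arch = spec.architecture
    if arch.endswith("ann"):
        net = model.state
        d["ann"] = {"hidden_nodes": net.hidden_nodes, "n_inputs": net.n_inputs,
                    "theta": net.theta.tolist()}
    elif arch == "svr":
        sk = model.state
        d["svr"] = {"support_vectors": sk.support_vectors_.tolist(),
                    "dual_coef": sk.dual_coef_.ravel().tolist(),
                    "intercept": float(sk.intercept_[0]),
                    "gamma": float(sk._gamma)}
    elif arch == "rf":
        trees = []
        for est in model.state.estimators_:
            t = est.tree_
            trees.append({"children_left": t.children_left.tolist(),
                          "children_right": t.children_right.tolist(),
                          "feature": t.feature.tolist(),
                          "threshold": t.threshold.tolist(),
                          "value": t.value.reshape(-1).tolist()})
        d["forest"] = trees
    Path(path).write_text(json.dumps(d))


def load_model(path: str | Path) -> TrainedRegressor:
    d = json.loads(Path(path).read_text())
    spec = ModelSpec(**d["spec"])
    x_mean = np.asarray(d["x_mean"])
    x_scale = np.asarray(d["x_scale"])
    arch = spec.architecture
    if arch.endswith("ann"):
        from .ann import MLPState
        net = MLPState(d["ann"]["n_inputs"], d["ann"]["hidden_nodes"],
                       theta=np.asarray(d["ann"]["theta"]))
        predict_std = net.forward
        state = net
    elif arch == "svr":
        sv = np.asarray(d["svr"]["support_vectors"])
        dual = np.asarray(d["svr"]["dual_coef"])
        b = d["svr"]["intercept"]
        gamma = d["svr"]["gamma"]

        def predict_std(Xs, sv=sv, dual=dual, b=b, gamma=gamma):
            sq = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-gamma * sq) @ dual + b

        state = d["svr"]
    elif arch == "rf":
        trees = [{k: np.asarray(v) for k, v in t.items()} for t in d["forest"]]

        def predict_std(Xs, trees=trees):
            out = np.zeros(Xs.shape[0])
            for t in trees:
                for i, x in enumerate(Xs):
                    node = 0
                    while t["children_left"][node] != -1:
                        if x[t["feature"][node]] <= t["threshold"][node]:
                            node = t["children_left"][node]
                        else:
                            node = t["children_right"][node]
                    out[i] += t["value"][node]
            return out / len(trees)

        state = d["forest"]
    else:  # pragma: no cover
        raise SchemaError(f"unknown architecture {arch!r} in model file")
    return TrainedRegressor(spec, x_mean, x_scale, d["y_mean"], d["y_scale"],
                            predict_std=predict_std, state=state)


# --------------------------------------------------------------------------
# run configuration and pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Default cohort sizes follow the study layout: ten training patients
    with 38 fractions each and ten validation patients sampled at ten
    fractions each.
    """

    params: GeneratorParams = field(default_factory=GeneratorParams)
    n_train_patients: int = 10
    n_fractions_per_patient: int = 38
    n_val_patients: int = 10
    n_val_fractions: int = 10
    architectures: tuple[str, ...] = ("br-ann", "lm-ann", "scg-ann", "svr", "rf")
    n_features: tuple[int, ...] = (1,)
    seed: int = 0
    out_dir: str = "ctvshift_run"

    def digest(self) -> str:
        """Hash of everything that determines the numbers (paths excluded)."""
        import hashlib
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params_raw = raw.pop("params", {})
        for key, val in list(params_raw.items()):
            if isinstance(val, (list, tuple)) and len(val) == 2:
                params_raw[key] = Range(*val)
        raw["params"] = GeneratorParams(**params_raw)
        for key in ("architectures", "n_features"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """simulate -> extract -> train -> evaluate, returning the report dict.

    The report mirrors the evaluation layout: per architecture and feature
    count, mean absolute residual +/- SD and max along SI, AP and pooled,
    for the patient-wise cross-validation and the independent validation
    cohort (one feature), plus the Spearman feature ranking.
    """
    if config.n_train_patients < 2:
        raise ValueError("the cross-validation needs at least 2 training patients")
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    train_cohort = simulate_cohort(config.params, config.n_train_patients,
                                   config.n_fractions_per_patient, int(seeds[0]))
    val_cohort = simulate_cohort(config.params, config.n_val_patients,
                                 config.n_val_fractions, int(seeds[1]))
    train_feat = extract_cohort_features(train_cohort, config.params.click_noise_sd,
                                         seed=int(seeds[2]),
                                         cop_click_noise_sd=config.params.cop_click_noise_sd)
    val_feat = extract_cohort_features(val_cohort, config.params.click_noise_sd,
                                       seed=int(seeds[3]),
                                       cop_click_noise_sd=config.params.cop_click_noise_sd)
    val_feat["patient_id"] = "V" + val_feat["patient_id"].astype(str)

    ranking = rank_features(train_feat)
    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_train_fractions": int(len(train_feat)),
        "n_val_fractions": int(len(val_feat)),
        "feature_ranking": {
            "order": ranking.order,
            "rho_si": ranking.rho_si, "rho_ap": ranking.rho_ap,
            "p_si": ranking.p_si, "p_ap": ranking.p_ap,
        },
        "lcv": {}, "validation": {},
    }
    residual_frames = []
    for arch in config.architectures:
        report["lcv"][arch] = {}
        for k in config.n_features:
            table = run_lcv(train_feat, arch, k, seed=config.seed)
            report["lcv"][arch][str(k)] = residual_summary(table)
            table.insert(0, "mode", "lcv")
            table.insert(1, "architecture", arch)
            table.insert(2, "n_features", k)
            residual_frames.append(table)
        vtable = run_validation(train_feat, val_feat, arch, 1, seed=config.seed)
        report["validation"][arch] = residual_summary(vtable)
        vtable.insert(0, "mode", "validation")
        vtable.insert(1, "architecture", arch)
        vtable.insert(2, "n_features", 1)
        residual_frames.append(vtable)

    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        write_feature_table(train_feat, out / "train_features.csv")
        write_feature_table(val_feat, out / "validation_features.csv")
        pd.concat(residual_frames, ignore_index=True).to_csv(
            out / "residuals.csv", index=False, float_format="%.12g")
    return report
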