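"""Model evaluation: feature ranking, cross-validation and comparators.

The central protocol is leave-one-out-by-patient cross-validation (LCV):
all fractions of one patient are held out together, models are fitted on
the remaining patients, and absolute residuals between reference and
predicted shifts are pooled over patients.  An independent validation run
fits on one cohort and predicts another.  Feature subsets are nested:
features enter in order of decreasing mean absolute Spearman correlation
with the SI and AP shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .raster import grid_for, rasterize
from .registration import grey_value_match
from .regressors import DEFAULT_HYPERPARAMETERS, train
# comparison statistics re-exported as part of the evaluation surface
from .stats import (cohens_kappa, dice_coefficient, f_test_variance,  # noqa: F401
                    spearman_rho, steel_dwass)  # noqa: F401
from .synthetic import GeneratorParams, add_gas_pocket, make_patient_baseline, sample_fraction

DIRECTIONS = ("si", "ap")


@dataclass
class FeatureRanking:
    """Features ordered by decreasing mean |rho| against the SI and AP shifts."""

    order: list[str]                    # e.g. ['f3', 'f4', ...]
    rho_si: dict[str, float]
    rho_ap: dict[str, float]
    p_si: dict[str, float]
    p_ap: dict[str, float]

    def subset(self, k: int) -> list[str]:
        """The nested subset of the first k features."""
        if not 1 <= k <= len(self.order):
            raise ValueError(f"k must be in 1..{len(self.order)}")
        return self.order[:k]

    @property
    def mean_abs_rho(self) -> dict[str, float]:
        return {f: (abs(self.rho_si[f]) + abs(self.rho_ap[f])) / 2.0
                for f in self.order}


def rank_features(features: pd.DataFrame) -> FeatureRanking:
    """Rank f1..f9 by mean of |Spearman rho| with the SI and AP shifts.

    Ties break toward the lower feature index, so a duplicated feature
    keeps its first position.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 fractions to rank features")
    rho_si, rho_ap, p_si, p_ap = {}, {}, {}, {}
    for col in FEATURE_COLUMNS:
        for target, rho_d, p_d in (("si", rho_si, p_si), ("ap", rho_ap, p_ap)):
            try:
                rho_d[col], p_d[col] = spearman_rho(features[col], features[target])
            except ValueError:  # constant column: no correlation evidence
                rho_d[col], p_d[col] = 0.0, 1.0
    key = {f: (abs(rho_si[f]) + abs(rho_ap[f])) / 2.0 for f in FEATURE_COLUMNS}
    order = sorted(FEATURE_COLUMNS, key=lambda f: (-key[f], int(f[1:])))
    return FeatureRanking(order, rho_si, rho_ap, p_si, p_ap)


def _fit_and_predict(train_df: pd.DataFrame, test_df: pd.DataFrame,
                     architecture: str, n_features: int,
                     hyperparameters: dict | None, seed: int,
                     ranking: FeatureRanking | None = None) -> pd.DataFrame:
    ranking = ranking or rank_features(train_df)
    cols = ranking.subset(n_features)
    rows = []
    for direction in DIRECTIONS:
        model = train(train_df[cols].to_numpy(), train_df[direction].to_numpy(),
                      architecture, hyperparameters, seed=seed, direction=direction)
        pred = model.predict(test_df[cols].to_numpy())
        ref = test_df[direction].to_numpy()
        rows.append(pd.DataFrame({
            "patient_id": test_df["patient_id"].to_numpy(),
            "fraction": test_df["fraction"].to_numpy(),
            "direction": direction,
            "reference": ref,
            "predicted": pred,
            "residual": np.abs(ref - pred),
        }))
    return pd.concat(rows, ignore_index=True)


def run_lcv(features: pd.DataFrame, architecture: str, n_features: int,
            hyperparameters: dict | None = None, seed: int = 0,
            rank_per_fold: bool = True) -> pd.DataFrame:
    """Leave-one-out-by-patient cross-validation over a feature table.

    Returns a residual table with one row per fraction and direction.
    ``rank_per_fold`` recomputes the feature ranking inside each training
    fold (no leakage from the held-out patient); switching it off uses a
    single pooled ranking.
    """
    patients = features["patient_id"].unique()
    if len(patients) < 2:
        raise ValueError("LCV needs at least 2 patients")
    pooled_ranking = None if rank_per_fold else rank_features(features)
    parts = []
    for pid in patients:
        test_df = features[features["patient_id"] == pid]
        if test_df.empty:
            warnings.warn(f"patient {pid} has no fractions; skipped", stacklevel=2)
            continue
        train_df = features[features["patient_id"] != pid]
        parts.append(_fit_and_predict(train_df, test_df, architecture, n_features,
                                      hyperparameters, seed, pooled_ranking))
    out = pd.concat(parts, ignore_index=True)
    out.attrs.update(architecture=architecture, n_features=n_features, mode="lcv")
    return out


def run_validation(train_features: pd.DataFrame, val_features: pd.DataFrame,
                   architecture: str, n_features: int,
                   hyperparameters: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Fit on every training fraction, predict every validation fraction."""
    overlap = set(train_features["patient_id"]) & set(val_features["patient_id"])
    if overlap:
        raise ValueError(f"training and validation patients overlap: {sorted(overlap)}")
    out = _fit_and_predict(train_features, val_features, architecture, n_features,
                           hyperparameters, seed)
    out.attrs.update(architecture=architecture, n_features=n_features, mode="validation")
    return out


def residual_summary(residual_table: pd.DataFrame, ddof: int = 1) -> dict:
    """Mean absolute residual +/- SD and max, per direction and pooled.

    The SD is the sample standard deviation (n-1) by default; set
    ``ddof=0`` for the population form.
    """
    if residual_table.empty:
        raise ValueError("residual table is empty")

    def _summ(res: np.ndarray) -> dict:
        return {"mean": float(res.mean()),
                "sd": float(res.std(ddof=ddof)) if res.size > ddof else 0.0,
                "max": float(res.max()),
                "n": int(res.size)}

    out = {d: _summ(residual_table.loc[residual_table["direction"] == d,
                                       "residual"].to_numpy())
           for d in DIRECTIONS if (residual_table["direction"] == d).any()}
    out["pooled"] = _summ(residual_table["residual"].to_numpy())
    return out


def architecture_comparison(features: pd.DataFrame, n_features: int = 1,
                            architectures=None, seed: int = 0) -> dict[str, dict]:
    """Pooled LCV residual summaries for each architecture on one table."""
    architectures = architectures or list(DEFAULT_HYPERPARAMETERS)
    out = {}
    for arch in architectures:
        table = run_lcv(features, arch, n_features, seed=seed)
        out[arch] = residual_summary(table)
    return out


def gas_sensitivity_trial(params: GeneratorParams, seed: int,
                          n_fractions: int = 3, pixel_size_mm: float = 1.0,
                          search_mm: float = 10.0) -> dict:
    """One paired trial of the grey-value comparator with and without gas.

    Draws a patient baseline and ``n_fractions`` fractions; each
    pretreatment anatomy is rasterized twice -- once with a rectal gas
    pocket inserted, once without -- and registered against the planning
    image within the CTV + 5 mm ROI.  Returns the mean absolute component
    error of each arm, averaged over the fractions.  The wall contours are
    identical in both arms, so any feature-based prediction is untouched
    by the pocket; only the grey-value comparator can react to it.
    """
    from .anatomy import SagittalAnatomy
    from .geometry import Contour

    rng = np.random.default_rng(seed)
    baseline = make_patient_baseline(params, "trial", int(rng.integers(2**31 - 1)))
    errs_gas, errs_nogas, records = [], [], []
    for k in range(n_fractions):
        rec = sample_fraction(baseline, params, k + 1,
                              int(rng.integers(2**31 - 1)), "trial")
        pre_nogas = SagittalAnatomy(bladder=rec.pretreatment.bladder,
                                    rectum=rec.pretreatment.rectum,
                                    prostate=rec.pretreatment.prostate,
                                    ctv=rec.pretreatment.ctv,
                                    bone=rec.pretreatment.bone, gas_region=None)
        pre_gas = pre_nogas
        for _ in range(8):  # ensure the gas arm really has a pocket
            pre_gas = add_gas_pocket(pre_nogas, rng, params)
            if pre_gas.gas_region is not None:
                break
        origin, shape = grid_for([rec.planning, pre_gas], pixel_size_mm,
                                 padding_mm=search_mm + 10.0)
        ref_img = rasterize(rec.planning, pixel_size_mm, origin=origin, shape=shape)
        roi = rec.planning.ctv.polygon.buffer(5.0)
        roi_contour = Contour(np.asarray(roi.exterior.coords)[:-1])
        truth = rec.reference_shift

        def err(anat) -> float:
            img = rasterize(anat, pixel_size_mm, include_gas=True,
                            origin=origin, shape=shape)
            m = grey_value_match(ref_img, img, roi_contour, search_mm=search_mm)
            return 0.5 * (abs(m.si - truth.si) + abs(m.ap - truth.ap))

        errs_gas.append(err(pre_gas))
        errs_nogas.append(err(pre_nogas))
        records.append((rec, pre_gas, pre_nogas))
    return {"error_gas": float(np.mean(errs_gas)),
            "error_nogas": float(np.mean(errs_nogas)),
            "records": records}
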