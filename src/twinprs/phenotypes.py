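"""Refraction and cognition phenotype preparation, plus the phenotypic
association models.

Raw optometric records carry sphere and cylinder powers per eye (dioptres,
minus-cylinder convention).  The analysis trait is the mean spherical
equivalent, SE = sphere + cylinder/2 averaged over the two eyes; myopia is
the binary trait mean SE <= -0.75 D.  Both analysis traits enter the twin
and polygenic models as age- and sex-adjusted standardised residuals.

Association models account for the twin structure with cluster-robust
(sandwich) standard errors over pair ids, which keeps every individual in
the model while correcting inference for relatedness; a one-twin-per-pair
subsample is available as a sensitivity option.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MYOPIA_THRESHOLD_D",
    "spherical_equivalent",
    "mean_spherical_equivalent",
    "classify_myopia",
    "prepare_refraction",
    "residualize",
    "linear_association",
    "quartile_odds_ratio",
    "AssociationResult",
    "OddsRatioResult",
]

logger = logging.getLogger(__name__)

MYOPIA_THRESHOLD_D = -0.75


def spherical_equivalent(sphere, cylinder):
    """Spherical equivalent in dioptres: sphere + cylinder/2."""
    return np.asarray(sphere, dtype=float) + np.asarray(cylinder, dtype=float) / 2.0


def mean_spherical_equivalent(se_right, se_left):
    """Per-individual refraction: mean of the two eyes' spherical equivalents."""
    return (np.asarray(se_right, dtype=float) + np.asarray(se_left, dtype=float)) / 2.0


def classify_myopia(mean_se, threshold: float = MYOPIA_THRESHOLD_D):
    """Myopia flag: mean spherical equivalent at or below -0.75 D
    (boundary inclusive)."""
    return np.asarray(mean_se, dtype=float) <= threshold


def _to_minus_cylinder(sphere: np.ndarray, cylinder: np.ndarray):
    """Validate minus-cylinder convention; transpose plus-cylinder rows.

    A plus-cylinder prescription (s, +c) is the same lens as (s + c, -c);
    the spherical equivalent is invariant under the transposition.
    """
    plus = cylinder > 0
    if plus.any():
        logger.warning("converted %d plus-cylinder records to minus-cylinder",
                       int(plus.sum()))
        sphere = np.where(plus, sphere + cylinder, sphere)
        cylinder = np.where(plus, -cylinder, cylinder)
    return sphere, cylinder


def prepare_refraction(records: pd.DataFrame) -> pd.DataFrame:
    """Derive mean_se and the myopia flag from per-eye refraction records.

    Expects columns ``sphere_right, cylinder_right, sphere_left,
    cylinder_left`` (dioptres); returns a copy with ``mean_se`` and
    ``myopia`` appended.
    """
    out = records.copy()
    ses = []
    for eye in ("right", "left"):
        s, c = _to_minus_cylinder(
            out[f"sphere_{eye}"].to_numpy(dtype=float),
            out[f"cylinder_{eye}"].to_numpy(dtype=float))
        ses.append(spherical_equivalent(s, c))
    out["mean_se"] = mean_spherical_equivalent(*ses)
    out["myopia"] = classify_myopia(out["mean_se"])
    return out


def residualize(trait, age, sex) -> np.ndarray:
    """Age- and sex-adjusted standardised residuals (z-scores).

    OLS of the trait on age and a sex indicator; residuals scaled to unit
    (population) standard deviation, so the output has mean 0 and SD 1 over
    the complete cases exactly.  Incomplete cases propagate as NaN.
    """
    trait = np.asarray(trait, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    sex_num = (np.char.upper(sex.astype(str)) == "M").astype(float) \
        if sex.dtype.kind in "OU" else sex.astype(float)
    ok = np.isfinite(trait) & np.isfinite(age) & np.isfinite(sex_num)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete cases")
    design = np.column_stack([np.ones(ok.sum()), age[ok], sex_num[ok]])
    coef, *_ = np.linalg.lstsq(design, trait[ok], rcond=None)
    resid = trait[ok] - design @ coef
    sd = resid.std()
    if sd < 1e-12 * max(1.0, np.abs(trait[ok]).max()):
        raise ValueError("residuals are constant; trait is fully explained "
                         "by the covariates or constant")
    out = np.full(trait.shape, np.nan)
    out[ok] = resid / sd
    return out


@dataclasses.dataclass
class AssociationResult:
    beta: float
    se: float
    p_value: float
    r_squared: float
    incremental_r2: float
    n: int


def _design(predictor, covariates, n):
    cols = [np.ones(n), np.asarray(predictor, dtype=float)]
    names = ["const", "predictor"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        for name in cov.columns:
            cols.append(cov[name].to_numpy(dtype=float))
            names.append(str(name))
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns {names})")
    return x, names


def linear_association(iq, refraction, covariates=None,
                       pairing=None) -> AssociationResult:
    """Linear model of refraction on IQ with relatedness-robust inference.

    Fits OLS of the refraction trait on the IQ trait (plus optional
    covariates) and reports the IQ coefficient with cluster-robust standard
    errors grouped by twin-pair id, the model r-squared, and the incremental
    r-squared of IQ over the covariates (the "variance explained").
    """
    iq = np.asarray(iq, dtype=float)
    y = np.asarray(refraction, dtype=float)
    ok = np.isfinite(iq) & np.isfinite(y)
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        ok &= ~cov_df.isna().any(axis=1).to_numpy()
        cov_df = cov_df.loc[ok]
    else:
        cov_df = None
    if ok.sum() < 10:
        raise ValueError("need at least 10 complete cases")
    x, _ = _design(iq[ok], cov_df, ok.sum())
    if pairing is not None:
        groups = np.asarray(pairing)[ok]
        model = sm.OLS(y[ok], x).fit(cov_type="cluster",
                                     cov_kwds={"groups": groups})
    else:
        model = sm.OLS(y[ok], x).fit()
    r2_full = model.rsquared
    if x.shape[1] > 2:
        base = sm.OLS(y[ok], np.delete(x, 1, axis=1)).fit()
        incr = r2_full - base.rsquared
    else:
        incr = r2_full
    return AssociationResult(
        beta=float(model.params[1]), se=float(model.bse[1]),
        p_value=float(model.pvalues[1]), r_squared=float(r2_full),
        incremental_r2=float(incr), n=int(ok.sum()))


@dataclasses.dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    per_sd_odds_ratio: float
    per_sd_p_value: float
    n: int


def iq_quartiles(iq: np.ndarray) -> np.ndarray:
    """Quartile index 1-4 on the standardised IQ distribution; values tied
    with a cut point fall in the lower quartile."""
    iq = np.asarray(iq, dtype=float)
    q = np.nanquantile(iq, [0.25, 0.5, 0.75])
    return 1 + (iq > q[0]).astype(int) + (iq > q[1]) + (iq > q[2])


def quartile_odds_ratio(iq, myopia, covariates=None,
                        pairing=None) -> OddsRatioResult:
    """Odds of myopia in the top versus bottom IQ quartile.

    Logistic regression of the myopia flag on a top-vs-bottom quartile
    indicator (restricted to individuals in those quartiles), with optional
    covariates and cluster-robust standard errors by pair id; the per-SD
    form (myopia on continuous IQ, all individuals) is reported alongside.
    Complete separation raises with a diagnostic rather than returning an
    unbounded estimate.
    """
    iq = np.asarray(iq, dtype=float)
    myo = np.asarray(myopia).astype(float)
    ok = np.isfinite(iq) & np.isfinite(myo)
    iq, myo = iq[ok], myo[ok]
    pairing = np.asarray(pairing)[ok] if pairing is not None else None
    cov_df = pd.DataFrame(covariates).loc[ok].reset_index(drop=True) \
        if covariates is not None else None

    quart = iq_quartiles(iq)
    keep = (quart == 1) | (quart == 4)
    top = (quart[keep] == 4).astype(float)
    y = myo[keep]
    for grp, lab in ((top == 1, "top"), (top == 0, "bottom")):
        cases = y[grp].sum()
        if cases == 0 or cases == grp.sum():
            raise ValueError(f"{lab} quartile has no variation in myopia "
                             "(complete separation)")
    x, _ = _design(top, cov_df.loc[keep] if cov_df is not None else None,
                   int(keep.sum()))

    def fit_logit(yv, xv, groups):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if groups is not None:
                    return sm.Logit(yv, xv).fit(
                        disp=0, cov_type="cluster",
                        cov_kwds={"groups": groups}, maxiter=200)
                return sm.Logit(yv, xv).fit(disp=0, maxiter=200)
            except Exception as exc:  # statsmodels raises on separation
                raise ValueError(f"logistic fit failed: {exc}") from exc

    groups_q = pairing[keep] if pairing is not None else None
    model = fit_logit(y, x, groups_q)
    if not np.isfinite(model.params).all() or np.abs(model.params[1]) > 20:
        raise ValueError("quasi-complete separation in quartile model")
    beta, se = model.params[1], model.bse[1]
    zc = 1.959963984540054
    x_sd, _ = _design(iq, cov_df, len(iq))
    model_sd = fit_logit(myo, x_sd, pairing)
    return OddsRatioResult(
        odds_ratio=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - zc * se)),
        ci_upper=float(np.exp(beta + zc * se)),
        p_value=float(model.pvalues[1]),
        per_sd_odds_ratio=float(np.exp(model_sd.params[1])),
        per_sd_p_value=float(model_sd.pvalues[1]),
        n=int(keep.sum()))
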