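"""Bivariate ACE/ADE twin model: Cholesky parameterisation, FIML fit,
standardised components and the genetic decomposition of the phenotypic
correlation.

The model follows the classical twin design.  For a pair of traits measured
on both members of MZ and DZ twin pairs, each 2x2 component covariance
(additive genetic A, shared environment C — or dominance D under ADE — and
unique environment E) is parameterised as a lower-triangular Cholesky factor
times its transpose, which keeps every implied covariance positive
semi-definite.  MZ co-twins correlate fully in A and C; DZ co-twins share C
fully but only half of A (and a quarter of D).  The likelihood is full
information maximum likelihood (FIML): each pair contributes a multivariate
normal density on its observed sub-vector, so partially missing co-twin data
are used rather than dropped.

The fitted Cholesky solution is reported in the correlated-factors form:
per-trait standardised proportions (A1, C1, E1, A2, C2, E2) plus cross-trait
factor correlations (rA, rC, rE), from which the phenotypic correlation
decomposes as

    rP = sqrt(A1 A2) rA + sqrt(C1 C2) rC + sqrt(E1 E2) rE,

whose genetic term sqrt(A1) * rA * sqrt(A2) is the shared genetic effect.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .simulate import TWIN_COLUMNS

__all__ = [
    "CholeskyParams",
    "VarianceComponents",
    "BivariateACEFit",
    "model_implied_covariance",
    "neg2_loglik",
    "fit_bivariate_ace",
    "standardize_components",
    "shared_genetic_effect",
    "proportion_of_rp_genetic",
    "confidence_intervals",
    "phenotypic_correlation",
]

_TRAIT_COLS = TWIN_COLUMNS[2:]
LOG_2PI = math.log(2.0 * math.pi)


def validate_twin_dataset(data: pd.DataFrame) -> None:
    missing = [c for c in TWIN_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"twin dataset lacks columns {missing}")
    bad = set(data["zygosity"]) - {"MZ", "DZ"}
    if bad:
        raise ValueError(f"unknown zygosity codes {sorted(bad)}")
    if data["pair_id"].duplicated().any():
        raise ValueError("pair_id values must be unique")


@dataclasses.dataclass(frozen=True)
class CholeskyParams:
    """Lower-triangular 2x2 Cholesky factors of the A, C (or D) and E
    component covariances, plus per-trait means shared across twins."""

    la: np.ndarray
    lc: np.ndarray
    le: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        for name in ("la", "lc", "le"):
            f = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, f)
            if f.shape != (2, 2) or abs(f[0, 1]) > 1e-12:
                raise ValueError(f"{name} must be 2x2 lower-triangular")
            if f[0, 0] < 0 or f[1, 1] < 0:
                raise ValueError(f"{name} diagonal must be non-negative")
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))

    @property
    def sigma_a(self) -> np.ndarray:
        return self.la @ self.la.T

    @property
    def sigma_c(self) -> np.ndarray:
        return self.lc @ self.lc.T

    @property
    def sigma_e(self) -> np.ndarray:
        return self.le @ self.le.T

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.la[0, 0], self.la[1, 0], self.la[1, 1],
            self.lc[0, 0], self.lc[1, 0], self.lc[1, 1],
            self.le[0, 0], self.le[1, 0], self.le[1, 1],
            self.mu[0], self.mu[1],
        ])

    @staticmethod
    def from_vector(v: np.ndarray) -> "CholeskyParams":
        v = np.asarray(v, dtype=float)
        mk = lambda a, b, c: np.array([[a, 0.0], [b, c]])
        return CholeskyParams(
            la=mk(v[0], v[1], v[2]),
            lc=mk(v[3], v[4], v[5]),
            le=mk(v[6], v[7], v[8]),
            mu=v[9:11],
        )


def model_implied_covariance(
    params: CholeskyParams, zygosity: str, model: str = "ACE"
) -> np.ndarray:
    """4x4 covariance of (trait1_t1, trait2_t1, trait1_t2, trait2_t2).

    The within-twin block is A + C + E (A + D + E for ADE).  The cross-twin
    block is A + C for MZ pairs; for DZ pairs additive effects are halved
    (0.5 A + C, or 0.5 A + 0.25 D under ADE, where the C slot carries D).
    """
    a, c, e = params.sigma_a, params.sigma_c, params.sigma_e
    within = a + c + e
    if zygosity == "MZ":
        cross = a + c
    elif zygosity == "DZ":
        cross = 0.5 * a + (0.25 * c if model == "ADE" else c)
    else:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    return np.block([[within, cross], [cross.T, within]])


def _compile(data: pd.DataFrame):
    """Group pairs by (zygosity, missingness pattern) into sufficient
    statistics so one likelihood evaluation costs O(patterns), not O(pairs)."""
    validate_twin_dataset(data)
    groups = []
    y_all = data[_TRAIT_COLS].to_numpy(dtype=float)
    zyg_all = data["zygosity"].to_numpy()
    for zyg in ("MZ", "DZ"):
        y = y_all[zyg_all == zyg]
        if not len(y):
            continue
        obs = np.isfinite(y)
        for pattern in map(tuple, np.unique(obs, axis=0)):
            idx = np.flatnonzero(pattern)
            if not len(idx):
                continue
            rows = y[(obs == pattern).all(axis=1)][:, idx]
            n = rows.shape[0]
            ybar = rows.mean(axis=0)
            dev = rows - ybar
            scatter = dev.T @ dev / n
            groups.append((zyg, idx, n, ybar, scatter))
    if not groups:
        raise ValueError("twin dataset has no observed trait values")
    return groups


_MU_INDEX = np.array([0, 1, 0, 1])

#: finite stand-in for +inf handed to the optimiser (keeps finite-difference
#: gradients defined near the singular boundary)
_BIG = 1e15


def _component_blocks(v: np.ndarray):
    """A, C, E 2x2 covariance blocks from the 11-vector, without building
    CholeskyParams (hot path for fitting and profiling)."""
    blocks = []
    for o in (0, 3, 6):
        a, b, c = v[o], v[o + 1], v[o + 2]
        blocks.append(np.array([[a * a, a * b], [a * b, b * b + c * c]]))
    return blocks


def _neg2ll_compiled(vec: np.ndarray, groups, model: str) -> float:
    a, c, e = _component_blocks(vec)
    within = a + c + e
    cross_mz = a + c
    cross_dz = 0.5 * a + (0.25 * c if model == "ADE" else c)
    sig = {"MZ": np.block([[within, cross_mz], [cross_mz, within]]),
           "DZ": np.block([[within, cross_dz], [cross_dz, within]])}
    mu4 = vec[9:11][_MU_INDEX]
    total = 0.0
    for zyg, idx, n, ybar, scatter in groups:
        sub = sig[zyg][np.ix_(idx, idx)]
        try:
            cf = linalg.cho_factor(sub, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        d = ybar - mu4[idx]
        sinv_s = linalg.cho_solve(cf, scatter, check_finite=False)
        sinv_d = linalg.cho_solve(cf, d, check_finite=False)
        total += n * (len(idx) * LOG_2PI + logdet
                      + np.trace(sinv_s) + d @ sinv_d)
    return total


def _objective(vec: np.ndarray, groups, model: str) -> float:
    return min(_neg2ll_compiled(vec, groups, model), _BIG)


def neg2_loglik(params: CholeskyParams, data: pd.DataFrame,
                model: str = "ACE") -> float:
    """-2 log FIML likelihood of the twin dataset under ``params``.

    Pairs with partially missing trait vectors contribute a reduced-dimension
    multivariate-normal term; a singular reduced covariance yields +inf.
    """
    return _neg2ll_compiled(params.to_vector(), _compile(data), model)


def _psd_chol(m: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Lower Cholesky factor of the PSD projection of a symmetric matrix."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    m = (v * np.clip(w, floor, None)) @ v.T
    return linalg.cholesky(m, lower=True)


def _moment_starts(data: pd.DataFrame, model: str) -> list[np.ndarray]:
    """Starting points: a Falconer-style moment estimator plus fixed
    alternatives spanning A-heavy, C-heavy and equal-split decompositions."""
    y = data[_TRAIT_COLS].to_numpy(dtype=float)
    mu = np.nanmean(np.vstack([y[:, 0:2], y[:, 2:4]]), axis=0)
    mu = np.nan_to_num(mu)

    def cross_block(zyg: str) -> np.ndarray | None:
        rows = y[(data["zygosity"] == zyg).to_numpy()]
        rows = rows[np.isfinite(rows).all(axis=1)]
        if len(rows) < 3:
            return None
        c = np.cov(rows, rowvar=False)
        return 0.5 * (c[:2, 2:] + c[2:, :2].T), 0.5 * (c[:2, :2] + c[2:, 2:])

    starts = []
    mz, dz = cross_block("MZ"), cross_block("DZ")
    if mz is not None and dz is not None:
        xmz, wmz = mz
        xdz, wdz = dz
        xmz = 0.5 * (xmz + xmz.T)
        xdz = 0.5 * (xdz + xdz.T)
        within = 0.5 * (wmz + wdz)
        if model == "ADE":
            a0 = 4.0 * xdz - xmz
            c0 = 2.0 * xmz - 4.0 * xdz
        else:
            a0 = 2.0 * (xmz - xdz)
            c0 = 2.0 * xdz - xmz
        e0 = within - xmz
        starts.append(np.concatenate([
            _tril(a0), _tril(c0), _tril(e0, floor=1e-3), mu]))
    v = np.nanvar(np.vstack([y[:, 0:2], y[:, 2:4]]), axis=0)
    v = np.where(np.isfinite(v) & (v > 0), v, 1.0)
    for wa, wc, we in ((1 / 3, 1 / 3, 1 / 3), (0.6, 0.05, 0.35),
                       (0.1, 0.5, 0.4), (0.45, 0.1, 0.45)):
        starts.append(np.concatenate([
            [math.sqrt(wa * v[0]), 0, math.sqrt(wa * v[1])],
            [math.sqrt(wc * v[0]), 0, math.sqrt(wc * v[1])],
            [math.sqrt(we * v[0]), 0, math.sqrt(we * v[1])],
            mu]))
    return starts


def _tril(m: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    f = _psd_chol(m, floor)
    return np.array([f[0, 0], f[1, 0], f[1, 1]])


_BOUNDS = (
    [(0.0, 10.0), (-10.0, 10.0), (0.0, 10.0)] * 2
    + [(1e-4, 10.0), (-10.0, 10.0), (1e-4, 10.0)]
    + [(-10.0, 10.0)] * 2
)


@dataclasses.dataclass
class VarianceComponents:
    """Correlated-factors summary of a bivariate fit: standardised variance
    proportions per trait and cross-trait factor correlations (NaN when the
    corresponding component variance is zero, since the correlation is then
    undefined)."""

    A1: float
    C1: float
    E1: float
    A2: float
    C2: float
    E2: float
    r_a: float
    r_c: float
    r_e: float
    model: str = "ACE"

    def shared_genetic_effect(self) -> float:
        return shared_genetic_effect(self.A1, self.r_a, self.A2)

    @property
    def implied_rp(self) -> float:
        terms = 0.0
        for v1, v2, r in ((self.A1, self.A2, self.r_a),
                          (self.C1, self.C2, self.r_c),
                          (self.E1, self.E2, self.r_e)):
            if v1 > 0 and v2 > 0 and np.isfinite(r):
                terms += math.sqrt(v1 * v2) * r
        return terms

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def standardize_components(params: CholeskyParams,
                           model: str = "ACE") -> VarianceComponents:
    """Convert Cholesky path estimates to the correlated-factors solution.

    Proportions are the per-trait diagonal shares of total variance; each
    cross-trait correlation is the off-diagonal of its component block scaled
    by the geometric mean of the diagonals.
    """
    a, c, e = params.sigma_a, params.sigma_c, params.sigma_e
    tot = np.diag(a) + np.diag(c) + np.diag(e)
    if (tot <= 0).any():
        raise ValueError("zero total variance for a trait")

    def corr(block: np.ndarray) -> float:
        denom = block[0, 0] * block[1, 1]
        return block[0, 1] / math.sqrt(denom) if denom > 1e-24 else np.nan

    return VarianceComponents(
        A1=a[0, 0] / tot[0], C1=c[0, 0] / tot[0], E1=e[0, 0] / tot[0],
        A2=a[1, 1] / tot[1], C2=c[1, 1] / tot[1], E2=e[1, 1] / tot[1],
        r_a=corr(a), r_c=corr(c), r_e=corr(e), model=model,
    )


def shared_genetic_effect(a1: float, r_a: float, a2: float) -> float:
    """Genetic contribution to the phenotypic correlation:
    sqrt(A1) * rA * sqrt(A2) (signed; take abs for the magnitude)."""
    if a1 < 0 or a2 < 0:
        raise ValueError("variance proportions must be non-negative")
    return math.sqrt(a1) * r_a * math.sqrt(a2)


def proportion_of_rp_genetic(shared: float, r_p: float) -> float:
    """Fraction of the phenotypic correlation attributable to shared genetic
    effects (shared / rP); undefined when rP is zero."""
    if r_p == 0:
        raise ValueError("phenotypic correlation is zero; proportion undefined")
    return shared / r_p


@dataclasses.dataclass
class BivariateACEFit:
    params: CholeskyParams
    minus2ll: float
    components: VarianceComponents
    model: str
    converged: bool
    n_iter: int
    grad_norm: float
    boundary_flags: list[str]
    n_pairs: dict
    ci: pd.DataFrame | None = None


def fit_bivariate_ace(data: pd.DataFrame, model: str = "ACE",
                      options: dict | None = None) -> BivariateACEFit:
    """Maximum-likelihood fit of the bivariate Cholesky twin model.

    Minimises the FIML -2 log-likelihood over the nine Cholesky paths and two
    means with L-BFGS-B from several moment-informed starting points
    (Falconer contrast of MZ/DZ covariances plus fixed alternative splits),
    keeping the best optimum; ties broken by parameter norm.  Cholesky
    diagonals are bounded at zero, so AE/CE submodels arise as boundary
    solutions and are flagged.

    Requires both zygosity groups; a single-zygosity dataset cannot separate
    A from C and is rejected.
    """
    opts = {"maxiter": 500, "starts": None, "require_both_zygosities": True}
    if options:
        opts.update(options)
    if model not in ("ACE", "ADE"):
        raise ValueError("model must be 'ACE' or 'ADE'")
    groups = _compile(data)
    zygs = {g[0] for g in groups}
    if opts["require_both_zygosities"] and zygs != {"MZ", "DZ"}:
        raise ValueError(
            "both MZ and DZ pairs are required to identify A and C; "
            f"found only {sorted(zygs)}")

    starts = opts["starts"] or _moment_starts(data, model)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS])
        res = optimize.minimize(
            _objective, x0, args=(groups, model), method="L-BFGS-B",
            bounds=_BOUNDS, options={"maxiter": opts["maxiter"]})
        key = (round(res.fun, 6), np.linalg.norm(res.x))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    if not np.isfinite(res.fun):
        raise RuntimeError(f"optimisation failed from all starts: {res.message}")
    params = CholeskyParams.from_vector(res.x)
    comps = standardize_components(params, model)
    flags = []
    for name, val in (("A1", comps.A1), ("C1", comps.C1), ("A2", comps.A2),
                      ("C2", comps.C2)):
        if val < 1e-3:
            flags.append(f"{name} at boundary 0")
    n_pairs = data["zygosity"].value_counts().to_dict()
    grad = getattr(res, "jac", np.array([np.nan]))
    return BivariateACEFit(
        params=params, minus2ll=float(res.fun), components=comps, model=model,
        converged=bool(res.success), n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(grad))), boundary_flags=flags,
        n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# derived quantities and confidence intervals

_QUANTITY_BOUNDS = {
    "A1": (0.0, 1.0), "C1": (0.0, 1.0), "E1": (0.0, 1.0),
    "A2": (0.0, 1.0), "C2": (0.0, 1.0), "E2": (0.0, 1.0),
    "rA": (-1.0, 1.0), "rC": (-1.0, 1.0), "rE": (-1.0, 1.0),
    "shared": (-1.0, 1.0),
}

DEFAULT_CI_QUANTITIES = ["A1", "C1", "E1", "A2", "C2", "E2", "rA", "rE"]


def _quantity(vec: np.ndarray, name: str, model: str) -> float:
    a, c, e = _component_blocks(vec)
    tot = np.diag(a) + np.diag(c) + np.diag(e)
    if name in ("A1", "C1", "E1"):
        return {"A1": a, "C1": c, "E1": e}[name][0, 0] / tot[0]
    if name in ("A2", "C2", "E2"):
        return {"A2": a, "C2": c, "E2": e}[name][1, 1] / tot[1]
    if name in ("rA", "rC", "rE"):
        block = {"rA": a, "rC": c, "rE": e}[name]
        denom = block[0, 0] * block[1, 1]
        return block[0, 1] / math.sqrt(denom) if denom > 1e-24 else np.nan
    if name == "shared":
        denom = a[0, 0] * a[1, 1]
        ra = a[0, 1] / math.sqrt(denom) if denom > 1e-24 else np.nan
        return math.sqrt(a[0, 0] / tot[0]) * ra * math.sqrt(a[1, 1] / tot[1])
    raise KeyError(name)


def _profile_bound(groups, model, name, base_vec, base_ll, thresh,
                   direction, maxiter=200):
    """One-sided profile-likelihood bound for a derived quantity.

    The constrained optimum at quantity value t is approximated by a
    quadratic penalty (weight escalated until the constraint holds to 1e-3);
    the bound is located by doubling steps to bracket the chi-square
    threshold, then bisection on t.
    """
    lo_nat, hi_nat = _QUANTITY_BOUNDS.get(name, (-np.inf, np.inf))
    q0 = _quantity(base_vec, name, model)
    warm = base_vec.copy()

    def profile(t: float) -> tuple[float, np.ndarray]:
        nonlocal warm
        w = 1e4
        x = warm
        for _ in range(4):
            res = optimize.minimize(
                lambda v: _objective(v, groups, model)
                + w * (_quantity(v, name, model) - t) ** 2,
                x, method="L-BFGS-B", bounds=_BOUNDS,
                options={"maxiter": maxiter})
            x = res.x
            if abs(_quantity(x, name, model) - t) < 1e-3:
                break
            w *= 30
        warm = x
        return _neg2ll_compiled(x, groups, model), x

    step = 0.03 if name in _QUANTITY_BOUNDS else 0.25 * (abs(q0) + 0.1)
    t_in = q0
    boundary = False
    t_out = None
    for _ in range(30):
        t = q0 + direction * step
        if t <= lo_nat or t >= hi_nat:
            t = lo_nat if direction < 0 else hi_nat
            val, _x = profile(t)
            if val <= thresh:
                return t, True  # CI endpoint pinned at the parameter bound
            t_out = t
            break
        val, _x = profile(t)
        if val > thresh:
            t_out = t
            break
        t_in = t
        step *= 2
    if t_out is None:
        return q0 + direction * step, True
    for _ in range(40):
        if abs(t_out - t_in) < 5e-4:
            break
        mid = 0.5 * (t_in + t_out)
        val, _x = profile(mid)
        if val > thresh:
            t_out = mid
        else:
            t_in = mid
    return 0.5 * (t_in + t_out), boundary


def profile_interval_covers(fit: BivariateACEFit, data: pd.DataFrame,
                            quantity: str, value: float,
                            level: float = 0.95) -> bool:
    """Whether the profile-likelihood CI for ``quantity`` contains ``value``.

    Equivalent to not rejecting the likelihood-ratio test of
    ``quantity == value`` at 1 - level: the constrained -2 lnL (computed by
    penalised optimisation, as in the interval search) must lie within the
    chi-square(1) quantile of the unconstrained optimum.  Much cheaper than
    locating both interval endpoints, so usable in coverage studies.
    """
    groups = _compile(data)
    est = _quantity(fit.params.to_vector(), quantity, fit.model)
    if not np.isfinite(est):
        return False
    if abs(est - value) < 1e-12:
        return True
    thresh = fit.minus2ll + stats.chi2.ppf(level, 1)
    w = 1e4
    x = fit.params.to_vector()
    for _ in range(4):
        res = optimize.minimize(
            lambda v: _objective(v, groups, fit.model)
            + w * (_quantity(v, quantity, fit.model) - value) ** 2,
            x, method="L-BFGS-B", bounds=_BOUNDS, options={"maxiter": 200})
        x = res.x
        if abs(_quantity(x, quantity, fit.model) - value) < 1e-3:
            break
        w *= 30
    return _neg2ll_compiled(x, groups, fit.model) <= thresh


def _simulate_from_fit(params: CholeskyParams, model: str,
                       n_mz: int, n_dz: int, rng) -> pd.DataFrame:
    frames = []
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        sigma = model_implied_covariance(params, zyg, model)
        mu4 = params.mu[_MU_INDEX]
        y = rng.multivariate_normal(mu4, sigma, size=n, method="cholesky")
        frames.append(pd.DataFrame({
            "pair_id": [f"{zyg}{i}" for i in range(n)],
            "zygosity": zyg,
            **{col: y[:, j] for j, col in enumerate(_TRAIT_COLS)},
        }))
    return pd.concat(frames, ignore_index=True)


def confidence_intervals(
    fit: BivariateACEFit,
    data: pd.DataFrame,
    method: str = "profile",
    level: float = 0.95,
    quantities: list[str] | None = None,
    options: dict | None = None,
) -> pd.DataFrame:
    """Confidence intervals for standardised components and correlations.

    ``profile`` inverts the likelihood-ratio test: each bound is the quantity
    value at which the constrained -2 lnL exceeds the optimum by the
    chi-square(1) quantile.  ``bootstrap`` refits parametric resamples drawn
    from the fitted model and takes percentile intervals.  Bounds pinned at
    the parameter-space edge (0/1 for proportions, +-1 for correlations) are
    flagged ``boundary``.
    """
    opts = {"n_boot": 200, "seed": 0, "maxiter": 200}
    if options:
        opts.update(options)
    quantities = quantities or DEFAULT_CI_QUANTITIES
    groups = _compile(data)
    base_vec = fit.params.to_vector()
    rows = []
    if method == "profile":
        thresh = fit.minus2ll + stats.chi2.ppf(level, 1)
        for name in quantities:
            est = _quantity(base_vec, name, fit.model)
            if not np.isfinite(est):
                rows.append((name, est, np.nan, np.nan, "profile", "undefined"))
                continue
            lo, lo_b = _profile_bound(groups, fit.model, name, base_vec,
                                      fit.minus2ll, thresh, -1, opts["maxiter"])
            hi, hi_b = _profile_bound(groups, fit.model, name, base_vec,
                                      fit.minus2ll, thresh, +1, opts["maxiter"])
            flag = "boundary" if (lo_b or hi_b) else ""
            rows.append((name, est, lo, hi, "profile", flag))
    elif method == "bootstrap":
        rng = np.random.default_rng(opts["seed"])
        counts = {z: int((data["zygosity"] == z).sum()) for z in ("MZ", "DZ")}
        draws = {name: [] for name in quantities}
        for _ in range(opts["n_boot"]):
            rep = _simulate_from_fit(fit.params, fit.model,
                                     counts["MZ"], counts["DZ"], rng)
            rep_groups = _compile(rep)
            res = optimize.minimize(
                _objective, base_vec, args=(rep_groups, fit.model),
                method="L-BFGS-B", bounds=_BOUNDS,
                options={"maxiter": opts["maxiter"]})
            for name in quantities:
                draws[name].append(_quantity(res.x, name, fit.model))
        alpha = 1.0 - level
        for name in quantities:
            est = _quantity(base_vec, name, fit.model)
            arr = np.asarray(draws[name], dtype=float)
            arr = arr[np.isfinite(arr)]
            lo, hi = np.quantile(arr, [alpha / 2, 1 - alpha / 2])
            # percentile interval widened to include the point estimate
            rows.append((name, est, min(lo, est), max(hi, est),
                         "bootstrap", ""))
    else:
        raise ValueError("method must be 'profile' or 'bootstrap'")
    return pd.DataFrame(rows, columns=["quantity", "estimate", "lower",
                                       "upper", "method", "flag"])


def phenotypic_correlation(data: pd.DataFrame, method: str = "pooled",
                           seed: int | None = None) -> float:
    """Within-person cross-trait Pearson correlation.

    ``pooled`` stacks both twins of every pair; ``one_per_pair`` samples one
    twin per pair (seeded) so observations are independent, at the cost of
    half the sample.
    """
    validate_twin_dataset(data)
    t1 = np.concatenate([data["trait1_t1"], data["trait1_t2"]])
    t2 = np.concatenate([data["trait2_t1"], data["trait2_t2"]])
    if method == "one_per_pair":
        rng = np.random.default_rng(seed)
        pick = rng.integers(2, size=len(data))
        n = len(data)
        idx = np.arange(n) + pick * n
        t1, t2 = t1[idx], t2[idx]
    elif method != "pooled":
        raise ValueError("method must be 'pooled' or 'one_per_pair'")
    ok = np.isfinite(t1) & np.isfinite(t2)
    t1, t2 = t1[ok], t2[ok]
    if len(t1) < 3:
        raise ValueError("need at least 3 complete individuals")
    if t1.std() < 1e-12 or t2.std() < 1e-12:
        raise ValueError("zero variance in a trait")
    return float(np.corrcoef(t1, t2)[0, 1])
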