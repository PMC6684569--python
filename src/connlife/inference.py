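"""Statistical layer: partial correlations with covariate control, BH-FDR,
Kolmogorov-Smirnov normality checks, and bootstrap mediation.

The mediation model treats age as the independent variable x, a functional
connectivity measure as the mediator M, and cognitive score as the outcome
y, with sex controlled in every regression:

    M = a x + covariates + e1
    y = b M + c' x + covariates + e2
    y = c x + covariates + e3

The indirect effect is ab = a*b, which for OLS with identical covariates
in all three regressions equals c - c' exactly.  Bootstrap inference
resamples subjects with replacement; per path, z is the bootstrap
mean/SD and p the two-sided percentile probability of the distribution
crossing zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateInputError,
    ParameterError,
    UndefinedStatisticError,
    ValidationError,
)

PATHS = ("a", "b", "c_prime", "c", "ab")


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p: float
    n: int
    df: int
    covariates: tuple[str, ...] = ()
    fdr_significant: bool | None = None


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def partial_correlation(
    x,
    y,
    covariates=None,
    add_intercept: bool = True,
    covariate_names: tuple[str, ...] = (),
) -> PartialCorrelationResult:
    """Pearson correlation of the residuals of x and y on the covariates.

    The p-value uses the t distribution with df = n - 2 - n_covariates.
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("x and y lengths differ")
    n = x.size
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValidationError("covariate length differs from x/y")
    k = C.shape[1]
    if n <= 2 + k:
        raise ParameterError(f"need n > 2 + {k} covariates, got n = {n}")
    Z = np.column_stack([np.ones(n), C]) if add_intercept else C
    if Z.shape[1]:
        rx, ry = _residualize(x, Z), _residualize(y, Z)
    else:
        rx, ry = x, y
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedStatisticError("zero residual variance after covariate removal")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p=p, n=n, df=df, covariates=covariate_names)


def bh_fdr(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level q.

    Sort p ascending, find the largest i with p_(i) <= i*q/m, flag all
    ranks <= i.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * np.arange(1, m + 1) / m
    passed = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        cutoff = np.max(np.flatnonzero(passed))
        flags[order[: cutoff + 1]] = True
    return flags


def ks_normality(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample KS test of standardized values against the standard normal.

    Returns (statistic, p, reject_flag at ``alpha``).  Standardizing first
    makes this a composite-normality screen rather than a test against a
    fully specified normal.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ParameterError(f"KS normality check needs n >= 5, got {v.size}")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance: normality undefined")
    z = (v - v.mean()) / sd
    stat, p = stats.kstest(z, "norm")
    return float(stat), float(p), bool(p < alpha)


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c_prime: float
    c: float
    ab: float
    n: int
    z_per_path: dict = field(default_factory=dict)
    p_per_path: dict = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    n_redraws: int = 0

    def path_table(self) -> pd.DataFrame:
        rows = []
        for path in PATHS:
            rows.append(
                {
                    "path": path,
                    "coef": getattr(self, path),
                    "z": self.z_per_path.get(path),
                    "p": self.p_per_path.get(path),
                }
            )
        return pd.DataFrame(rows)


def _design(x: np.ndarray, C: np.ndarray, *extra) -> np.ndarray:
    return np.column_stack([np.ones(x.size), *extra, x, C])


def _check_xyc(x, mediator, y, covariates):
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(mediator, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (x.size == m.size == y.size):
        raise ValidationError("x, mediator and y lengths differ")
    if covariates is None:
        C = np.empty((x.size, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != x.size:
            raise ValidationError("covariate length differs from x")
    p_max = 3 + C.shape[1]
    if x.size <= p_max:
        raise ParameterError(f"need n > {p_max} observations, got {x.size}")
    return x, m, y, C


def _ols_coefs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("collinear mediation design; pseudoinverse used", stacklevel=3)
    return coef


def fit_mediation(x, mediator, y, covariates=None) -> MediationResult:
    """Point estimates of the mediation paths by three OLS fits."""
    x, m, yv, C = _check_xyc(x, mediator, y, covariates)
    a = float(_ols_coefs(_design(x, C), m)[1])
    bm = _ols_coefs(np.column_stack([np.ones(x.size), m, x, C]), yv)
    b, c_prime = float(bm[1]), float(bm[2])
    c = float(_ols_coefs(_design(x, C), yv)[1])
    return MediationResult(a=a, b=b, c_prime=c_prime, c=c, ab=a * b, n=x.size)


def _batched_paths(
    x: np.ndarray, m: np.ndarray, yv: np.ndarray, C: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Vectorized per-draw path coefficients.

    ``idx`` is B x n resample indices; returns a B x 5 array of
    (a, b, c', c, ab), solving the three normal-equation systems for every
    draw with one batched ``solve`` each.  Raises LinAlgError on any
    singular draw (caller redraws).
    """
    n = x.size
    Xa = np.column_stack([np.ones(n), x, C])            # mediator model
    Xb = np.column_stack([np.ones(n), m, x, C])         # outcome model
    a = _batched_coef(Xa[idx], m[idx], 1)
    bm = _batched_coef2(Xb[idx], yv[idx], (1, 2))
    c = _batched_coef(Xa[idx], yv[idx], 1)
    b, c_prime = bm[:, 0], bm[:, 1]
    return np.column_stack([a, b, c_prime, c, a * b])


def _batched_coef(Xb: np.ndarray, yb: np.ndarray, j: int) -> np.ndarray:
    G = np.einsum("bij,bik->bjk", Xb, Xb)
    h = np.einsum("bij,bi->bj", Xb, yb)
    return np.linalg.solve(G, h[..., None])[:, j, 0]


def _batched_coef2(Xb: np.ndarray, yb: np.ndarray, js: tuple[int, int]) -> np.ndarray:
    G = np.einsum("bij,bik->bjk", Xb, Xb)
    h = np.einsum("bij,bi->bj", Xb, yb)
    beta = np.linalg.solve(G, h[..., None])[..., 0]
    return beta[:, list(js)]


class Mediation(BaseEstimator):
    """Bootstrap mediation estimator (sklearn-style).

    Parameters
    ----------
    n_boot : int, default 10000
        Bootstrap resamples; at least ~1000 for inference-grade p-values.
    seed : int or None
        Seed for the resampling stream; fixed seed gives identical z and p.
    ci_method : {"percentile", "bca"}
        Confidence-interval flavour for :meth:`conf_int`.  p-values always
        use the percentile rule 2*min(frac<=0, frac>=0), floored at
        2/n_boot.

    Fitted attributes: ``a_``, ``b_``, ``c_prime_``, ``c_``, ``ab_``,
    ``z_per_path_``, ``p_per_path_``, ``boot_paths_`` (n_boot x 5),
    ``result_`` (a :class:`MediationResult`).
    """

    def __init__(
        self, n_boot: int = 10000, seed: int | None = None, ci_method: str = "percentile"
    ):
        self.n_boot = n_boot
        self.seed = seed
        self.ci_method = ci_method

    def fit(self, x, mediator, y, covariates=None):
        if self.ci_method not in ("percentile", "bca"):
            raise ParameterError(f"unknown ci_method {self.ci_method!r}")
        x, m, yv, C = _check_xyc(x, mediator, y, covariates)
        point = fit_mediation(x, m, yv, C)
        n = x.size
        rng = np.random.default_rng(self.seed)
        boots = np.empty((self.n_boot, 5))
        filled = 0
        redraws = 0
        while filled < self.n_boot:
            todo = self.n_boot - filled
            idx = rng.integers(0, n, size=(todo, n))
            try:
                boots[filled:] = _batched_paths(x, m, yv, C, idx)
                filled = self.n_boot
            except np.linalg.LinAlgError:
                # a degenerate draw (constant regressor) somewhere in the
                # batch: fall back to per-draw solves, redrawing bad ones
                for row in idx:
                    while True:
                        try:
                            boots[filled] = _batched_paths(x, m, yv, C, row[None])[0]
                            break
                        except np.linalg.LinAlgError:
                            redraws += 1
                            row = rng.integers(0, n, size=n)
                    filled += 1
                    if filled == self.n_boot:
                        break
        z = {}
        p = {}
        for j, path in enumerate(PATHS):
            col = boots[:, j]
            sd = col.std(ddof=1)
            z[path] = float(col.mean() / sd) if sd > 0 else float("inf")
            frac_le = np.mean(col <= 0)
            frac_ge = np.mean(col >= 0)
            p[path] = float(min(1.0, max(2.0 / self.n_boot, 2.0 * min(frac_le, frac_ge))))
        self.a_, self.b_ = point.a, point.b
        self.c_prime_, self.c_, self.ab_ = point.c_prime, point.c, point.ab
        self.boot_paths_ = boots
        self.z_per_path_, self.p_per_path_ = z, p
        self.n_redraws_ = redraws
        self._data_ = (x, m, yv, C)
        self.result_ = MediationResult(
            a=point.a,
            b=point.b,
            c_prime=point.c_prime,
            c=point.c,
            ab=point.ab,
            n=n,
            z_per_path=z,
            p_per_path=p,
            n_boot=self.n_boot,
            seed=self.seed,
            n_redraws=redraws,
        )
        return self

    def conf_int(self, path: str = "ab", level: float = 0.95) -> tuple[float, float]:
        """Bootstrap confidence interval for one path (percentile or BCa)."""
        j = PATHS.index(path)
        boots = self.boot_paths_[:, j]
        alpha = 1.0 - level
        if self.ci_method == "percentile":
            lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
            return float(lo), float(hi)
        # BCa: bias correction from the bootstrap distribution, acceleration
        # from the jackknife.
        theta = getattr(self, f"{path}_")
        z0 = stats.norm.ppf(np.clip(np.mean(boots < theta), 1e-9, 1 - 1e-9))
        x, m, yv, C = self._data_
        n = x.size
        jack = np.empty(n)
        keep = np.arange(n)
        for i in range(n):
            sel = np.delete(keep, i)
            jack[i] = _batched_paths(x, m, yv, C, sel[None])[0, j]
        jm = jack.mean()
        num = np.sum((jm - jack) ** 3)
        den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
        acc = num / den if den > 0 else 0.0
        zlo, zhi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
        q_lo = stats.norm.cdf(z0 + (z0 + zlo) / (1 - acc * (z0 + zlo)))
        q_hi = stats.norm.cdf(z0 + (z0 + zhi) / (1 - acc * (z0 + zhi)))
        lo, hi = np.quantile(boots, [q_lo, q_hi])
        return float(lo), float(hi)


def bootstrap_mediation(
    x, mediator, y, covariates=None, n_boot: int = 10000, seed: int | None = None
) -> MediationResult:
    """Bootstrap mediation inference (wrapper over :class:`Mediation`)."""
    est = Mediation(n_boot=n_boot, seed=seed).fit(x, mediator, y, covariates)
    return est.result_


def mediation_candidates(
    measures: pd.DataFrame, age, ace, sex, alpha: float = 0.05
) -> list[str]:
    """Columns of ``measures`` eligible for mediation: uncorrected p < 0.05
    against both age (controlling sex) and ACE-R (controlling age and sex).
    """
    age = np.asarray(age, dtype=float)
    ace = np.asarray(ace, dtype=float)
    sex = np.asarray(sex, dtype=float)
    out = []
    for col in measures.columns:
        v = measures[col].to_numpy(dtype=float)
        p_age = partial_correlation(v, age, covariates=sex).p
        p_ace = partial_correlation(
            v, ace, covariates=np.column_stack([age, sex])
        ).p
        if p_age < alpha and p_ace < alpha:
            out.append(col)
    return out
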