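"""Linear association engine.

Fits ordinary least squares models of inverse-normal phenotypes on variant
dosage plus covariates and reports two-sided p-values as finite
negative-log10 values, accurate far below floating-point underflow.  A
Frisch-Waugh-Lovell fast path residualizes the phenotype block and the
dosage once per missingness pattern and reproduces the naive per-test fit
exactly (same coefficients, standard errors and degrees of freedom).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special

from .datatypes import STAGE_INT, STAGE_LOG, TraitMatrix
from .errors import (
    DegenerateVariantError,
    RankDeficiencyError,
    ValidationError,
)
from .preprocess import BLOM_OFFSET, TestId, phenotype

LN10 = math.log(10.0)

#: Cap on neglog10_p for perfect (zero-residual) fits; keeps matrices finite.
PERFECT_FIT_CAP = 9999.0

#: Two-sided p below which the direct t survival function is abandoned for
#: the log-space route (comfortably above double underflow at ~1e-308).
_UNDERFLOW_SWITCH = 1e-280


# ---------------------------------------------------------------------------
# extreme p-values in log space
# ---------------------------------------------------------------------------

def _log_betacf(a: float, b: float, x: float, max_iter: int = 100000, eps: float = 1e-16) -> float:
    """Continued fraction for the regularized incomplete beta (NR betacf).

    Converges rapidly for ``x < (a + 1) / (a + b + 2)``, which always holds
    in the deep-tail regime where this routine is used.
    """
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            return h
    raise ValidationError("incomplete-beta continued fraction did not converge")


def _neglog10_t_logspace(t_abs: float, df: float) -> float:
    """Two-sided t tail via log-space regularized incomplete beta.

    ``p = I_x(df/2, 1/2)`` with ``x = df / (df + t^2)``; evaluated entirely
    on the log scale so the result stays finite for arbitrarily large |t|.
    """
    a = df / 2.0
    b = 0.5
    x = df / (df + t_abs * t_abs)
    cf = _log_betacf(a, b, x)
    log_p = (
        a * math.log(x)
        + b * math.log1p(-x)
        - math.log(a)
        - special.betaln(a, b)
        + math.log(cf)
    )
    return -log_p / LN10


def _neglog10_normal(z_abs: float) -> float:
    """Two-sided normal tail from the log CDF (asymptotic-safe for any z)."""
    return -(math.log(2.0) + float(special.log_ndtr(-z_abs))) / LN10


def neglog10_p_from_t(t_stat: float, df: float) -> float:
    """Negative log10 of the two-sided t-tail probability.

    Uses the standard survival function in the underflow-safe regime and a
    log-space incomplete-beta continued fraction (normal log-CDF for
    infinite df) beyond it; the two branches agree to well within 1e-6
    relative at the switch point.
    """
    if not np.isfinite(t_stat):
        raise ValidationError(f"non-finite t statistic: {t_stat!r}")
    if not (df >= 1):
        raise ValidationError(f"df must be >= 1, got {df!r}")
    t_abs = abs(float(t_stat))
    if t_abs == 0.0:
        return 0.0
    if math.isinf(df):
        p = 2.0 * float(special.ndtr(-t_abs))
        if p > _UNDERFLOW_SWITCH:
            return -math.log10(p)
        return _neglog10_normal(t_abs)
    p = 2.0 * float(special.stdtr(df, -t_abs))
    if p > _UNDERFLOW_SWITCH:
        return -math.log10(p)
    return _neglog10_t_logspace(t_abs, df)


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def _as_design(covariates) -> tuple[np.ndarray, list[str]]:
    """Covariates -> (2-D float array, column names); None -> empty block."""
    if covariates is None:
        return np.empty((0, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), [str(c) for c in covariates.columns]
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise RankDeficiencyError naming the pivoted-out columns."""
    if X.shape[1] == 0:
        return
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [names[i] for i in piv[rank:]]
        raise RankDeficiencyError(bad)


@dataclass
class AssociationResult:
    """One (variant, test) regression outcome for the dosage/exposure term."""

    variant: str
    test: TestId | None
    beta: float
    se: float
    t_stat: float
    neglog10_p: float
    n: int
    df: int
    perfect_fit: bool = False

    @property
    def p_value(self) -> float:
        """Two-sided p; underflows to 0.0 for extreme signals (use neglog10_p)."""
        return 10.0 ** (-self.neglog10_p)


def _fit_core(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    term: int,
    variant: str,
    test: TestId | None,
    cap: float,
) -> AssociationResult:
    """OLS of y on X; inference for column ``term``.  Inputs are complete-case."""
    n, p = X.shape
    _check_rank(X, names)
    XtX = X.T @ X
    Xty = X.T @ y
    coef = linalg.solve(XtX, Xty, assume_a="pos")
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = n - p
    tss = float(((y - y.mean()) ** 2).sum())
    inv_term = float(linalg.solve(XtX, np.eye(p)[:, term], assume_a="pos")[term])
    beta = float(coef[term])
    if rss <= max(tss, 1.0) * 1e-24:
        warnings.warn(
            f"perfect fit for variant {variant!r}; neglog10_p capped at {cap}",
            RuntimeWarning,
            stacklevel=3,
        )
        return AssociationResult(variant, test, beta, 0.0, math.inf if beta else 0.0, cap, n, dof, True)
    sigma2 = rss / dof
    se = math.sqrt(sigma2 * inv_term)
    t = beta / se
    return AssociationResult(variant, test, beta, se, t, neglog10_p_from_t(t, dof), n, dof)


def fit_linear_assoc(
    y,
    dosage,
    covariates=None,
    conditional=None,
    variant: str = "",
    test: TestId | None = None,
    min_n: int = 10,
    cap: float = PERFECT_FIT_CAP,
) -> AssociationResult:
    """OLS of ``y`` on [intercept, dosage, covariates, conditional dosages].

    Rows with any missing value in the model variables are dropped
    (listwise deletion); the complete-case ``n`` is reported.  Effect size,
    SE and t refer to the dosage term; the two-sided p-value is reported as
    ``neglog10_p`` via :func:`neglog10_p_from_t`.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    C, cnames = _as_design(covariates)
    D, dnames = _as_design(conditional)
    n_total = y.shape[0]
    if g.shape[0] != n_total:
        raise ValidationError("y and dosage lengths differ")
    mask = ~np.isnan(y) & ~np.isnan(g)
    blocks = [g[:, None]]
    if C.size:
        mask &= ~np.isnan(C).any(axis=1)
        blocks.append(C)
    if D.size:
        mask &= ~np.isnan(D).any(axis=1)
        blocks.append(D)
    n = int(mask.sum())
    if n < min_n:
        raise ValidationError(f"only {n} complete cases (< {min_n})")
    gm = g[mask]
    if np.all(gm == gm[0]):
        raise DegenerateVariantError(f"dosage constant on complete cases for {variant!r}")
    X = np.column_stack([np.ones(n)] + [b[mask] for b in blocks])
    names = ["intercept", "dosage"] + cnames + dnames
    return _fit_core(y[mask], X, names, term=1, variant=variant, test=test, cap=cap)


def residualize(matrix, covariates) -> np.ndarray:
    """Replace each column with its OLS residual against [1, covariates].

    All rows must be complete (the caller selects the shared complete-case
    set); residuals are orthogonal to the covariate block by construction.
    """
    M = np.asarray(matrix, dtype=float)
    one_d = M.ndim == 1
    if one_d:
        M = M[:, None]
    C, cnames = _as_design(covariates)
    n = M.shape[0]
    X = np.ones((n, 1)) if not C.size else np.column_stack([np.ones(n), C])
    _check_rank(X, ["intercept"] + cnames)
    coef, *_ = np.linalg.lstsq(X, M, rcond=None)
    R = M - X @ coef
    return R[:, 0] if one_d else R


def scan_variant(
    variant: str,
    dosage,
    tests: list[TestId],
    log_traits: TraitMatrix,
    covariates=None,
    conditional=None,
    int_offset: float | str = BLOM_OFFSET,
    cap: float = PERFECT_FIT_CAP,
    min_n: int = 10,
) -> list[AssociationResult]:
    """Fit every test for one variant, sharing work across tests.

    Phenotypes (INT of log traits / log ratios) are built once; tests are
    grouped by phenotype missingness pattern and, per group, the phenotype
    block and the dosage are residualized against [intercept, covariates,
    conditional dosages] so each test reduces to a simple regression with
    degrees of freedom matching the full model.  Per-test degeneracies
    (constant phenotype, too few cases) yield flagged results, not aborts.
    """
    if log_traits.stage not in (STAGE_LOG,):
        raise ValidationError(f"scan_variant expects a log-stage panel, got {log_traits.stage!r}")
    g = np.asarray(dosage, dtype=float)
    C, cnames = _as_design(covariates)
    D, dnames = _as_design(conditional)
    if D.size:
        for j in range(D.shape[1]):
            col = D[:, j]
            both = ~np.isnan(col) & ~np.isnan(g)
            if both.any() and np.array_equal(col[both], g[both]):
                raise ValidationError(
                    f"conditional covariate {dnames[j]!r} equals the lead dosage for {variant!r}"
                )

    # phenotypes for all tests (full-sample INT, as in the naive route)
    Y = np.empty((log_traits.n_samples, len(tests)))
    usable = []
    for j, test in enumerate(tests):
        try:
            Y[:, j] = phenotype(log_traits, test, int_offset)
            usable.append(j)
        except Exception:
            Y[:, j] = np.nan

    base_mask = ~np.isnan(g)
    if C.size:
        base_mask &= ~np.isnan(C).any(axis=1)
    if D.size:
        base_mask &= ~np.isnan(D).any(axis=1)

    cov_block = np.column_stack([b for b in (C, D) if b.size]) if (C.size or D.size) else None
    k_cov = 0 if cov_block is None else cov_block.shape[1]

    results: list[AssociationResult | None] = [None] * len(tests)
    groups: dict[bytes, list[int]] = {}
    nan_y = np.isnan(Y[base_mask])
    for j in usable:
        groups.setdefault(nan_y[:, j].tobytes(), []).append(j)

    base_idx = np.flatnonzero(base_mask)
    for key, members in groups.items():
        col_nan = np.frombuffer(key, dtype=bool)
        rows = base_idx[~col_nan]
        n = rows.size
        dof = n - (k_cov + 2)  # intercept + dosage + covariate block
        if n < min_n or dof < 1:
            continue
        gm = g[rows]
        if np.all(gm == gm[0]):
            continue
        cov_rows = cov_block[rows] if cov_block is not None else None
        g_res = residualize(gm, cov_rows)
        Y_res = residualize(Y[np.ix_(rows, members)], cov_rows)
        gg = float(g_res @ g_res)
        if gg <= n * np.finfo(float).eps:
            continue
        gy = g_res @ Y_res
        betas = gy / gg
        rss = np.einsum("ij,ij->j", Y_res, Y_res) - betas**2 * gg
        rss = np.maximum(rss, 0.0)
        tss = np.einsum("ij,ij->j", Y_res, Y_res)
        for idx, j in enumerate(members):
            test = tests[j]
            if rss[idx] <= max(tss[idx], 1.0) * 1e-24:
                results[j] = AssociationResult(
                    variant, test, float(betas[idx]), 0.0,
                    math.inf if betas[idx] else 0.0, cap, n, dof, True,
                )
                continue
            sigma2 = rss[idx] / dof
            se = math.sqrt(sigma2 / gg)
            t = float(betas[idx]) / se
            results[j] = AssociationResult(
                variant, test, float(betas[idx]), se, t,
                neglog10_p_from_t(t, dof), n, dof,
            )
    return [r for r in results if r is not None]


@dataclass
class RatioFit:
    """Summary of a trait-on-ratio (or two-coefficient) regression."""

    mode: str
    coef: dict = field(default_factory=dict)  # name -> (estimate, se)
    r_squared: float = float("nan")
    n: int = 0


def trait_on_ratio(outcome, log_num, log_den, covariates=None, mode: str = "ratio") -> RatioFit:
    """Regress an outcome on a log ratio or on its two components separately.

    ``mode='ratio'`` uses the single predictor ``log_num - log_den``;
    ``mode='two_coef'`` enters ``log_num`` and ``log_den`` as separate
    terms so the equal-and-opposite pattern underlying a ratio
    relationship can be examined.  Returns coefficients, SEs and R^2.
    """
    if mode not in ("ratio", "two_coef"):
        raise ValidationError(f"unknown mode {mode!r}")
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(log_num, dtype=float)
    b = np.asarray(log_den, dtype=float)
    C, cnames = _as_design(covariates)
    mask = ~np.isnan(y) & ~np.isnan(a) & ~np.isnan(b)
    if C.size:
        mask &= ~np.isnan(C).any(axis=1)
    n = int(mask.sum())
    if n < 10:
        raise ValidationError(f"only {n} complete cases (< 10)")
    if mode == "ratio":
        preds = [(a - b)[mask]]
        pnames = ["log_ratio"]
    else:
        preds = [a[mask], b[mask]]
        pnames = ["log_num", "log_den"]
    blocks = [np.ones(n)] + preds + ([C[mask]] if C.size else [])
    X = np.column_stack(blocks)
    names = ["intercept"] + pnames + cnames
    _check_rank(X, names)
    ym = y[mask]
    XtX = X.T @ X
    coef = linalg.solve(XtX, X.T @ ym, assume_a="pos")
    resid = ym - X @ coef
    rss = float(resid @ resid)
    tss = float(((ym - ym.mean()) ** 2).sum())
    dof = n - X.shape[1]
    sigma2 = rss / dof if dof > 0 else float("nan")
    XtX_inv = linalg.solve(XtX, np.eye(X.shape[1]), assume_a="pos")
    ses = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    fit = RatioFit(mode=mode, n=n, r_squared=1.0 - rss / tss if tss > 0 else float("nan"))
    for name, c, s in zip(names, coef, ses):
        fit.coef[name] = (float(c), float(s))
    return fit


def exposure_assoc(
    traits: TraitMatrix,
    exposure,
    covariates=None,
    exclusions=None,
    min_n: int = 10,
) -> list[AssociationResult]:
    """Per-trait effect of a binary exposure, producing an effect profile.

    ``exclusions`` is a boolean mask of samples to drop before fitting
    (e.g. users of non-statin cholesterol-lowering drugs).  The exposure
    enters the model in place of the dosage term.
    """
    if traits.stage != STAGE_INT:
        raise ValidationError(f"exposure_assoc expects an INT-stage panel, got {traits.stage!r}")
    e = np.asarray(exposure, dtype=float)
    uniq = set(np.unique(e[~np.isnan(e)]))
    if not uniq <= {0.0, 1.0}:
        raise ValidationError(f"exposure must be binary 0/1, found values {sorted(uniq)[:5]}")
    keep = np.ones(traits.n_samples, dtype=bool)
    if exclusions is not None:
        keep &= ~np.asarray(exclusions, dtype=bool)
    ek = np.where(keep, e, np.nan)
    if len(set(np.unique(ek[~np.isnan(ek)]))) < 2:
        raise DegenerateVariantError("exposure constant after exclusions")
    cov = covariates
    results = []
    for trait in traits.data.columns:
        y = np.where(keep, traits.data[trait].to_numpy(), np.nan)
        results.append(
            fit_linear_assoc(y, ek, cov, variant="exposure", test=TestId.single(str(trait)), min_n=min_n)
        )
    return results
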