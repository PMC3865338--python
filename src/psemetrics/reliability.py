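"""Internal-consistency coefficients computed from first principles.

Implements the Guttman lower bounds lambda_1 .. lambda_6, Cronbach's alpha
(identical to lambda_3; KR-20 on dichotomous items), McDonald's omega total
from a minimum-residual common-factor fit, and Fisher-transformed mean
correlations.  All coefficients operate on an :class:`~psemetrics.data_model.
ItemMatrix`, so the same machinery serves category-score, picture-score and
dichotomous items.

Conventions
-----------
Variances and covariances use the population denominator N by default
(``ddof=0``), matching the expectation-based definitions the lower bounds were
derived under; the sample convention is available via ``ddof=1``.  The
ratio-form coefficients (lambda_1, alpha, lambda_4, lambda_6) are invariant to
this choice; lambda_2 and lambda_5 are not, because they take square roots of
summed squared covariances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize

from .data_model import ItemMatrix, ScoringTensor, to_category_items, \
    to_dichotomous_items, to_picture_items

__all__ = [
    "CovarianceSummary",
    "ReliabilityReport",
    "Lambda4Result",
    "OmegaResult",
    "covariance_summary",
    "alpha",
    "kr20",
    "lambda1",
    "lambda2",
    "lambda3",
    "lambda4",
    "lambda5",
    "lambda6",
    "lambda_suite",
    "omega_total",
    "fisher_mean_correlation",
    "reliability_report",
    "UndefinedCoefficientError",
    "InsufficientDataError",
]


class UndefinedCoefficientError(ValueError):
    """The coefficient is undefined for this matrix (e.g. zero test variance)."""


class InsufficientDataError(ValueError):
    """Too few subjects or items for the requested computation."""


def _check(m: ItemMatrix, min_items: int = 2) -> np.ndarray:
    x = np.asarray(m.scores, dtype=float)
    if x.shape[0] < 2:
        raise InsufficientDataError(
            f"need at least 2 subjects, got {x.shape[0]}"
        )
    if x.shape[1] < min_items:
        raise InsufficientDataError(
            f"need at least {min_items} items, got {x.shape[1]}"
        )
    return x


@dataclass
class CovarianceSummary:
    """Item-level first and second moments of one item matrix."""

    items: tuple[str, ...]
    means: np.ndarray
    variances: np.ndarray
    covariance: np.ndarray
    correlation: np.ndarray          # NaN where an item has zero variance
    total_variance: float
    item_total: np.ndarray           # item vs. rest-of-test correlation
    zero_variance_items: tuple[str, ...]
    ddof: int = 0

    def pairwise_covariance_sum(self) -> float:
        """Sum of covariances over unordered item pairs."""
        return float((self.covariance.sum() - np.trace(self.covariance)) / 2.0)


def covariance_summary(
    m: ItemMatrix, ddof: int = 0, item_total: Literal["rest", "total"] = "rest"
) -> CovarianceSummary:
    """Means, variances, covariance/correlation matrices and item-total r.

    ``item_total="rest"`` correlates each item with the sum of the remaining
    items (corrected item-total correlation); ``"total"`` uses the full test
    score including the item itself.
    """
    x = _check(m)
    n_sub = x.shape[0]
    cov = np.cov(x, rowvar=False, ddof=ddof)
    cov = np.atleast_2d(cov)
    var = np.diag(cov).copy()
    zero = var <= 0
    sd = np.sqrt(np.where(zero, np.nan, var))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
    total = x.sum(axis=1)
    vt = float(np.var(total, ddof=ddof))
    r_it = np.full(x.shape[1], np.nan)
    for j in range(x.shape[1]):
        ref = total - x[:, j] if item_total == "rest" else total
        if np.var(ref) > 0 and var[j] > 0:
            r_it[j] = np.corrcoef(x[:, j], ref)[0, 1]
    return CovarianceSummary(
        items=m.items,
        means=x.mean(axis=0),
        variances=var,
        covariance=cov,
        correlation=corr,
        total_variance=vt,
        item_total=r_it,
        zero_variance_items=tuple(
            lab for lab, z in zip(m.items, zero) if z
        ),
        ddof=ddof,
    )


def _var_terms(m: ItemMatrix, ddof: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """(item variances, covariance matrix, total variance) under one ddof."""
    x = _check(m)
    cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=ddof))
    vt = float(np.var(x.sum(axis=1), ddof=ddof))
    return np.diag(cov).copy(), cov, vt


def lambda1(m: ItemMatrix, ddof: int = 0) -> float:
    """Guttman's first lower bound: 1 - sum(V_j)/V_T."""
    var, _, vt = _var_terms(m, ddof)
    if vt <= 0:
        raise UndefinedCoefficientError("total score has zero variance")
    return float(1.0 - var.sum() / vt)


def lambda2(m: ItemMatrix, ddof: int = 0) -> float:
    """lambda_1 plus the covariance term sqrt(n/(n-1) * sum γ_jk^2)/V_T."""
    var, cov, vt = _var_terms(m, ddof)
    if vt <= 0:
        raise UndefinedCoefficientError("total score has zero variance")
    n = len(var)
    off = cov.copy()
    np.fill_diagonal(off, 0.0)
    c2 = float((off**2).sum())
    return float(1.0 - var.sum() / vt + np.sqrt(n / (n - 1) * c2) / vt)


def alpha(m: ItemMatrix, ddof: int = 0) -> float:
    """Cronbach's alpha = Guttman's lambda_3 = (n/(n-1)) * (1 - sum V_j / V_T).

    On a dichotomous item matrix this is exactly KR-20.  The value can be
    negative when items covary negatively (the picture-score pathology).
    """
    var, _, vt = _var_terms(m, ddof)
    if vt <= 0:
        raise UndefinedCoefficientError("total score has zero variance")
    n = len(var)
    return float(n / (n - 1) * (1.0 - var.sum() / vt))


lambda3 = alpha


def kr20(m: ItemMatrix) -> float:
    """Kuder-Richardson formula 20 via item proportions p_j q_j.

    Defined for dichotomous item matrices only; algebraically identical to
    alpha under the population variance convention.
    """
    if m.mode != "dichotomous":
        raise ValueError("KR-20 is defined for dichotomous item matrices")
    x = _check(m)
    p = x.mean(axis=0)
    pq = p * (1.0 - p)
    vt = float(np.var(x.sum(axis=1)))
    if vt <= 0:
        raise UndefinedCoefficientError("total score has zero variance")
    n = x.shape[1]
    return float(n / (n - 1) * (1.0 - pq.sum() / vt))


@dataclass
class Lambda4Result:
    value: float
    strategy: str
    split: tuple[tuple[str, ...], tuple[str, ...]]


def _lambda4_for_split(
    x: np.ndarray, idx_a: Sequence[int], idx_b: Sequence[int], ddof: int
) -> float:
    a = x[:, list(idx_a)].sum(axis=1)
    b = x[:, list(idx_b)].sum(axis=1)
    vt = np.var(a + b, ddof=ddof)
    if vt <= 0:
        raise UndefinedCoefficientError("total score has zero variance")
    return float(2.0 * (1.0 - (np.var(a, ddof=ddof) + np.var(b, ddof=ddof)) / vt))


def lambda4(
    m: ItemMatrix,
    strategy: Literal["max", "first_last", "odd_even"] = "max",
    ddof: int = 0,
    exhaustive_limit: int = 20,
    rng: np.random.Generator | None = None,
) -> Lambda4Result:
    """Guttman's split-half bound 2*(1 - (V_a + V_b)/V_T) for a 2-way split.

    ``max`` searches all balanced splits when n <= ``exhaustive_limit`` and
    otherwise runs a greedy pairwise-swap ascent from the odd/even split;
    ``first_last`` puts the first ceil(n/2) items against the rest;
    ``odd_even`` alternates items.
    """
    x = _check(m)
    n = x.shape[1]
    idx = list(range(n))

    def result(a: Sequence[int], b: Sequence[int]) -> Lambda4Result:
        return Lambda4Result(
            value=_lambda4_for_split(x, a, b, ddof),
            strategy=strategy,
            split=(
                tuple(m.items[i] for i in a),
                tuple(m.items[i] for i in b),
            ),
        )

    if strategy == "first_last":
        k = (n + 1) // 2
        return result(idx[:k], idx[k:])
    if strategy == "odd_even":
        return result(idx[0::2], idx[1::2])
    if strategy != "max":
        raise ValueError(f"unknown lambda4 strategy {strategy!r}")

    half = n // 2
    if n <= exhaustive_limit:
        best: tuple[float, tuple, tuple] | None = None
        # enumerate each balanced split once: for even n pin item 0 to side a
        pool = idx[1:] if n % 2 == 0 else idx
        size = half - 1 if n % 2 == 0 else half
        for comb in itertools.combinations(pool, size):
            a = ((0,) + comb) if n % 2 == 0 else comb
            b = tuple(i for i in idx if i not in a)
            v = _lambda4_for_split(x, a, b, ddof)
            if best is None or v > best[0]:
                best = (v, a, b)
        assert best is not None
        return result(best[1], best[2])

    # greedy swap ascent for large n
    a = set(idx[0::2])
    b = set(idx[1::2])
    current = _lambda4_for_split(x, sorted(a), sorted(b), ddof)
    improved = True
    while improved:
        improved = False
        for i in sorted(a):
            for j in sorted(b):
                na = (a - {i}) | {j}
                nb = (b - {j}) | {i}
                v = _lambda4_for_split(x, sorted(na), sorted(nb), ddof)
                if v > current + 1e-12:
                    a, b, current = na, nb, v
                    improved = True
    return result(sorted(a), sorted(b))


def lambda5(m: ItemMatrix, ddof: int = 0) -> float:
    """lambda_1 plus 2*sqrt(max_j sum_{k != j} γ_jk^2)/V_T.

    Designed for the case of one item with large absolute covariances with
    the others relative to the covariances among those others.
    """
    var, cov, vt = _var_terms(m, ddof)
    if vt <= 0:
        raise UndefinedCoefficientError("total score has zero variance")
    off = cov.copy()
    np.fill_diagonal(off, 0.0)
    col_ss = (off**2).sum(axis=0)
    return float(1.0 - var.sum() / vt + 2.0 * np.sqrt(col_ss.max()) / vt)


def _smc(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlation of each item on the remaining items.

    Solves the normal equations per item; a singular remaining-item block
    (perfectly collinear items) falls back to the minimum-norm solution with
    a warning, which still yields the correct projection R^2.
    """
    p = corr.shape[0]
    smc = np.empty(p)
    warned = False
    for j in range(p):
        mask = np.arange(p) != j
        sub = corr[np.ix_(mask, mask)]
        rj = corr[mask, j]
        try:
            beta = np.linalg.solve(sub, rj)
        except np.linalg.LinAlgError:
            if not warned:
                warnings.warn(
                    "singular correlation block; using pseudo-inverse for SMC",
                    stacklevel=3,
                )
                warned = True
            beta = np.linalg.pinv(sub) @ rj
        smc[j] = float(rj @ beta)
    return np.clip(smc, 0.0, 1.0)


def lambda6(m: ItemMatrix, ddof: int = 0, strict: bool = False) -> float:
    """1 - sum of regression error variances over V_T.

    The error variance of item j is V_j * (1 - SMC_j) with SMC_j the squared
    multiple correlation of item j on the remaining items.  Items with zero
    variance contribute zero error variance and are excluded from the SMC
    computation (with a warning; ``strict=True`` raises instead).
    """
    var, cov, vt = _var_terms(m, ddof)
    if vt <= 0:
        raise UndefinedCoefficientError("total score has zero variance")
    varying = var > 0
    if not varying.all():
        msg = f"{int((~varying).sum())} zero-variance item(s) excluded from SMC"
        if strict:
            raise UndefinedCoefficientError(msg)
        warnings.warn(msg, stacklevel=2)
    sub = cov[np.ix_(varying, varying)]
    sd = np.sqrt(np.diag(sub))
    corr = sub / np.outer(sd, sd)
    err = np.zeros_like(var)
    err[varying] = var[varying] * (1.0 - _smc(corr))
    return float(1.0 - err.sum() / vt)


def lambda_suite(m: ItemMatrix, ddof: int = 0) -> tuple[float, float, float]:
    """(lambda_1, lambda_2, lambda_5) in one pass."""
    return lambda1(m, ddof), lambda2(m, ddof), lambda5(m, ddof)


@dataclass
class OmegaResult:
    value: float
    n_factors: int
    converged: bool
    loadings: np.ndarray
    uniquenesses: np.ndarray
    dropped_items: tuple[str, ...]
    n_iterations: int


def _minres_objective(psi: np.ndarray, r: np.ndarray, k: int) -> float:
    rr = r.copy()
    np.fill_diagonal(rr, 1.0 - psi)
    vals, vecs = np.linalg.eigh(rr)
    order = np.argsort(vals)[::-1][:k]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    resid = r - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    return float((resid**2).sum())


def _minres_fa(
    r: np.ndarray, n_factors: int, max_iter: int = 1000, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Minimum-residual common-factor fit of a correlation matrix.

    Minimises the off-diagonal residual sum of squares over the uniquenesses;
    given uniquenesses, loadings come from the leading eigenvectors of the
    reduced correlation matrix.
    """
    p = r.shape[0]
    start = 1.0 - _smc(r)
    start = np.clip(start, 0.01, 0.99)
    res = optimize.minimize(
        _minres_objective,
        start,
        args=(r, n_factors),
        method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": tol * 1e-3, "gtol": tol},
    )
    psi = res.x
    rr = r.copy()
    np.fill_diagonal(rr, 1.0 - psi)
    vals, vecs = np.linalg.eigh(rr)
    order = np.argsort(vals)[::-1][:n_factors]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    # sign convention: majority-positive columns
    for f in range(lam.shape[1]):
        if lam[:, f].sum() < 0:
            lam[:, f] = -lam[:, f]
    communality = (lam**2).sum(axis=1)
    return lam, 1.0 - communality, bool(res.success), int(res.nit)


def omega_total(
    m: ItemMatrix | np.ndarray,
    n_factors: int = 1,
    max_iter: int = 1000,
    tol: float = 1e-6,
    strict: bool = False,
) -> OmegaResult:
    """McDonald's omega total from a common-factor model of the correlations.

    omega_t = 1 - sum(u_j^2) / sum(R), where u_j^2 are the uniquenesses of a
    minres factor fit and sum(R) is the total of the observed correlation
    matrix (the implied total variance of the unit-scaled test).  Accepts an
    item matrix or a ready-made correlation matrix.  Zero-variance items are
    dropped with a warning.  Non-convergence is flagged on the result, not
    fatal.
    """
    dropped: tuple[str, ...] = ()
    if isinstance(m, ItemMatrix):
        summ = covariance_summary(m)
        varying = summ.variances > 0
        if not varying.all():
            dropped = summ.zero_variance_items
            msg = f"dropping zero-variance items {dropped} before factor fit"
            if strict:
                raise UndefinedCoefficientError(msg)
            warnings.warn(msg, stacklevel=2)
        r = summ.correlation[np.ix_(varying, varying)]
    else:
        r = np.asarray(m, dtype=float)
    if r.shape[0] < 3:
        raise InsufficientDataError("factor estimation needs at least 3 items")
    lam, uniq, converged, nit = _minres_fa(r, n_factors, max_iter, tol)
    vt = float(r.sum())
    value = float(1.0 - uniq.sum() / vt)
    if not converged:
        warnings.warn(
            f"minres factor fit did not converge after {nit} iterations",
            stacklevel=2,
        )
    return OmegaResult(
        value=value,
        n_factors=n_factors,
        converged=converged,
        loadings=lam,
        uniquenesses=uniq,
        dropped_items=dropped,
        n_iterations=nit,
    )


def fisher_mean_correlation(rs: Iterable[float]) -> float:
    """Mean correlation via the Fisher z transformation: tanh(mean(atanh r))."""
    arr = np.asarray(list(rs), dtype=float)
    if arr.size == 0:
        raise ValueError("no correlations supplied")
    if (np.abs(arr) >= 1.0).any():
        raise ValueError("correlations of magnitude 1 have infinite Fisher z")
    return float(np.tanh(np.arctanh(arr).mean()))


@dataclass
class ReliabilityReport:
    """All coefficients for one scale x aggregation-mode cell."""

    scale_id: str
    mode: str
    n_items: int
    n_subjects: int
    variance_denominator: str
    lambda1: float = np.nan
    lambda2: float = np.nan
    alpha: float = np.nan                 # = lambda3; KR-20 when dichotomous
    lambda4_max: float = np.nan
    lambda4_first_last: float = np.nan
    lambda5: float = np.nan
    lambda6: float = np.nan
    omega_total: float = np.nan
    is_kr20: bool = False
    lambda4_max_split: tuple | None = None
    omega_converged: bool | None = None
    omega_n_factors: int = 1
    include_weighting: bool = True
    errors: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "scale": self.scale_id,
            "mode": self.mode,
            "items": self.n_items,
            "subjects": self.n_subjects,
            "variance_denominator": self.variance_denominator,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3_alpha": self.alpha,
            "lambda4_max": self.lambda4_max,
            "lambda4_first_last": self.lambda4_first_last,
            "lambda5": self.lambda5,
            "lambda6": self.lambda6,
            "omega_total": self.omega_total,
            "kr20": self.is_kr20,
            "include_weighting": self.include_weighting,
            "errors": dict(self.errors),
        }


def report_for_matrix(
    m: ItemMatrix,
    scale_id: str = "scale",
    ddof: int = 0,
    omega_n_factors: int = 1,
    include_weighting: bool = True,
) -> ReliabilityReport:
    """Compute the full coefficient family for one item matrix.

    Individual coefficient failures (undefined values, non-convergence) are
    recorded per coefficient in ``errors`` rather than aborting the report.
    """
    rep = ReliabilityReport(
        scale_id=scale_id,
        mode=m.mode,
        n_items=m.n_items,
        n_subjects=m.n_subjects,
        variance_denominator="n" if ddof == 0 else "n-1",
        is_kr20=(m.mode == "dichotomous"),
        omega_n_factors=omega_n_factors,
        include_weighting=include_weighting,
    )

    def attempt(name: str, fn):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fn()
        except Exception as exc:  # reported per cell, never fatal
            rep.errors[name] = str(exc)
            return None

    v = attempt("lambda1", lambda: lambda1(m, ddof))
    if v is not None:
        rep.lambda1 = v
    v = attempt("lambda2", lambda: lambda2(m, ddof))
    if v is not None:
        rep.lambda2 = v
    v = attempt("alpha", lambda: alpha(m, ddof))
    if v is not None:
        rep.alpha = v
    r4 = attempt("lambda4_max", lambda: lambda4(m, "max", ddof))
    if r4 is not None:
        rep.lambda4_max = r4.value
        rep.lambda4_max_split = r4.split
    r4f = attempt("lambda4_first_last", lambda: lambda4(m, "first_last", ddof))
    if r4f is not None:
        rep.lambda4_first_last = r4f.value
    v = attempt("lambda5", lambda: lambda5(m, ddof))
    if v is not None:
        rep.lambda5 = v
    v = attempt("lambda6", lambda: lambda6(m, ddof))
    if v is not None:
        rep.lambda6 = v
    om = attempt("omega_total", lambda: omega_total(m, omega_n_factors))
    if om is not None:
        rep.omega_total = om.value
        rep.omega_converged = om.converged
    return rep


def reliability_report(
    t_hs: ScoringTensor,
    t_ff: ScoringTensor,
    include_weighting: bool = True,
    ddof: int = 0,
    omega_n_factors: int = 1,
) -> dict[tuple[str, str], ReliabilityReport]:
    """Coefficient reports for both scales in all three aggregation modes.

    Returns a mapping keyed by (scale_id, mode) covering category, picture
    and dichotomous items, mirroring the standard comparison layout.
    """
    out: dict[tuple[str, str], ReliabilityReport] = {}
    for t in (t_hs, t_ff):
        for builder in (to_category_items, to_picture_items, to_dichotomous_items):
            m = builder(t, include_weighting=include_weighting)
            out[(t.scale_id, m.mode)] = report_for_matrix(
                m,
                scale_id=t.scale_id,
                ddof=ddof,
                omega_n_factors=omega_n_factors,
                include_weighting=include_weighting,
            )
    return out
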