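"""Subgroup membership, summary statistics and per-subgroup test statistics.

Nested biomarker-positive subpopulations are S+(q_k) = {i : x_i <= q_k} for
pre-specified increasing thresholds q_1 < ... < q_K; with q_K equal to the
biomarker maximum the last test is the full-population test.  All tests are
one-sided against H1: delta(q_k) = mu_t(q_k) - mu_c(q_k) > 0.

A statistic is *computable* when each arm contributes at least two subjects
to the subgroup and the pooled variance is positive; otherwise it is a NaN
flagged through the ``degenerate`` mask, to be resolved by the calling
decision procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import special
from scipy import stats as sps

from .model import TrialData

__all__ = [
    "NestedDesign",
    "SubgroupSummary",
    "StatVector",
    "GeneralSubgroups",
    "GeneralSummary",
    "summarize_subgroups",
    "t_statistic",
    "z_statistic",
    "regression_statistic",
    "disjoint_pvalues",
    "inverse_normal_statistics",
    "general_subgroup_summary",
    "general_t_statistic",
    "MIN_PER_ARM",
]

#: minimum subjects per arm for a subgroup statistic to be computable
MIN_PER_ARM = 2


@dataclass(frozen=True)
class NestedDesign:
    """Ordered thresholds defining nested subpopulations, plus the one-sided
    familywise significance level."""

    thresholds: Tuple[float, ...]
    alpha: float = 0.025

    def __post_init__(self) -> None:
        t = tuple(float(q) for q in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if len(t) < 1:
            raise ValueError("at least one threshold is required")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def K(self) -> int:
        return len(self.thresholds)


@dataclass
class SubgroupSummary:
    """Per-subgroup arm counts, means and unbiased variances (arrays over k).

    ``var_t``/``var_c`` are NaN when the arm has fewer than two members.
    """

    thresholds: np.ndarray
    nt: np.ndarray
    nc: np.ndarray
    mean_t: np.ndarray
    mean_c: np.ndarray
    var_t: np.ndarray
    var_c: np.ndarray

    @property
    def K(self) -> int:
        return self.nt.size

    @property
    def delta_hat(self) -> np.ndarray:
        return self.mean_t - self.mean_c

    @property
    def df(self) -> np.ndarray:
        return self.nt + self.nc - 2

    @property
    def pooled_var(self) -> np.ndarray:
        """(nt-1, nc-1)-weighted combination of the two arm variances."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return (
                (self.nt - 1) * self.var_t + (self.nc - 1) * self.var_c
            ) / (self.nt + self.nc - 2)

    @property
    def pooled_sd(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(self.pooled_var)

    @property
    def degenerate(self) -> np.ndarray:
        """True where the minimum-size rule fails (arm count < 2 or
        non-positive pooled variance)."""
        with np.errstate(invalid="ignore"):
            bad = (self.nt < MIN_PER_ARM) | (self.nc < MIN_PER_ARM)
            pv = self.pooled_var
            return bad | ~np.isfinite(pv) | (pv <= 0)


@dataclass
class StatVector:
    """Test statistics per subgroup with their degrees of freedom (NaN df for
    known-variance z statistics), a method tag and degeneracy flags."""

    values: np.ndarray
    df: np.ndarray
    method: str
    degenerate: np.ndarray
    information: Optional[np.ndarray] = None

    @property
    def K(self) -> int:
        return self.values.size


def _arm_stats(y: np.ndarray, masks: np.ndarray, u: np.ndarray, arm: int):
    """Counts, means and unbiased variances of ``y`` for one arm across a
    stack of membership masks (K x N boolean)."""
    sel = masks & (u == arm)
    n = sel.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s1 = sel @ y
        s2 = sel @ (y * y)
        mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
        ss = s2 - np.maximum(n, 1) * mean**2
        var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
    return n, mean, np.maximum(var, 0.0)


def _nested_masks(x: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    q = np.asarray(thresholds, dtype=float)
    return x[None, :] <= q[:, None]


def summarize_subgroups(data: TrialData, design: NestedDesign) -> SubgroupSummary:
    """Arm-wise counts, means and variances of each nested subpopulation.

    Subgroup k contains exactly the subjects with x <= q_k (membership is
    inclusive at the threshold); all its summaries use those subjects only.
    """
    masks = _nested_masks(data.x, design.thresholds)
    nt, mt, vt = _arm_stats(data.y, masks, data.u, 1)
    nc, mc, vc = _arm_stats(data.y, masks, data.u, 0)
    return SubgroupSummary(
        thresholds=np.asarray(design.thresholds, dtype=float),
        nt=nt, nc=nc, mean_t=mt, mean_c=mc, var_t=vt, var_c=vc,
    )


def t_statistic(summary: SubgroupSummary) -> StatVector:
    """Pooled-variance two-sample t statistics, one per subgroup.

    T(q_k) = delta_hat / sqrt(s_p^2 (1/nt + 1/nc)), df = nt + nc - 2.
    """
    bad = summary.degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(summary.pooled_var * (1.0 / summary.nt + 1.0 / summary.nc))
        t = summary.delta_hat / se
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, summary.df.astype(float))
    return StatVector(values=t, df=df, method="t", degenerate=bad)


def z_statistic(
    summary: SubgroupSummary, sigma_t: float, sigma_c: float
) -> StatVector:
    """Known-variance z statistics delta_hat / sqrt(st^2/nt + sc^2/nc)."""
    if sigma_t <= 0 or sigma_c <= 0:
        raise ValueError("known standard deviations must be > 0")
    bad = (summary.nt < 1) | (summary.nc < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma_t**2 / summary.nt + sigma_c**2 / summary.nc)
        z = summary.delta_hat / se
    z = np.where(bad, np.nan, z)
    return StatVector(
        values=z, df=np.full(summary.K, np.nan), method="z", degenerate=bad
    )


def _ols_treatment_effect(y: np.ndarray, u: np.ndarray, x: np.ndarray):
    """Least-squares fit of y ~ 1 + u + x; returns (t_value, df, information)
    or None when the design is singular."""
    n = y.size
    if n < 4 or u.min() == u.max() or x.min() == x.max():
        return None
    X = np.column_stack([np.ones(n), u.astype(float), x])
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(XtX) > 1e12:
        return None
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - 3
    s2 = float(resid @ resid) / df
    var_b1 = s2 * XtX_inv[1, 1]
    if var_b1 <= 0:
        return None
    return beta[1] / np.sqrt(var_b1), df, 1.0 / var_b1


def regression_statistic(data: TrialData, design: NestedDesign) -> StatVector:
    """Biomarker-adjusted treatment-effect tests per subgroup.

    Within each S+(q_k) the linear model Y = b0 + b1 U + b2 X + e is fitted
    by least squares; the statistic is b1_hat / SE(b1_hat) with
    nt + nc - 3 degrees of freedom, and the observed information is
    1 / Var(b1_hat) (used for the boundary correlation structure).
    """
    masks = _nested_masks(data.x, design.thresholds)
    K = masks.shape[0]
    vals = np.full(K, np.nan)
    df = np.full(K, np.nan)
    info = np.full(K, np.nan)
    bad = np.ones(K, dtype=bool)
    for k in range(K):
        m = masks[k]
        res = _ols_treatment_effect(data.y[m], data.u[m], data.x[m])
        if res is not None:
            vals[k], df[k], info[k] = res
            bad[k] = False
    return StatVector(
        values=vals, df=df, method="regression", degenerate=bad, information=info
    )


def disjoint_pvalues(data: TrialData, design: NestedDesign):
    """One-sided t-test p-values and precision weights of the disjoint
    biomarker slices S+(q_{k-1}, q_k] = {i : q_{k-1} < x_i <= q_k}.

    The first slice has an open lower edge below every observation, so the
    slices partition S+(q_K).  Weights are w_k = (1/nt + 1/nc)^{-1} computed
    within each slice.  Returns (p, w, degenerate mask).
    """
    q = np.asarray(design.thresholds, dtype=float)
    edges = np.concatenate([[-np.inf], q])
    K = q.size
    p = np.full(K, np.nan)
    w = np.full(K, np.nan)
    bad = np.ones(K, dtype=bool)
    for k in range(K):
        m = (data.x > edges[k]) & (data.x <= edges[k + 1])
        yt = data.y[m & (data.u == 1)]
        yc = data.y[m & (data.u == 0)]
        nt, nc = yt.size, yc.size
        if nt < MIN_PER_ARM or nc < MIN_PER_ARM:
            continue
        sp2 = ((nt - 1) * yt.var(ddof=1) + (nc - 1) * yc.var(ddof=1)) / (
            nt + nc - 2
        )
        if sp2 <= 0:
            continue
        tval = (yt.mean() - yc.mean()) / np.sqrt(sp2 * (1 / nt + 1 / nc))
        p[k] = special.stdtr(nt + nc - 2, -tval)  # one-sided upper tail
        w[k] = 1.0 / (1.0 / nt + 1.0 / nc)
        bad[k] = False
    return p, w, bad


def inverse_normal_statistics(p: np.ndarray, w: np.ndarray) -> StatVector:
    """Weighted inverse-normal combination statistics over nested unions of
    disjoint slices.

    C(q_k) = sum_{m<=k} sqrt(w_m) Phi^{-1}(1 - p_m) / sqrt(sum_{m<=k} w_m),
    which has unit variance when the p's are independent uniforms; the
    cumulative information I_k = sum_{m<=k} w_m drives the group-sequential
    correlation sqrt(I_j/I_k).  Degenerate slices poison every C(q_k) whose
    union contains them.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.shape != w.shape or p.ndim != 1:
        raise ValueError("p and w must be 1-d arrays of equal length")
    bad_in = ~np.isfinite(p) | ~np.isfinite(w) | (w <= 0)
    ok = ~bad_in
    if np.any((p[ok] <= 0) | (p[ok] >= 1)):
        import warnings

        warnings.warn(
            "p-value at 0 or 1: infinite quantile propagated", RuntimeWarning
        )
    z = np.where(ok, -special.ndtri(np.clip(p, 0.0, 1.0)), 0.0)
    sw = np.where(ok, w, 0.0)
    num = np.cumsum(np.sqrt(sw) * z)
    info = np.cumsum(sw)
    bad = np.cumsum(bad_in) > 0  # any degenerate slice so far
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(bad, np.nan, num / np.sqrt(info))
    return StatVector(
        values=c,
        df=np.full(p.size, np.nan),
        method="inverse_normal",
        degenerate=bad,
        information=np.where(bad, np.nan, info),
    )


# ---------------------------------------------------------------------------
# general (possibly non-nested) subgroups


@dataclass(frozen=True)
class GeneralSubgroups:
    """Subgroups defined as finite unions of half-open biomarker intervals
    (lo, hi]; lo may be -inf and hi +inf."""

    sets: Tuple[Tuple[Tuple[float, float], ...], ...]

    def __post_init__(self) -> None:
        norm = []
        for s in self.sets:
            ivs = tuple((float(lo), float(hi)) for lo, hi in s)
            if len(ivs) == 0:
                raise ValueError("each subgroup needs at least one interval")
            for lo, hi in ivs:
                if not lo < hi:
                    raise ValueError(f"empty interval ({lo}, {hi}]")
            norm.append(ivs)
        object.__setattr__(self, "sets", tuple(norm))

    @property
    def K(self) -> int:
        return len(self.sets)

    def membership(self, x: np.ndarray) -> np.ndarray:
        """K x N boolean mask of subjects in each set."""
        x = np.asarray(x, dtype=float)
        out = np.zeros((self.K, x.size), dtype=bool)
        for k, ivs in enumerate(self.sets):
            for lo, hi in ivs:
                out[k] |= (x > lo) & (x <= hi)
        return out


@dataclass
class GeneralSummary:
    """Per-set and pairwise-intersection arm summaries for general
    subgroups (inputs of the general covariance formula)."""

    nt: np.ndarray
    nc: np.ndarray
    mean_t: np.ndarray
    mean_c: np.ndarray
    var_t: np.ndarray
    var_c: np.ndarray
    # intersections, all K x K (diagonal = the sets themselves)
    nt_int: np.ndarray
    nc_int: np.ndarray
    var_t_int: np.ndarray
    var_c_int: np.ndarray

    @property
    def K(self) -> int:
        return self.nt.size

    @property
    def delta_hat(self) -> np.ndarray:
        return self.mean_t - self.mean_c

    @property
    def degenerate(self) -> np.ndarray:
        vt = np.nan_to_num(self.var_t, nan=0.0)
        vc = np.nan_to_num(self.var_c, nan=0.0)
        return (
            (self.nt < MIN_PER_ARM)
            | (self.nc < MIN_PER_ARM)
            | (vt + vc <= 0)
        )


def general_subgroup_summary(
    data: TrialData, groups: GeneralSubgroups
) -> GeneralSummary:
    """Summaries of each set and of every pairwise intersection of sets."""
    masks = groups.membership(data.x)
    nt, mt, vt = _arm_stats(data.y, masks, data.u, 1)
    nc, mc, vc = _arm_stats(data.y, masks, data.u, 0)
    K = groups.K
    nt_i = np.zeros((K, K), dtype=int)
    nc_i = np.zeros((K, K), dtype=int)
    vt_i = np.full((K, K), np.nan)
    vc_i = np.full((K, K), np.nan)
    for j in range(K):
        for k in range(j, K):
            m = masks[j] & masks[k]
            a, _, va = _arm_stats(data.y, m[None, :], data.u, 1)
            b, _, vb = _arm_stats(data.y, m[None, :], data.u, 0)
            nt_i[j, k] = nt_i[k, j] = a[0]
            nc_i[j, k] = nc_i[k, j] = b[0]
            vt_i[j, k] = vt_i[k, j] = va[0]
            vc_i[j, k] = vc_i[k, j] = vb[0]
    return GeneralSummary(
        nt=nt, nc=nc, mean_t=mt, mean_c=mc, var_t=vt, var_c=vc,
        nt_int=nt_i, nc_int=nc_i, var_t_int=vt_i, var_c_int=vc_i,
    )


def general_t_statistic(summary: GeneralSummary) -> StatVector:
    """Pooled two-sample t statistics for general subgroups."""
    bad = summary.degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        pv = ((summary.nt - 1) * summary.var_t + (summary.nc - 1) * summary.var_c) / (
            summary.nt + summary.nc - 2
        )
        se = np.sqrt(pv * (1.0 / summary.nt + 1.0 / summary.nc))
        t = summary.delta_hat / se
    bad = bad | ~np.isfinite(t)
    return StatVector(
        values=np.where(bad, np.nan, t),
        df=np.where(bad, np.nan, (summary.nt + summary.nc - 2).astype(float)),
        method="t",
        degenerate=bad,
    )
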