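"""Single-step decision procedures for nested and general subgroups.

Seven procedure names are recognised:

``sidak``
    t statistics against per-subgroup t quantiles at the Sidak-adjusted
    level 1-(1-alpha)^(1/K); conservative under the positive dependence of
    nested tests.
``z_gs``
    t statistics against normal-scale group-sequential boundaries from the
    equal-variance covariance (the "z-test": no quantile substitution).
``t_gs``
    the same boundaries mapped to the t scale by quantile substitution
    (df = nt+nc-2).
``adjusted_t``
    boundaries from the variance-adjusted plug-in covariance, then quantile
    substitution; controls the FWER when a prognostic biomarker makes the
    outcome variance differ across subpopulations.
``regression``
    biomarker-adjusted treatment tests against boundaries from the
    observed-information covariance, substituted at df = nt+nc-3.
``inverse_normal``
    weighted inverse-normal combination statistics of the disjoint
    biomarker slices against normal-scale boundaries from the cumulative
    weight information.
``full_population``
    the single one-sided t-test on all subjects at level alpha.

``z_known`` (validation only) tests true z statistics, computed with
user-supplied known standard deviations, against the same normal-scale
boundaries as ``z_gs``; it attains the nominal level exactly and serves as
a simulation oracle.

Every procedure rejects H0k when its statistic exceeds the boundary; strong
familywise error control of the level-controlling procedures follows from
the closed testing principle because removing hypotheses only enlarges each
remaining rejection region.

Degenerate subgroups (an arm below two subjects, or zero variance) are
handled by mode: ``analysis`` raises with advice to merge thresholds, while
``simulation`` treats the affected hypotheses as not rejected and counts the
event — a conservative rule that keeps the FWER valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import special
from scipy import stats as sps

from . import boundaries as bnd
from . import subgroups as sg
from .model import TrialData
from .subgroups import GeneralSubgroups, NestedDesign

__all__ = [
    "PROCEDURES",
    "DecisionResult",
    "DegenerateSubgroupError",
    "run_procedure",
    "adjusted_pvalues",
    "stepp_tail_subgroups",
    "run_general_procedure",
]

PROCEDURES = (
    "sidak",
    "z_gs",
    "t_gs",
    "adjusted_t",
    "regression",
    "inverse_normal",
    "full_population",
)


class DegenerateSubgroupError(ValueError):
    """A subgroup is too small (or has zero variance) for its test
    statistic; merge adjacent thresholds or supply more data."""


@dataclass
class DecisionResult:
    """Per-hypothesis statistics, boundaries and decisions of one run."""

    procedure: str
    thresholds: np.ndarray
    statistics: np.ndarray
    boundaries: np.ndarray  # on the scale the statistics are compared on
    reject: np.ndarray
    df: np.ndarray
    degenerate: np.ndarray
    attained_alpha: Optional[float] = None
    adjusted_p: Optional[np.ndarray] = None

    @property
    def any_reject(self) -> bool:
        return bool(self.reject.any())

    @property
    def n_degenerate(self) -> int:
        return int(self.degenerate.sum())


def _handle_degenerate(stat: sg.StatVector, mode: str, what: str) -> None:
    if mode == "analysis" and stat.degenerate.any():
        ks = np.flatnonzero(stat.degenerate) + 1
        raise DegenerateSubgroupError(
            f"{what} degenerate for subgroup(s) {ks.tolist()} "
            "(an arm has fewer than 2 subjects or zero variance); "
            "merge adjacent thresholds or collect more data"
        )


def _pocock_or_obf(cov, info, alpha, family, cache=None, cache_key=None):
    if family == "pocock":
        factory = lambda x0: bnd.pocock_common_critical_value(cov, alpha, x0=x0)
    elif family == "obf":
        factory = lambda x0: bnd.obf_critical_values(cov, info, alpha)
    else:
        raise ValueError("boundary family must be 'pocock' or 'obf'")
    if cache is not None and cache_key is not None:
        return cache.get_or_compute((family,) + cache_key, factory)
    return factory(None)


def run_procedure(
    name: str,
    data: TrialData,
    design: NestedDesign,
    *,
    boundary_family: str = "pocock",
    mode: str = "analysis",
    cache: Optional[bnd.BoundaryCache] = None,
    known_sigmas: Optional[Tuple[float, float]] = None,
    covariance_form: str = "simplified",
    alpha: Optional[float] = None,
) -> DecisionResult:
    """Run one decision procedure on subject-level data.

    Parameters
    ----------
    name : str
        One of :data:`PROCEDURES` (or ``"z_known"`` with ``known_sigmas``).
    boundary_family : {"pocock", "obf"}
        Equal critical values (default) or O'Brien-Fleming-type.
    mode : {"analysis", "simulation"}
        Degenerate-subgroup handling (see module docstring).
    cache : BoundaryCache, optional
        Reuses boundary root-solves across simulation replicates.
    alpha : float, optional
        Overrides ``design.alpha`` (used by the adjusted-p-value search).
    """
    if mode not in ("analysis", "simulation"):
        raise ValueError("mode must be 'analysis' or 'simulation'")
    alpha = design.alpha if alpha is None else float(alpha)
    K = design.K
    thr = np.asarray(design.thresholds, dtype=float)

    if name == "full_population":
        full = NestedDesign(thresholds=(max(float(data.x.max()), thr[-1]),), alpha=alpha)
        summ = sg.summarize_subgroups(data, full)
        stat = sg.t_statistic(summ)
        _handle_degenerate(stat, mode, "full-population t statistic")
        ok = ~stat.degenerate
        b = np.where(
            ok, -special.stdtrit(np.where(ok, stat.df, 1.0), alpha), np.inf
        )
        rej = ok & (stat.values > b)
        return DecisionResult(
            procedure=name, thresholds=np.asarray(full.thresholds),
            statistics=stat.values, boundaries=b, reject=rej, df=stat.df,
            degenerate=stat.degenerate, attained_alpha=alpha,
        )

    if name == "inverse_normal":
        p, w, bad_slices = sg.disjoint_pvalues(data, design)
        stat = sg.inverse_normal_statistics(p, w)
        _handle_degenerate(stat, mode, "inverse-normal combination")
        ok = ~stat.degenerate
        if not ok.any():
            b = np.full(K, np.inf)
            return DecisionResult(
                procedure=name, thresholds=thr, statistics=stat.values,
                boundaries=b, reject=np.zeros(K, bool), df=stat.df,
                degenerate=stat.degenerate,
            )
        info = stat.information[ok]
        cov = bnd.information_covariance(info)
        key = (cache.info_key(info),) if cache is not None else None
        bs = _pocock_or_obf(cov, info, alpha, boundary_family, cache, key)
        b = np.full(K, np.inf)
        b[ok] = bs.normal_scale
        rej = ok & (stat.values > b)
        return DecisionResult(
            procedure=name, thresholds=thr, statistics=stat.values,
            boundaries=b, reject=rej, df=stat.df, degenerate=stat.degenerate,
            attained_alpha=bs.attained_alpha,
        )

    if name == "regression":
        stat = sg.regression_statistic(data, design)
        _handle_degenerate(stat, mode, "regression statistic")
        ok = ~stat.degenerate
        if not ok.any():
            return DecisionResult(
                procedure=name, thresholds=thr, statistics=stat.values,
                boundaries=np.full(K, np.inf), reject=np.zeros(K, bool),
                df=stat.df, degenerate=stat.degenerate,
            )
        info = stat.information[ok]
        if np.any(np.diff(info) < 0):
            # estimated information can be non-monotone in small samples;
            # enforce nesting by a running maximum before forming Sigma
            info = np.maximum.accumulate(info)
        cov = bnd.information_covariance(info)
        key = (cache.info_key(info),) if cache is not None else None
        bs = _pocock_or_obf(cov, info, alpha, boundary_family, cache, key)
        b = np.full(K, np.inf)
        b[ok] = bnd.quantile_substitution(bs.normal_scale, stat.df[ok])
        rej = ok & (stat.values > b)
        return DecisionResult(
            procedure=name, thresholds=thr, statistics=stat.values,
            boundaries=b, reject=rej, df=stat.df, degenerate=stat.degenerate,
            attained_alpha=bs.attained_alpha,
        )

    # remaining procedures share the nested subgroup summaries
    summ = sg.summarize_subgroups(data, design)

    if name == "z_known":
        if known_sigmas is None:
            raise ValueError("z_known requires known_sigmas=(sigma_t, sigma_c)")
        stat = sg.z_statistic(summ, *known_sigmas)
    else:
        stat = sg.t_statistic(summ)

    if name == "sidak":
        _handle_degenerate(stat, mode, "t statistic")
        ok = ~stat.degenerate
        ac = bnd.sidak_level(alpha, K)
        b = np.where(
            ok, -special.stdtrit(np.where(ok, stat.df, 1.0), ac), np.inf
        )
        rej = ok & (stat.values > b)
        return DecisionResult(
            procedure=name, thresholds=thr, statistics=stat.values,
            boundaries=b, reject=rej, df=stat.df, degenerate=stat.degenerate,
            attained_alpha=None,
        )

    if name not in ("z_gs", "t_gs", "adjusted_t", "z_known"):
        raise ValueError(f"unknown procedure {name!r}")

    _handle_degenerate(stat, mode, "t statistic")
    ok = ~stat.degenerate
    if not ok.any():
        return DecisionResult(
            procedure=name, thresholds=thr, statistics=stat.values,
            boundaries=np.full(K, np.inf), reject=np.zeros(K, bool),
            df=stat.df, degenerate=stat.degenerate,
        )
    nt, nc = summ.nt[ok], summ.nc[ok]
    ckey = None
    if name == "adjusted_t":
        sub = sg.SubgroupSummary(
            thresholds=summ.thresholds[ok], nt=nt, nc=nc,
            mean_t=summ.mean_t[ok], mean_c=summ.mean_c[ok],
            var_t=summ.var_t[ok], var_c=summ.var_c[ok],
        )
        cov = bnd.variance_adjusted_covariance(sub, form=covariance_form)
        if cache is not None:
            ckey = (cache.counts_key(nt, nc), cache.sd_key(sub.pooled_sd))
    else:
        cov = bnd.equal_variance_covariance(nt, nc)
        if cache is not None:
            ckey = (cache.counts_key(nt, nc),)
    info = 1.0 / (1.0 / nt + 1.0 / nc)
    bs = _pocock_or_obf(cov, info, alpha, boundary_family, cache, ckey)
    b = np.full(K, np.inf)
    if name == "z_gs" or name == "z_known":
        b[ok] = bs.normal_scale
    else:
        b[ok] = bnd.quantile_substitution(bs.normal_scale, stat.df[ok])
    rej = ok & (stat.values > b)
    return DecisionResult(
        procedure=name, thresholds=thr, statistics=stat.values,
        boundaries=b, reject=rej, df=stat.df, degenerate=stat.degenerate,
        attained_alpha=bs.attained_alpha,
    )


def adjusted_pvalues(
    name: str,
    data: TrialData,
    design: NestedDesign,
    *,
    boundary_family: str = "pocock",
    mode: str = "analysis",
    tol: float = 1e-6,
    **kwargs,
) -> np.ndarray:
    """Single-step multiplicity-adjusted p-values.

    For each hypothesis the smallest level alpha at which the procedure
    rejects it, found by bisection (the rejection region is monotone in
    alpha).  Consistency: adjusted p <= alpha iff the level-alpha run
    rejects, up to the bisection tolerance.

    Values are floored at 1e-5: below that level the boundary solve would
    require tail probabilities beyond the accuracy of the multivariate
    normal integration, and any reported value would be spurious precision.
    """
    K = design.K
    lo_a, hi_a = 1e-5, 1.0 - 1e-9

    def rejects(alpha: float) -> np.ndarray:
        res = run_procedure(
            name, data, design, boundary_family=boundary_family,
            mode=mode, alpha=alpha, **kwargs,
        )
        return res.reject

    out = np.ones(K)
    r_lo = rejects(lo_a)
    r_hi = rejects(hi_a)
    for k in range(K):
        if r_lo[k]:
            out[k] = lo_a
            continue
        if not r_hi[k]:
            out[k] = 1.0
            continue
        a, b = lo_a, hi_a
        while b - a > tol:
            mid = 0.5 * (a + b)
            if rejects(mid)[k]:
                b = mid
            else:
                a = mid
        out[k] = b
    return out


def stepp_tail_subgroups(thresholds: Sequence[float]) -> GeneralSubgroups:
    """Tail-oriented subgroup family: K cumulative-from-the-left sets
    {x <= q_k} plus K-1 cumulative-from-the-right sets {x > q_k}, the
    largest threshold being +inf so the full population appears once —
    2K-1 sets in total."""
    q = [float(v) for v in thresholds]
    if len(q) < 1:
        raise ValueError("at least one threshold is required")
    if any(b <= a for a, b in zip(q, q[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if not np.isinf(q[-1]):
        raise ValueError("largest threshold must be +inf (full population)")
    sets = [((-np.inf, qk),) for qk in q]
    sets += [((qk, np.inf),) for qk in q[:-1]]
    return GeneralSubgroups(sets=tuple(sets))


def run_general_procedure(
    data: TrialData,
    groups: GeneralSubgroups,
    alpha: float = 0.025,
    *,
    mode: str = "analysis",
    critical_values: Optional[np.ndarray] = None,
    tol: float = bnd.MVN_TOL,
) -> DecisionResult:
    """Multiple t-test for general (possibly non-nested) subgroups.

    Statistics and the plug-in covariance come from per-set and pairwise-
    intersection summaries; by default a common normal-scale critical value
    is solved from the level-alpha condition and mapped to the t scale of
    each set by quantile substitution.  Alternatively a user-supplied vector
    of normal-scale critical values is validated against the level-alpha
    condition and then substituted.
    """
    summ = sg.general_subgroup_summary(data, groups)
    stat = sg.general_t_statistic(summ)
    _handle_degenerate(stat, mode, "general-subgroup t statistic")
    ok = ~stat.degenerate
    K = groups.K
    if not ok.any():
        return DecisionResult(
            procedure="general_t", thresholds=np.arange(K, dtype=float),
            statistics=stat.values, boundaries=np.full(K, np.inf),
            reject=np.zeros(K, bool), df=stat.df, degenerate=stat.degenerate,
        )
    idx = np.flatnonzero(ok)
    sub = sg.GeneralSummary(
        nt=summ.nt[idx], nc=summ.nc[idx],
        mean_t=summ.mean_t[idx], mean_c=summ.mean_c[idx],
        var_t=summ.var_t[idx], var_c=summ.var_c[idx],
        nt_int=summ.nt_int[np.ix_(idx, idx)],
        nc_int=summ.nc_int[np.ix_(idx, idx)],
        var_t_int=summ.var_t_int[np.ix_(idx, idx)],
        var_c_int=summ.var_c_int[np.ix_(idx, idx)],
    )
    cov = bnd.general_covariance(sub)
    if critical_values is not None:
        c = np.asarray(critical_values, dtype=float)
        if c.size != idx.size:
            raise ValueError("critical_values must match the number of sets")
        attained = bnd.mvn_tail_probability(cov, c, tol=tol)
        if attained > alpha + 2 * tol:
            raise ValueError(
                f"supplied critical values attain level {attained:.5f} > "
                f"alpha={alpha}"
            )
        normal_c = c
    else:
        bs = bnd.pocock_common_critical_value(cov, alpha, tol=tol)
        normal_c = bs.normal_scale
        attained = bs.attained_alpha
    b = np.full(K, np.inf)
    b[idx] = bnd.quantile_substitution(normal_c, stat.df[idx])
    rej = ok & (stat.values > b)
    return DecisionResult(
        procedure="general_t", thresholds=np.arange(K, dtype=float),
        statistics=stat.values, boundaries=b, reject=rej, df=stat.df,
        degenerate=stat.degenerate, attained_alpha=attained,
    )
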