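"""Monte-Carlo operating characteristics: FWER, disjunctive power and
sample-size determination for the subpopulation testing procedures.

Replicates are mutually independent and individually reproducible: replicate
r of a run with root seed s uses the stream seeded by the pair (s, r), so
results do not depend on execution order or the degree of parallelism.
Boundary computations are memoized across replicates (see
:class:`~subpoptests.boundaries.BoundaryCache`).

The default replicate count is 10^4; Monte-Carlo standard errors
sqrt(p(1-p)/R) are reported alongside every estimate so that comparisons can
be stated in multiples of the simulation noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .boundaries import BoundaryCache
from .model import ModelSpec, replicate_rng, simulate_trial
from .procedures import run_procedure
from .subgroups import NestedDesign

__all__ = [
    "Scenario",
    "OCResult",
    "estimate_fwer",
    "estimate_power",
    "sample_size_search",
    "analytic_two_sample_n",
    "analytic_two_sample_power",
    "scenario_grid",
]


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: a data-generating model, a nested design
    (explicit thresholds, or K equally spaced quantile-based thresholds
    q_k = k/K), the procedures to run, and the Monte-Carlo size."""

    model: ModelSpec
    K: Optional[int] = None
    thresholds: Optional[Tuple[float, ...]] = None
    procedures: Tuple[str, ...] = ("adjusted_t",)
    replicates: int = 10_000
    seed: int = 0
    alpha: float = 0.025
    boundary_family: str = "pocock"
    covariance_form: str = "simplified"
    label: str = ""

    def __post_init__(self) -> None:
        if (self.K is None) == (self.thresholds is None):
            raise ValueError("give exactly one of K or thresholds")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.procedures, str):
            object.__setattr__(self, "procedures", (self.procedures,))
        else:
            object.__setattr__(self, "procedures", tuple(self.procedures))

    @property
    def design(self) -> NestedDesign:
        if self.thresholds is not None:
            return NestedDesign(thresholds=self.thresholds, alpha=self.alpha)
        q = tuple((k + 1) / self.K for k in range(self.K))
        return NestedDesign(thresholds=q, alpha=self.alpha)


@dataclass
class OCResult:
    """Monte-Carlo estimate of an operating characteristic."""

    procedure: str
    estimate: float
    replicates: int
    seed: int
    per_hypothesis: np.ndarray
    degenerate_count: int = 0

    @property
    def mc_se(self) -> float:
        p = self.estimate
        return float(np.sqrt(p * (1.0 - p) / self.replicates))


def _merge_results(a: OCResult, b: OCResult) -> OCResult:
    """Pool two runs over disjoint replicate-index ranges of one stream."""
    R = a.replicates + b.replicates
    return OCResult(
        procedure=a.procedure,
        estimate=(a.estimate * a.replicates + b.estimate * b.replicates) / R,
        replicates=R,
        seed=a.seed,
        per_hypothesis=(
            a.per_hypothesis * a.replicates + b.per_hypothesis * b.replicates
        ) / R,
        degenerate_count=a.degenerate_count + b.degenerate_count,
    )


def _run_scenario(
    scenario: Scenario, procedures: Sequence[str], *, rep_start: int = 0
) -> Dict[str, OCResult]:
    design = scenario.design
    model = scenario.model
    caches = {p: BoundaryCache() for p in procedures}
    known = (model.sigma, model.sigma)
    K = design.K
    any_rej = {p: 0 for p in procedures}
    per_hyp = {p: np.zeros(K if p != "full_population" else 1) for p in procedures}
    degen = {p: 0 for p in procedures}
    for r in range(rep_start, rep_start + scenario.replicates):
        data = simulate_trial(model, replicate_rng(scenario.seed, r))
        for p in procedures:
            res = run_procedure(
                p,
                data,
                design,
                boundary_family=scenario.boundary_family,
                covariance_form=scenario.covariance_form,
                mode="simulation",
                cache=caches[p],
                known_sigmas=known if p == "z_known" else None,
            )
            any_rej[p] += res.any_reject
            per_hyp[p] += res.reject
            degen[p] += res.n_degenerate
    return {
        p: OCResult(
            procedure=p,
            estimate=any_rej[p] / scenario.replicates,
            replicates=scenario.replicates,
            seed=scenario.seed,
            per_hypothesis=per_hyp[p] / scenario.replicates,
            degenerate_count=degen[p],
        )
        for p in procedures
    }


def estimate_fwer(scenario: Scenario) -> Dict[str, OCResult]:
    """Familywise error rate: proportion of replicates rejecting at least
    one hypothesis, per procedure.

    The scenario must satisfy the global null (beta1 = beta3 = 0); a
    prognostic effect beta2 is allowed — that is exactly the stress case.
    """
    m = scenario.model
    if m.beta1 != 0 or m.beta3 != 0:
        raise ValueError(
            "FWER scenarios require beta1 = beta3 = 0 (global null); "
            "use estimate_power for alternatives"
        )
    return _run_scenario(scenario, scenario.procedures)


def estimate_power(scenario: Scenario) -> Dict[str, OCResult]:
    """Disjunctive power (reject at least one hypothesis) per procedure,
    plus the single full-population t-test for comparison."""
    procs = list(scenario.procedures)
    if "full_population" not in procs:
        procs.append("full_population")
    return _run_scenario(scenario, procs)


def _power_at_n(
    scenario: Scenario, procedure: str, n: int,
    *, rep_start: int = 0, replicates: Optional[int] = None,
) -> OCResult:
    model = dataclasses.replace(scenario.model, n_per_group=int(n))
    sc = dataclasses.replace(scenario, model=model, procedures=(procedure,))
    if replicates is not None:
        sc = dataclasses.replace(sc, replicates=int(replicates))
    return _run_scenario(sc, (procedure,), rep_start=rep_start)[procedure]


def _next_candidate(lo, hi, p_lo, p_hi, target, stall):
    """Probit-scale false position on the (n, power) bracket, clamped to
    the interior; falls back to the midpoint when one endpoint sticks."""
    if stall >= 2 or not np.isfinite(p_lo) or not np.isfinite(p_hi):
        return (lo + hi) // 2
    z = sps.norm.ppf(np.clip([p_lo, p_hi, target], 1e-4, 1 - 1e-4))
    if z[1] <= z[0]:
        return (lo + hi) // 2
    frac = (z[2] - z[0]) / (z[1] - z[0])
    mid = int(round(lo + frac * (hi - lo)))
    return min(max(mid, lo + 1), hi - 1)


def sample_size_search(
    scenario: Scenario,
    target_power: float,
    n_bracket: Tuple[int, int],
    procedure: Optional[str] = None,
    refine_replicates: Optional[int] = None,
):
    """Smallest per-group n whose estimated disjunctive power reaches the
    target.

    The search brackets the target on integers, proposing candidates by
    probit-scale false position (safeguarded by midpoint steps), and every
    candidate size reuses the same replicate seeds (common random numbers),
    which keeps the estimated power curve essentially monotone in n.

    ``refine_replicates`` (> ``scenario.replicates``) adds a second stage:
    the candidate sizes adjacent to the located edge are re-estimated at the
    larger replicate count and the returned n is the smallest whose refined
    power reaches the target.  This shrinks the Monte-Carlo noise of the
    returned edge (roughly one subject per power-SE/slope) at the cost of a
    few extra high-precision evaluations.

    Returns a dict with the selected n, the power estimates straddling the
    target and their Monte-Carlo standard errors.
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    procedure = procedure or scenario.procedures[0]
    lo, hi = int(n_bracket[0]), int(n_bracket[1])
    if lo < 2 or hi <= lo:
        raise ValueError("n_bracket must satisfy 2 <= lo < hi")
    lo_orig = lo
    base: Dict[int, OCResult] = {}

    def eval_base(n: int) -> OCResult:
        if n not in base:
            base[n] = _power_at_n(scenario, procedure, n)
        return base[n]

    r_lo = eval_base(lo)
    r_hi = eval_base(hi)
    if r_lo.estimate >= target_power:
        return {
            "n": lo, "procedure": procedure, "at_bracket_edge": True,
            "power_at_n": r_lo.estimate, "mc_se_at_n": r_lo.mc_se,
            "power_below": None, "mc_se_below": None,
        }
    if r_hi.estimate < target_power:
        raise ValueError(
            f"bracket does not straddle the target: power({lo})="
            f"{r_lo.estimate:.3f}, power({hi})={r_hi.estimate:.3f} "
            f"< {target_power}"
        )
    stall_lo = stall_hi = 0
    while hi - lo > 1:
        mid = _next_candidate(
            lo, hi, r_lo.estimate, r_hi.estimate, target_power,
            max(stall_lo, stall_hi),
        )
        r_mid = eval_base(mid)
        if r_mid.estimate >= target_power:
            hi, r_hi = mid, r_mid
            stall_hi, stall_lo = 0, stall_lo + 1
        else:
            lo, r_lo = mid, r_mid
            stall_lo, stall_hi = 0, stall_hi + 1

    if refine_replicates and refine_replicates > scenario.replicates:
        # second stage: re-estimate the sizes adjacent to the located edge
        # at the larger replicate count.  Replicates are index-seeded, so
        # the refinement only simulates the additional indices and pools
        # them with the first-stage estimate for that n.
        extra = int(refine_replicates) - scenario.replicates

        def eval_refined(n: int) -> OCResult:
            more = _power_at_n(
                scenario, procedure, n,
                rep_start=scenario.replicates, replicates=extra,
            )
            return _merge_results(eval_base(n), more)

        n = hi
        r_below = r_lo
        r_n = eval_refined(n)
        if r_n.estimate >= target_power:
            # walk down while the refined estimate still clears the target
            while n - 1 >= lo_orig:
                r_below = eval_refined(n - 1)
                if r_below.estimate >= target_power:
                    n, r_n = n - 1, r_below
                else:
                    break
        else:
            while r_n.estimate < target_power:
                n += 1
                r_below = r_n
                r_n = eval_refined(n)
        return {
            "n": n, "procedure": procedure, "at_bracket_edge": False,
            "power_at_n": r_n.estimate, "mc_se_at_n": r_n.mc_se,
            "power_below": r_below.estimate, "mc_se_below": r_below.mc_se,
        }

    return {
        "n": hi, "procedure": procedure, "at_bracket_edge": False,
        "power_at_n": r_hi.estimate, "mc_se_at_n": r_hi.mc_se,
        "power_below": r_lo.estimate, "mc_se_below": r_lo.mc_se,
    }


def analytic_two_sample_power(
    n: int, effect_size: float, alpha: float = 0.025
) -> float:
    """Exact power of the one-sided two-sample pooled t-test at per-group
    size n against a standardized effect, via the noncentral t
    distribution (df = 2n-2, noncentrality effect*sqrt(n/2))."""
    df = 2 * n - 2
    crit = sps.t.isf(alpha, df)
    return float(sps.nct.sf(crit, df, effect_size * np.sqrt(n / 2.0)))


def analytic_two_sample_n(
    effect_size: float, alpha: float = 0.025, power: float = 0.9
) -> int:
    """Smallest per-group n for the full-population one-sided t-test to
    reach the target power; exact noncentral-t computation, no simulation."""
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    za, zb = sps.norm.isf(alpha), sps.norm.isf(1.0 - power)
    n = max(2, int(np.floor(2.0 * ((za + zb) / effect_size) ** 2) - 2))
    while analytic_two_sample_power(n, effect_size, alpha) < power:
        n += 1
    while n > 2 and analytic_two_sample_power(n - 1, effect_size, alpha) >= power:
        n -= 1
    return n


_FIGURES = ("fwer_step", "fwer_linear", "power_step", "power_linear", "misspec")
_FWER_PROCS = ("sidak", "z_gs", "t_gs", "adjusted_t", "regression", "inverse_normal")
_POWER_PROCS = ("sidak", "t_gs", "adjusted_t", "regression", "inverse_normal")


def scenario_grid(
    figure: str,
    *,
    replicates: int = 10_000,
    n_per_group: int = 80,
    seed: int = 0,
) -> list:
    """Factorial scenario grids of the simulation study.

    All grids use K in {2, 4, 8} equally spaced quantile thresholds
    q_k = k/K, per-group size 80 and one-sided alpha 0.025.  FWER grids vary
    the prognostic effect (0..3 in steps of 0.5, with beta1 = beta3 = 0);
    power grids vary the predictive effect (0..1 in steps of 0.25).  Step
    grids cross with true cutoffs gamma in {0.2, 0.5, 0.8}; the
    misspecification grid uses the increasing-effect and
    intermediate-peak shapes.
    """
    if figure not in _FIGURES:
        raise ValueError(f"unknown figure tag {figure!r}; one of {_FIGURES}")
    Ks = (2, 4, 8)
    gammas = (0.2, 0.5, 0.8)
    deltas = tuple(np.linspace(0.0, 3.0, 7))
    effects = tuple(np.linspace(0.0, 1.0, 5))
    out = []

    def add(model, K, procs, label):
        out.append(
            Scenario(
                model=model, K=K, procedures=procs, replicates=replicates,
                seed=seed, label=label,
            )
        )

    if figure == "fwer_step":
        for K in Ks:
            for g in gammas:
                for d in deltas:
                    add(
                        ModelSpec(beta2=d, shape="step-decreasing", gamma=g,
                                  n_per_group=n_per_group),
                        K, _FWER_PROCS, f"fwer_step K={K} gamma={g} delta={d:g}",
                    )
    elif figure == "fwer_linear":
        for K in Ks:
            for d in deltas:
                add(
                    ModelSpec(beta2=d, shape="linear-decreasing",
                              n_per_group=n_per_group),
                    K, _FWER_PROCS, f"fwer_linear K={K} beta2={d:g}",
                )
    elif figure == "power_step":
        for K in Ks:
            for g in gammas:
                for e in effects:
                    add(
                        ModelSpec(beta3=e, shape="step-decreasing", gamma=g,
                                  n_per_group=n_per_group),
                        K, _POWER_PROCS, f"power_step K={K} gamma={g} effect={e:g}",
                    )
    elif figure == "power_linear":
        for K in Ks:
            for e in effects:
                add(
                    ModelSpec(beta3=e, shape="linear-decreasing",
                              n_per_group=n_per_group),
                    K, _POWER_PROCS, f"power_linear K={K} beta3={e:g}",
                )
    else:  # misspec
        shapes = (
            ("step-increasing", 0.5),
            ("intermediate-peak", 0.5),
            ("linear-increasing", None),
        )
        for shape, g in shapes:
            for K in Ks:
                for d in (0.0, 1.5, 3.0):
                    add(
                        ModelSpec(beta2=d, shape=shape, gamma=g,
                                  n_per_group=n_per_group),
                        K, _FWER_PROCS, f"misspec_fwer {shape} K={K} beta2={d:g}",
                    )
                for e in (0.5, 1.0):
                    add(
                        ModelSpec(beta3=e, shape=shape, gamma=g,
                                  n_per_group=n_per_group),
                        K, _POWER_PROCS, f"misspec_power {shape} K={K} beta3={e:g}",
                    )
    return out
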