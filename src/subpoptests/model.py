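"""Data-generating model for biomarker-defined subpopulation trials.

The outcome of subject ``i`` in a two-arm parallel-group trial follows

    Y_i = beta0 + beta1*U_i + beta2*f(X_i) + beta3*U_i*f(X_i) + eps_i,

where ``U_i`` is the treatment indicator, ``X_i`` a continuous baseline
biomarker and ``eps_i ~ N(0, sigma^2)``.  The biomarker acts prognostically
through ``beta2`` (shifts the outcome in both arms) and predictively through
``beta3`` (modifies the treatment effect).  The effect-shape function ``f``
is shared by the prognostic and predictive terms and is one of

``step-decreasing``
    1 for ``x <= gamma``, 0 above: a biomarker-low responder subgroup with
    prevalence ``gamma``.
``step-increasing``
    The complement, 1 for ``x > gamma`` (subgroup misspecification scenario).
``linear-decreasing``
    ``1 - x``: effects fade linearly with the biomarker.
``linear-increasing``
    ``x`` (misspecification scenario).
``intermediate-peak``
    Indicator of the central band ``(0.5 - gamma/2, 0.5 + gamma/2]``: the
    largest effects occur at intermediate biomarker values while the nested
    tests accumulate from the low end.  The band is centred so that its
    prevalence stays ``gamma``, keeping scenarios comparable.

Simulated trials have exactly ``n_per_group`` subjects per arm (fixed
allocation) and biomarker values drawn i.i.d. uniform on [0, 1]; subgroup
sample sizes are therefore random even though the trial is balanced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "STEP_SHAPES",
    "SHAPES",
    "ModelSpec",
    "TrialData",
    "effect_function",
    "simulate_trial",
    "replicate_rng",
]

STEP_SHAPES = ("step-decreasing", "step-increasing", "intermediate-peak")
SHAPES = STEP_SHAPES + ("linear-decreasing", "linear-increasing")


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of the data-generating model.

    Parameters
    ----------
    beta0, beta1, beta2, beta3 : float
        Intercept, main treatment effect, prognostic coefficient and
        predictive coefficient (outcome units).
    shape : str
        Effect-shape family, one of :data:`SHAPES`.
    gamma : float or None
        True cutoff in [0, 1]; required for the step-type shapes, ignored
        (and must be None) for the linear shapes.
    sigma : float
        Residual standard deviation, > 0.
    n_per_group : int
        Number of subjects per arm in simulated trials.
    """

    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    shape: str = "step-decreasing"
    gamma: Union[float, None] = None
    sigma: float = 1.0
    n_per_group: int = 80

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(
                f"unknown shape {self.shape!r}; expected one of {SHAPES}"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if int(self.n_per_group) != self.n_per_group or self.n_per_group < 1:
            raise ValueError("n_per_group must be a positive integer")
        if self.shape in STEP_SHAPES:
            if self.gamma is None:
                raise ValueError(f"shape {self.shape!r} requires gamma")
            if not 0.0 <= self.gamma <= 1.0:
                raise ValueError("gamma must lie in [0, 1]")
        elif self.gamma is not None:
            raise ValueError(f"gamma is not used by shape {self.shape!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class TrialData:
    """Subject-level trial data: outcome ``y``, arm ``u`` (1 = treatment,
    0 = control) and biomarker ``x``."""

    y: np.ndarray
    u: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u)
        self.x = np.asarray(self.x, dtype=float)
        if not (self.y.shape == self.u.shape == self.x.shape) or self.y.ndim != 1:
            raise ValueError("y, u, x must be 1-d arrays of equal length")
        if not np.isin(self.u, (0, 1)).all():
            raise ValueError("u must contain only 0/1")
        if np.isnan(self.y).any() or np.isnan(self.x).any():
            raise ValueError("missing values are not allowed")
        self.u = self.u.astype(np.int8)

    def __len__(self) -> int:
        return self.y.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.arange(1, len(self) + 1),
                "y": self.y,
                "u": self.u,
                "x": self.x,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialData":
        # Delegates to the richer validating reader to keep one code path.
        from .io import read_trial_csv

        return read_trial_csv(path)


def effect_function(spec: ModelSpec, x) -> np.ndarray:
    """Evaluate the shared prognostic/predictive shape function f(x).

    Vectorized over ``x``; returns an array of the same shape.
    """
    x = np.asarray(x, dtype=float)
    if spec.shape == "step-decreasing":
        return (x <= spec.gamma).astype(float)
    if spec.shape == "step-increasing":
        return (x > spec.gamma).astype(float)
    if spec.shape == "linear-decreasing":
        return 1.0 - x
    if spec.shape == "linear-increasing":
        return x.copy()
    # intermediate-peak: central band of prevalence gamma
    lo, hi = 0.5 - spec.gamma / 2.0, 0.5 + spec.gamma / 2.0
    return ((x > lo) & (x <= hi)).astype(float)


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Independent, reproducible-in-isolation stream for replicate ``rep``.

    Seeding the generator with the pair (seed, rep) gives a counter-style
    scheme: replicate r can be regenerated without drawing r-1 predecessors,
    and results are invariant to how replicates are distributed over workers.
    """
    return np.random.default_rng([int(seed), int(rep)])


def simulate_trial(
    spec: ModelSpec, seed: Union[int, np.random.Generator]
) -> TrialData:
    """Draw one trial from the model.

    Exactly ``n_per_group`` subjects per arm (treatment first), biomarker
    i.i.d. uniform on [0, 1] independent of arm, normal errors.  The same
    (spec, seed) pair yields bit-identical data.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(int(seed))
    )
    n = int(spec.n_per_group)
    u = np.repeat(np.array([1, 0], dtype=np.int8), n)
    x = rng.uniform(0.0, 1.0, size=2 * n)
    eps = rng.normal(0.0, spec.sigma, size=2 * n)
    f = effect_function(spec, x)
    y = spec.beta0 + spec.beta1 * u + spec.beta2 * f + spec.beta3 * u * f + eps
    return TrialData(y=y, u=u, x=x)
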