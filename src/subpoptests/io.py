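"""CSV readers/writers, fixture generation and report formatting."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import ModelSpec, TrialData, simulate_trial
from .oc import OCResult
from .procedures import DecisionResult

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "generate_fixtures",
    "write_analysis_report",
    "write_oc_report",
    "load_config",
]


class TrialCSVError(ValueError):
    """Malformed trial CSV (missing columns, bad arm codes, missing values)."""


def read_trial_csv(path) -> TrialData:
    """Read subject-level trial data from CSV.

    Requires named columns ``y``, ``u``, ``x`` in any order (``subject_id``
    is optional and ignored).  ``u`` must be 0/1 and no value may be
    missing; errors name the offending rows (1-based, excluding header).
    The biomarker may be on any scale — analysis-mode thresholds are
    interpreted on the same scale.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("y", "u", "x") if c not in df.columns]
    if missing:
        raise TrialCSVError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    for col in ("y", "u", "x"):
        bad = df.index[df[col].isna()].tolist()
        if bad:
            rows = [i + 1 for i in bad[:10]]
            raise TrialCSVError(
                f"{path}: missing values in column {col!r} at row(s) {rows}"
            )
    u = df["u"].to_numpy()
    bad = df.index[~np.isin(u, (0, 1))].tolist()
    if bad:
        rows = [i + 1 for i in bad[:10]]
        raise TrialCSVError(
            f"{path}: arm indicator u must be 0 or 1; offending row(s) {rows}"
        )
    return TrialData(
        y=df["y"].to_numpy(float), u=u.astype(np.int8), x=df["x"].to_numpy(float)
    )


def write_trial_csv(data: TrialData, path) -> None:
    data.to_csv(path)


def load_config(path) -> dict:
    """Plain-text key-value run configuration (YAML; JSON is a subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def _metadata_lines(meta: Dict) -> list:
    meta = {"tool": "subpoptests", "version": __version__, **meta}
    return [f"# {k} = {v}" for k, v in meta.items()]


def write_analysis_report(
    results: Sequence[DecisionResult],
    summary_rows: pd.DataFrame,
    path,
    meta: Optional[Dict] = None,
) -> pd.DataFrame:
    """Tidy per-subgroup-per-procedure report (statistics and boundaries to
    4 decimals in the human-readable columns, full precision retained in
    the machine-readable ones), with a metadata footer of '#' lines."""
    frames = []
    for res in results:
        k = np.arange(1, res.statistics.size + 1)
        frames.append(
            pd.DataFrame(
                {
                    "procedure": res.procedure,
                    "subgroup": k,
                    "threshold": res.thresholds,
                    "statistic": res.statistics,
                    "boundary": res.boundaries,
                    "df": res.df,
                    "reject": res.reject,
                    "degenerate": res.degenerate,
                    "adjusted_p": (
                        res.adjusted_p
                        if res.adjusted_p is not None
                        else np.full(res.statistics.size, np.nan)
                    ),
                }
            )
        )
    rep = pd.concat(frames, ignore_index=True)
    rep = summary_rows.merge(rep, on=["subgroup", "threshold"], how="right")
    with open(path, "w") as fh:
        rep.round(
            {"statistic": 4, "boundary": 4, "adjusted_p": 4,
             "mean_t": 4, "mean_c": 4, "sd_t": 4, "sd_c": 4}
        ).to_csv(fh, index=False)
        for line in _metadata_lines(meta or {}):
            fh.write(line + "\n")
    return rep


def write_oc_report(
    rows: Iterable[dict], path, meta: Optional[Dict] = None
) -> pd.DataFrame:
    """One row per scenario x procedure, with the Monte-Carlo SE column."""
    df = pd.DataFrame(list(rows))
    with open(path, "w") as fh:
        df.to_csv(fh, index=False)
        for line in _metadata_lines(meta or {}):
            fh.write(line + "\n")
    return df


#: fixture recipes: small seeded datasets covering the main analysis cases
_FIXTURES = {
    "null_prognostic": ModelSpec(
        beta2=2.0, shape="step-decreasing", gamma=0.5, n_per_group=40
    ),
    "step_alternative": ModelSpec(
        beta3=1.0, shape="step-decreasing", gamma=0.5, n_per_group=40
    ),
    "linear_alternative": ModelSpec(
        beta3=1.0, shape="linear-decreasing", n_per_group=40
    ),
    # only ~1.2 expected subjects per arm below q1=0.15: triggers the
    # degenerate-subgroup rule for small thresholds
    "degenerate_subgroup": ModelSpec(
        beta2=1.0, shape="step-decreasing", gamma=0.5, n_per_group=8
    ),
}


def generate_fixtures(out_dir, seed: int = 0) -> Dict[str, Path]:
    """Write the bundled synthetic example datasets and their manifest.

    Regenerates bit-identically from the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    paths = {}
    for i, (name, spec) in enumerate(sorted(_FIXTURES.items())):
        data = simulate_trial(spec, seed=np.random.default_rng([seed, i]))
        p = out / f"{name}.csv"
        data.to_csv(p)
        paths[name] = p
        manifest[name] = {"seed": [seed, i], "model": spec.to_dict()}
        if name == "degenerate_subgroup":
            # a first threshold isolating a single subject, so the smallest
            # subgroup violates the two-per-arm minimum by construction
            xs = np.sort(data.x)
            manifest[name]["suggested_thresholds"] = [
                float(0.5 * (xs[0] + xs[1])), 1.0
            ]
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mpath
    return paths
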