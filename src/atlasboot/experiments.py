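"""Type-I-error and power simulation designs for the weighting schemes.

Both experiments resample subjects from supplied cohort tables and run the
weighted Collins–Dekker permutation test of the group effect, adjusting
for nuisance covariates (age and intracranial volume by default), under
one or more weighting schemes:

* ``precision`` — inverse bootstrap variance (the ``precision_weight``
  column),
* ``inverse_cv`` — reciprocal coefficient of variation (``cv_weight``),
* ``identity`` — unit weights (equivalent to OLS).

The type-I-error design draws ``2n`` subjects without replacement from a
single (control) pool and assigns artificial group labels at random, so
the null holds by construction.  The power design draws ``n`` subjects
with replacement from each of two groups; duplicated subjects are treated
as distinct observations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import collins_dekker_test

__all__ = ["ExperimentConfig", "ExperimentResult", "type1_experiment", "power_experiment"]

SCHEME_COLUMNS = {"precision": "precision_weight", "inverse_cv": "cv_weight", "identity": None}


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid of per-group sample sizes, replicate count and test settings."""

    n_grid: tuple[int, ...] = (5, 10, 20, 40, 80)
    n_reps: int = 1000
    alpha: float = 0.05
    schemes: tuple[str, ...] = ("precision", "identity")
    n_perm: int = 999
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "icv")
    response: str = "volume_mm3"

    def __post_init__(self) -> None:
        if any(n < 3 for n in self.n_grid):
            raise ValueError("n_grid entries must be >= 3")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        unknown = set(self.schemes) - set(SCHEME_COLUMNS)
        if unknown:
            raise ValueError(f"unknown weighting schemes: {sorted(unknown)}")


@dataclass(frozen=True)
class ExperimentResult:
    """Tidy rejection rates plus the raw per-replicate p-values."""

    rates: pd.DataFrame  # columns: scheme, n, rejection_rate, n_reps, alpha, seed
    p_values: pd.DataFrame  # columns: scheme, n, rep, p_value
    config: ExperimentConfig


def _require_columns(table: pd.DataFrame, config: ExperimentConfig) -> None:
    needed = {config.response, *config.covariates}
    for scheme in config.schemes:
        col = SCHEME_COLUMNS[scheme]
        if col is not None:
            needed.add(col)
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")


def _weights_for(table: pd.DataFrame, scheme: str) -> np.ndarray:
    col = SCHEME_COLUMNS[scheme]
    if col is None:
        return np.ones(len(table))
    return table[col].to_numpy(dtype=float)


def _run_tests(
    table: pd.DataFrame,
    group: np.ndarray,
    config: ExperimentConfig,
    perm_seed: int,
) -> dict[str, float]:
    y = table[config.response].to_numpy(dtype=float)
    Z = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in config.covariates]
    )
    out = {}
    for scheme in config.schemes:
        w = _weights_for(table, scheme)
        res = collins_dekker_test(
            y, group.astype(float), Z, w, n_perm=config.n_perm, seed=perm_seed
        )
        out[scheme] = res.p_value
    return out


def _collect(records: list[dict], config: ExperimentConfig) -> ExperimentResult:
    p_values = pd.DataFrame.from_records(records)
    rates = (
        p_values.assign(reject=lambda d: d["p_value"] < config.alpha)
        .groupby(["scheme", "n"], as_index=False)["reject"]
        .mean()
        .rename(columns={"reject": "rejection_rate"})
    )
    rates["n_reps"] = config.n_reps
    rates["alpha"] = config.alpha
    rates["seed"] = config.seed
    return ExperimentResult(rates=rates, p_values=p_values, config=config)


def type1_experiment(controls: pd.DataFrame, config: ExperimentConfig) -> ExperimentResult:
    """Null rejection rates with artificial group labels on one pool.

    Per replicate: draw ``2n`` subjects without replacement (covariates and
    weights travel with the subject), assign n to each artificial group at
    random, and test the label effect under every scheme.
    """
    _require_columns(controls, config)
    if len(controls) < 2 * max(config.n_grid):
        raise ValueError(
            f"need at least {2 * max(config.n_grid)} control subjects, have {len(controls)}"
        )
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    records = []
    for n in config.n_grid:
        for rep in range(config.n_reps):
            idx = rng.choice(len(controls), size=2 * n, replace=False)
            sub = controls.iloc[idx].reset_index(drop=True)
            labels = np.zeros(2 * n, dtype=int)
            labels[rng.choice(2 * n, size=n, replace=False)] = 1
            perm_seed = int(rng.integers(0, 2**31 - 1))
            for scheme, p in _run_tests(sub, labels, config, perm_seed).items():
                records.append({"scheme": scheme, "n": n, "rep": rep, "p_value": p})
    return _collect(records, config)


def power_experiment(
    group0: pd.DataFrame, group1: pd.DataFrame, config: ExperimentConfig
) -> ExperimentResult:
    """Rejection rates for a real group contrast, resampling with replacement.

    Per replicate: draw ``n`` subjects with replacement from each group and
    test the group effect under every scheme.
    """
    for tbl, name in ((group0, "group0"), (group1, "group1")):
        if len(tbl) == 0:
            raise ValueError(f"{name} table is empty")
        _require_columns(tbl, config)
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    records = []
    for n in config.n_grid:
        for rep in range(config.n_reps):
            i0 = rng.choice(len(group0), size=n, replace=True)
            i1 = rng.choice(len(group1), size=n, replace=True)
            sub = pd.concat(
                [group0.iloc[i0], group1.iloc[i1]], ignore_index=True
            )
            labels = np.repeat([0, 1], n)
            perm_seed = int(rng.integers(0, 2**31 - 1))
            for scheme, p in _run_tests(sub, labels, config, perm_seed).items():
                records.append({"scheme": scheme, "n": n, "rep": rep, "p_value": p})
    return _collect(records, config)
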