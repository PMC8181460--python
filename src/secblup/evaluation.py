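"""Accuracy evaluation: the simulation grid and the train/test CV harness.

Accuracy is the Pearson correlation between predicted breeding values and
either the simulated genetic effects (simulation study) or the observed
phenotypes (real-data style CV), on the test set.  The grid runner sweeps
the causal-effect and correlation grids of the simulation design; every
(cell, replicate) task carries its own child RNG, so results are identical
for any execution order or degree of parallelism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .kinship import partition_kinship
from .multikernel import gm_blup, m_blup, multi_blup
from .predict import predict_univariate
from .reduction import ls_blup, rf_blup
from .reml import UnivariateGBLUP
from .selindex import si_blup
from .simulate import (
    LAMBDA_GRID,
    N_CAUSAL,
    RHO_GRID,
    benchmark_predict,
    build_structural_model,
    simulate_dataset,
    simulate_plot_data,
)

__all__ = [
    "accuracy",
    "AccuracyReport",
    "run_simulation_grid",
    "run_real_data_cv",
    "GRID_METHODS",
]


def accuracy(u_hat, reference) -> float:
    """Pearson correlation between predictions and a reference vector.

    The reference is either true genetic effects (simulation) or observed
    phenotypes (real data).  A constant prediction vector carries no
    ranking information and scores 0, with a warning.
    """
    u = np.asarray(u_hat, dtype=float).ravel()
    v = np.asarray(reference, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError("length mismatch")
    if u.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(u).any() or np.isnan(v).any():
        raise ValueError("NaN values in accuracy inputs")
    if np.ptp(u) == 0.0 or np.ptp(v) == 0.0:
        warnings.warn("constant vector in accuracy computation; returning 0")
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


# ---------------------------------------------------------------------------
# simulation grid
# ---------------------------------------------------------------------------


def _grid_gblup(ds, scenario, rng):
    y = ds.y_focal_train
    fit = UnivariateGBLUP(y, eig=ds.kpart.eigh_oo()).fit()
    return predict_univariate(fit, y, ds.kpart, scenario=scenario)


def _grid_benchmark(ds, scenario, rng):
    return benchmark_predict(ds, scenario)


def _grid_ls_blup(ds, scenario, rng):
    return ls_blup(
        ds.y_focal_train,
        ds.secondary_frame(),
        ds.kpart,
        scenario,
        seed=rng,
    )


def _grid_rf_blup(ds, scenario, rng):
    return rf_blup(
        ds.y_focal_train,
        ds.secondary_frame(),
        ds.kpart,
        scenario,
        seed=rng,
    )


def _grid_si_blup(ds, scenario, rng):
    plots = simulate_plot_data(ds, n_reps=2, seed=rng)
    means = plots.drop(columns="rep").groupby("genotype", sort=False).mean()
    sec_cols = [c for c in means.columns if c != "Y1"]
    if scenario == 2:
        ys_means = ds.secondary_frame()
    else:
        ys_means = means[sec_cols]
    return si_blup(
        plots,
        ds.y_focal_train,
        ys_means,
        ds.kpart,
        scenario,
        seed=rng,
    )


def _grid_multi_blup(ds, scenario, rng):
    return multi_blup(ds.y_focal_train, ds.secondary_frame(), ds.kpart, seed=rng)


def _grid_gm_blup(ds, scenario, rng):
    kp = ds.kpart
    return gm_blup(
        ds.y_focal_train,
        ds.secondary_frame().loc[kp.train_ids],
        kp,
        scenario=scenario,
        seed=rng,
    )


def _grid_m_blup(ds, scenario, rng):
    return m_blup(ds.y_focal_train, ds.secondary_frame(), ds.kpart)


#: method name -> (runner, supported scenarios, scenario-independent?)
GRID_METHODS = {
    "gblup": (_grid_gblup, (1, 2), True),
    "benchmark": (_grid_benchmark, (1, 2), False),
    "ls-blup": (_grid_ls_blup, (1, 2), False),
    "rf-blup": (_grid_rf_blup, (1, 2), False),
    "si-blup": (_grid_si_blup, (1, 2), False),
    "multi-blup": (_grid_multi_blup, (2,), False),
    "gm-blup": (_grid_gm_blup, (1, 2), False),
    "m-blup": (_grid_m_blup, (2,), False),
}


def _parse_methods(methods, scenarios):
    """Expand method names (optionally 'name:scenario') into run entries."""
    entries = []
    for spec_ in methods:
        if ":" in spec_:
            name, sc = spec_.split(":")
            sc_list = [int(sc)]
        else:
            name, sc_list = spec_, list(scenarios)
        name = name.lower()
        if name not in GRID_METHODS:
            raise ValueError(f"unknown method {name!r}; choose from {sorted(GRID_METHODS)}")
        fn, supported, indep = GRID_METHODS[name]
        wanted = [s for s in sc_list if s in supported]
        if not wanted:
            raise ValueError(f"method {name!r} is not valid in scenarios {sc_list}")
        if indep:
            wanted = wanted[:1]
        for s in wanted:
            entries.append((name, s, fn))
    return entries


@dataclass
class AccuracyReport:
    """Long-format accuracy rows plus per-cell aggregates."""

    results: pd.DataFrame
    errors: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        keys = [
            c
            for c in ("method", "scenario", "lambda_causal", "rho_G", "rho_E")
            if c in self.results.columns
        ]
        grp = self.results.groupby(keys, dropna=False)["accuracy"]
        out = grp.agg(
            mean="mean", sd="std", n_ok="count", n_total="size"
        ).reset_index()
        out["se"] = out["sd"] / np.sqrt(out["n_ok"].clip(lower=1))
        return out

    def summary(self) -> str:
        agg = self.aggregate()
        return agg.to_string(index=False, float_format=lambda v: f"{v:.3f}")


def _run_cell(master_seed, cell_idx, cell, rep, entries, sim_kwargs):
    lam, rg, re_ = cell
    rng = np.random.default_rng((int(master_seed), int(cell_idx), int(rep)))
    model = build_structural_model(lam, rg, re_, p=sim_kwargs.pop_p)
    rows, errors = [], []
    try:
        ds = simulate_dataset(
            model,
            n=sim_kwargs.n,
            n_test=sim_kwargs.n_test,
            m=sim_kwargs.m,
            maf_min=sim_kwargs.maf_min,
            seed=rng,
        )
    except Exception as exc:  # noqa: BLE001
        for name, sc, _fn in entries:
            rows.append((name, sc, lam, rg, re_, rep, np.nan))
        errors.append((cell, rep, "simulate", repr(exc)))
        return rows, errors
    truth = ds.u_focal_test
    for name, sc, fn in entries:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred = fn(ds, sc, rng)
                r = accuracy(pred.u_test.to_numpy(), truth)
        except Exception as exc:  # noqa: BLE001 - record-and-continue policy
            r = np.nan
            errors.append((cell, rep, name, repr(exc)))
        rows.append((name, sc, lam, rg, re_, rep, r))
    return rows, errors


class _SimKwargs:
    def __init__(self, n, n_test, m, maf_min, p):
        self.n, self.n_test, self.m, self.maf_min, self.pop_p = (
            n,
            n_test,
            m,
            maf_min,
            p,
        )


def run_simulation_grid(
    methods=("gblup", "benchmark"),
    *,
    lambdas=LAMBDA_GRID,
    rho_Gs=RHO_GRID,
    rho_Es=RHO_GRID,
    replicates: int = 50,
    seed: int = 1,
    scenarios=(1, 2),
    n: int = 500,
    n_test: int = 100,
    m: int = 1500,
    maf_min: float = 0.3,
    p: int = N_CAUSAL,
    n_jobs: int = 1,
) -> AccuracyReport:
    """Simulate-fit-predict-score over the lambda x rho_G x rho_E grid.

    ``p`` is the number of secondary traits carried by each dataset; the
    default keeps only the causal block, which is sufficient for methods
    that do not see the 297 noise traits (univariate GBLUP, benchmark).
    A failed replicate records NaN and the grid continues.
    """
    entries = _parse_methods(methods, scenarios)
    cells = [
        (lam, rg, re_) for lam in lambdas for rg in rho_Gs for re_ in rho_Es
    ]
    sim_kwargs = _SimKwargs(n, n_test, m, maf_min, p)
    tasks = [
        (ci, cell, rep)
        for ci, cell in enumerate(cells)
        for rep in range(replicates)
    ]
    out = Parallel(n_jobs=n_jobs)(
        delayed(_run_cell)(seed, ci, cell, rep, entries, sim_kwargs)
        for ci, cell, rep in tasks
    )
    rows, errors = [], []
    for r, e in out:
        rows.extend(r)
        errors.extend(e)
    df = pd.DataFrame(
        rows,
        columns=[
            "method",
            "scenario",
            "lambda_causal",
            "rho_G",
            "rho_E",
            "replicate",
            "accuracy",
        ],
    )
    return AccuracyReport(
        results=df,
        errors=errors,
        provenance={
            "seed": seed,
            "replicates": replicates,
            "n": n,
            "n_test": n_test,
            "m": m,
            "maf_min": maf_min,
            "p": p,
            "methods": [f"{name}:{sc}" for name, sc, _ in entries],
        },
    )


# ---------------------------------------------------------------------------
# real-data style cross-validation
# ---------------------------------------------------------------------------


_CV_METHODS = {"gblup", "ls-blup", "rf-blup", "multi-blup", "gm-blup", "m-blup"}


def run_real_data_cv(
    phenotypes: pd.DataFrame,
    secondary: pd.DataFrame,
    kinship: pd.DataFrame,
    *,
    focal: str | None = None,
    methods=("gblup",),
    scenario: int = 1,
    n_splits: int = 160,
    train_frac: float = 0.7,
    seed: int = 1,
    diagonal_residual: bool = True,
    n_jobs: int = 1,
) -> AccuracyReport:
    """Random 70/30 train/test splits; accuracy against the observed test
    phenotypes (a biased but method-invariant estimate of true accuracy
    when focal and secondary traits come from different plants)."""
    focal = focal or phenotypes.columns[0]
    y_all = phenotypes[focal].dropna()
    ids = [g for g in kinship.index if g in y_all.index]
    if len(ids) < 10:
        raise ValueError("fewer than 10 genotypes shared by phenotypes and kinship")
    bad = set(methods) - _CV_METHODS
    if bad:
        raise ValueError(f"methods not supported in the CV harness: {sorted(bad)}")

    def one_split(s):
        rng = np.random.default_rng((int(seed), int(s)))
        n_all = len(ids)
        n_test = max(1, int(round((1.0 - train_frac) * n_all)))
        test_ids = list(rng.choice(np.array(ids, dtype=object), n_test, replace=False))
        kp = partition_kinship(kinship.loc[ids, ids], test_ids)
        y_fo = y_all.loc[kp.train_ids].to_numpy()
        y_ft = y_all.loc[kp.test_ids].to_numpy()
        rows, errors = [], []
        for name in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if name == "gblup":
                        fit = UnivariateGBLUP(y_fo, eig=kp.eigh_oo()).fit()
                        pred = predict_univariate(fit, y_fo, kp, scenario=scenario)
                    elif name == "ls-blup":
                        pred = ls_blup(
                            y_fo, secondary, kp, scenario,
                            diagonal_residual=diagonal_residual, seed=rng,
                        )
                    elif name == "rf-blup":
                        pred = rf_blup(
                            y_fo, secondary, kp, scenario,
                            diagonal_residual=diagonal_residual, seed=rng,
                        )
                    elif name == "multi-blup":
                        pred = multi_blup(y_fo, secondary, kp, seed=rng)
                    elif name == "gm-blup":
                        pred = gm_blup(y_fo, secondary, kp, scenario=scenario, seed=rng)
                    elif name == "m-blup":
                        pred = m_blup(y_fo, secondary, kp)
                    r = accuracy(pred.u_test.loc[kp.test_ids].to_numpy(), y_ft)
            except Exception as exc:  # noqa: BLE001
                r = np.nan
                errors.append((s, name, repr(exc)))
            rows.append((name, scenario, s, r))
        return rows, errors

    out = Parallel(n_jobs=n_jobs)(delayed(one_split)(s) for s in range(n_splits))
    rows, errors = [], []
    for r, e in out:
        rows.extend(r)
        errors.extend(e)
    df = pd.DataFrame(rows, columns=["method", "scenario", "split", "accuracy"])
    df = df.rename(columns={"split": "replicate"})
    return AccuracyReport(
        results=df,
        errors=errors,
        provenance={
            "seed": seed,
            "n_splits": n_splits,
            "train_frac": train_frac,
            "focal": focal,
            "scenario": scenario,
        },
    )
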