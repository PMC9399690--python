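"""Surrogate sensitivity analysis of activation time.

A gradient-boosted tree ensemble (GBTE) is trained to predict a cell's ERK
activation time from its sampled kinetic parameter vector. The trained
surrogate is validated by fivefold cross-validation of R^2 and explained
variance (EV; their equality implies a zero-mean residual, i.e. an unbiased
predictor), and parameter influence is scored by permutation importance:
the drop in R^2 when one feature column is shuffled across the dataset,
repeated k times and tested for positivity with a one-tailed t-test.

Censored cells (no threshold crossing before the horizon) carry the
horizon as their activation-time label, preserving the signal that slow
regimes exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from .constructs import CARConstruct
from .parameters import KineticParameterSet
from .simulate import DEFAULT_SETTINGS, SimulationSettings
from .variability import (
    AntigenDistributionSpec,
    KineticVariabilitySpec,
    run_population,
)

DEFAULT_GBT_PARAMS = {
    "n_estimators": 500,
    "max_depth": 3,
    "learning_rate": 0.05,
    "subsample": 0.8,
}


@dataclass
class SurrogateDataset:
    X: pd.DataFrame                    # n x p sampled kinetic parameters
    y: np.ndarray                      # activation times (min), horizon if censored
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.isna().any().any() or np.any(~np.isfinite(self.y)):
            raise ValueError("surrogate dataset must not contain missing values")
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


@dataclass(frozen=True)
class SurrogateMetrics:
    r2_mean: float
    r2_sd: float
    ev_mean: float
    ev_sd: float

    def __post_init__(self) -> None:
        if self.r2_mean > self.ev_mean + 1e-12:
            raise ValueError("EV must dominate R^2 (equality iff unbiased)")


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Coefficient of determination and explained variance.

    R^2 = 1 - SS_res / SS_tot; EV = 1 - Var(residual) / Var(y_true).
    EV >= R^2 always, with equality iff the residual has zero mean.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true is constant; R^2 and EV are undefined")
    resid = y_true - y_pred
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    ev = 1.0 - float(np.var(resid)) / float(np.var(y_true))
    return {"r2": r2, "ev": ev}


def generate_surrogate_dataset(
    construct: CARConstruct,
    registry: KineticParameterSet,
    antigen: float,
    kinetic_spec: KineticVariabilitySpec | None = None,
    settings: SimulationSettings = DEFAULT_SETTINGS,
    n: int = 1000,
    seed: int = 0,
) -> SurrogateDataset:
    """Simulate n cells at fixed antigen with sampled kinetics -> (X, y).

    Cells whose integration fails are dropped (count recorded in
    provenance); censored cells keep y = horizon.
    """
    if n < 100:
        raise ValueError("need n >= 100 for a meaningful surrogate dataset")
    if kinetic_spec is None:
        kinetic_spec = KineticVariabilitySpec()
    records, _ = run_population(
        construct,
        registry,
        AntigenDistributionSpec(kind="fixed", fixed_value=antigen),
        kinetic_spec,
        settings,
        n=n,
        seed=seed,
    )
    names = kinetic_spec.resolve_names(registry)
    ok = records["solver_status"] >= 0
    records = records[ok]
    y = records["activation_time_min"].to_numpy().copy()
    y[~records["active"].to_numpy()] = settings.horizon
    return SurrogateDataset(
        X=records[names].reset_index(drop=True),
        y=y,
        provenance={
            "construct": construct.label,
            "antigen": antigen,
            "n_requested": n,
            "n_failed": int((~ok).sum()),
            "seed": seed,
            "horizon": settings.horizon,
        },
    )


def fit_surrogate(
    dataset: SurrogateDataset,
    hyperparameters: dict | None = None,
    cv_seed: int = 0,
    n_splits: int = 5,
) -> tuple[GradientBoostingRegressor, SurrogateMetrics]:
    """Fivefold-CV-validated GBTE; final model refit on all data."""
    hp = dict(DEFAULT_GBT_PARAMS)
    if hyperparameters:
        hp.update(hyperparameters)
    X = dataset.X.to_numpy()
    y = dataset.y
    if np.ptp(y) == 0.0:
        raise ValueError("activation times are constant; surrogate fit refused")
    if len(y) < n_splits:
        raise ValueError(f"need at least {n_splits} samples for {n_splits}-fold CV")

    r2s, evs = [], []
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=cv_seed)
    for train, test in kf.split(X):
        model = GradientBoostingRegressor(random_state=cv_seed, **hp)
        model.fit(X[train], y[train])
        m = evaluate_metrics(y[test], model.predict(X[test]))
        r2s.append(m["r2"])
        evs.append(m["ev"])
    metrics = SurrogateMetrics(
        r2_mean=float(np.mean(r2s)),
        r2_sd=float(np.std(r2s, ddof=1)),
        ev_mean=float(np.mean(evs)),
        ev_sd=float(np.std(evs, ddof=1)),
    )
    final = GradientBoostingRegressor(random_state=cv_seed, **hp)
    final.fit(X, y)
    return final, metrics


def permutation_importance_report(
    model,
    dataset: SurrogateDataset,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance with a one-tailed t-test over k shuffles.

    For each feature, Delta-R^2 = R^2(baseline) - R^2(column shuffled),
    repeated k times. Scores are reported raw — sampling noise can make
    them slightly negative on evaluation data — and significance comes
    from a one-tailed t-test (H1: mean Delta-R^2 > 0, df = k - 1), not
    from clipping.
    """
    if k < 2:
        raise ValueError("k >= 2 shuffles needed for the t-test")
    X = dataset.X.to_numpy().copy()
    y = dataset.y
    baseline = evaluate_metrics(y, model.predict(X))["r2"]
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(dataset.feature_names):
        drops = np.empty(k)
        col = X[:, j].copy()
        for rep in range(k):
            X[:, j] = rng.permutation(col)
            drops[rep] = baseline - evaluate_metrics(y, model.predict(X))["r2"]
        X[:, j] = col
        sd = float(np.std(drops, ddof=1))
        if sd > 0:
            tstat = float(np.mean(drops) / (sd / np.sqrt(k)))
            pval = float(stats.t.sf(tstat, df=k - 1))
        else:  # all drops identical (e.g. exactly zero for an unused column)
            tstat, pval = (np.inf, 0.0) if np.mean(drops) > 0 else (0.0, 1.0)
        rows.append(
            {
                "feature": name,
                "mean_importance": float(np.mean(drops)),
                "sd_importance": sd,
                "t_stat": tstat,
                "p_value": pval,
                "k": k,
            }
        )
    report = pd.DataFrame(rows).sort_values(
        "mean_importance", ascending=False, ignore_index=True
    )
    report["rank"] = np.arange(1, len(report) + 1)
    return report
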