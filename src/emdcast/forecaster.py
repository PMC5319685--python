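"""End-to-end hybrid forecasting pipeline.

The full method (mode ``emd_pso_bpann``) runs six stages: (1) decompose
the monthly series into IMFs plus a residue, (2) min-max normalize each
component onto [-1, 1], (3) search good initial network weights and
thresholds for each component with PSO, (4) refine each network by
resilient backpropagation on the training span, (5) forecast every
component over the test horizon, (6) superpose the denormalized component
forecasts into the final prediction.

Mode ``pso_bpann`` skips decomposition (one network on the raw series);
mode ``bpann`` additionally skips PSO (random initialization only).  Each
component's one-step-ahead inputs are its own three most recent values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import emd, mlp, pso
from .emd import Decomposition, SiftConfig
from .errors import EmdcastError, InvalidInputError
from .metrics import MetricBundle, evaluate
from .mlp import MLPParameters, Normalizer, TrainConfig
from .pso import PSOConfig
from .series import Month, TimeSeries, add_months, month_index

__all__ = [
    "Mode",
    "Scheme",
    "HybridModel",
    "ForecastReport",
    "split_by_date",
    "fit",
    "predict",
    "compare_methods",
]

Mode = Literal["emd_pso_bpann", "pso_bpann", "bpann"]
Scheme = Literal["one_step_ahead", "recursive"]

N_LAGS_DEFAULT = 3
HIDDEN_DEFAULT = mlp.hidden_node_count(3, 1, 10)  # 3-14-1 architecture


def component_seed(master_seed: int, component: int, purpose: int) -> int:
    """Deterministic per-component sub-seed derived from the master seed."""
    ss = np.random.SeedSequence((master_seed, component, purpose))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class HybridModel:
    """Fitted pipeline: the training-time decomposition view, one
    (network, normalizer) pair per component, and the configs used."""

    mode: Mode
    decomposition: Decomposition | None
    component_models: tuple[tuple[MLPParameters, Normalizer], ...]
    component_train_mse: tuple[float, ...]
    pso_best_fitness: tuple[float, ...]
    n_lags: int
    train_end: Month  # last calendar month seen during training
    series_start: Month
    sift_config: SiftConfig
    train_config: TrainConfig
    pso_config: PSOConfig
    decompose_scope: Literal["full", "train"]
    master_seed: int

    @property
    def n_components(self) -> int:
        return len(self.component_models)


@dataclass(frozen=True)
class ForecastReport:
    """Forecast horizon results: superposed and per-component predictions,
    the observed values, and the four evaluation criteria."""

    predicted: np.ndarray
    observed: np.ndarray
    per_component_predicted: np.ndarray  # (n_steps, n_components)
    metrics: MetricBundle
    horizon_labels: tuple[Month, ...]


def split_by_date(series: TimeSeries, last_train_month: Month) -> tuple[TimeSeries, TimeSeries]:
    """Split into train (start..last_train_month inclusive) and test
    (the remainder); both parts must be non-empty."""
    k = series.index_of(last_train_month)
    if k == len(series) - 1:
        raise InvalidInputError("no test months remain after the split")
    if k < 1:
        raise InvalidInputError("training span must contain more than one month")
    return series.slice(0, k + 1), series.slice(k + 1, len(series))


def _component_paths(
    series: TimeSeries, mode: Mode, n_train: int, cfg: SiftConfig, scope: str
) -> tuple[Decomposition | None, list[np.ndarray]]:
    """Full observed value path of each modeled component.

    With ``scope='train'`` the paths end at the split, so nothing after it
    can influence the fit.
    """
    if mode == "emd_pso_bpann":
        source = series.values if scope == "full" else series.values[:n_train]
        decomposition = emd.decompose(source, cfg)
        return decomposition, decomposition.components()
    path = series.values if scope == "full" else series.values[:n_train]
    return None, [path]


def fit(
    series: TimeSeries,
    last_train_month: Month,
    mode: Mode = "emd_pso_bpann",
    *,
    n_lags: int = N_LAGS_DEFAULT,
    n_hidden: int = HIDDEN_DEFAULT,
    sift_config: SiftConfig | None = None,
    train_config: TrainConfig | None = None,
    pso_config: PSOConfig | None = None,
    decompose_scope: Literal["full", "train"] = "full",
    seed: int = 0,
) -> HybridModel:
    """Fit the hybrid model on everything up to ``last_train_month``.

    With ``decompose_scope='full'`` the decomposition is computed on the
    whole series before splitting (so test-period values shape the IMFs,
    as when a completed record is decomposed once and then studied);
    ``'train'`` restricts it to the training span for a leakage-free fit.
    Deterministic given ``seed``.
    """
    if mode not in ("emd_pso_bpann", "pso_bpann", "bpann"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    sift_config = sift_config or SiftConfig()
    train_config = train_config or TrainConfig()
    pso_config = pso_config or PSOConfig()
    n_train = series.index_of(last_train_month) + 1
    if n_train <= n_lags + 1:
        raise InvalidInputError("training span too short for lag embedding")

    decomposition, paths = _component_paths(
        series, mode, n_train, sift_config, decompose_scope
    )

    fitted: list[tuple[MLPParameters, Normalizer]] = []
    train_mses: list[float] = []
    pso_fits: list[float] = []
    for c_idx, path in enumerate(paths):
        try:
            # Pipeline order is decompose -> normalize -> split, so the
            # scaling spans the whole component path; with scope='train'
            # the path itself stops at the split.
            scaled, norm = mlp.normalize(path)
            inputs, targets = mlp.lag_embed(scaled[:n_train], n_lags)
            if mode in ("emd_pso_bpann", "pso_bpann"):
                objective = pso.make_mse_objective(inputs, targets, n_lags, n_hidden)
                cfg = replace(pso_config, seed=component_seed(seed, c_idx, 0))
                best_pos, best_fit, _ = pso.optimize(
                    objective, pso.particle_dimension(n_lags, n_hidden, 1), cfg
                )
                params0 = pso.decode(best_pos, n_lags, n_hidden)
            else:
                best_fit = float("nan")
                params0 = mlp.init_params(n_lags, n_hidden, component_seed(seed, c_idx, 1))
            tcfg = replace(train_config, seed=component_seed(seed, c_idx, 2))
            params, history = mlp.train(params0, inputs, targets, tcfg)
            fitted.append((params, norm))
            train_mses.append(float(history.min()))
            pso_fits.append(best_fit)
        except EmdcastError as exc:
            raise type(exc)(f"component {c_idx + 1}: {exc}") from exc

    return HybridModel(
        mode=mode,
        decomposition=decomposition,
        component_models=tuple(fitted),
        component_train_mse=tuple(train_mses),
        pso_best_fitness=tuple(pso_fits),
        n_lags=n_lags,
        train_end=last_train_month,
        series_start=series.start,
        sift_config=sift_config,
        train_config=train_config,
        pso_config=pso_config,
        decompose_scope=decompose_scope,
        master_seed=seed,
    )


def _observed_component_paths(model: HybridModel, series: TimeSeries) -> list[np.ndarray]:
    """Per-component observed value paths used to source lagged inputs."""
    if model.mode == "emd_pso_bpann":
        assert model.decomposition is not None
        return model.decomposition.components()
    return [series.values]


def predict(
    model: HybridModel,
    series: TimeSeries,
    horizon_start: Month,
    horizon_end: Month,
    scheme: Scheme = "one_step_ahead",
) -> ForecastReport:
    """Forecast each component over [horizon_start, horizon_end] and
    superpose.

    ``one_step_ahead`` feeds each step the observed (decomposed) values of
    the previous ``n_lags`` months; ``recursive`` feeds the model's own
    earlier predictions once the horizon has begun.
    """
    if scheme not in ("one_step_ahead", "recursive"):
        raise InvalidInputError(f"unknown scheme {scheme!r}")
    h0 = month_index(series.start, horizon_start)
    h1 = month_index(series.start, horizon_end)
    if h1 < h0:
        raise InvalidInputError("horizon_end precedes horizon_start")
    if h0 < model.n_lags:
        raise InvalidInputError(
            f"horizon starts at month offset {h0}; need {model.n_lags} months of history"
        )
    if h1 >= len(series):
        raise InvalidInputError("horizon extends past the observed series")
    paths = _observed_component_paths(model, series)
    for k, path in enumerate(paths):
        if path.size <= h1:
            raise InvalidInputError(
                f"component {k + 1} values end before the horizon; refit with "
                "decompose_scope='full' or use a shorter horizon"
            )

    n_steps = h1 - h0 + 1
    per_component = np.empty((n_steps, model.n_components))
    for c_idx, ((params, norm), path) in enumerate(zip(model.component_models, paths)):
        scaled_path = 2.0 * (path - norm.observed_min) / (
            norm.observed_max - norm.observed_min
        ) - 1.0
        working = scaled_path.copy()
        for s, t in enumerate(range(h0, h1 + 1)):
            lags = (
                scaled_path[t - model.n_lags : t]
                if scheme == "one_step_ahead"
                else working[t - model.n_lags : t]
            )
            yhat_scaled = mlp.forward(params, lags)
            if scheme == "recursive":
                working[t] = yhat_scaled
            per_component[s, c_idx] = mlp.denormalize(np.array([yhat_scaled]), norm)[0]

    predicted = per_component.sum(axis=1)
    observed = series.values[h0 : h1 + 1]
    labels = tuple(add_months(series.start, t) for t in range(h0, h1 + 1))
    return ForecastReport(
        predicted=predicted,
        observed=observed,
        per_component_predicted=per_component,
        metrics=evaluate(predicted, observed),
        horizon_labels=labels,
    )


def fit_predict(
    series: TimeSeries,
    last_train_month: Month,
    mode: Mode = "emd_pso_bpann",
    scheme: Scheme = "one_step_ahead",
    seed: int = 0,
    **fit_kwargs,
) -> tuple[HybridModel, ForecastReport]:
    """Convenience wrapper: fit on the training span, forecast the rest."""
    model = fit(series, last_train_month, mode, seed=seed, **fit_kwargs)
    horizon_start = add_months(last_train_month, 1)
    return model, predict(model, series, horizon_start, series.end, scheme)


def compare_methods(
    series: TimeSeries,
    last_train_month: Month,
    methods: Sequence[Mode] = ("emd_pso_bpann", "pso_bpann", "bpann"),
    seeds: Sequence[int] = (0,),
    scheme: Scheme = "one_step_ahead",
    **fit_kwargs,
) -> pd.DataFrame:
    """Run fit + predict for every (method, seed) pair on the same split.

    Returns a tidy frame with one row per run and columns
    method, seed, R, RMSE, MAPE, SSE, n.
    """
    if not methods:
        raise InvalidInputError("need at least one method")
    rows = []
    for method in methods:
        for seed in seeds:
            _, report = fit_predict(
                series, last_train_month, method, scheme=scheme, seed=seed, **fit_kwargs
            )
            m = report.metrics
            rows.append(
                {
                    "method": method,
                    "seed": seed,
                    "R": m.R,
                    "RMSE": m.RMSE,
                    "MAPE": m.MAPE,
                    "SSE": m.SSE,
                    "n": m.n,
                }
            )
    return pd.DataFrame(rows)
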