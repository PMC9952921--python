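"""Rank selection and six-weight grid search by reconstruction quality.

The protocol first scans the rank k over a small range (default 1..5) and
fixes the best k, then grid-searches the six penalty weights over a shared
value set (default [0.001, 0.01, 0.1, 1], giving 4^6 = 4096 combinations).
Every grid cell is fitted from the same seeded initialization so that only
the weights differ between cells.

Grid enumeration order is the odometer order of
``itertools.product(value_set, repeat=6)`` over
(lambda_v, lambda_u, gamma_feat, gamma_sample, beta_u, beta_v), i.e. the
first weight varies slowest and the last varies fastest. The order is
deterministic and stable across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .factorization import (
    FactorModel,
    Hyperparameters,
    fit_dlonmf,
    reconstruction_pcc,
    relative_error,
)
from .graphs import ConnectivityGraph
from .io import ExpressionMatrix

DEFAULT_K_VALUES: tuple[int, ...] = (1, 2, 3, 4, 5)
DEFAULT_VALUE_SET: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)

WEIGHT_NAMES: tuple[str, ...] = (
    "lambda_v",
    "lambda_u",
    "gamma_feat",
    "gamma_sample",
    "beta_u",
    "beta_v",
)


@dataclass
class GridSearchResult:
    """Outcome of a weight grid search.

    ``entries`` is an ordered list of (hyperparameters, reconstruction_pcc,
    relative_error) tuples in enumeration order; ``best_index`` maximizes
    PCC with ties broken by lower relative error, then earlier index.
    """

    entries: list[tuple[Hyperparameters, float, float]]
    best_index: int
    grid_spec: tuple[float, ...]

    @property
    def best(self) -> tuple[Hyperparameters, float, float]:
        return self.entries[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for hp, pcc, err in self.entries:
            row = {name: getattr(hp, name) for name in WEIGHT_NAMES}
            row["reconstruction_pcc"] = pcc
            row["relative_error"] = err
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_weight_grid(
    value_set: Sequence[float] = DEFAULT_VALUE_SET,
) -> list[tuple[float, ...]]:
    """All |value_set|^6 weight combinations in deterministic odometer order.

    The tuple order is (lambda_v, lambda_u, gamma_feat, gamma_sample,
    beta_u, beta_v); the first component varies slowest.
    """
    if not value_set:
        raise ParameterError("value_set must be non-empty")
    return list(itertools.product([float(v) for v in value_set], repeat=6))


def select_rank(
    X: ExpressionMatrix | np.ndarray,
    feature_graph: ConnectivityGraph | None,
    sample_graph: ConnectivityGraph | None,
    hp_base: Hyperparameters,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    seed: int | None = None,
    rule: Literal["max-pcc", "parsimony"] = "parsimony",
) -> tuple[int, list[tuple[int, float]]]:
    """Fit one model per candidate rank and pick the best by reconstruction PCC.

    ``rule='max-pcc'`` takes the argmax (ties -> smaller k). On noiseless or
    near-noiseless data the PCC is flat above the true rank, so the default
    ``rule='parsimony'`` returns the smallest k whose PCC reaches 99.5% of
    the maximum.
    """
    if not k_values:
        raise ParameterError("k_values must be non-empty")
    per_k: list[tuple[int, float]] = []
    for k in k_values:
        hp = replace(hp_base, k=int(k), seed=hp_base.seed if seed is None else seed)
        model = fit_dlonmf(X, feature_graph, sample_graph, hp)
        per_k.append((int(k), reconstruction_pcc(X, model.U, model.V)))
    pccs = np.array([p for _, p in per_k])
    if rule == "max-pcc":
        best_k = per_k[int(np.argmax(pccs))][0]
    elif rule == "parsimony":
        threshold = 0.995 * pccs.max()
        best_k = next(k for k, p in per_k if p >= threshold)
    else:
        raise ParameterError(f"unknown rank rule {rule!r}")
    return best_k, per_k


def grid_search(
    X: ExpressionMatrix | np.ndarray,
    feature_graph: ConnectivityGraph | None,
    sample_graph: ConnectivityGraph | None,
    k: int,
    value_set: Sequence[float] = DEFAULT_VALUE_SET,
    seed: int = 0,
    budget: int | Literal["all"] = "all",
    n_iter: int = 100,
) -> GridSearchResult:
    """Fit the model at every weight combination (or a seeded subsample).

    The rank k is fixed beforehand (rank selection happens first). With an
    integer ``budget`` a uniform sample of that many cells is drawn without
    replacement, seeded, and evaluated in enumeration order. Every cell uses
    the same seed so differences isolate the weights.
    """
    combos = enumerate_weight_grid(value_set)
    indices = np.arange(len(combos))
    if budget != "all":
        budget = int(budget)
        if budget <= 0:
            raise ParameterError(f"budget must be positive, got {budget}")
        if budget < len(combos):
            rng = np.random.default_rng(seed)
            indices = np.sort(rng.choice(len(combos), size=budget, replace=False))

    entries: list[tuple[Hyperparameters, float, float]] = []
    for idx in indices:
        weights = dict(zip(WEIGHT_NAMES, combos[idx]))
        hp = Hyperparameters(k=int(k), n_iter=n_iter, seed=seed, **weights)
        model = fit_dlonmf(X, feature_graph, sample_graph, hp)
        entries.append(
            (
                hp,
                reconstruction_pcc(X, model.U, model.V),
                relative_error(X, model.U, model.V),
            )
        )
    best_index = _best_entry_index(entries)
    return GridSearchResult(
        entries=entries, best_index=best_index, grid_spec=tuple(float(v) for v in value_set)
    )


def _best_entry_index(entries: list[tuple[Hyperparameters, float, float]]) -> int:
    if not entries:
        raise ParameterError("no grid entries to rank")
    best = 0
    for i, (_, pcc, err) in enumerate(entries[1:], start=1):
        _, best_pcc, best_err = entries[best]
        if pcc > best_pcc or (pcc == best_pcc and err < best_err):
            best = i
    return best
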