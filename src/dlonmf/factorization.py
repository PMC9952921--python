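"""The DL-ONMF core: objective, gradients, multiplicative updates, training.

The model factorizes a non-negative genes x samples matrix X (m x n) as
X ~ U V with U (m x k) the non-negative basis (gene loadings) and V (k x n)
the non-negative coefficients (sample embeddings), minimizing

    ||X - UV||_F^2
      + lambda_v ||V||_F^2 + lambda_u ||U||_F^2          (ridge growth control)
      + gamma_feat Tr(U^T L_u U) + gamma_sample Tr(V L_v V^T)   (graph smoothness)
      + beta_u ||U^T U - I_k||_F^2 + beta_v ||V V^T - I_k||_F^2 (orthogonality)

subject to U, V >= 0, where L_u = D_u - S_u is the m x m gene-graph Laplacian
and L_v = D_v - S_v the n x n sample-graph Laplacian. The orthogonality
penalties discourage redundant factors; the graph terms pull connected
genes/samples toward similar representations.

Optimization uses KKT-derived multiplicative updates. Splitting each gradient
into its non-negative positive and negative parts (L = D - S gives the split
for the graph terms) yields

    U <- U * (X V^T + gamma_feat S_u U + 2 beta_u U)
           / (U V V^T + lambda_u U + gamma_feat D_u U + 2 beta_u U U^T U + eps)
    V <- V * (U^T X + gamma_sample V S_v + 2 beta_v V)
           / (U^T U V + lambda_v V + gamma_sample V D_v + 2 beta_v V V^T V + eps)

U is updated first, then V against the fresh U. With every weight at zero
both rules reduce exactly to the classical Lee-Seung multiplicative NMF
updates. Non-negativity is preserved by construction: numerator and
denominator are sums of products of non-negative quantities (plus eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from .errors import (
    NonNegativityError,
    NumericalError,
    ParameterError,
    ShapeError,
    UndefinedMetricError,
)
from .graphs import ConnectivityGraph
from .io import ExpressionMatrix


@dataclass(frozen=True)
class Hyperparameters:
    """Rank, penalty weights and run controls for a DL-ONMF fit.

    The six weights follow the objective above: ``lambda_u``/``lambda_v``
    ridge-penalize ||U||_F^2 / ||V||_F^2, ``gamma_feat``/``gamma_sample``
    weight the gene- and sample-graph Laplacian terms, and
    ``beta_u``/``beta_v`` weight the column-orthogonality penalties.
    ``tol=0`` disables early stopping so exactly ``n_iter`` updates run.
    """

    k: int
    lambda_v: float = 0.0
    lambda_u: float = 0.0
    gamma_feat: float = 0.0
    gamma_sample: float = 0.0
    beta_u: float = 0.0
    beta_v: float = 0.0
    n_iter: int = 100
    tol: float = 0.0
    seed: int = 0
    eps: float = 1e-10
    normalize: str = "none"  # {"none", "u-columns"}

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"rank k must be >= 1, got {self.k}")
        for name in ("lambda_v", "lambda_u", "gamma_feat", "gamma_sample", "beta_u", "beta_v"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_iter < 0:
            raise ParameterError(f"n_iter must be >= 0, got {self.n_iter}")
        if self.tol < 0:
            raise ParameterError(f"tol must be >= 0, got {self.tol}")
        if self.eps <= 0:
            raise ParameterError(f"eps must be > 0, got {self.eps}")
        if self.normalize not in ("none", "u-columns"):
            raise ParameterError(f"unknown normalize mode {self.normalize!r}")

    def with_weights_zero(self) -> "Hyperparameters":
        return replace(
            self,
            lambda_v=0.0,
            lambda_u=0.0,
            gamma_feat=0.0,
            gamma_sample=0.0,
            beta_u=0.0,
            beta_v=0.0,
        )


def default_hyperparameters(k: int = 5, seed: int = 0, n_iter: int = 100) -> Hyperparameters:
    """The shipped default weight combination for the chosen rank.

    The ridge weight on ||V||_F^2 is 0.001 and on ||U||_F^2 is 1, with all
    graph and orthogonality weights at 0.001 — the best cell of the default
    [0.001, 0.01, 0.1, 1] grid under this method's reference protocol.
    """
    return Hyperparameters(
        k=k,
        lambda_v=0.001,
        lambda_u=1.0,
        gamma_feat=0.001,
        gamma_sample=0.001,
        beta_u=0.001,
        beta_v=0.001,
        n_iter=n_iter,
        seed=seed,
    )


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Per-term values of the DL-ONMF objective at one iterate."""

    fit: float
    ridge_v: float
    ridge_u: float
    graph_feat: float
    graph_sample: float
    orth_u: float
    orth_v: float

    @property
    def total(self) -> float:
        return (
            self.fit
            + self.ridge_v
            + self.ridge_u
            + self.graph_feat
            + self.graph_sample
            + self.orth_u
            + self.orth_v
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "fit": self.fit,
            "ridge_v": self.ridge_v,
            "ridge_u": self.ridge_u,
            "graph_feat": self.graph_feat,
            "graph_sample": self.graph_sample,
            "orth_u": self.orth_u,
            "orth_v": self.orth_v,
            "total": self.total,
        }


@dataclass
class FactorModel:
    """A fitted factorization: basis U, coefficients V and the training trace.

    ``objective_history`` holds one :class:`ObjectiveBreakdown` per recorded
    state, starting with the initialization, so its length is
    ``converged_at + 1``. ``factors_history`` is populated only when the fit
    was run with ``record_factors=True``.
    """

    U: np.ndarray
    V: np.ndarray
    objective_history: list[ObjectiveBreakdown]
    hyperparameters: Hyperparameters
    converged_at: int
    gene_ids: list[str] | None = None
    sample_ids: list[str] | None = None
    factors_history: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def reconstruction(self) -> np.ndarray:
        return self.U @ self.V


def _as_array(X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def init_factors(
    m: int,
    n: int,
    k: int,
    seed: int,
    scale: float | str = "auto",
    x_mean: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Strictly positive uniform random factors, deterministic per seed.

    With ``scale='auto'`` the caller passes the data mean ``x_mean`` and the
    entries are scaled by ``sqrt(x_mean / k)`` so that the initial product
    U V has roughly the magnitude of X.
    """
    if k > min(m, n):
        raise ParameterError(f"rank k={k} exceeds min(m, n)={min(m, n)}")
    if scale == "auto":
        if x_mean is None:
            raise ParameterError("scale='auto' requires x_mean")
        factor = float(np.sqrt(max(x_mean, 0.0) / k))
        factor = factor if factor > 0 else 1.0
    else:
        factor = float(scale)
        if factor <= 0:
            raise ParameterError("scale must be positive")
    rng = np.random.default_rng(seed)
    U = factor * np.clip(rng.random((m, k)), np.finfo(float).tiny, None)
    V = factor * np.clip(rng.random((k, n)), np.finfo(float).tiny, None)
    return U, V


def _check_shapes(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    feature_graph: ConnectivityGraph | None,
    sample_graph: ConnectivityGraph | None,
) -> None:
    m, n = X.shape
    if U.shape[0] != m or V.shape[1] != n or U.shape[1] != V.shape[0]:
        raise ShapeError(
            f"incompatible shapes: X {X.shape}, U {U.shape}, V {V.shape}"
        )
    if feature_graph is not None and feature_graph.S.shape != (m, m):
        raise ShapeError(
            f"feature graph is {feature_graph.S.shape}, expected ({m}, {m})"
        )
    if sample_graph is not None and sample_graph.S.shape != (n, n):
        raise ShapeError(
            f"sample graph is {sample_graph.S.shape}, expected ({n}, {n})"
        )


def objective(
    X: ExpressionMatrix | np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    feature_graph: ConnectivityGraph | None,
    sample_graph: ConnectivityGraph | None,
    hp: Hyperparameters,
) -> ObjectiveBreakdown:
    """Evaluate every term of the objective at (U, V). Pure function."""
    Xa = _as_array(X)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    _check_shapes(Xa, U, V, feature_graph, sample_graph)
    if (hp.gamma_feat > 0 and feature_graph is None) or (
        hp.gamma_sample > 0 and sample_graph is None
    ):
        raise ParameterError("graph weight > 0 requires the corresponding graph")

    k = U.shape[1]
    I_k = np.eye(k)
    fit = float(np.linalg.norm(Xa - U @ V) ** 2)
    ridge_v = hp.lambda_v * float(np.linalg.norm(V) ** 2)
    ridge_u = hp.lambda_u * float(np.linalg.norm(U) ** 2)
    graph_feat = (
        hp.gamma_feat * float(np.trace(U.T @ feature_graph.L @ U))
        if hp.gamma_feat > 0
        else 0.0
    )
    graph_sample = (
        hp.gamma_sample * float(np.trace(V @ sample_graph.L @ V.T))
        if hp.gamma_sample > 0
        else 0.0
    )
    orth_u = hp.beta_u * float(np.linalg.norm(U.T @ U - I_k) ** 2)
    orth_v = hp.beta_v * float(np.linalg.norm(V @ V.T - I_k) ** 2)
    return ObjectiveBreakdown(
        fit=fit,
        ridge_v=ridge_v,
        ridge_u=ridge_u,
        graph_feat=graph_feat,
        graph_sample=graph_sample,
        orth_u=orth_u,
        orth_v=orth_v,
    )


def gradients(
    X: ExpressionMatrix | np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    feature_graph: ConnectivityGraph | None,
    sample_graph: ConnectivityGraph | None,
    hp: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (unconstrained) gradients of the objective w.r.t. U and V.

    dU = -2 X V^T + 2 U V V^T + 2 lambda_u U + 2 gamma_feat L_u U
         + 4 beta_u (U U^T U - U)
    dV = -2 U^T X + 2 U^T U V + 2 lambda_v V + 2 gamma_sample V L_v
         + 4 beta_v (V V^T V - V)

    The non-negativity multipliers are never materialized; they are
    eliminated in the KKT derivation of the multiplicative updates.
    """
    Xa = _as_array(X)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    _check_shapes(Xa, U, V, feature_graph, sample_graph)

    dU = -2.0 * Xa @ V.T + 2.0 * U @ (V @ V.T) + 2.0 * hp.lambda_u * U
    dV = -2.0 * U.T @ Xa + 2.0 * (U.T @ U) @ V + 2.0 * hp.lambda_v * V
    if hp.gamma_feat > 0:
        if feature_graph is None:
            raise ParameterError("gamma_feat > 0 requires a feature graph")
        dU += 2.0 * hp.gamma_feat * feature_graph.L @ U
    if hp.gamma_sample > 0:
        if sample_graph is None:
            raise ParameterError("gamma_sample > 0 requires a sample graph")
        dV += 2.0 * hp.gamma_sample * V @ sample_graph.L
    if hp.beta_u > 0:
        dU += 4.0 * hp.beta_u * (U @ (U.T @ U) - U)
    if hp.beta_v > 0:
        dV += 4.0 * hp.beta_v * (V @ (V.T @ V) - V)
    return dU, dV


def update_step(
    X: ExpressionMatrix | np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    feature_graph: ConnectivityGraph | None,
    sample_graph: ConnectivityGraph | None,
    hp: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    """One alternating multiplicative update: U first, then V with the new U.

    Zero entries stay zero (multiplicative invariant) and no entry can turn
    negative because numerator and denominator are non-negative.
    """
    Xa = _as_array(X)
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    _check_shapes(Xa, U, V, feature_graph, sample_graph)
    if (U < 0).any() or (V < 0).any():
        raise NonNegativityError("update_step requires non-negative U and V")

    eps = hp.eps

    numer_u = Xa @ V.T
    denom_u = U @ (V @ V.T) + hp.lambda_u * U
    if hp.gamma_feat > 0:
        numer_u = numer_u + hp.gamma_feat * feature_graph.S @ U
        denom_u = denom_u + hp.gamma_feat * feature_graph.degrees[:, None] * U
    if hp.beta_u > 0:
        numer_u = numer_u + 2.0 * hp.beta_u * U
        denom_u = denom_u + 2.0 * hp.beta_u * U @ (U.T @ U)
    U_new = U * numer_u / (denom_u + eps)

    numer_v = U_new.T @ Xa
    denom_v = (U_new.T @ U_new) @ V + hp.lambda_v * V
    if hp.gamma_sample > 0:
        numer_v = numer_v + hp.gamma_sample * V @ sample_graph.S
        denom_v = denom_v + hp.gamma_sample * V * sample_graph.degrees[None, :]
    if hp.beta_v > 0:
        numer_v = numer_v + 2.0 * hp.beta_v * V
        denom_v = denom_v + 2.0 * hp.beta_v * V @ (V.T @ V)
    V_new = V * numer_v / (denom_v + eps)

    if hp.normalize == "u-columns":
        norms = np.linalg.norm(U_new, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        U_new = U_new / safe[None, :]
        V_new = V_new * safe[:, None]
    return U_new, V_new


def fit_dlonmf(
    X: ExpressionMatrix | np.ndarray,
    feature_graph: ConnectivityGraph | None,
    sample_graph: ConnectivityGraph | None,
    hp: Hyperparameters,
    record_factors: bool = False,
) -> FactorModel:
    """Fit the DL-ONMF model by iterated multiplicative updates.

    Runs ``hp.n_iter`` updates from a seeded positive initialization,
    recording the objective breakdown at every state (initial state
    included). If ``hp.tol > 0``, stops early once the relative change of
    the total objective falls below ``tol``.
    """
    Xa = _as_array(X)
    if (Xa < 0).any():
        raise NonNegativityError("X must be non-negative; see enforce_nonnegativity")
    m, n = Xa.shape
    if hp.k > min(m, n):
        raise ParameterError(f"rank k={hp.k} exceeds min(m, n)={min(m, n)}")

    U, V = init_factors(m, n, hp.k, hp.seed, scale="auto", x_mean=float(Xa.mean()))
    history = [objective(Xa, U, V, feature_graph, sample_graph, hp)]
    factors: list[tuple[np.ndarray, np.ndarray]] = []
    if record_factors:
        factors.append((U.copy(), V.copy()))

    iterations = 0
    for it in range(hp.n_iter):
        U, V = update_step(Xa, U, V, feature_graph, sample_graph, hp)
        if not (np.isfinite(U).all() and np.isfinite(V).all()):
            raise NumericalError(f"non-finite factor entries at iteration {it + 1}")
        breakdown = objective(Xa, U, V, feature_graph, sample_graph, hp)
        history.append(breakdown)
        if record_factors:
            factors.append((U.copy(), V.copy()))
        iterations = it + 1
        if hp.tol > 0:
            prev = history[-2].total
            denom = max(abs(prev), np.finfo(float).tiny)
            if abs(prev - breakdown.total) / denom < hp.tol:
                break

    gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else None
    sample_ids = X.sample_ids if isinstance(X, ExpressionMatrix) else None
    return FactorModel(
        U=U,
        V=V,
        objective_history=history,
        hyperparameters=hp,
        converged_at=iterations,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        factors_history=factors,
    )


def fit_nmf(
    X: ExpressionMatrix | np.ndarray,
    k: int,
    n_iter: int = 100,
    seed: int = 0,
    record_factors: bool = False,
) -> FactorModel:
    """Plain Lee-Seung multiplicative NMF: the model with all weights zero."""
    hp = Hyperparameters(k=k, n_iter=n_iter, seed=seed)
    return fit_dlonmf(X, None, None, hp, record_factors=record_factors)


def reconstruction_pcc(
    X: ExpressionMatrix | np.ndarray, U: np.ndarray, V: np.ndarray
) -> float:
    """Pearson correlation between the entries of X and of UV (flattened).

    Measures reconstruction quality on a -1..1 scale; 1 means UV reproduces
    X up to an affine rescaling of its entries.
    """
    Xa = _as_array(X)
    R = np.asarray(U, dtype=float) @ np.asarray(V, dtype=float)
    if Xa.shape != R.shape:
        raise ShapeError(f"X is {Xa.shape} but UV is {R.shape}")
    x = Xa.ravel()
    r = R.ravel()
    if np.ptp(x) == 0 or np.ptp(r) == 0:
        raise UndefinedMetricError("correlation undefined for a constant matrix")
    return float(pearsonr(x, r).statistic)


def relative_error(
    X: ExpressionMatrix | np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    normalized: bool = False,
) -> float:
    """Squared Frobenius reconstruction error ||X - UV||_F^2.

    Despite the conventional name, the default is the *absolute* squared
    error, matching how the quantity is defined for this method.
    ``normalized=True`` divides by ||X||_F^2 (an extra convenience, clearly
    not the published definition).
    """
    Xa = _as_array(X)
    R = np.asarray(U, dtype=float) @ np.asarray(V, dtype=float)
    if Xa.shape != R.shape:
        raise ShapeError(f"X is {Xa.shape} but UV is {R.shape}")
    err = float(np.linalg.norm(Xa - R) ** 2)
    if normalized:
        denom = float(np.linalg.norm(Xa) ** 2)
        if denom == 0:
            raise UndefinedMetricError("cannot normalize by ||X||^2 = 0")
        return err / denom
    return err


def save_model(model: FactorModel, outdir: str | Path) -> None:
    """Persist U, V, the objective history and hyperparameters as TSV/YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = model.U.shape[1]
    factor_names = [f"factor_{i + 1}" for i in range(k)]
    gene_ids = model.gene_ids or [f"gene_{i + 1}" for i in range(model.U.shape[0])]
    sample_ids = model.sample_ids or [
        f"sample_{j + 1}" for j in range(model.V.shape[1])
    ]
    pd.DataFrame(model.U, index=gene_ids, columns=factor_names).to_csv(
        outdir / "U.tsv", sep="\t"
    )
    pd.DataFrame(model.V, index=factor_names, columns=sample_ids).to_csv(
        outdir / "V.tsv", sep="\t"
    )
    history = pd.DataFrame([b.as_dict() for b in model.objective_history])
    history.insert(0, "iteration", range(len(model.objective_history)))
    hp_dict = {
        name: getattr(model.hyperparameters, name)
        for name in (
            "k",
            "lambda_v",
            "lambda_u",
            "gamma_feat",
            "gamma_sample",
            "beta_u",
            "beta_v",
            "n_iter",
            "tol",
            "seed",
            "eps",
            "normalize",
        )
    }
    with open(outdir / "history.tsv", "w") as fh:
        for name, value in hp_dict.items():
            fh.write(f"# {name}: {value}\n")
        history.to_csv(fh, sep="\t", index=False)
    with open(outdir / "hyperparameters.yaml", "w") as fh:
        yaml.safe_dump(hp_dict, fh, sort_keys=False)


def load_factor_matrix(path: str | Path) -> pd.DataFrame:
    """Read a persisted U or V TSV back as a labeled DataFrame."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def lee_seung_reference_step(
    X: np.ndarray, U: np.ndarray, V: np.ndarray, eps: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Classical plain-NMF multiplicative step (U first, then V).

    Provided for documentation and external cross-checks; the package's own
    tests use an independent re-implementation as the oracle.
    """
    U = U * (X @ V.T) / (U @ (V @ V.T) + eps)
    V = V * (U.T @ X) / ((U.T @ U) @ V + eps)
    return U, V
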