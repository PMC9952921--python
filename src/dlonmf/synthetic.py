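"""Synthetic expression matrices with planted factor and cluster structure.

The generator emulates the shape of a curated-gene-panel expression matrix
over a few hundred samples (tens of genes x hundreds of samples): a
non-negative low-rank signal U* V* with block structure — each factor loads
a disjoint gene module, each sample cluster is dominated by its own block of
factors — plus non-negative noise. It makes every other module testable
against known ground truth (true factors, true labels) without any
external download. It does not attempt to emulate platform or batch
effects, or any real gene-panel covariance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .io import ExpressionMatrix

NoiseModel = Literal["gaussian-clipped", "poisson"]


@dataclass(frozen=True)
class GenerationSpec:
    """Parameters a dataset was generated from (kept alongside the data)."""

    m: int
    n: int
    k_true: int
    c: int
    separation: float
    noise_sd: float
    noise_model: NoiseModel
    seed: int


@dataclass
class SyntheticDataset:
    """A generated matrix with its ground-truth factors and cluster labels."""

    X: ExpressionMatrix
    true_labels: np.ndarray
    true_U: np.ndarray
    true_V: np.ndarray
    spec: GenerationSpec


def generate_planted(
    m: int = 60,
    n: int = 120,
    k_true: int = 3,
    c: int = 3,
    separation: float = 6.0,
    noise_sd: float = 0.2,
    noise_model: NoiseModel = "gaussian-clipped",
    seed: int = 0,
    proportions: Sequence[float] | None = None,
) -> SyntheticDataset:
    """Generate a planted-structure dataset.

    Samples are assigned to the ``c`` clusters round-robin (or by
    ``proportions`` for imbalanced designs). The k_true factors are split
    into ``c`` contiguous blocks; a sample's coefficients are
    ``separation * U(0.5, 1.5)`` on its cluster's factor block and
    ``U(0, 1)`` elsewhere, so ``separation`` is the single knob for the
    in-block to off-block magnitude ratio (task difficulty). Gene loadings
    put each factor on a disjoint gene module (``U(0.5, 1.5)``) over a
    small uniform background. Noise: ``gaussian-clipped`` forms
    ``max(0, U* V* + N(0, noise_sd))`` (continuous, microarray-like);
    ``poisson`` draws ``Poisson(U* V*)`` for count-like data
    (``noise_sd`` ignored). Deterministic per seed.
    """
    if c > n:
        raise ParameterError(f"c={c} exceeds n={n}")
    if k_true > min(m, n):
        raise ParameterError(f"k_true={k_true} exceeds min(m, n)={min(m, n)}")
    if c > k_true:
        raise ParameterError(f"c={c} clusters need at least c factors, got k_true={k_true}")
    if separation < 0 or noise_sd < 0:
        raise ParameterError("separation and noise_sd must be >= 0")
    if noise_model not in ("gaussian-clipped", "poisson"):
        raise ParameterError(f"unknown noise model {noise_model!r}")

    rng = np.random.default_rng(seed)

    if proportions is None:
        labels = np.arange(n) % c
    else:
        if len(proportions) != c:
            raise ParameterError(f"{len(proportions)} proportions for {c} clusters")
        weights = np.asarray(proportions, dtype=float)
        if (weights <= 0).any():
            raise ParameterError("proportions must be positive")
        sizes = np.maximum(1, np.round(n * weights / weights.sum()).astype(int))
        while sizes.sum() > n:
            sizes[int(np.argmax(sizes))] -= 1
        while sizes.sum() < n:
            sizes[int(np.argmin(sizes))] += 1
        labels = np.repeat(np.arange(c), sizes)

    factor_blocks = np.array_split(np.arange(k_true), c)
    gene_blocks = np.array_split(np.arange(m), k_true)

    true_U = rng.uniform(0.0, 0.1, size=(m, k_true))
    for f, genes in enumerate(gene_blocks):
        true_U[genes, f] = rng.uniform(0.5, 1.5, size=genes.size)

    true_V = rng.uniform(0.0, 1.0, size=(k_true, n))
    for j in range(n):
        block = factor_blocks[labels[j]]
        true_V[block, j] = separation * rng.uniform(0.5, 1.5, size=block.size)

    signal = true_U @ true_V
    if noise_model == "gaussian-clipped":
        X_values = np.maximum(0.0, signal + rng.normal(0.0, noise_sd, size=signal.shape))
    else:
        X_values = rng.poisson(signal).astype(float)

    X = ExpressionMatrix(
        X_values,
        gene_ids=[f"gene_{i + 1:03d}" for i in range(m)],
        sample_ids=[f"sample_{j + 1:03d}" for j in range(n)],
    )
    spec = GenerationSpec(
        m=m,
        n=n,
        k_true=k_true,
        c=c,
        separation=float(separation),
        noise_sd=float(noise_sd),
        noise_model=noise_model,
        seed=int(seed),
    )
    return SyntheticDataset(
        X=X, true_labels=labels, true_U=true_U, true_V=true_V, spec=spec
    )


def default_cohort_preset(seed: int = 0) -> SyntheticDataset:
    """The 110-gene x 451-sample preset with two planted subtypes, rank 5.

    Mirrors the shape of a 110-gene pyroptosis panel over 205 + 246 = 451
    post-reperfusion samples, with rank 5 and two subtypes — the end-to-end
    demonstration configuration. Moderate separation (6) and low noise
    (sd 0.2) make the planted subtypes recoverable but non-trivial.
    """
    return generate_planted(
        m=110, n=451, k_true=5, c=2, separation=6.0, noise_sd=0.2, seed=seed
    )


def save_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write X.tsv, truth_labels.tsv, true_U.tsv, true_V.tsv and spec.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.X.to_frame().to_csv(outdir / "X.tsv", sep="\t")
    pd.DataFrame(
        {"sample_id": dataset.X.sample_ids, "cluster": dataset.true_labels}
    ).to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
    k = dataset.true_U.shape[1]
    factor_names = [f"factor_{i + 1}" for i in range(k)]
    pd.DataFrame(dataset.true_U, index=dataset.X.gene_ids, columns=factor_names).to_csv(
        outdir / "true_U.tsv", sep="\t"
    )
    pd.DataFrame(dataset.true_V, index=factor_names, columns=dataset.X.sample_ids).to_csv(
        outdir / "true_V.tsv", sep="\t"
    )
    with open(outdir / "spec.yaml", "w") as fh:
        yaml.safe_dump(asdict(dataset.spec), fh, sort_keys=False)
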