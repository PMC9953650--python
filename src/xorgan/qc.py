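"""Replicate-level quality control: sample correlation and PCA scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "PCAResult", "sample_correlation", "pca_scores"]


@dataclass
class CorrelationMatrix:
    samples: list[str]
    values: pd.DataFrame  # symmetric, unit diagonal, NaN where undefined

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")


def sample_correlation(
    m: ExpressionMatrix,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> CorrelationMatrix:
    """Pearson correlation between sample columns, on log(x + pseudocount)
    by default.  Constant columns yield NaN entries with a warning; the
    diagonal is forced to 1."""
    if m.values.shape[1] < 2:
        raise ValueError("need at least two samples for correlation")
    X = m.values.to_numpy(dtype=float)
    if log_transform:
        X = np.log(X + pseudocount)
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        logger.warning("constant sample column(s), correlation undefined: %s",
                       list(m.samples[constant]))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=m.samples, columns=m.samples)
    return CorrelationMatrix(samples=list(m.samples), values=df)


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples × components
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame      # genes × components (loadings)

    def write(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        self.scores.to_csv(prefix + "scores.tsv", sep="\t",
                           index_label="sample")
        pd.DataFrame(
            {"component": self.scores.columns,
             "variance_fraction": self.explained_variance_ratio}
        ).to_csv(prefix + "variance.tsv", sep="\t", index=False)


def pca_scores(
    m: ExpressionMatrix,
    n_components: int,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> PCAResult:
    """PCA via SVD of the gene-centered (optionally log-scaled) matrix.

    Component signs are fixed by forcing each component's largest-magnitude
    gene loading positive, so outputs are reproducible across platforms.
    """
    n_samples = m.values.shape[1]
    n_genes = m.values.shape[0]
    max_comp = min(n_samples - 1, n_genes) if n_samples > 1 else 0
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, {max_comp}] for "
            f"{n_samples} samples x {n_genes} genes")
    X = m.values.to_numpy(dtype=float)
    if log_transform:
        X = np.log(X + pseudocount)
    centered = X - X.mean(axis=1, keepdims=True)  # center each gene
    # samples are observations: work on the samples × genes orientation
    U, S, Vt = np.linalg.svd(centered.T, full_matrices=False)
    total_var = float((S ** 2).sum())
    k = n_components
    loadings = Vt[:k].T  # genes × k
    sign = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(k)])
    sign[sign == 0] = 1.0
    scores = (U[:, :k] * S[:k]) * sign
    evr = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.samples, columns=cols),
        explained_variance_ratio=evr,
        components=pd.DataFrame(loadings * sign, index=m.genes, columns=cols),
    )
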