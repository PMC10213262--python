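"""Frozen-reference normalization for population-independent inference.

The classifier is trained once; new cohorts must be brought onto the
training data's scale without ever re-estimating anything from the
training set. At fit time the panel-restricted training matrix is frozen
as (i) the pooled sorted vector of all its values and (ii) per-gene mean
and standard deviation. At mapping time a new dataset is quantile-mapped
onto the pooled reference — each value is replaced by the reference
quantile at its empirical CDF position — and then z-scaled per gene with
the frozen training statistics, yielding the model-ready feature matrix.

The quantile map uses the pooled empirical CDF of the new dataset (all
genes × samples) by default, which makes mapping the training data onto
its own reference exactly idempotent; a per-sample mode is available for
single-sample inference at the cost of panel-size quantization. Both are
monotone within every sample and invariant to strictly increasing
transformations of the new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GenePanel, logger


@dataclass
class ReferenceDistribution:
    """Frozen training distribution: pooled quantiles + per-gene z-stats."""

    quantiles: np.ndarray  # sorted pooled training values
    gene_means: pd.Series  # indexed by gene, training mean
    gene_sds: pd.Series  # indexed by gene, training SD (ddof=1), > 0
    gene_order: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.quantiles = np.asarray(self.quantiles, dtype=float)
        if np.any(np.diff(self.quantiles) < 0):
            raise ValueError("reference quantile vector must be nondecreasing")
        if (self.gene_sds <= 0).any():
            bad = list(self.gene_sds.index[self.gene_sds <= 0])
            raise ValueError(f"non-positive reference SD for genes: {bad}")

    def to_dict(self) -> dict:
        return {
            "quantiles": self.quantiles.tolist(),
            "gene_means": self.gene_means.to_dict(),
            "gene_sds": self.gene_sds.to_dict(),
            "gene_order": list(self.gene_order),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceDistribution":
        order = list(d["gene_order"])
        return cls(
            quantiles=np.asarray(d["quantiles"], dtype=float),
            gene_means=pd.Series(d["gene_means"]).reindex(order),
            gene_sds=pd.Series(d["gene_sds"]).reindex(order),
            gene_order=order,
            provenance=dict(d.get("provenance", {})),
        )


def fit_reference(
    train: ExpressionMatrix,
    panel: GenePanel,
    provenance: dict | None = None,
) -> ReferenceDistribution:
    """Freeze the training distribution on the panel genes.

    Every panel gene must be present; a zero-variance gene is rejected by
    name (it cannot be z-scaled and would carry no signal).
    """
    sub = train.restrict(panel.gene_ids)
    means = sub.values.mean(axis=1)
    sds = sub.values.std(axis=1, ddof=1)
    zero = list(sds.index[~(sds > 0)])
    if zero:
        raise ValueError(f"panel genes with zero variance in training data: {zero}")
    pooled = np.sort(sub.to_array(), axis=None)
    logger.info(
        "reference fitted: %d genes, %d pooled values", len(panel), pooled.size
    )
    return ReferenceDistribution(
        quantiles=pooled,
        gene_means=means,
        gene_sds=sds,
        gene_order=panel.gene_ids,
        provenance=provenance or {},
    )


def _reference_quantile(ref: ReferenceDistribution, p: np.ndarray) -> np.ndarray:
    """Linear interpolation of the pooled reference quantile function.

    The sorted pooled values sit at plotting positions (i + 0.5)/M;
    probabilities beyond the extremes clamp to the min/max value.
    """
    m = ref.quantiles.size
    pos = (np.arange(m) + 0.5) / m
    return np.interp(p, pos, ref.quantiles)


def map_to_reference(
    new: ExpressionMatrix,
    ref: ReferenceDistribution,
    mode: str = "dataset",
    z_scale: bool = True,
) -> ExpressionMatrix:
    """Map a new dataset onto the frozen reference; return model-ready features.

    mode="dataset" (default): CDF positions come from midranks over the
    pooled values of the whole new dataset — exactly idempotent on the
    training data itself. mode="sample": positions come from within-sample
    midranks only, usable for a single sample. After quantile mapping,
    values are z-scaled per gene with the frozen training mean/SD
    (disable with ``z_scale=False`` to inspect the quantile-mapped values
    on the reference's original scale); rows are returned in the
    reference gene order.
    """
    missing = [g for g in ref.gene_order if g not in new.values.index]
    if missing:
        raise KeyError(f"new dataset lacks reference panel genes: {missing}")
    if len(ref.gene_order) < 2:
        raise ValueError("reference mapping needs at least 2 panel genes")
    sub = new.restrict(ref.gene_order)
    x = sub.to_array()
    if mode == "dataset":
        p = (rankdata(x, method="average", axis=None).reshape(x.shape) - 0.5) / x.size
        mapped = _reference_quantile(ref, p)
    elif mode == "sample":
        mapped = np.empty_like(x)
        n_g = x.shape[0]
        for j in range(x.shape[1]):
            p = (rankdata(x[:, j], method="average") - 0.5) / n_g
            mapped[:, j] = _reference_quantile(ref, p)
    else:
        raise ValueError("mode must be 'dataset' or 'sample'")
    if z_scale:
        mapped = (
            mapped - ref.gene_means.to_numpy()[:, None]
        ) / ref.gene_sds.to_numpy()[:, None]
    return ExpressionMatrix(
        pd.DataFrame(mapped, index=ref.gene_order, columns=sub.sample_ids)
    )
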