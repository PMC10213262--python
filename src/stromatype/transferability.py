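"""Cross-dataset feature-transferability scoring and panel filtering.

A candidate gene is useful to a cross-platform classifier only if its
expression behaves consistently across datasets generated on different
platforms and tissues. The score used here is rank-based and therefore
invariant to any per-dataset monotone transformation: within each
dataset, each candidate gene receives the normalized rank (in [0, 1]) of
its median expression among the candidate genes; the transferability
score is one minus the mean absolute rank difference over all dataset
pairs. Genes that are absent from a dataset, or whose dispersion (median
absolute deviation) collapses below a floor in any dataset — constant or
censored probes — are flagged and scored 0. Panel filtering keeps genes
scoring at or above a threshold (default 0.7) with the floor flag unset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation, rankdata

from .io import ExpressionMatrix, GenePanel, AXES, logger

#: Default transferability threshold for dropping genes from the panel.
DEFAULT_THRESHOLD = 0.7

#: Default dispersion floor: a gene is degenerate in a dataset when its
#: MAD falls below this fraction of the median panel MAD there.
DEFAULT_FLOOR_FRAC = 0.1


@dataclass
class TransferabilityReport:
    """Per-gene transferability scores and keep/drop diagnostics.

    ``table`` is indexed by gene id with columns: score, floor_flag,
    keep, and one ``rank_<i>`` / ``mad_<i>`` column per dataset
    (NaN where the gene is absent).
    """

    table: pd.DataFrame
    threshold: float
    floor_frac: float
    n_datasets: int

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    def kept_genes(self) -> list[str]:
        return list(self.table.index[self.table["keep"]])


def _median_ranks(em: ExpressionMatrix, candidates: list[str]) -> pd.Series:
    """Normalized rank in [0,1] of median expression among candidates."""
    present = [g for g in candidates if g in em.values.index]
    med = em.values.loc[present].median(axis=1)
    n = len(present)
    if n == 1:
        ranks = pd.Series([0.5], index=present)
    else:
        ranks = pd.Series((rankdata(med.to_numpy()) - 1.0) / (n - 1.0), index=present)
    return ranks.reindex(candidates)


def transferability_scores(
    datasets: list[ExpressionMatrix],
    candidates: GenePanel,
    threshold: float = DEFAULT_THRESHOLD,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
) -> TransferabilityReport:
    """Score each candidate gene's expression consistency across datasets.

    Deterministic; symmetric in dataset order; invariant to per-dataset
    strictly increasing transformations of expression. Absent or
    floor-flagged genes score 0.
    """
    if len(datasets) < 2:
        raise ValueError("transferability needs at least 2 datasets")
    genes = candidates.gene_ids
    for i, em in enumerate(datasets):
        present = sum(g in em.values.index for g in genes)
        if present < 0.5 * len(genes):
            raise ValueError(
                f"dataset {i} contains only {present}/{len(genes)} candidate genes"
            )

    ranks = pd.DataFrame(
        {f"rank_{i}": _median_ranks(em, genes) for i, em in enumerate(datasets)}
    )
    mads = pd.DataFrame(index=pd.Index(genes), dtype=float)
    floor_flag = pd.Series(False, index=pd.Index(genes))
    for i, em in enumerate(datasets):
        present = [g for g in genes if g in em.values.index]
        mad = pd.Series(
            median_abs_deviation(em.values.loc[present].to_numpy(), axis=1),
            index=present,
        )
        floor = floor_frac * float(mad.median())
        mads[f"mad_{i}"] = mad.reindex(genes)
        flagged = mad.index[mad < floor]
        floor_flag.loc[flagged] = True
        # absent genes are degenerate by definition
        floor_flag.loc[[g for g in genes if g not in present]] = True

    pair_diffs = [
        (ranks[f"rank_{i}"] - ranks[f"rank_{j}"]).abs()
        for i, j in combinations(range(len(datasets)), 2)
    ]
    score = 1.0 - pd.concat(pair_diffs, axis=1).mean(axis=1)
    score = score.fillna(0.0)
    score[floor_flag] = 0.0

    table = pd.concat([score.rename("score"), floor_flag.rename("floor_flag")], axis=1)
    table["keep"] = (table["score"] >= threshold) & ~table["floor_flag"]
    table = pd.concat([table, ranks, mads], axis=1)
    report = TransferabilityReport(
        table=table,
        threshold=threshold,
        floor_frac=floor_frac,
        n_datasets=len(datasets),
    )
    logger.info(
        "transferability: %d/%d genes pass threshold %.2f across %d datasets",
        int(table["keep"].sum()),
        len(genes),
        threshold,
        len(datasets),
    )
    return report


def filter_panel(
    report: TransferabilityReport,
    candidates: GenePanel,
    threshold: float | None = None,
) -> GenePanel:
    """Keep panel genes scoring ≥ threshold with the floor flag unset.

    Preserves axis and weighted annotations; errors if the result is
    empty or an entire biological axis is eliminated.
    """
    thr = report.threshold if threshold is None else threshold
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    keep = set(
        report.table.index[
            (report.table["score"] >= thr) & ~report.table["floor_flag"]
        ]
    )
    filtered = candidates.subset(keep)
    if len(filtered.entries) == 0:
        raise ValueError(f"no genes pass transferability threshold {thr}")
    for axis in AXES:
        if candidates.axis_genes(axis) and not filtered.axis_genes(axis):
            raise ValueError(
                f"transferability filter at threshold {thr} eliminated the "
                f"entire {axis} axis"
            )
    logger.info("panel filtered: %d → %d genes", len(candidates), len(filtered))
    return filtered
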