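"""Population-dependent z-score labeling: axis scores and quadrant subtypes.

Training labels come from the preliminary, population-dependent model:
each weighted panel gene is z-scored across the samples of the cohort,
each sample's immune and angiogenesis axis scores are the means of the
z-scores of that axis's weighted genes, and the sample's subtype is the
quadrant of its (immune, angio) score pair — A angio-high/immune-low,
IA immune-high/angio-low, IS both high, ID both low. "High" is strictly
above the threshold (default 0 on both axes), so exact-boundary samples
fall to "low"; ties are measure-zero on continuous data.

Because z-scores are population statistics, labels depend on the cohort
composition — the very property the trained classifier with its frozen
reference distribution is designed to remove at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel, AXES, logger


@dataclass
class AxisScores:
    """Per-sample immune and angiogenesis scores in z-units."""

    table: pd.DataFrame  # index sample_id; columns immune_score, angio_score

    @property
    def immune(self) -> pd.Series:
        return self.table["immune_score"]

    @property
    def angio(self) -> pd.Series:
        return self.table["angio_score"]


@dataclass
class SubtypeLabels:
    """Per-sample subtype assignment in {A, IA, ID, IS}."""

    labels: pd.Series  # index sample_id

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(["A", "IA", "ID", "IS"], fill_value=0)


def axis_scores(expr: ExpressionMatrix, panel: GenePanel) -> AxisScores:
    """Mean per-gene z-score (ddof=1) over each axis's weighted genes.

    Unweighted panel genes are classifier features but do not contribute
    to axis scoring. Zero-variance genes are excluded with a warning; an
    axis left without usable genes is an error.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    scores = {}
    for axis, col in (("immune", "immune_score"), ("angiogenesis", "angio_score")):
        genes = panel.axis_genes(axis, weighted_only=True)
        missing = [g for g in genes if g not in expr.values.index]
        if missing:
            raise KeyError(f"{axis} genes absent from expression matrix: {missing}")
        vals = expr.values.loc[genes]
        sds = vals.std(axis=1, ddof=1)
        degenerate = list(sds.index[~(sds > 0)])
        if degenerate:
            logger.warning(
                "excluding %d zero-variance %s gene(s): %s",
                len(degenerate),
                axis,
                degenerate,
            )
            vals = vals.drop(index=degenerate)
            sds = sds.drop(index=degenerate)
        if vals.shape[0] == 0:
            raise ValueError(f"no usable (non-constant) weighted genes on {axis} axis")
        z = vals.sub(vals.mean(axis=1), axis=0).div(sds, axis=0)
        scores[col] = z.mean(axis=0)
    return AxisScores(pd.DataFrame(scores, index=pd.Index(expr.sample_ids)))


def quadrant_label(
    scores: AxisScores, thresholds: tuple[float, float] = (0.0, 0.0)
) -> SubtypeLabels:
    """Map (immune, angio) score pairs to quadrant subtypes.

    ``thresholds`` is the (immune, angio) cutoff pair; a score counts as
    high only when strictly above its cutoff.
    """
    t_imm, t_ang = thresholds
    imm_hi = scores.immune > t_imm
    ang_hi = scores.angio > t_ang
    labels = pd.Series(
        np.select(
            [imm_hi & ang_hi, imm_hi & ~ang_hi, ~imm_hi & ang_hi],
            ["IS", "IA", "A"],
            default="ID",
        ),
        index=scores.table.index,
    )
    return SubtypeLabels(labels)


def label_cohort(
    expr: ExpressionMatrix,
    panel: GenePanel,
    thresholds: tuple[float, float] = (0.0, 0.0),
) -> tuple[AxisScores, SubtypeLabels]:
    """Convenience: axis scores then quadrant labels in one call."""
    scores = axis_scores(expr, panel)
    return scores, quadrant_label(scores, thresholds)
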