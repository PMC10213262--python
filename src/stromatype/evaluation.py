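"""Predictive-performance evaluation of binary biomarkers against RECIST.

Any binary biomarker — a TME-derived B+/B− call or a comparator such as
PD-L1 CPS ≥ 1 or MSI-H — is scored against RECIST best objective
response (responders = CR + PR). B+ is treated as "predicted responder".
Metrics are the standard confusion-derived set (accuracy, F1,
sensitivity/recall, specificity, PPV/precision, NPV), the Mann–Whitney
rank-statistic AUROC for continuous scores, and per-arm overall response
rates with their fold enrichment ORR(B+)/ORR(B−). NE/unevaluable
responses are excluded from every metric with an audit count.

The no-biomarker reference is a prior-probability null classifier that
predicts "responder" with probability equal to the cohort prevalence p;
its expected metrics have closed forms (sensitivity = PPV = F1 = p,
specificity = NPV = 1 − p, accuracy = p² + (1 − p)²), and a Monte-Carlo
mode verifies them by simulation.

All rates are stored as exact fractions of integer counts; presentation
rounding (half-up, 2 decimals; 1 decimal for fold enrichment) is applied
only when formatting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CohortClinical, logger
from .biomarker import BiomarkerCalls


def round_half_up(x: float, decimals: int = 2) -> float:
    """Presentation rounding: half-up at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{x:.10f}").quantize(q, rounding=ROUND_HALF_UP))


def _positive_mask(biomarker) -> pd.Series:
    """Boolean B+ mask from BiomarkerCalls or a boolean Series."""
    if isinstance(biomarker, BiomarkerCalls):
        return biomarker.positive_mask
    s = pd.Series(biomarker)
    return s.astype(bool)


@dataclass
class MetricsReport:
    """Confusion counts and derived rates for one binary biomarker."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0
    auroc_value: float | None = None
    rounding_policy: str = "half-up, 2 decimals (1 for fold enrichment)"

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_evaluated

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def f1(self) -> float:
        return 2 * self.tp / (2 * self.tp + self.fp + self.fn)

    @property
    def orr_overall(self) -> float:
        """Cohort-wide response rate among evaluated samples."""
        return (self.tp + self.fn) / self.n_evaluated

    @property
    def orr_positive(self) -> float:
        """Response rate in the B+ arm (B+ predicts response)."""
        return self.tp / (self.tp + self.fp)

    @property
    def orr_negative(self) -> float:
        return self.fn / (self.fn + self.tn)

    @property
    def fold_enrichment(self) -> float | None:
        if self.orr_negative == 0:
            return None
        return self.orr_positive / self.orr_negative

    def to_dict(self, rounded: bool = False) -> dict:
        r2 = (lambda v: round_half_up(v, 2)) if rounded else (lambda v: v)
        fold = self.fold_enrichment
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "n_evaluated": self.n_evaluated,
            "n_excluded": self.n_excluded,
            "accuracy": r2(self.accuracy),
            "f1": r2(self.f1),
            "sensitivity": r2(self.sensitivity),
            "specificity": r2(self.specificity),
            "ppv": r2(self.ppv),
            "npv": r2(self.npv),
            "auroc": r2(self.auroc_value) if self.auroc_value is not None else None,
            "orr_positive": r2(self.orr_positive),
            "orr_negative": r2(self.orr_negative),
            "fold_enrichment": (
                (round_half_up(fold, 1) if rounded else fold)
                if fold is not None
                else None
            ),
            "rounding_policy": self.rounding_policy,
        }


def _align(biomarker, clinical: CohortClinical) -> tuple[pd.Series, pd.Series, int]:
    """Align B+ mask with evaluable responder flags; count NE exclusions."""
    pos = _positive_mask(biomarker)
    common = [s for s in clinical.sample_ids if s in pos.index]
    if not common:
        raise ValueError("biomarker calls and clinical table share no samples")
    resp = clinical.table.loc[common, "responder"]
    evaluable = resp.notna()
    n_excluded = int((~evaluable).sum())
    resp = resp[evaluable].astype(bool)
    pos = pos.loc[resp.index]
    if len(resp) == 0:
        raise ValueError("no evaluable samples (all responses NE)")
    return pos, resp, n_excluded


def confusion_metrics(biomarker, clinical: CohortClinical) -> MetricsReport:
    """Standard confusion-derived metrics, B+ as predicted responder."""
    pos, resp, n_excluded = _align(biomarker, clinical)
    if resp.all() or (~resp).all():
        raise ValueError("need at least one responder and one non-responder")
    report = MetricsReport(
        tp=int((pos & resp).sum()),
        fp=int((pos & ~resp).sum()),
        fn=int((~pos & resp).sum()),
        tn=int((~pos & ~resp).sum()),
        n_excluded=n_excluded,
    )
    logger.info(
        "confusion metrics on %d samples (%d NE excluded): ACC %.3f",
        report.n_evaluated,
        n_excluded,
        report.accuracy,
    )
    return report


def auroc(scores: pd.Series, clinical: CohortClinical) -> float:
    """AUROC via the Mann–Whitney rank statistic with midrank ties.

    Equals the probability that a random responder outscores a random
    non-responder, ties counted half. All-tied scores yield 0.5 with a
    warning.
    """
    s = pd.Series(scores)
    pos_dummy = pd.Series(True, index=s.index)  # reuse alignment machinery
    _, resp, _ = _align(pos_dummy, clinical)
    s = s.loc[resp.index].astype(float)
    n_pos = int(resp.sum())
    n_neg = int((~resp).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one responder and one non-responder")
    if s.nunique() == 1:
        warnings.warn("all scores identical; AUROC is 0.5 by convention")
        return 0.5
    ranks = rankdata(s.to_numpy())
    r_pos = ranks[resp.to_numpy()].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def orr_enrichment(
    biomarker, clinical: CohortClinical
) -> tuple[float, float, float | None]:
    """(ORR in B+, ORR in B−, fold enrichment); fold is None when the
    B− arm has zero responders."""
    pos, resp, _ = _align(biomarker, clinical)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one B+ and one B− evaluable sample")
    orr_p = float(resp[pos].mean())
    orr_n = float(resp[~pos].mean())
    fold = None if orr_n == 0 else orr_p / orr_n
    return orr_p, orr_n, fold


@dataclass
class BaselineReport:
    """Expected metrics of the prior-probability null classifier."""

    mode: str  # "analytic" or "monte_carlo"
    prevalence: float
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    reps: int | None = None
    seed: int | None = None

    def to_dict(self, rounded: bool = False) -> dict:
        r = (lambda v: round_half_up(v, 2)) if rounded else (lambda v: v)
        return {
            "mode": self.mode,
            "prevalence": self.prevalence,
            "accuracy": r(self.accuracy),
            "f1": r(self.f1),
            "sensitivity": r(self.sensitivity),
            "specificity": r(self.specificity),
            "ppv": r(self.ppv),
            "npv": r(self.npv),
            "reps": self.reps,
            "seed": self.seed,
        }


def baseline_null(
    clinical: CohortClinical,
    mode: str = "analytic",
    reps: int = 100_000,
    seed: int = 0,
) -> BaselineReport:
    """Null-model metrics: predictions sampled with P(responder) = prevalence.

    analytic mode returns the closed forms; monte_carlo simulates ``reps``
    random prediction vectors over the cohort's actual responder labels
    and averages the metrics (undefined metrics in a replicate — e.g. PPV
    with no predicted positives — are skipped).
    """
    resp = clinical.evaluable()["responder"].astype(bool).to_numpy()
    n = resp.size
    if n == 0:
        raise ValueError("no evaluable samples")
    p = float(resp.mean())
    if p in (0.0, 1.0):
        raise ValueError(f"prevalence must be in (0, 1), got {p}")
    if mode == "analytic":
        return BaselineReport(
            mode=mode,
            prevalence=p,
            accuracy=p**2 + (1 - p) ** 2,
            f1=p,
            sensitivity=p,
            specificity=1 - p,
            ppv=p,
            npv=1 - p,
        )
    if mode != "monte_carlo":
        raise ValueError("mode must be 'analytic' or 'monte_carlo'")
    rng = np.random.default_rng(seed)
    pred = rng.random((reps, n)) < p
    tp = (pred & resp).sum(axis=1).astype(float)
    fp = (pred & ~resp).sum(axis=1).astype(float)
    fn = (~pred & resp).sum(axis=1).astype(float)
    tn = (~pred & ~resp).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        metrics = {
            "accuracy": (tp + tn) / n,
            "f1": 2 * tp / (2 * tp + fp + fn),
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
            "ppv": tp / (tp + fp),
            "npv": tn / (tn + fn),
        }
    means = {k: float(np.nanmean(v)) for k, v in metrics.items()}
    return BaselineReport(mode=mode, prevalence=p, reps=reps, seed=seed, **means)


def subgroup_metrics(
    biomarker,
    clinical: CohortClinical,
    subgroup: pd.Series | tuple[str, object],
) -> MetricsReport:
    """Confusion metrics restricted to a clinical subgroup.

    ``subgroup`` is either a boolean mask over sample ids or a
    (column, value) pair such as ("msi", "MSS").
    """
    t = clinical.table
    if isinstance(subgroup, tuple):
        col, val = subgroup
        if col not in t.columns:
            raise KeyError(f"clinical table has no column {col!r}")
        mask = t[col] == val
    else:
        mask = subgroup.reindex(t.index).fillna(False).astype(bool)
    ids = list(t.index[mask])
    if not ids:
        raise ValueError("subgroup is empty")
    sub_clin = CohortClinical(t.loc[ids].drop(columns="responder"))
    pos = _positive_mask(biomarker)
    return confusion_metrics(pos.loc[[s for s in ids if s in pos.index]], sub_clin)
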