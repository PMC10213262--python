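"""Mechanism-of-action biomarker logic on top of subtype probabilities.

A therapy class defines which TME subtypes are expected to respond:
anti-angiogenic agents target the vasculature-rich subtypes (A + IS),
immune checkpoint inhibitors the immune-high subtypes (IA + IS), and
TLR9-agonist combinations the immune-suppressed subtype (IS). A sample
is biomarker-positive (B+) when its combined probability over the rule's
positive subtypes reaches the threshold (default 0.5; a sample exactly
at threshold is B+, matching a signed biomarker score of 0 being
designated positive). The signed biomarker score is 2·P(B+) − 1, so the
B+/B− partition is exactly the sign partition of the score. A
single-subtype high-confidence mode (e.g. IA at ≥ 0.90) is available for
precision-oriented rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import CohortClinical, SUBTYPES
from .model import SubtypeCalls

#: Standard mechanism-of-action rules.
STANDARD_RULES = {
    "anti-angio": ("A", "IS"),
    "immune": ("IA", "IS"),
    "tlr9-combo": ("IS",),
}


@dataclass(frozen=True)
class BiomarkerRule:
    name: str
    positive_subtypes: tuple[str, ...]
    combined_threshold: float = 0.5
    mode: str = "combined"  # or "single_high"
    single_high_subtype: str | None = None
    single_high_threshold: float = 0.90

    def __post_init__(self):
        unknown = sorted(set(self.positive_subtypes) - set(SUBTYPES))
        if unknown:
            raise ValueError(f"rule references unknown subtype(s): {unknown}")
        if not self.positive_subtypes or len(set(self.positive_subtypes)) >= len(
            SUBTYPES
        ):
            raise ValueError("positive subtypes must be a nonempty proper subset")
        if not 0.0 < self.combined_threshold < 1.0:
            raise ValueError("combined_threshold must be in (0, 1)")
        if self.mode not in ("combined", "single_high"):
            raise ValueError("mode must be 'combined' or 'single_high'")
        if self.mode == "single_high":
            if self.single_high_subtype not in SUBTYPES:
                raise ValueError(
                    f"unknown single_high subtype {self.single_high_subtype!r}"
                )
            if not 0.0 < self.single_high_threshold < 1.0:
                raise ValueError("single_high_threshold must be in (0, 1)")

    @classmethod
    def standard(cls, name: str) -> "BiomarkerRule":
        if name not in STANDARD_RULES:
            raise KeyError(
                f"unknown rule {name!r}; standard rules: {sorted(STANDARD_RULES)}"
            )
        return cls(name=name, positive_subtypes=STANDARD_RULES[name])


@dataclass
class BiomarkerCalls:
    """Per-sample B+/B− status with combined probability and signed score."""

    table: pd.DataFrame  # index sample_id; status, combined_probability, score
    rule: BiomarkerRule

    @property
    def status(self) -> pd.Series:
        return self.table["status"]

    @property
    def positive_mask(self) -> pd.Series:
        return self.table["status"] == "B+"

    @property
    def score(self) -> pd.Series:
        return self.table["score"]

    def __len__(self) -> int:
        return len(self.table)


def biomarker_call(calls: SubtypeCalls, rule: BiomarkerRule) -> BiomarkerCalls:
    """Apply a MOA rule to subtype probabilities.

    combined mode: B+ ⇔ Σ P(positive subtypes) ≥ combined_threshold.
    single_high mode: B+ ⇔ P(single_high_subtype) ≥ single_high_threshold.
    In both modes the combined probability and score 2·P − 1 are reported
    over the rule's positive subtypes.
    """
    combined = calls.probabilities[
        [f"P_{c}" for c in rule.positive_subtypes]
    ].sum(axis=1)
    if rule.mode == "combined":
        positive = combined >= rule.combined_threshold
    else:
        positive = (
            calls.probabilities[f"P_{rule.single_high_subtype}"]
            >= rule.single_high_threshold
        )
    table = pd.DataFrame(
        {
            "status": positive.map({True: "B+", False: "B-"}),
            "combined_probability": combined,
            "score": 2.0 * combined - 1.0,
        },
        index=calls.table.index,
    )
    return BiomarkerCalls(table=table, rule=rule)


def high_confidence_summary(
    calls: SubtypeCalls, threshold: float = 0.8
) -> tuple[float, pd.Series]:
    """Fraction of samples called with max probability ≥ threshold.

    Returns the overall fraction and the per-subtype breakdown (fraction
    of each called subtype's samples that are high confidence).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if len(calls) == 0:
        raise ValueError("no subtype calls given")
    high = calls.max_probability >= threshold
    frac = float(high.mean())
    per_subtype = (
        pd.DataFrame({"subtype": calls.subtype, "high": high})
        .groupby("subtype")["high"]
        .mean()
        .reindex(SUBTYPES, fill_value=0.0)
    )
    return frac, per_subtype


def subtype_transitions(
    pre: SubtypeCalls, post: SubtypeCalls, pairing: CohortClinical
) -> pd.DataFrame:
    """4×4 pre→post subtype transition counts over matched sample pairs.

    The clinical table supplies the pairing (pair_id + timepoint); every
    pair must have exactly one pre call and one post call. The returned
    table has pre subtypes as rows, post subtypes as columns, and sums to
    the number of pairs.
    """
    t = pairing.table
    if "pair_id" not in t.columns or "timepoint" not in t.columns:
        raise ValueError("clinical table lacks pair_id/timepoint columns")
    paired = t.dropna(subset=["pair_id"])
    counts = pd.DataFrame(0, index=list(SUBTYPES), columns=list(SUBTYPES))
    unmatched = []
    for pid, grp in paired.groupby("pair_id"):
        pre_ids = grp.index[grp["timepoint"] == "pre"]
        post_ids = grp.index[grp["timepoint"] == "post"]
        if len(pre_ids) != 1 or len(post_ids) != 1:
            unmatched.extend(grp.index.tolist())
            continue
        if pre_ids[0] not in pre.table.index or post_ids[0] not in post.table.index:
            unmatched.extend([pre_ids[0], post_ids[0]])
            continue
        counts.loc[
            pre.subtype[pre_ids[0]], post.subtype[post_ids[0]]
        ] += 1
    if unmatched:
        raise ValueError(f"unpaired or uncalled samples: {sorted(set(unmatched))}")
    return counts
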