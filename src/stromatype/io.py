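"""Shared data model, file readers/writers, configuration, and logging.

Expression matrices are stored genes × samples (the dominant convention for
delimited expression text files) on a log2 scale. Clinical tables carry
RECIST best objective response (BOR) plus optional comparator biomarkers
(PD-L1 CPS, MSI status) and pre/post pairing for matched-sample analyses.
Gene panels annotate each gene with its biological axis (immune or
angiogenesis) and whether it contributes to population-dependent axis
scoring (the ``weighted`` flag).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("stromatype")

#: Tokens treated as missing in expression files.
MISSING_TOKENS = ["", "NA", "N/A", "NaN", "nan", "null"]

#: The four TME subtypes in the fixed (alphabetical) class order used
#: everywhere, including argmax tie-breaks.
SUBTYPES = ("A", "IA", "ID", "IS")

#: Biological axes a panel gene may belong to.
AXES = ("immune", "angiogenesis")

#: Recognized RECIST best-objective-response tokens.
BOR_TOKENS = ("CR", "PR", "SD", "PD", "NE")

#: BOR values that count as response (RECIST 1.1 responders = CR + PR).
RESPONDER_BOR = ("CR", "PR")


def configure_logging(verbosity: int = 1) -> None:
    """Set up console logging. 0 = warnings, 1 = info, 2 = debug."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


@dataclass
class RunConfig:
    """Run-level options shared by all pipeline stages.

    The seed is threaded through every stochastic step and recorded in
    every output artifact for provenance.
    """

    seed: int = 0
    out_dir: str = "."
    verbosity: int = 1
    transpose: bool = False
    log2_transform: bool = False
    missing_gene_max_frac: float = 0.2


class ExpressionMatrix:
    """Genes × samples matrix of continuous (log2-scale) expression.

    Thin wrapper around a float DataFrame that enforces the invariants the
    pipeline relies on: unique gene and sample ids, at least one of each,
    and finite values (missing values must be resolved before
    construction).
    """

    def __init__(self, values: pd.DataFrame):
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 gene and 1 sample")
        dup_g = values.index[values.index.duplicated()].unique().tolist()
        if dup_g:
            raise ValueError(f"duplicate gene ids: {dup_g}")
        dup_s = values.columns[values.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        arr = values.astype(float)
        if not np.isfinite(arr.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        self.values = arr
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_array(self) -> np.ndarray:
        """Dense (genes × samples) float array."""
        return self.values.to_numpy()

    def restrict(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Subset to ``gene_ids`` in the given order; error on absences."""
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)])

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        g, s = self.shape
        return f"ExpressionMatrix({g} genes × {s} samples)"


@dataclass(frozen=True)
class PanelEntry:
    gene_id: str
    axis: str
    weighted: bool = True

    def __post_init__(self):
        if self.axis not in AXES:
            raise ValueError(
                f"unknown axis {self.axis!r} for gene {self.gene_id!r}; "
                f"expected one of {AXES}"
            )


@dataclass
class GenePanel:
    """The model feature set: genes annotated with axis and weighted flag."""

    entries: list[PanelEntry]

    def __post_init__(self):
        ids = [e.gene_id for e in self.entries]
        dup = sorted({g for g in ids if ids.count(g) > 1})
        if dup:
            raise ValueError(f"duplicate gene ids in panel: {dup}")
        if not self.entries:
            raise ValueError("gene panel is empty")

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def axis_genes(self, axis: str, weighted_only: bool = False) -> list[str]:
        if axis not in AXES:
            raise ValueError(f"unknown axis {axis!r}")
        return [
            e.gene_id
            for e in self.entries
            if e.axis == axis and (e.weighted or not weighted_only)
        ]

    def axis_of(self) -> dict[str, str]:
        return {e.gene_id: e.axis for e in self.entries}

    def subset(self, gene_ids: Iterable[str]) -> "GenePanel":
        keep = set(gene_ids)
        return GenePanel([e for e in self.entries if e.gene_id in keep])


@dataclass
class CohortClinical:
    """Per-sample clinical annotations keyed by sample id.

    ``table`` is indexed by sample_id with columns: bor, responder
    (nullable boolean; pd.NA when bor is NE), and optionally pdl1_cps,
    msi, pair_id, timepoint.
    """

    table: pd.DataFrame

    def __post_init__(self):
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dup}")
        if "bor" not in self.table.columns:
            raise ValueError("clinical table requires a 'bor' column")
        bad = set(self.table["bor"]) - set(BOR_TOKENS)
        if bad:
            raise ValueError(f"unrecognized BOR tokens: {sorted(bad)}")
        resp = self.table["bor"].map(
            lambda b: pd.NA if b == "NE" else b in RESPONDER_BOR
        )
        self.table = self.table.assign(responder=resp.astype("boolean"))
        if "pair_id" in self.table.columns:
            self._check_pairing()

    def _check_pairing(self) -> None:
        paired = self.table.dropna(subset=["pair_id"])
        if len(paired) and "timepoint" not in paired.columns:
            raise ValueError("pair_id given without a timepoint column")
        for pid, grp in paired.groupby("pair_id"):
            tps = sorted(grp["timepoint"].tolist())
            if tps != ["post", "pre"]:
                raise ValueError(
                    f"pair {pid!r} must link exactly one pre and one post "
                    f"sample, got timepoints {tps}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def evaluable(self) -> pd.DataFrame:
        """Rows with a determinate responder flag (BOR not NE)."""
        return self.table[self.table["responder"].notna()]

    def subset(self, sample_ids: Sequence[str]) -> "CohortClinical":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing}")
        return CohortClinical(self.table.loc[list(sample_ids)].drop(columns="responder"))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_expression_matrix(
    path: str | Path, options: RunConfig | None = None
) -> ExpressionMatrix:
    """Read a delimited genes × samples expression file.

    First column holds gene ids, header row holds sample ids. Honors the
    missing-value policy: genes with more than ``missing_gene_max_frac``
    missing values are dropped with a warning; remaining missing values
    are imputed with the gene's observed median. ``options.transpose``
    transposes on read (for samples × genes files); ``options.
    log2_transform`` applies log2(x + 1) for raw-scale inputs.
    """
    options = options or RunConfig()
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=MISSING_TOKENS,
        keep_default_na=False,
    )
    if options.transpose:
        df = df.T
    for dim, ids in (("gene", df.index), ("sample", df.columns)):
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate {dim} ids in {path.name}: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[g, s]!r} at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    frac_missing = numeric.isna().mean(axis=1)
    drop = frac_missing[frac_missing > options.missing_gene_max_frac]
    if len(drop):
        logger.warning(
            "dropping %d gene(s) with >%d%% missing values: %s",
            len(drop),
            int(options.missing_gene_max_frac * 100),
            list(drop.index),
        )
        numeric = numeric.drop(index=drop.index)
    if numeric.isna().to_numpy().any():
        medians = numeric.median(axis=1)
        numeric = numeric.apply(lambda row: row.fillna(medians[row.name]), axis=1)
    if options.log2_transform:
        numeric = np.log2(numeric + 1.0)
    em = ExpressionMatrix(numeric)
    logger.info("read %d genes × %d samples from %s", *em.shape, path.name)
    return em


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    em.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_clinical_table(path: str | Path) -> CohortClinical:
    """Read a per-sample clinical CSV (sample_id, bor, optional extras).

    Unrecognized BOR tokens are mapped to NE with a warning; NE samples
    carry an undefined responder flag and are excluded from metrics
    downstream.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"pair_id": "string"})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path.name} lacks required 'sample_id' column")
    if "bor" not in df.columns:
        raise ValueError(f"{path.name} lacks required 'bor' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    bor = df["bor"].astype(str).str.strip().str.upper()
    unknown = sorted(set(bor) - set(BOR_TOKENS))
    if unknown:
        logger.warning("unknown BOR token(s) %s mapped to NE", unknown)
        bor = bor.where(bor.isin(BOR_TOKENS), "NE")
    df["bor"] = bor
    if "msi" in df.columns:
        df["msi"] = df["msi"].fillna("unknown")
    return CohortClinical(df)


def write_clinical_table(clinical: CohortClinical, path: str | Path) -> None:
    clinical.table.to_csv(Path(path), index_label="sample_id")


def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a gene-panel configuration (JSON or YAML list of entries).

    Each entry: ``{gene_id, axis, weighted}`` with axis in
    {immune, angiogenesis}; ``weighted`` defaults to true.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)  # YAML is a JSON superset
    if isinstance(raw, dict) and "panel" in raw:
        raw = raw["panel"]
    if not isinstance(raw, list):
        raise ValueError(f"{path.name}: expected a list of panel entries")
    entries = [
        PanelEntry(
            gene_id=str(e["gene_id"]),
            axis=str(e["axis"]),
            weighted=bool(e.get("weighted", True)),
        )
        for e in raw
    ]
    panel = GenePanel(entries)
    n_imm = len(panel.axis_genes("immune"))
    n_ang = len(panel.axis_genes("angiogenesis"))
    logger.info(
        "panel %s: %d genes (%d immune, %d angiogenesis)",
        path.name,
        len(panel),
        n_imm,
        n_ang,
    )
    return panel


def write_gene_panel(panel: GenePanel, path: str | Path) -> None:
    path = Path(path)
    payload = [
        {"gene_id": e.gene_id, "axis": e.axis, "weighted": e.weighted}
        for e in panel.entries
    ]
    with open(path, "w") as fh:
        if path.suffix.lower() in {".yaml", ".yml"}:
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=1)
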