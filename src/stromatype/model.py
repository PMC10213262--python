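"""The TME subtype classifier: a shallow tanh/softmax neural network.

Architecture. An input layer of panel genes (reference-normalized
expression), a hidden layer of exactly two neurons, and a four-class
output layer. Each hidden neuron computes f(x) = tanh(w·x + b); the
output layer applies softmax to an affine map of the two hidden
activations, yielding probabilities over the subtypes (A, IA, ID, IS) in
fixed alphabetical order. The argmax subtype is reported with no minimum
probability threshold; ties break to the first class in order.

Training minimizes the multi-class cross-entropy (plus a small L2
penalty) with the L-BFGS solver, iterating until the loss has failed to
improve by at least ``tol`` for ``patience`` consecutive iterations, up
to ``max_iter`` iterations. Weights are initialized from a seeded normal
scaled by 1/sqrt(fan-in), so training is deterministic given the seed.

The two hidden activations are the model's latent space: with only two
neurons the network is forced to compress the panel onto two axes, which
in practice align with the immune and angiogenesis biology of the panel
— an emergent structure that ``neuron_axis_alignment`` quantifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.model_selection import RepeatedStratifiedKFold

from .io import ExpressionMatrix, GenePanel, SUBTYPES, AXES, logger
from .normalize import ReferenceDistribution

N_HIDDEN = 2
N_CLASSES = len(SUBTYPES)


@dataclass
class TrainConfig:
    """Training hyperparameters and the cross-validation layout."""

    tol: float = 1e-4
    patience: int = 10
    max_iter: int = 1000
    alpha: float = 1e-4  # L2 strength
    init_scale: float = 1.0
    seed: int = 0
    cv_repeats: int = 3
    cv_folds: int = 10
    alpha_grid: tuple[float, ...] = (1e-4, 1e-2, 1.0)

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be ≥ 2")


@dataclass
class TrainedModel:
    """Parameters and provenance of a trained subtype classifier."""

    hidden_weights: np.ndarray  # (n_genes, 2)
    hidden_biases: np.ndarray  # (2,)
    output_weights: np.ndarray  # (2, 4)
    output_biases: np.ndarray  # (4,)
    gene_order: list[str]
    class_order: tuple[str, ...] = SUBTYPES
    reference: ReferenceDistribution | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.output_biases = np.asarray(self.output_biases, dtype=float)
        g = len(self.gene_order)
        if self.hidden_weights.shape != (g, N_HIDDEN):
            raise ValueError("hidden_weights shape mismatch with gene_order")
        if self.output_weights.shape != (N_HIDDEN, N_CLASSES):
            raise ValueError("output_weights must be 2 × 4")
        if tuple(self.class_order) != SUBTYPES:
            raise ValueError(f"class_order must be {SUBTYPES}")
        for arr in (
            self.hidden_weights,
            self.hidden_biases,
            self.output_weights,
            self.output_biases,
        ):
            if not np.isfinite(arr).all():
                raise ValueError("model parameters must be finite")

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        doc = {
            "schema_version": 1,
            "gene_order": list(self.gene_order),
            "class_order": list(self.class_order),
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_biases": self.output_biases.tolist(),
            "reference": self.reference.to_dict() if self.reference else None,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != 1:
            raise ValueError(f"unsupported model schema: {doc.get('schema_version')}")
        ref = doc.get("reference")
        return cls(
            hidden_weights=np.asarray(doc["hidden_weights"]),
            hidden_biases=np.asarray(doc["hidden_biases"]),
            output_weights=np.asarray(doc["output_weights"]),
            output_biases=np.asarray(doc["output_biases"]),
            gene_order=list(doc["gene_order"]),
            class_order=tuple(doc["class_order"]),
            reference=ReferenceDistribution.from_dict(ref) if ref else None,
            metadata=doc.get("metadata", {}),
        )


@dataclass
class SubtypeCalls:
    """Per-sample classifier output: probabilities, latent, argmax subtype."""

    table: pd.DataFrame
    # index sample_id; columns P_A, P_IA, P_ID, P_IS, subtype, neuron1,
    # neuron2, max_probability

    @property
    def probabilities(self) -> pd.DataFrame:
        return self.table[[f"P_{c}" for c in SUBTYPES]]

    @property
    def subtype(self) -> pd.Series:
        return self.table["subtype"]

    @property
    def latent(self) -> pd.DataFrame:
        return self.table[["neuron1", "neuron2"]]

    @property
    def max_probability(self) -> pd.Series:
        return self.table["max_probability"]

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Forward pass and loss
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(
    x: np.ndarray, w1: np.ndarray, b1: np.ndarray, w2: np.ndarray, b2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and class probabilities for samples × genes x."""
    h = np.tanh(x @ w1 + b1)
    p = _softmax(h @ w2 + b2)
    return h, p


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta: np.ndarray, n_genes: int):
    i = n_genes * N_HIDDEN
    w1 = theta[:i].reshape(n_genes, N_HIDDEN)
    b1 = theta[i : i + N_HIDDEN]
    j = i + N_HIDDEN
    w2 = theta[j : j + N_HIDDEN * N_CLASSES].reshape(N_HIDDEN, N_CLASSES)
    b2 = theta[j + N_HIDDEN * N_CLASSES :]
    return w1, b1, w2, b2


def _loss_grad(
    theta: np.ndarray, x: np.ndarray, y: np.ndarray, alpha: float
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy + (alpha/2n)·||W||² and its analytic gradient."""
    n, n_genes = x.shape
    w1, b1, w2, b2 = _unpack(theta, n_genes)
    h, p = _forward(x, w1, b1, w2, b2)
    eps = 1e-12
    ce = -np.mean(np.log(p[np.arange(n), y] + eps))
    reg = 0.5 * alpha * (np.sum(w1**2) + np.sum(w2**2)) / n
    dz2 = p.copy()
    dz2[np.arange(n), y] -= 1.0
    dz2 /= n
    gw2 = h.T @ dz2 + alpha * w2 / n
    gb2 = dz2.sum(axis=0)
    dh = dz2 @ w2.T
    dz1 = dh * (1.0 - h**2)
    gw1 = x.T @ dz1 + alpha * w1 / n
    gb1 = dz1.sum(axis=0)
    return ce + reg, _pack(gw1, gb1, gw2, gb2)


def _init_params(n_genes: int, cfg: TrainConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    w1 = rng.normal(0.0, cfg.init_scale / np.sqrt(n_genes), (n_genes, N_HIDDEN))
    b1 = np.zeros(N_HIDDEN)
    w2 = rng.normal(0.0, cfg.init_scale / np.sqrt(N_HIDDEN), (N_HIDDEN, N_CLASSES))
    b2 = np.zeros(N_CLASSES)
    return _pack(w1, b1, w2, b2)


class _EarlyStop:
    """Loss-plateau rule: stop after `patience` iterations without a ≥ tol
    improvement over the best loss seen."""

    def __init__(self, fun, tol: float, patience: int):
        self.fun = fun
        self.tol = tol
        self.patience = patience
        self.best = np.inf
        self.stale = 0
        self.n_iter = 0
        self.triggered = False

    def __call__(self, xk) -> None:
        self.n_iter += 1
        loss = self.fun(xk)
        if loss < self.best - self.tol:
            self.stale = 0
        else:
            self.stale += 1
        self.best = min(self.best, loss)
        if self.stale >= self.patience:
            self.triggered = True
            raise StopIteration


def _prepare_xy(
    features: ExpressionMatrix, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(features.sample_ids)
    if labels.isna().any():
        miss = list(labels.index[labels.isna()])
        raise ValueError(f"samples without labels: {miss}")
    x = features.to_array().T  # samples × genes
    if not np.isfinite(x).all():
        raise ValueError("features contain non-finite values")
    class_idx = {c: k for k, c in enumerate(SUBTYPES)}
    bad = sorted(set(labels) - set(SUBTYPES))
    if bad:
        raise ValueError(f"unknown subtype labels: {bad}")
    y = np.array([class_idx[c] for c in labels])
    return x, y


def train_model(
    features: ExpressionMatrix,
    labels: pd.Series,
    cfg: TrainConfig | None = None,
    reference: ReferenceDistribution | None = None,
    require_min_n: bool = True,
) -> TrainedModel:
    """Fit the two-hidden-neuron classifier on normalized features.

    ``features`` is genes × samples, already reference-normalized;
    ``labels`` maps sample id to subtype and must contain all four
    classes. Deterministic given ``cfg.seed``. The returned model
    records iterations run, final loss, and the stopping reason.
    """
    cfg = cfg or TrainConfig()
    x, y = _prepare_xy(features, labels)
    present = set(labels)
    missing = [c for c in SUBTYPES if c not in present]
    if missing:
        raise ValueError(f"labels lack subtype class(es): {missing}")
    if require_min_n and x.shape[0] < 5 * N_CLASSES:
        raise ValueError(
            f"need at least {5 * N_CLASSES} samples to train, got {x.shape[0]}"
        )

    theta0 = _init_params(x.shape[1], cfg)
    loss_at = lambda t: _loss_grad(t, x, y, cfg.alpha)[0]
    stopper = _EarlyStop(loss_at, cfg.tol, cfg.patience)
    res = minimize(
        _loss_grad,
        theta0,
        args=(x, y, cfg.alpha),
        method="L-BFGS-B",
        jac=True,
        callback=stopper,
        options={"maxiter": cfg.max_iter, "ftol": 1e-15, "gtol": 1e-12},
    )
    theta = res.x
    final_loss = loss_at(theta)
    init_loss = loss_at(theta0)
    if final_loss > init_loss:  # pathological; keep the better point
        theta, final_loss = theta0, init_loss
    w1, b1, w2, b2 = _unpack(theta, x.shape[1])
    if stopper.triggered:
        reason = f"loss plateau (<{cfg.tol} improvement for {cfg.patience} iterations)"
    elif stopper.n_iter >= cfg.max_iter:
        reason = f"reached max_iter={cfg.max_iter}"
    else:
        reason = f"solver converged ({res.message})"
    logger.info(
        "trained in %d iterations, loss %.5f (%s)", stopper.n_iter, final_loss, reason
    )
    return TrainedModel(
        hidden_weights=w1,
        hidden_biases=b1,
        output_weights=w2,
        output_biases=b2,
        gene_order=features.gene_ids,
        reference=reference,
        metadata={
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "n_iterations": stopper.n_iter,
            "initial_loss": float(init_loss),
            "final_loss": float(final_loss),
            "stopping_reason": reason,
            "n_training_samples": int(x.shape[0]),
        },
    )


def predict_subtypes(model: TrainedModel, features: ExpressionMatrix) -> SubtypeCalls:
    """Forward pass on normalized features; pure and deterministic.

    Feature gene order must match the model's; mismatches are reported
    by name.
    """
    if features.gene_ids != list(model.gene_order):
        extra = sorted(set(features.gene_ids) - set(model.gene_order))
        missing = sorted(set(model.gene_order) - set(features.gene_ids))
        raise ValueError(
            "feature genes do not match model gene order "
            f"(missing: {missing}, unexpected: {extra}, or order differs)"
        )
    x = features.to_array().T
    h, p = _forward(
        x,
        model.hidden_weights,
        model.hidden_biases,
        model.output_weights,
        model.output_biases,
    )
    idx = p.argmax(axis=1)  # first-in-class-order tie-break
    table = pd.DataFrame(
        {f"P_{c}": p[:, k] for k, c in enumerate(SUBTYPES)},
        index=pd.Index(features.sample_ids, name="sample_id"),
    )
    table["subtype"] = [SUBTYPES[k] for k in idx]
    table["neuron1"] = h[:, 0]
    table["neuron2"] = h[:, 1]
    table["max_probability"] = p.max(axis=1)
    return SubtypeCalls(table)


def latent_coordinates(
    model: TrainedModel, features: ExpressionMatrix
) -> pd.DataFrame:
    """Hidden-layer activations (neuron1, neuron2), each in (−1, 1)."""
    return predict_subtypes(model, features).latent


def output_layer_probabilities(model: TrainedModel, latent: np.ndarray) -> np.ndarray:
    """Class probabilities for arbitrary latent points (used for contour
    backgrounds): softmax of the output layer applied to (neuron1, neuron2)."""
    latent = np.asarray(latent, dtype=float).reshape(-1, N_HIDDEN)
    return _softmax(latent @ model.output_weights + model.output_biases)


# ---------------------------------------------------------------------------
# End-to-end convenience: raw expression in, trained model / calls out
# ---------------------------------------------------------------------------


def train_from_raw(
    expr: ExpressionMatrix,
    panel: GenePanel,
    cfg: TrainConfig | None = None,
    thresholds: tuple[float, float] = (0.0, 0.0),
):
    """Full training pipeline from raw (log-scale) expression.

    Freezes the reference distribution on the panel genes, maps the
    training data through it to model-ready features, derives training
    labels with the population-dependent z-score quadrant model, and
    fits the classifier with the reference embedded.

    Returns (model, labels).
    """
    from .labeling import label_cohort
    from .normalize import fit_reference, map_to_reference

    cfg = cfg or TrainConfig()
    ref = fit_reference(expr, panel, provenance={"seed": cfg.seed})
    features = map_to_reference(expr, ref)
    _, labels = label_cohort(expr, panel, thresholds)
    m = train_model(features, labels.labels, cfg, reference=ref)
    return m, labels


def classify_raw(model: TrainedModel, expr: ExpressionMatrix) -> SubtypeCalls:
    """Normalize a raw cohort through the model's embedded reference and
    classify it."""
    from .normalize import map_to_reference

    if model.reference is None:
        raise ValueError("model has no embedded reference distribution")
    return predict_subtypes(model, map_to_reference(expr, model.reference))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    best_config: TrainConfig
    table: pd.DataFrame  # columns alpha, repeat, fold, accuracy
    summary: pd.DataFrame  # per-alpha mean/std accuracy

    @property
    def best_alpha(self) -> float:
        return self.best_config.alpha


def cross_validate(
    features: ExpressionMatrix,
    labels: pd.Series,
    cfg: TrainConfig | None = None,
) -> CVResult:
    """Repeated stratified k-fold CV over the regularization grid.

    Selects the grid point with the highest mean validation accuracy;
    ties go to the smallest alpha.
    """
    cfg = cfg or TrainConfig()
    if not cfg.alpha_grid:
        raise ValueError("hyperparameter grid is empty")
    x, y = _prepare_xy(features, labels)
    if x.shape[0] < cfg.cv_folds * N_CLASSES:
        raise ValueError(
            f"need ≥ {cfg.cv_folds * N_CLASSES} samples for "
            f"{cfg.cv_folds}-fold stratified CV"
        )
    labels = labels.reindex(features.sample_ids)
    splitter = RepeatedStratifiedKFold(
        n_splits=cfg.cv_folds, n_repeats=cfg.cv_repeats, random_state=cfg.seed
    )
    rows = []
    for alpha in cfg.alpha_grid:
        fold_cfg = replace(cfg, alpha=alpha)
        for split_no, (tr, va) in enumerate(splitter.split(x, y)):
            rep, fold = divmod(split_no, cfg.cv_folds)
            sub = ExpressionMatrix(features.values.iloc[:, tr])
            m = train_model(
                sub, labels.iloc[tr], fold_cfg, require_min_n=False
            )
            val = ExpressionMatrix(features.values.iloc[:, va])
            pred = predict_subtypes(m, val).subtype
            acc = float((pred.to_numpy() == labels.iloc[va].to_numpy()).mean())
            rows.append(
                {"alpha": alpha, "repeat": rep, "fold": fold, "accuracy": acc}
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("alpha")["accuracy"].agg(["mean", "std"]).reset_index()
    )
    best = summary.sort_values(["mean", "alpha"], ascending=[False, True]).iloc[0]
    best_cfg = replace(cfg, alpha=float(best["alpha"]))
    logger.info(
        "CV selected alpha=%g (mean accuracy %.3f)", best_cfg.alpha, best["mean"]
    )
    return CVResult(best_config=best_cfg, table=table, summary=summary)


# ---------------------------------------------------------------------------
# Interpretability: neuron ↔ axis alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    """How well the hidden neurons separate the panel's two biologies.

    For the best assignment of neurons to axes (allowing each neuron's
    sign orientation to flip — tanh networks are sign-symmetric),
    ``alignment`` gives, per axis, the fraction of (own-axis gene,
    other-axis gene) pairs in which the own-axis gene carries the larger
    oriented weight on the assigned neuron (ties count half) — 1.0 when
    the axis's genes all outweigh the rest, 0.5 when the weights carry
    no axis structure. The raw positive-weight fractions for every
    neuron × axis combination are kept in ``positive_fraction``.
    """

    assignment: dict[str, int]  # axis -> neuron index (0 or 1)
    orientation: dict[str, int]  # axis -> ±1 applied to that neuron's weights
    alignment: dict[str, float]  # axis -> sign-alignment fraction in [0, 1]
    positive_fraction: pd.DataFrame  # neurons × axes raw positive-weight fracs
    interpretable: bool

    @property
    def mean_alignment(self) -> float:
        return float(np.mean(list(self.alignment.values())))


def neuron_axis_alignment(
    model: TrainedModel,
    panel: GenePanel,
    interpretable_threshold: float = 0.8,
) -> AlignmentReport:
    """Assign hidden neurons to biological axes by weight structure.

    Searches the two neuron↔axis assignments and each neuron's sign
    orientation for the maximal mean alignment (rank separation of
    own-axis vs other-axis weights); reports whether both axes reach
    ``interpretable_threshold``.
    """
    axis_of = panel.axis_of()
    genes = [g for g in model.gene_order if g in axis_of]
    if not genes:
        raise ValueError("panel shares no genes with the model")
    w = pd.DataFrame(
        model.hidden_weights,
        index=model.gene_order,
        columns=["neuron1", "neuron2"],
    ).loc[genes]
    in_axis = {a: np.array([axis_of[g] == a for g in genes]) for a in AXES}

    positive_fraction = pd.DataFrame(
        {
            a: [(w.iloc[:, j][in_axis[a]] > 0).mean() for j in range(N_HIDDEN)]
            for a in AXES
        },
        index=["neuron1", "neuron2"],
    )

    def sign_alignment(j: int, axis: str, eps: int) -> float:
        from scipy.stats import rankdata as _rankdata

        oriented = eps * w.iloc[:, j].to_numpy()
        own = in_axis[axis]
        ranks = _rankdata(oriented)
        n_own, n_other = int(own.sum()), int((~own).sum())
        u = ranks[own].sum() - n_own * (n_own + 1) / 2.0
        return float(u / (n_own * n_other))

    best = None
    for perm in ((0, 1), (1, 0)):
        for e0 in (1, -1):
            for e1 in (1, -1):
                assign = {AXES[0]: perm[0], AXES[1]: perm[1]}
                orient = {AXES[0]: e0, AXES[1]: e1}
                align = {a: sign_alignment(assign[a], a, orient[a]) for a in AXES}
                score = np.mean(list(align.values()))
                if best is None or score > best[0]:
                    best = (score, assign, orient, align)
    _, assign, orient, align = best
    return AlignmentReport(
        assignment=assign,
        orientation=orient,
        alignment=align,
        positive_fraction=positive_fraction,
        interpretable=all(v >= interpretable_threshold for v in align.values()),
    )
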