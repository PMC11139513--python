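"""Model training, the repeated stratified cross-validation protocol, and
classification metrics.

Evaluation follows the screening-oriented conventions of the field: macro-
averaged F1 is the primary criterion (robust to class imbalance), with
weighted F1, ROC AUC and — for binary tasks — sensitivity at 99% specificity
(the operating point relevant for population screening) reported alongside.
Normalization is fitted inside each training fold only, so test folds never
leak into feature scaling or model selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit

from .embedding import ZScoreNormalizer
from .model import MODEL_MODES, PathwayClassifier
from .nn import Adam, cross_entropy
from .pathways import GenePathwayMask
from .transformer import AttentionConfig

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "CVPlan", "MetricsReport", "train_model",
           "cross_validate", "compute_metrics", "sensitivity_at_specificity"]


@dataclass
class TrainConfig:
    """Optimization settings; all randomness derives from ``seed``."""

    lr: float = 3e-3
    epochs: int = 80
    batch_size: int = 32
    seed: int = 0
    weight_decay: float = 1e-4
    dropout_c: float = 0.3
    model_mode: str = "pathformer"
    pooling: str = "mean_over_dims"
    patience: int = 15
    val_fraction: float = 0.2
    class_weighted: bool = True
    #: after early stopping picks an epoch budget on the validation split,
    #: retrain from scratch on the full training set for that many epochs
    refit: bool = False

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("lr, epochs and batch_size must be positive")
        if self.model_mode not in MODEL_MODES:
            raise ValueError(f"unknown model mode {self.model_mode!r}")


@dataclass
class CVPlan:
    """k-fold cross-validation repeated with reshuffling, stratified."""

    k: int = 5
    repeats: int = 2
    seed: int = 0
    stratified: bool = True

    @property
    def n_folds(self) -> int:
        return self.k * self.repeats


@dataclass
class MetricsReport:
    """Per-fold metrics plus their mean and standard deviation."""

    fold_metrics: pd.DataFrame
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def from_folds(cls, rows: list[dict]) -> "MetricsReport":
        df = pd.DataFrame(rows)
        num = df.select_dtypes("number")
        return cls(fold_metrics=df, mean=num.mean().to_dict(),
                   sd=num.std(ddof=1).to_dict())


def _class_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    if (counts == 0).any():
        missing = np.where(counts == 0)[0].tolist()
        raise ValueError(f"classes {missing} absent from the training split; "
                         "review stratification")
    return counts.sum() / (n_classes * counts)


def compute_metrics(labels: np.ndarray, predictions: np.ndarray,
                    scores: np.ndarray) -> dict:
    """Macro/weighted F1, AUC, and (binary) sensitivity at 99% specificity.

    ``scores`` are class probabilities, shape (n, k).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("AUC undefined for single-class labels")
    out = {
        "macro_f1": skm.f1_score(labels, predictions, average="macro",
                                 zero_division=0),
        "weighted_f1": skm.f1_score(labels, predictions, average="weighted",
                                    zero_division=0),
    }
    n_classes = scores.shape[1]
    if n_classes == 2:
        out["auc"] = skm.roc_auc_score(labels, scores[:, 1])
        out["sensitivity_at_spec99"] = sensitivity_at_specificity(
            scores[:, 1], labels, spec=0.99)
    else:
        # unweighted one-vs-rest mean over classes
        out["auc"] = skm.roc_auc_score(labels, scores, multi_class="ovr",
                                       average="macro")
        out["sensitivity_at_spec99"] = float("nan")
    return out


def sensitivity_at_specificity(scores: np.ndarray, labels: np.ndarray,
                               spec: float = 0.99) -> float:
    """Recall of positives at the smallest threshold giving specificity >= spec.

    A sample is called positive when its score is >= the threshold.  With
    fewer than 1/(1-spec) negatives the threshold is degenerate (only a
    threshold rejecting every negative qualifies); a warning is emitted.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    neg = scores[labels == 0]
    pos = scores[labels == 1]
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("both classes required")
    if len(neg) < 1.0 / (1.0 - spec):
        warnings.warn(f"only {len(neg)} negatives: specificity {spec:.2f} "
                      "threshold is degenerate", stacklevel=2)
    for t in np.unique(scores):  # ascending candidate cutoffs
        if (neg < t).mean() >= spec:
            return float((pos >= t).mean())
    return 0.0  # only a threshold above every score rejects enough negatives


def train_model(eg: np.ndarray, labels: np.ndarray, mask: GenePathwayMask,
                p0: np.ndarray | None, cfg: TrainConfig,
                attn_cfg: AttentionConfig | None = None,
                train_idx: np.ndarray | None = None,
                val_idx: np.ndarray | None = None
                ) -> tuple[PathwayClassifier, pd.DataFrame]:
    """Fit a classifier on normalized gene embeddings.

    eg: (S, Ng, Dg) *normalized* gene embedding; labels: int-coded (S,).
    When ``val_idx`` is None a stratified ``val_fraction`` of the training
    samples is held out for early stopping on validation macro-F1.
    Returns the fitted model (best-validation weights restored) and a
    per-epoch training log.
    """
    labels = np.asarray(labels)
    n_classes = int(labels.max()) + 1
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    if train_idx is None:
        train_idx = np.arange(eg.shape[0])
    train_idx = np.asarray(train_idx)
    if val_idx is None and cfg.val_fraction > 0 and len(train_idx) >= 10:
        splitter = StratifiedShuffleSplit(n_splits=1,
                                          test_size=cfg.val_fraction,
                                          random_state=cfg.seed)
        sub, val = next(splitter.split(train_idx.reshape(-1, 1),
                                       labels[train_idx]))
        val_idx = train_idx[val]
        train_idx = train_idx[sub]
    val_idx = np.asarray(val_idx) if val_idx is not None else None

    model = PathwayClassifier(mask, p0, eg.shape[2], n_classes,
                              attn_cfg, mode=cfg.model_mode,
                              pooling=cfg.pooling, dropout_c=cfg.dropout_c,
                              seed=cfg.seed)
    weights = (_class_weights(labels[train_idx], n_classes)
               if cfg.class_weighted else None)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay,
               sparse_modules=model.sparse_modules())
    rng = np.random.default_rng(cfg.seed + 1)

    log_rows = []
    best_f1, best_state, best_epoch, stale = -np.inf, None, -1, 0
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            logits = model(eg[batch])
            loss = cross_entropy(logits, labels[batch], weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: check learning rate "
                    f"({cfg.lr}) and input scaling")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_idx is not None and len(val_idx):
            pred = model.predict(eg[val_idx])
            val_f1 = skm.f1_score(labels[val_idx], pred, average="macro",
                                  zero_division=0)
            row["val_macro_f1"] = val_f1
            if val_f1 > best_f1 + 1e-12:
                best_f1, best_epoch, stale = val_f1, epoch, 0
                best_state = model.state_dict()
            else:
                stale += 1
            log_rows.append(row)
            if stale >= cfg.patience:
                logger.info("early stop at epoch %d (best %d, f1=%.3f)",
                            epoch, best_epoch, best_f1)
                break
        else:
            log_rows.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    if cfg.refit and val_idx is not None and len(val_idx) and best_epoch >= 0:
        refit_cfg = TrainConfig(**{**vars(cfg), "refit": False,
                                   "val_fraction": 0.0,
                                   "epochs": best_epoch + 1})
        full_idx = np.concatenate([train_idx, val_idx])
        model, refit_log = train_model(eg, labels, mask, p0, refit_cfg,
                                       attn_cfg, train_idx=full_idx,
                                       val_idx=None)
        refit_log["phase"] = "refit"
        log = pd.DataFrame(log_rows)
        log["phase"] = "selection"
        return model, pd.concat([log, refit_log], ignore_index=True)
    model.eval()
    return model, pd.DataFrame(log_rows)


def grid_search(eg: np.ndarray, labels: np.ndarray, mask: GenePathwayMask,
                p0: np.ndarray | None, cfg: TrainConfig,
                attn_cfg: AttentionConfig | None,
                train_idx: np.ndarray,
                grid: dict[str, list] | None = None
                ) -> tuple[TrainConfig, "AttentionConfig", pd.DataFrame]:
    """Select hyperparameters on an inner validation split of the training set.

    ``grid`` maps parameter names (TrainConfig fields, or
    'row_residual_coeff' for the attention beta) to candidate values; the
    full cartesian product is evaluated by training on an inner split and
    scoring validation macro-F1.  Defaults to a small grid over learning
    rate and classifier dropout.
    """
    import itertools

    from sklearn import metrics as _skm

    if grid is None:
        grid = {"lr": [1e-3, 3e-3], "dropout_c": [0.1, 0.3]}
    attn_cfg = attn_cfg if attn_cfg is not None else AttentionConfig()
    names = list(grid)
    labels = np.asarray(labels)
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=cfg.val_fraction,
                                      random_state=cfg.seed)
    sub, val = next(splitter.split(train_idx.reshape(-1, 1),
                                   labels[train_idx]))
    inner_tr, inner_val = train_idx[sub], train_idx[val]
    rows, best = [], (-np.inf, None, None)
    for combo in itertools.product(*grid.values()):
        params = dict(zip(names, combo))
        t_kwargs = {k: v for k, v in params.items()
                    if k != "row_residual_coeff"}
        trial_cfg = TrainConfig(**{**vars(cfg), **t_kwargs})
        trial_attn = attn_cfg
        if "row_residual_coeff" in params:
            from dataclasses import replace
            trial_attn = replace(attn_cfg,
                                 row_residual_coeff=params["row_residual_coeff"])
        model, _ = train_model(eg, labels, mask, p0, trial_cfg, trial_attn,
                               train_idx=inner_tr, val_idx=inner_val)
        f1 = _skm.f1_score(labels[inner_val], model.predict(eg[inner_val]),
                           average="macro", zero_division=0)
        rows.append({**params, "val_macro_f1": f1})
        if f1 > best[0]:
            best = (f1, trial_cfg, trial_attn)
    return best[1], best[2], pd.DataFrame(rows)


def cross_validate(eg_raw: np.ndarray, labels: np.ndarray,
                   mask: GenePathwayMask, p0: np.ndarray | None,
                   plan: CVPlan, cfg: TrainConfig,
                   attn_cfg: AttentionConfig | None = None,
                   normalize: bool = True, n_ensemble: int = 1
                   ) -> MetricsReport:
    """Repeated stratified k-fold cross-validation.

    eg_raw: *unnormalized* gene embedding (S, Ng, Dg); z-scoring is fitted on
    each training fold and applied to its test fold, so no test information
    reaches feature scaling (``normalize=False`` expects pre-scaled input and
    exists for leakage-sensitivity experiments).  ``n_ensemble`` > 1 trains
    that many differently initialized models per fold and averages their
    predicted probabilities — a variance reducer worth its cost on small
    cohorts.
    """
    labels = np.asarray(labels)
    if not plan.stratified:
        raise NotImplementedError("only stratified plans are supported")
    splitter = RepeatedStratifiedKFold(n_splits=plan.k,
                                       n_repeats=plan.repeats,
                                       random_state=plan.seed)
    rows = []
    for fold, (tr, te) in enumerate(splitter.split(labels.reshape(-1, 1),
                                                   labels)):
        if len(np.unique(labels[tr])) < len(np.unique(labels)):
            raise ValueError(f"fold {fold}: a class is absent from the "
                             "training split; review stratification")
        if normalize:
            eg = ZScoreNormalizer().fit_transform(eg_raw, sample_idx=tr)
        else:
            eg = eg_raw
        scores = np.zeros((len(te), len(np.unique(labels))))
        for member in range(n_ensemble):
            fold_cfg = TrainConfig(**{**vars(cfg), "seed":
                                      (cfg.seed * 997 + 31 * member + fold)
                                      % (2 ** 31)})
            model, _ = train_model(eg, labels, mask, p0, fold_cfg, attn_cfg,
                                   train_idx=tr)
            scores += model.predict_proba(eg[te])
        scores /= n_ensemble
        pred = scores.argmax(axis=1)
        row = {"fold": fold, **compute_metrics(labels[te], pred, scores)}
        rows.append(row)
        logger.info("fold %d: macro_f1=%.3f auc=%.3f", fold,
                    row["macro_f1"], row["auc"])
    return MetricsReport.from_folds(rows)
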