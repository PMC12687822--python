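"""Feedforward habitat classifier.

A deliberately simple architecture: the flattened climate sequence feeds
three fully connected hidden layers of 128, 64 and 32 ReLU units and a
single-logit output.  Training minimizes binary cross-entropy on the logit
(the numerically stable fused form) with Adam at learning rate 1e-3, and
early-stops on validation AUC — the weights returned are those of the
best-AUC epoch, not the last one.  Patience is 10 epochs during
cross-validation and 100 during final model training.

Implemented directly in NumPy: the network is small enough that explicit
forward/backward passes are fast on one CPU and give bit-level determinism
from a seed, which the checkpointing contract requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import features as feat
from .calibration import FNRCalibrator
from .features import SequenceScaler


def bce_with_logits(logit, label):
    """Binary cross-entropy on a raw logit: softplus(logit) - label*logit.

    Equivalent to -[y log sigma(z) + (1-y) log(1-sigma(z))] but stable for
    large |z|.
    """
    z = np.asarray(logit, dtype=float)
    y = np.asarray(label, dtype=float)
    loss = np.logaddexp(0.0, z) - y * z
    return loss if loss.ndim else float(loss)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class ModelConfig:
    """Hyperparameters; everything unstated by the protocol is fixed here
    and recorded in the checkpoint."""

    hidden_sizes: tuple = (128, 64, 32)
    learning_rate: float = 1e-3
    patience_cv: int = 10
    patience_final: int = 100
    max_epochs: int = 1000
    batch_size: int = 256
    seed: int = 0
    seq_len: int = 365
    variable_subset: tuple = feat.DERIVED_VARS
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    # fraction of the training split carved out (stratified, seeded) to act
    # as both the early-stopping validation set and the calibration
    # reference population; see fit_pipeline
    validation_fraction: float = 0.5
    flatten_order: str = "day_major_oldest_first"

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        self.variable_subset = tuple(self.variable_subset)
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.patience_cv < 1 or self.patience_final < 1:
            raise ValueError("patience must be >= 1")
        if not self.variable_subset:
            raise ValueError("variable subset must be non-empty")


class HabitatFFNN(BaseEstimator, ClassifierMixin):
    """Binary habitat classifier: 128/64/32 ReLU MLP on flattened sequences.

    Parameters follow the training protocol described in the module
    docstring.  ``patience`` counts epochs without a new best validation
    AUC; ``fit`` accepts an explicit validation set, otherwise carves a
    seeded stratified ``validation_fraction`` out of the training data.

    Fitted attributes (trailing underscore) include the layer weights
    ``coefs_``/``intercepts_`` at the best-AUC epoch, ``best_epoch_``,
    ``best_val_auc_`` and a per-epoch ``training_log_``.
    """

    def __init__(
        self,
        hidden_sizes=(128, 64, 32),
        learning_rate=1e-3,
        batch_size=256,
        max_epochs=1000,
        patience=100,
        validation_fraction=0.1,
        adam_beta1=0.9,
        adam_beta2=0.999,
        adam_eps=1e-8,
        random_state=0,
    ):
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.adam_eps = adam_eps
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _init_weights(self, n_features, rng):
        """Seeded uniform fan-in init, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
        sizes = [n_features, *self.hidden_sizes, 1]
        coefs, intercepts = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            coefs.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            intercepts.append(rng.uniform(-bound, bound, size=fan_out))
        return coefs, intercepts

    def _forward(self, X, coefs, intercepts):
        acts = [X]
        h = X
        for W, b in zip(coefs[:-1], intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = (h @ coefs[-1] + intercepts[-1]).ravel()
        return logits, acts

    def _backward(self, acts, logits, y, coefs):
        n = len(y)
        delta = (_sigmoid(logits) - y)[:, None] / n  # dL/dlogit
        grads_W, grads_b = [], []
        for layer in range(len(coefs) - 1, -1, -1):
            a = acts[layer]
            grads_W.append(a.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ coefs[layer].T) * (acts[layer] > 0)
        return grads_W[::-1], grads_b[::-1]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise ValueError("fit requires both classes {0, 1} present")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            X, y, X_val, y_val = _stratified_carveout(X, y, self.validation_fraction, rng)
        else:
            X_val = np.asarray(X_val, dtype=np.float64)
            y_val = np.asarray(y_val, dtype=np.float64).ravel()
        if len(np.unique(y_val)) < 2 or len(np.unique(y)) < 2:
            raise ValueError("both classes must be present in train and validation sets")

        coefs, intercepts = self._init_weights(X.shape[1], rng)
        m_W = [np.zeros_like(W) for W in coefs]
        v_W = [np.zeros_like(W) for W in coefs]
        m_b = [np.zeros_like(b) for b in intercepts]
        v_b = [np.zeros_like(b) for b in intercepts]
        b1, b2, eps = self.adam_beta1, self.adam_beta2, self.adam_eps

        best_auc, best_epoch = -np.inf, -1
        best = None
        log = []
        t = 0
        n = len(y)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                logits, acts = self._forward(X[idx], coefs, intercepts)
                if not np.all(np.isfinite(logits)):
                    raise FloatingPointError(
                        f"non-finite logits at epoch {epoch}; aborting (lr too high?)"
                    )
                epoch_loss += bce_with_logits(logits, y[idx]).sum()
                gW, gb = self._backward(acts, logits, y[idx], coefs)
                t += 1
                corr = np.sqrt(1 - b2**t) / (1 - b1**t)
                for l in range(len(coefs)):
                    m_W[l] = b1 * m_W[l] + (1 - b1) * gW[l]
                    v_W[l] = b2 * v_W[l] + (1 - b2) * gW[l] ** 2
                    coefs[l] -= self.learning_rate * corr * m_W[l] / (np.sqrt(v_W[l]) + eps)
                    m_b[l] = b1 * m_b[l] + (1 - b1) * gb[l]
                    v_b[l] = b2 * v_b[l] + (1 - b2) * gb[l] ** 2
                    intercepts[l] -= self.learning_rate * corr * m_b[l] / (np.sqrt(v_b[l]) + eps)
            val_logits, _ = self._forward(X_val, coefs, intercepts)
            val_auc = roc_auc_score(y_val, val_logits)
            log.append({"epoch": epoch, "train_loss": epoch_loss / n, "val_auc": float(val_auc)})
            if val_auc > best_auc:
                best_auc, best_epoch = float(val_auc), epoch
                best = ([W.copy() for W in coefs], [b.copy() for b in intercepts])
            elif epoch - best_epoch >= self.patience:
                break

        self.coefs_, self.intercepts_ = best
        self.best_epoch_ = best_epoch
        self.best_val_auc_ = best_auc
        self.training_log_ = log
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        logits, _ = self._forward(np.asarray(X, dtype=np.float64), self.coefs_, self.intercepts_)
        return logits

    def predict_proba(self, X):
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


def _stratified_carveout(X, y, fraction, rng):
    """Seeded stratified carve-out used as the final-training validation set."""
    val_idx = []
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(fraction * len(idx))))
        val_idx.append(rng.choice(idx, size=n_val, replace=False))
    val_idx = np.sort(np.concatenate(val_idx))
    train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
    return X[train_idx], y[train_idx], X[val_idx], y[val_idx]


def train(train_set, val_set, config: ModelConfig, patience: int | None = None) -> HabitatFFNN:
    """Train one network on explicit train/validation sets (final-training
    patience by default)."""
    clf = HabitatFFNN(
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=patience if patience is not None else config.patience_final,
        adam_beta1=config.adam_beta1,
        adam_beta2=config.adam_beta2,
        adam_eps=config.adam_eps,
        random_state=config.seed,
    )
    X_val, y_val = (val_set if isinstance(val_set, tuple) else (val_set.X, val_set.y))
    X_tr, y_tr = (train_set if isinstance(train_set, tuple) else (train_set.X, train_set.y))
    return clf.fit(X_tr, y_tr, X_val=X_val, y_val=y_val)


def cross_validate(train_set, config: ModelConfig, k: int = 5, folds=None) -> dict:
    """k-fold CV at cross-validation patience; returns per-fold AUCs."""
    from .sampling import make_folds

    folds = folds if folds is not None else make_folds(
        train_set, k, np.random.default_rng(config.seed)
    )
    aucs = []
    for fold_id, (tr, va) in enumerate(folds):
        cfg = ModelConfig(**{**asdict(config), "seed": config.seed + fold_id})
        clf = train((train_set.X[tr], train_set.y[tr]), (train_set.X[va], train_set.y[va]),
                    cfg, patience=config.patience_cv)
        aucs.append(float(roc_auc_score(train_set.y[va], clf.decision_function(train_set.X[va]))))
    return {"fold_aucs": aucs, "mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs))}


# ---------------------------------------------------------------------------
# the reusable prediction object
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Network + scaler + FNR calibration reference + full config."""

    model: HabitatFFNN
    scaler: SequenceScaler
    calibrator: FNRCalibrator | None
    config: ModelConfig
    training_log: list = field(default_factory=list)

    def predict_scores(self, X_raw) -> np.ndarray:
        """Raw probabilities in (0,1) for unscaled feature rows."""
        Xs = self.scaler.transform(np.atleast_2d(np.asarray(X_raw, dtype=float)))
        return self.model.predict_proba(Xs)[:, 1]

    def predict_map(self, derived, date, calibrated: bool = True) -> np.ndarray:
        """Raster of scores (or FNRs) for one prediction date.

        Cells lacking ``seq_len`` days of history raise; within a valid
        cube every cell is predicted (ocean masking is an output concern).
        """
        n_lat = derived.sizes["lat"]
        n_lon = derived.sizes["lon"]
        Xm = feat.assemble_map_matrix(derived, date, self.config.seq_len, self.config.variable_subset)
        scores = self.predict_scores(Xm)
        if calibrated:
            if self.calibrator is None:
                raise ValueError("model has no calibration reference")
            scores = self.calibrator.transform(scores)
        return scores.reshape(n_lat, n_lon)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single .npz archive: weights, scaler stats, calibration reference
        and a JSON-encoded config + training log.  Bit-exact round trip."""
        path = Path(path)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.model.coefs_, self.model.intercepts_)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        arrays["scaler_mean"] = np.asarray(self.scaler.mean_)
        arrays["scaler_scale"] = np.asarray(self.scaler.scale_)
        arrays["scaler_var"] = np.asarray(self.scaler.var_)
        if self.calibrator is not None:
            arrays["calibration_ref"] = self.calibrator.reference_
        cfg = asdict(self.config)
        meta = {
            "config": cfg,
            "n_layers": len(self.model.coefs_),
            "best_epoch": getattr(self.model, "best_epoch_", None),
            "best_val_auc": getattr(self.model, "best_val_auc_", None),
            "training_log": self.training_log,
        }
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
            config = ModelConfig(**meta["config"])
            clf = HabitatFFNN(
                hidden_sizes=config.hidden_sizes,
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                max_epochs=config.max_epochs,
                random_state=config.seed,
            )
            clf.coefs_ = [z[f"W{i}"] for i in range(meta["n_layers"])]
            clf.intercepts_ = [z[f"b{i}"] for i in range(meta["n_layers"])]
            clf.n_features_in_ = clf.coefs_[0].shape[0]
            clf.classes_ = np.array([0, 1])
            clf.best_epoch_ = meta["best_epoch"]
            clf.best_val_auc_ = meta["best_val_auc"]
            scaler = SequenceScaler()
            scaler.mean_ = z["scaler_mean"]
            scaler.scale_ = z["scaler_scale"]
            scaler.var_ = z["scaler_var"]
            scaler.n_features_in_ = scaler.mean_.shape[0]
            scaler.with_mean = scaler.with_std = True
            scaler.n_samples_seen_ = 1
            calib = None
            if "calibration_ref" in z:
                calib = FNRCalibrator().fit(z["calibration_ref"])
        return cls(model=clf, scaler=scaler, calibrator=calib,
                   config=config, training_log=meta["training_log"])


def fit_pipeline(train_set, config: ModelConfig, patience: int | None = None) -> TrainedModel:
    """Scale -> train -> calibrate on one training split.

    The training split is divided once (stratified, seeded) into a gradient
    half and a validation/calibration half of ``validation_fraction``.  The
    network trains on the gradient rows and early-stops on the carve-out's
    AUC; the calibration reference is the final network's scores on the
    carve-out *presences*.  Scoring presences the optimizer never saw is
    what keeps the FNR "risk percentile" reading honest: scores of
    memorized training presences are systematically inflated relative to
    exchangeable new presences, which would skew held-out FNRs toward 0.
    The scaler is fitted on the full training split (unsupervised, no
    leakage).
    """
    scaler = SequenceScaler().fit(train_set.X)
    Xs = scaler.transform(train_set.X)
    y = np.asarray(train_set.y, dtype=float)
    rng = np.random.default_rng(config.seed)
    X_gr, y_gr, X_val, y_val = _stratified_carveout(Xs, y, config.validation_fraction, rng)
    clf = HabitatFFNN(
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=patience if patience is not None else config.patience_final,
        adam_beta1=config.adam_beta1,
        adam_beta2=config.adam_beta2,
        adam_eps=config.adam_eps,
        random_state=config.seed,
    ).fit(X_gr, y_gr, X_val=X_val, y_val=y_val)
    pres_scores = clf.predict_proba(X_val[y_val == 1])[:, 1]
    calibrator = FNRCalibrator().fit(np.clip(pres_scores, 1e-12, 1 - 1e-12))
    return TrainedModel(model=clf, scaler=scaler, calibrator=calibrator,
                        config=config, training_log=clf.training_log_)
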