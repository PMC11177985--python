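"""Scikit-learn style estimators for infarct segmentation.

:class:`UNetSegmenter` wraps one of the encoder-decoder architectures in a
fit/predict interface over arrays of bullseye images: ``X`` has shape
(n, H, W, 3) with values in [0, 1], ``y`` has shape (n, H, W) and is binary.
Training minimizes the selected loss (binary cross-entropy, soft Dice or
soft IoU) with Adam, monitors a validation loss with early stopping and
restores the best weights.  ``score`` returns the mean Dice coefficient.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .losses import TRAINING_LOSSES, dsc_score, confusion
from .networks import NetworkConfig, build_network, forward_proba
from .nn import Adam, Tensor


def _validate_images(X, y=None):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError("X must have shape (n, H, W, 3)")
    if X.shape[1] != X.shape[2]:
        raise ValueError("images must be square")
    if X.min() < 0 or X.max() > 1:
        raise ValueError("pixel values must lie in [0, 1]")
    if y is None:
        return X
    y = np.asarray(y)
    if y.shape != X.shape[:3]:
        raise ValueError("y must have shape (n, H, W)")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("y must be binary")
    return X, y.astype(np.float32)


class UNetSegmenter(BaseEstimator):
    """Single-fidelity encoder-decoder infarct segmenter.

    Parameters
    ----------
    architecture : {"unet", "attention_unet", "dense_unet",
        "residual_attention_unet"}
    base_channels, depth : channel schedule (widths double per level).
    loss : {"bce", "dsc", "iou"} training loss.
    epochs, patience, batch_size, learning_rate : optimization protocol;
        early stopping monitors the validation loss and restores the best
        checkpoint.
    validation_fraction : fraction of ``fit`` data held out for early
        stopping when no explicit validation set is passed.
    threshold : probability cut for ``predict``.
    random_state : seeds weight initialization and batch shuffling.
    """

    def __init__(self, architecture: str = "unet", base_channels: int = 16,
                 depth: int = 5, loss: str = "bce", epochs: int = 100,
                 patience: int = 5, batch_size: int = 128,
                 learning_rate: float = 1e-3, validation_fraction: float = 0.15,
                 threshold: float = 0.5, random_state=None, verbose: int = 0):
        self.architecture = architecture
        self.base_channels = base_channels
        self.depth = depth
        self.loss = loss
        self.epochs = epochs
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.random_state = random_state
        self.verbose = verbose

    # -- internals -----------------------------------------------------------
    def _batch_loss(self, model, loss_fn, X, y):
        out = model(Tensor(X.transpose(0, 3, 1, 2)))
        return loss_fn(out, y[:, None, :, :])

    def _eval_loss(self, model, loss_fn, X, y, batch: int = 8):
        model.set_training(False)
        total, n = 0.0, 0
        for i in range(0, X.shape[0], batch):
            xb, yb = X[i:i + batch], y[i:i + batch]
            total += float(self._batch_loss(model, loss_fn, xb, yb).data) * len(xb)
            n += len(xb)
        model.set_training(True)
        return total / max(n, 1)

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X, y = _validate_images(X, y)
        if self.loss not in TRAINING_LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        loss_fn = TRAINING_LOSSES[self.loss]
        rng = np.random.default_rng(self.random_state)

        if X_val is None and self.validation_fraction > 0 and X.shape[0] > 2:
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            perm = rng.permutation(X.shape[0])
            X, y, X_val, y_val = (X[perm[n_val:]], y[perm[n_val:]],
                                  X[perm[:n_val]], y[perm[:n_val]])
        elif X_val is not None:
            X_val, y_val = _validate_images(X_val, y_val)

        config = NetworkConfig(architecture=self.architecture,
                               input_size=X.shape[1],
                               base_channels=self.base_channels,
                               depth=self.depth,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
        model = build_network(config)
        opt = Adam(model.parameters(), lr=self.learning_rate)

        best_val, best_state, best_epoch = np.inf, None, -1
        history = []
        stall = 0
        n = X.shape[0]
        bs = min(self.batch_size, n)
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for i in range(0, n, bs):
                idx = perm[i:i + bs]
                opt.zero_grad()
                loss = self._batch_loss(model, loss_fn, X[idx], y[idx])
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            epoch_loss /= n
            record = {"epoch": epoch, "train_loss": epoch_loss}
            if X_val is not None:
                val_loss = self._eval_loss(model, loss_fn, X_val, y_val)
                record["val_loss"] = val_loss
            else:
                val_loss = epoch_loss
            history.append(record)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(
                    f"{k}={v:.4f}" for k, v in record.items() if k != "epoch"))
            if val_loss < best_val - 1e-7:
                best_val, best_epoch, stall = val_loss, epoch, 0
                best_state = [p.copy() for p in model.state_arrays()]
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            model.load_state_arrays(best_state)

        self.model_ = model
        self.config_ = config
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = float(best_val)
        self.n_parameters_ = model.n_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = _validate_images(X)
        return forward_proba(self.model_, X)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-image Dice coefficient."""
        X, y = _validate_images(X, y)
        pred = self.predict(X)
        return float(np.mean([
            dsc_score(confusion(pred[i], y[i])) for i in range(len(pred))]))
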