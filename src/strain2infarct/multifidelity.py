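"""Composite multi-fidelity network for cross-domain infarct segmentation.

Abundant clean (low-fidelity) strain images and very scarce human-CMR-like
(high-fidelity) images are combined through a composite of three networks:
a low-fidelity UNet ``NN_LF`` producing y_L, and two high-fidelity
correction networks that consume the channel stack of the high-fidelity
image x_H (3 channels) and y_L (1 channel) — ``NN_HF1``, a single linear
10x10 convolution realising the linear map F_l, and ``NN_HF2``, the same
kernel followed by a leaky ReLU realising the nonlinear map F_nl.  The
combined prediction is

    y_H = F_l(x_H, y_L) + F_nl(x_H, y_L),

clipped to [0, 1] before thresholding.  All three networks are trained
jointly by minimizing

    MSE = MSE_L + MSE_H + lambda * sum(beta_i^2)

where MSE_L is the per-pixel mean squared error of the UNet on the
low-fidelity set, MSE_H that of the combined output on the high-fidelity
training set (one example plus its three fixed rotations), and the last
term an L2 penalty over the weights of all branches.  The held-out
high-fidelity example is never seen during training (swap-patients
protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .estimators import UNetSegmenter, _validate_images
from .losses import confusion, dsc_score
from .networks import NetworkConfig, build_network
from .nn import Adam, Conv2d, Module, Tensor, concat


class DataLeakageError(ValueError):
    """High-fidelity training and evaluation examples coincide."""


class MultiFidelityNet(Module):
    """UNet (low fidelity) + linear and nonlinear 10x10 conv corrections."""

    def __init__(self, base_channels: int = 16, depth: int = 5,
                 in_channels: int = 3, leaky_slope: float = 0.01,
                 seed: int | None = None):
        rng = np.random.default_rng(seed)
        config = NetworkConfig(architecture="unet", in_channels=in_channels,
                               base_channels=base_channels, depth=depth,
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
        self.nn_lf = build_network(config)
        self.hf1 = Conv2d(in_channels + 1, 1, 10, rng)   # F_l, no activation
        self.hf2 = Conv2d(in_channels + 1, 1, 10, rng)   # F_nl, leaky ReLU
        self.leaky_slope = leaky_slope

    def lf_params(self):
        return self.nn_lf.parameters()

    def hf_params(self):
        return self.hf1.parameters() + self.hf2.parameters()

    def forward_lf(self, x: Tensor) -> Tensor:
        return self.nn_lf(x)

    def forward_hf(self, x_h: Tensor, clip: bool = False) -> Tensor:
        """Combined high-fidelity output y_H = F_l + F_nl (raw sum)."""
        y_l = self.nn_lf(x_h)
        z = concat([x_h, y_l], axis=1)
        y = self.hf1(z) + self.hf2(z).leaky_relu(self.leaky_slope)
        return y.clip01() if clip else y


@dataclass
class MultiFidelityLossTerms:
    mse_l: float
    mse_h: float
    reg: float

    @property
    def total(self) -> float:
        return self.mse_l + self.mse_h + self.reg


def _mse(pred: Tensor, target: np.ndarray) -> Tensor:
    return ((pred - Tensor(target)) ** 2.0).mean()


def multifidelity_loss(model: MultiFidelityNet, X_lf, y_lf, X_hf, y_hf,
                       lam: float = 1e-4):
    """Differentiable combined loss; returns (Tensor total, value terms)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if len(X_lf) == 0 or len(X_hf) == 0:
        raise ValueError("empty batch")
    p_l = model.forward_lf(Tensor(X_lf.transpose(0, 3, 1, 2)))
    mse_l = _mse(p_l, y_lf[:, None, :, :])
    p_h = model.forward_hf(Tensor(X_hf.transpose(0, 3, 1, 2)))
    mse_h = _mse(p_h, y_hf[:, None, :, :])
    total = mse_l + mse_h
    if lam > 0:
        reg = None
        for p in model.lf_params() + model.hf_params():
            term = (p * p).sum()
            reg = term if reg is None else reg + term
        reg = reg * lam
        total = total + reg
        reg_val = float(reg.data)
    else:
        reg_val = 0.0
    terms = MultiFidelityLossTerms(mse_l=float(mse_l.data),
                                   mse_h=float(mse_h.data), reg=reg_val)
    return total, terms


def augment_example(x_hf: np.ndarray, y_hf: np.ndarray):
    """One example plus its three fixed rotations (N_H = 4)."""
    xs = [np.rot90(x_hf, k, axes=(0, 1)) for k in range(4)]
    ys = [np.rot90(y_hf, k, axes=(0, 1)) for k in range(4)]
    return np.ascontiguousarray(np.stack(xs)), np.ascontiguousarray(np.stack(ys))


class MultiFidelitySegmenter(BaseEstimator):
    """Composite multi-fidelity segmenter with a fit/predict interface.

    ``fit(X_lf, y_lf, x_hf, y_hf)`` takes the low-fidelity training arrays
    and a single high-fidelity example (augmented internally with its three
    rotations); ``x_hf_holdout`` may be passed to guard against leakage.
    """

    def __init__(self, base_channels: int = 16, depth: int = 5,
                 n_lf: int | None = None, epochs: int = 30,
                 batch_size: int = 16, learning_rate: float = 1e-3,
                 lambda_reg: float = 1e-4, leaky_slope: float = 0.01,
                 threshold: float = 0.5, random_state=None, verbose: int = 0):
        self.base_channels = base_channels
        self.depth = depth
        self.n_lf = n_lf
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lambda_reg = lambda_reg
        self.leaky_slope = leaky_slope
        self.threshold = threshold
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X_lf, y_lf, x_hf, y_hf, x_hf_holdout=None):
        X_lf, y_lf = _validate_images(X_lf, y_lf)
        x_hf = np.asarray(x_hf, dtype=np.float32)
        y_hf = np.asarray(y_hf)
        if x_hf.ndim != 3:
            raise ValueError("x_hf must be a single (H, W, 3) example")
        if x_hf_holdout is not None and np.allclose(x_hf, x_hf_holdout):
            raise DataLeakageError(
                "high-fidelity training and held-out examples are identical")
        rng = np.random.default_rng(self.random_state)

        n_lf = X_lf.shape[0] if self.n_lf is None else self.n_lf
        if n_lf < 1:
            raise ValueError("need at least one low-fidelity sample")
        if n_lf > X_lf.shape[0]:
            raise ValueError("n_lf exceeds the library size")
        if n_lf < X_lf.shape[0]:
            idx = rng.choice(X_lf.shape[0], n_lf, replace=False)
            X_lf, y_lf = X_lf[idx], y_lf[idx]

        X_hf, Y_hf = augment_example(x_hf, y_hf)
        X_hf = X_hf.astype(np.float32)
        Y_hf = Y_hf.astype(np.float32)

        model = MultiFidelityNet(base_channels=self.base_channels,
                                 depth=self.depth,
                                 leaky_slope=self.leaky_slope,
                                 seed=int(rng.integers(0, 2 ** 31 - 1)))
        opt = Adam(model.lf_params() + model.hf_params(),
                   lr=self.learning_rate)
        history = []
        n = X_lf.shape[0]
        bs = min(self.batch_size, n)
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            terms_sum = np.zeros(3)
            steps = 0
            for i in range(0, n, bs):
                idx = perm[i:i + bs]
                opt.zero_grad()
                loss, terms = multifidelity_loss(
                    model, X_lf[idx], y_lf[idx], X_hf, Y_hf,
                    lam=self.lambda_reg)
                loss.backward()
                opt.step()
                terms_sum += (terms.mse_l, terms.mse_h, terms.reg)
                steps += 1
            rec = {"epoch": epoch,
                   "mse_l": terms_sum[0] / steps,
                   "mse_h": terms_sum[1] / steps,
                   "reg": terms_sum[2] / steps}
            rec["total"] = sum(v for k, v in rec.items() if k != "epoch")
            history.append(rec)
            if self.verbose:
                print(f"epoch {epoch}: total={rec['total']:.4f}")
        self.model_ = model
        self.history_ = history
        self.n_parameters_ = model.nn_lf.n_parameters() + sum(
            p.data.size for p in model.hf_params())
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = _validate_images(X)
        self.model_.set_training(False)
        out = []
        for i in range(0, X.shape[0], 8):
            x = Tensor(X[i:i + 8].transpose(0, 3, 1, 2))
            out.append(self.model_.forward_hf(x, clip=True).data[:, 0])
        self.model_.set_training(True)
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        pred = self.predict(X)
        y = np.asarray(y)
        return float(np.mean([
            dsc_score(confusion(pred[i], y[i])) for i in range(len(pred))]))


def train_multifidelity(X_lf, y_lf, x_hf, y_hf, n_lf=None,
                        x_hf_holdout=None, **kwargs) -> MultiFidelitySegmenter:
    """Train the composite network on the library plus one HF example."""
    est = MultiFidelitySegmenter(n_lf=n_lf, **kwargs)
    return est.fit(X_lf, y_lf, x_hf, y_hf, x_hf_holdout=x_hf_holdout)


def swap_protocol(X_lf, y_lf, hf_examples, **kwargs):
    """Train on HF example A, evaluate on B, then reverse the roles.

    ``hf_examples`` is ((x_a, y_a), (x_b, y_b)); returns the two held-out
    DSC values.
    """
    (x_a, y_a), (x_b, y_b) = hf_examples
    out = []
    for (xt, yt), (xe, ye) in (((x_a, y_a), (x_b, y_b)),
                               ((x_b, y_b), (x_a, y_a))):
        est = train_multifidelity(X_lf, y_lf, xt, yt,
                                  x_hf_holdout=xe, **kwargs)
        out.append(est.score(xe[None], np.asarray(ye)[None]))
    return tuple(out)


def ablate_lf_count(X_lf, y_lf, hf_pair, counts, n_seeds: int = 5,
                    sf_params=None, **mf_params) -> pd.DataFrame:
    """DSC of multi- and single-fidelity models versus low-fidelity count.

    For each count, subsample the library and train both the composite
    network (on the subsample plus HF example A) and a single-fidelity UNet
    baseline (on the subsample only), evaluating both on the held-out HF
    example B across ``n_seeds`` seeds.  Returns one row per
    (count, seed, model).
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if n_seeds < 2:
        raise ValueError("need at least two seeds")
    if max(counts) > len(X_lf):
        raise ValueError("count exceeds library size")
    (x_a, y_a), (x_b, y_b) = hf_pair
    sf_params = dict(sf_params or {})
    rows = []
    for n_lf in counts:
        for seed in range(n_seeds):
            mf = train_multifidelity(X_lf, y_lf, x_a, y_a, n_lf=n_lf,
                                     x_hf_holdout=x_b, random_state=seed,
                                     **mf_params)
            rows.append({"n_lf": n_lf, "seed": seed, "model": "multi_fidelity",
                         "dsc": mf.score(x_b[None], np.asarray(y_b)[None])})
            rng = np.random.default_rng(seed)
            idx = (np.arange(len(X_lf)) if n_lf >= len(X_lf)
                   else rng.choice(len(X_lf), n_lf, replace=False))
            sf = UNetSegmenter(random_state=seed, **sf_params)
            sf.fit(X_lf[idx], y_lf[idx])
            rows.append({"n_lf": n_lf, "seed": seed, "model": "single_fidelity",
                         "dsc": sf.score(x_b[None], np.asarray(y_b)[None])})
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and std DSC per (count, model)."""
    return (table.groupby(["n_lf", "model"])["dsc"]
            .agg(["mean", "std"]).reset_index())
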