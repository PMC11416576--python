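"""Scikit-learn style segmentation estimators.

The trainable networks are exposed as estimators with the usual
``fit`` / ``predict`` / ``predict_proba`` surface so they compose with
sklearn model selection:

* :class:`UNetSegmenter` — the custom 6-class U-Net trained with
  categorical cross-entropy;
* :class:`MSUNetSegmenter` — the multi-scale multi-label U-Net trained
  with the class-weighted Dice loss (disc + cup, K = 2);
* :class:`BUNetSegmenter` — MSU-Net plus side-output deep supervision
  (per-head Dice losses fused with the final-layer loss).

``X`` is a batch of images with shape (n, H, W, 3), float in [0, 1] (a
uint8 batch is scaled by 255 automatically).  ``y`` is (n, H, W) integer
label masks for the multiclass model, or (n, H, W, K) binary stacks for
the multi-label models.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .architectures import (
    BUNet,
    BUNetConfig,
    CustomUNet,
    MSUNet,
    MSUNetConfig,
    build_backbone_unet,
)
from .losses_metrics import DiceLossConfig, SideOutputConfig, side_output_loss
from .nn import functional as F

__all__ = ["UNetSegmenter", "MSUNetSegmenter", "BUNetSegmenter", "fit_loop"]


def _as_float_batch(X):
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[None]
    if np.issubdtype(X.dtype, np.integer):
        X = X.astype(np.float32) / 255.0
    return X.astype(np.float32)


def _one_hot(y, n_classes):
    y = np.asarray(y)
    if y.max(initial=0) >= n_classes or y.min(initial=0) < 0:
        raise ValueError(f"label mask contains a class id outside 0..{n_classes - 1}")
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[y]


def _dice_loss_graph(probs, g_flat, weights, eps):
    """Multi-label Dice loss built from autograd primitives.

    ``probs`` is a (N, H, W, K) probability tensor; the loss graph mirrors
    the closed-form loss so its reverse-mode gradient can be checked
    against the analytic expression.
    """
    n_pix = int(np.prod(probs.shape[:-1]))
    k = probs.shape[-1]
    p = nn.Tensor(probs.data.reshape(n_pix, k), _parents=(probs,),
                  _backward=lambda g: (g.reshape(probs.shape),))
    g = g_flat.astype(probs.dtype)
    inter = F.tsum(F.mul(p, nn.Tensor(g)), axis=0)
    den = F.add(F.tsum(F.power(p, 2.0), axis=0),
                nn.Tensor((g ** 2).sum(axis=0) + eps))
    per_class = F.div(inter, den)
    weighted = F.mul(per_class, nn.Tensor(np.asarray(weights, dtype=probs.dtype)))
    return F.sub(nn.Tensor(np.asarray(1.0, dtype=probs.dtype)),
                 F.tsum(F.mul(weighted, nn.Tensor(np.asarray(2.0, dtype=probs.dtype)))))


def _epoch_order(n, rng, shuffle):
    return rng.permutation(n) if shuffle else np.arange(n)


def init_head_from_priors(model, y, multilabel=False):
    """Initialise the classifier head at the class base rates.

    Zeroes the final 1x1 convolution's weights and sets its biases to the
    log class priors (softmax head) or prior log-odds (sigmoid head), so
    the network starts from calibrated marginal predictions instead of
    random confident ones — standard practice for class-imbalanced dense
    prediction.
    """
    y = np.asarray(y)
    k = model.n_classes
    if multilabel:
        freq = y.reshape(-1, k).mean(axis=0).astype(np.float64)
        bias = np.log((freq + 1e-8) / (1.0 - freq + 1e-8))
    else:
        freq = np.array([(y == c).mean() for c in range(k)])
        bias = np.log(freq + 1e-8)
    head = model.base.head if isinstance(model, BUNet) else model.head
    head.weight.data[:] = 0.0
    head.bias.data[:] = bias.astype(head.bias.dtype)


def fit_loop(model, X, y, *, loss_name, epochs, learning_rate, seed,
             validation=None, shuffle_within_epoch=False,
             dice_cfg=None, side_cfg=None, callback=None):
    """Train ``model`` with Adam at batch size 1; returns the history dict.

    ``loss_name`` is ``"categorical_crossentropy"`` (softmax-logit models)
    or ``"multilabel_dice"`` (sigmoid multi-label models).  With a
    :class:`~fundusseg.architectures.BUNet` the side-output losses are
    fused via ``side_cfg`` and added to the final-layer loss.
    """
    X = _as_float_batch(X)
    y = np.asarray(y)
    is_bu = isinstance(model, BUNet)
    n_classes = model.n_classes
    dice_cfg = dice_cfg or DiceLossConfig(
        n_classes=n_classes,
        class_weights=tuple(np.full(n_classes, 1.0 / n_classes)),
    )
    side_cfg = side_cfg or SideOutputConfig()
    rng = np.random.default_rng(seed)
    model.reseed_dropout(seed)
    opt = nn.Adam(model.parameters(), learning_rate=learning_rate)
    history = {"loss": [], "val_loss": [], "accuracy": [], "val_accuracy": [],
               "jaccard": [], "val_jaccard": []}

    if loss_name == "categorical_crossentropy":
        targets = _one_hot(y, n_classes)
    elif loss_name == "multilabel_dice":
        if y.ndim != 4 or y.shape[-1] != n_classes:
            raise ValueError(
                "multilabel_dice expects (n, H, W, K) binary target stacks"
            )
        targets = y.astype(np.float32)
    else:
        raise ValueError(f"unknown loss '{loss_name}'")

    def eval_batch(Xb, Tb):
        model.eval()
        losses, accs, jacs = [], [], []
        for xi, ti in zip(Xb, Tb):
            out = model.forward(xi[None])
            if is_bu:
                out = out[0]
            if loss_name == "categorical_crossentropy":
                p = F.softmax(out.data, axis=-1)
                eps = np.finfo(np.float64).tiny
                losses.append(float(-(ti * np.log(p + eps)).sum()
                                    / np.prod(ti.shape[:-1])))
                pred = p[0].argmax(axis=-1)
                true = ti.argmax(axis=-1)
            else:
                p = out.data
                from .losses_metrics import multilabel_dice_loss

                losses.append(multilabel_dice_loss(
                    p.reshape(-1, n_classes).clip(0.0, 1.0),
                    ti.reshape(-1, n_classes), dice_cfg))
                pred = (p[0] >= 0.5).astype(int)
                true = ti.astype(int)
            accs.append(float((pred == true).mean()))
            inter = np.logical_and(pred > 0, true > 0).sum()
            union = np.logical_or(pred > 0, true > 0).sum()
            jacs.append(1.0 if union == 0 else float(inter / union))
        return float(np.mean(losses)), float(np.mean(accs)), float(np.mean(jacs))

    for epoch in range(epochs):
        model.train()
        epoch_losses = []
        for idx in _epoch_order(len(X), rng, shuffle_within_epoch):
            xi = X[idx][None]
            ti = targets[idx][None]
            out = model.forward(xi)
            if loss_name == "categorical_crossentropy":
                final = out[0] if is_bu else out
                loss = F.softmax_cross_entropy(final, ti)
            else:
                if is_bu:
                    final, sides = out
                    flat_t = ti.reshape(-1, n_classes)
                    side_vals = []
                    loss = _dice_loss_graph(final, flat_t,
                                            dice_cfg.class_weights,
                                            dice_cfg.smoothing_eps)
                    for m, s in enumerate(sides[: side_cfg.n_side_outputs]):
                        sl = _dice_loss_graph(s, flat_t,
                                              dice_cfg.class_weights,
                                              dice_cfg.smoothing_eps)
                        side_vals.append(float(sl.data))
                        loss = F.add(loss, F.mul(
                            sl, nn.Tensor(np.float32(side_cfg.fusion_weights[m]))))
                    _ = side_output_loss(side_vals, side_cfg)  # recorded value
                else:
                    loss = _dice_loss_graph(out, ti.reshape(-1, n_classes),
                                            dice_cfg.class_weights,
                                            dice_cfg.smoothing_eps)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        tr_loss, tr_acc, tr_jac = eval_batch(X, targets)
        history["loss"].append(tr_loss)
        history["accuracy"].append(tr_acc)
        history["jaccard"].append(tr_jac)
        if validation is not None:
            Xv, yv = validation
            Xv = _as_float_batch(Xv)
            tv = (_one_hot(np.asarray(yv), n_classes)
                  if loss_name == "categorical_crossentropy"
                  else np.asarray(yv).astype(np.float32))
            v_loss, v_acc, v_jac = eval_batch(Xv, tv)
            history["val_loss"].append(v_loss)
            history["val_accuracy"].append(v_acc)
            history["val_jaccard"].append(v_jac)
        if callback is not None:
            callback(epoch, history)
    model.eval()
    return history


class _SegmenterBase(BaseEstimator):
    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X):
        self._check_fitted()
        X = _as_float_batch(X)
        return np.stack([self.model_.predict_proba(xi[None])[0] for xi in X])

    # -- persistence ------------------------------------------------------
    def _materialize(self, input_size):
        """Build an untrained ``model_`` for the given input size."""
        dummy = np.zeros((1,) + tuple(input_size), dtype=np.float32)
        self.model_ = self._build(dummy)
        return self.model_

    def save(self, path):
        """Store estimator parameters and network weights as an .npz."""
        self._check_fitted()
        import json

        weights = {f"w{i}": p.data
                   for i, p in enumerate(self.model_.parameters())}
        meta = json.dumps({
            "class": type(self).__name__,
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "input_size": list(self.model_.input_size),
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **weights)

    @staticmethod
    def load(path):
        import json

        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            weights = [archive[f"w{i}"]
                       for i in range(len(archive.files) - 1)]
        classes = {c.__name__: c for c in
                   (UNetSegmenter, MSUNetSegmenter, BUNetSegmenter)}
        params = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in meta["params"].items()}
        est = classes[meta["class"]](**params)
        model = est._materialize(tuple(meta["input_size"]))
        for p, w in zip(model.parameters(), weights):
            if p.data.shape != w.shape:
                raise ValueError("stored weights do not match the architecture")
            p.data = w.astype(p.data.dtype)
        model.eval()
        return est


class UNetSegmenter(_SegmenterBase):
    """Custom 6-class U-Net trained with categorical cross-entropy.

    Parameters follow the training protocol of the method: Adam with
    learning rate 1e-4, batch size 1, no shuffling within epochs, seed 42.
    """

    def __init__(self, n_classes=6, input_size=None, dropout_rate=0.1,
                 epochs=100, learning_rate=1e-4, seed=42,
                 shuffle_within_epoch=False, head_init="prior"):
        self.n_classes = n_classes
        self.input_size = input_size
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.shuffle_within_epoch = shuffle_within_epoch
        self.head_init = head_init

    def _build(self, X):
        size = self.input_size or X.shape[1:]
        return CustomUNet(input_size=size, n_classes=self.n_classes,
                          dropout_rate=self.dropout_rate, seed=self.seed)

    def fit(self, X, y, validation=None):
        X = _as_float_batch(X)
        self.model_ = self._build(X)
        if self.head_init == "prior":
            init_head_from_priors(self.model_, y, multilabel=False)
        self.history_ = fit_loop(
            self.model_, X, y, loss_name="categorical_crossentropy",
            epochs=self.epochs, learning_rate=self.learning_rate,
            seed=self.seed, validation=validation,
            shuffle_within_epoch=self.shuffle_within_epoch,
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X):
        """Per-pixel argmax class mask, ties going to the lowest class id."""
        proba = self.predict_proba(X)
        return proba.argmax(axis=-1)


class MSUNetSegmenter(_SegmenterBase):
    """Multi-scale multi-label U-Net (disc + cup) trained with the
    class-weighted Dice loss; ``predict`` thresholds each class at 0.5."""

    def __init__(self, n_classes=2, input_size=None, scales=3,
                 base_filters=8, dropout_rate=0.1, epochs=100,
                 learning_rate=1e-4, seed=42, class_weights=None,
                 threshold=0.5, shuffle_within_epoch=False,
                 head_init="prior"):
        self.n_classes = n_classes
        self.input_size = input_size
        self.scales = scales
        self.base_filters = base_filters
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.class_weights = class_weights
        self.threshold = threshold
        self.shuffle_within_epoch = shuffle_within_epoch
        self.head_init = head_init

    def _dice_cfg(self):
        w = (tuple(self.class_weights) if self.class_weights is not None
             else tuple(np.full(self.n_classes, 1.0 / self.n_classes)))
        return DiceLossConfig(n_classes=self.n_classes, class_weights=w)

    def _build(self, X):
        size = self.input_size or X.shape[1:]
        cfg = MSUNetConfig(n_classes=self.n_classes, scales=self.scales,
                           base_filters=self.base_filters, input_size=size,
                           dropout_rate=self.dropout_rate, seed=self.seed)
        return MSUNet(cfg)

    def fit(self, X, y, validation=None):
        X = _as_float_batch(X)
        self.model_ = self._build(X)
        if self.head_init == "prior":
            init_head_from_priors(self.model_, y, multilabel=True)
        self.history_ = fit_loop(
            self.model_, X, y, loss_name="multilabel_dice",
            epochs=self.epochs, learning_rate=self.learning_rate,
            seed=self.seed, validation=validation,
            shuffle_within_epoch=self.shuffle_within_epoch,
            dice_cfg=self._dice_cfg(),
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X, mode="threshold"):
        """Multi-label binary stacks (default) or argmax label masks."""
        proba = self.predict_proba(X)
        if mode == "threshold":
            return (proba >= self.threshold).astype(np.uint8)
        if mode == "argmax":
            return proba.argmax(axis=-1)
        raise ValueError("mode must be 'threshold' or 'argmax'")


class BUNetSegmenter(MSUNetSegmenter):
    """MSU-Net plus side-output deep supervision during training.

    The auxiliary heads only shape the training objective; inference uses
    the final-layer output.
    """

    def _materialize(self, input_size):
        dummy = np.zeros((1,) + tuple(input_size), dtype=np.float32)
        base = self._build(dummy)
        self.model_ = BUNet(base, BUNetConfig(
            n_side_outputs=self.n_side_outputs,
            fusion_weights=tuple(self.fusion_weights), seed=self.seed))
        return self.model_

    def __init__(self, n_classes=2, input_size=None, scales=3,
                 base_filters=8, dropout_rate=0.1, epochs=100,
                 learning_rate=1e-4, seed=42, class_weights=None,
                 threshold=0.5, shuffle_within_epoch=False,
                 head_init="prior", n_side_outputs=4,
                 fusion_weights=(0.25, 0.25, 0.25, 0.25)):
        super().__init__(n_classes=n_classes, input_size=input_size,
                         scales=scales, base_filters=base_filters,
                         dropout_rate=dropout_rate, epochs=epochs,
                         learning_rate=learning_rate, seed=seed,
                         class_weights=class_weights, threshold=threshold,
                         shuffle_within_epoch=shuffle_within_epoch,
                         head_init=head_init)
        self.n_side_outputs = n_side_outputs
        self.fusion_weights = fusion_weights

    def fit(self, X, y, validation=None):
        X = _as_float_batch(X)
        base = self._build(X)
        side_cfg = SideOutputConfig(n_side_outputs=self.n_side_outputs,
                                    fusion_weights=tuple(self.fusion_weights))
        self.model_ = BUNet(base, BUNetConfig(
            n_side_outputs=self.n_side_outputs,
            fusion_weights=tuple(self.fusion_weights), seed=self.seed))
        if self.head_init == "prior":
            init_head_from_priors(self.model_, y, multilabel=True)
        self.history_ = fit_loop(
            self.model_, X, y, loss_name="multilabel_dice",
            epochs=self.epochs, learning_rate=self.learning_rate,
            seed=self.seed, validation=validation,
            shuffle_within_epoch=self.shuffle_within_epoch,
            dice_cfg=self._dice_cfg(), side_cfg=side_cfg,
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self
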