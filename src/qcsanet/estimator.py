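"""Scikit-learn style estimator around the QCSA network.

`QCSAClassifier` follows the fit/predict contract: hyper-parameters are
constructor arguments, fitted state lives in trailing-underscore
attributes, and the class composes with ``sklearn.base.clone`` and model
selection utilities.  Input is a batch of images rather than a flat design
matrix — ``(n, H, W)`` grayscale or ``(n, H, W, 3)`` RGB arrays scaled to
[0, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .attention import AttentionConfig
from .data import balance as _balance_weights
from .data import DatasetManifest, ManifestRecord
from .layers import count_parameters
from .network import ModelConfig, build_qcsa_network, predict as _predict
from .training import TrainConfig, train as _train

__all__ = ["QCSAClassifier"]


class QCSAClassifier(BaseEstimator, ClassifierMixin):
    """Quaternion channel-spatial attention network, binary classifier.

    Parameters
    ----------
    input_size : (H, W) of the training images; default 50x50.
    block_widths : quaternion-channel widths of the four residual blocks.
        The default is the miniature CPU-scale schedule.
    attention : build the channel+spatial attention gates (False gives the
        plain quaternion residual twin).
    param_free_attention : use the parameter-free gate variant (adds zero
        learnable parameters).
    reduction_ratio, spatial_kernel : attention geometry; the ratio must
        divide every block width.
    head : 'flatten' or 'quaternion-norm' pooled-feature transition.
    encode_mode : 'gray-replicate' or 'rgb-imaginary' quaternion embedding.
    epochs, batch_size, lr, decay : optimization schedule (Adam).
    class_weight : None or 'balanced' (weights N / (2 N_label)).
    validation_fraction : share of the training data held out to select
        the best-validation-loss checkpoint (0 disables).
    random_state : seed controlling initialization, shuffling and the
        validation holdout.

    Attributes
    ----------
    network_ : the trained :class:`~qcsanet.network.QcsaNetwork`.
    history_ : per-epoch :class:`~qcsanet.training.TrainHistory`.
    classes_ : ``array([0, 1])``.
    n_parameters_ : (total, trainable) count of the fitted network.
    """

    def __init__(self, input_size=(50, 50), block_widths=(2, 4, 4, 8),
                 attention=True, param_free_attention=False,
                 reduction_ratio=2, spatial_kernel=7, head="flatten",
                 encode_mode="gray-replicate", epochs=10, batch_size=16,
                 lr=0.001, decay=1e-6, class_weight=None,
                 validation_fraction=0.1, random_state=0, verbose=0):
        self.input_size = input_size
        self.block_widths = block_widths
        self.attention = attention
        self.param_free_attention = param_free_attention
        self.reduction_ratio = reduction_ratio
        self.spatial_kernel = spatial_kernel
        self.head = head
        self.encode_mode = encode_mode
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.decay = decay
        self.class_weight = class_weight
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            input_size=tuple(self.input_size),
            block_widths=tuple(self.block_widths),
            attention=AttentionConfig(
                reduction_ratio=self.reduction_ratio,
                spatial_kernel=self.spatial_kernel,
                parameterized=not self.param_free_attention),
            use_attention=self.attention,
            head=self.head,
            seed=self.random_state,
        )

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim not in (3, 4):
            raise ValueError("X must be (n, H, W) or (n, H, W, 3) images")
        h, w = self.input_size
        if X.shape[1:3] != (h, w):
            raise ValueError(f"images must be {h}x{w}; got {X.shape[1:3]}")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        return X

    def fit(self, X, y):
        """Train on images ``X`` in [0, 1] with binary labels ``y``."""
        X = self._validate_images(X)
        y = np.asarray(y).astype(int).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("binary labels {0, 1} with both classes required")
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.random_state)
        n = len(X)
        n_val = int(round(self.validation_fraction * n))
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        class_weights = None
        if self.class_weight == "balanced":
            manifest = DatasetManifest([
                ManifestRecord("", int(t), "train") for t in y[tr_idx]])
            class_weights = _balance_weights(manifest, "class-weights")

        net = build_qcsa_network(self._model_config())
        cfg = TrainConfig(lr=self.lr, decay=self.decay,
                          batch_size=self.batch_size, epochs=self.epochs,
                          seed=self.random_state)
        net, history = _train(
            net, X[tr_idx], y[tr_idx],
            X[val_idx] if n_val else None, y[val_idx] if n_val else None,
            cfg=cfg, class_weights=class_weights,
            encode_mode=self.encode_mode, verbose=self.verbose)
        self.network_ = net
        self.history_ = history
        self.n_parameters_ = count_parameters(net)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_images(X)
        p1 = _predict(self.network_, X, encode_mode=self.encode_mode)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
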