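"""Step 2a — multi-head self-attention binary classifier over FCNs.

A single attention layer: each ROI is one token whose feature vector is its
row of the subject's input matrix (FCN adjacency or correlation matrix),
linearly projected to ``model_width = H * d_k``. The layer runs ``H`` heads
of scaled dot-product attention

    attn(Q, K) = softmax(Q K^T / sqrt(d_k)),   head = attn(Q, K) V,

concatenates the heads, applies the output projection and a one-hidden-layer
perceptron, mean-pools over tokens, and emits two-class logits. After
training, the per-subject attention distribution matrix is the element-wise
mean of the H head weight matrices, extracted with dropout disabled.

The model is implemented directly in NumPy with analytic gradients and an
Adam optimizer; the architecture is a fixed, shallow graph so reverse-mode
differentiation is written out by hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from fcnfusion.datatypes import AttentionMatrix, ConnectivityMatrix, Fcn

logger = logging.getLogger(__name__)

__all__ = [
    "AttnConfig",
    "SelfAttentionClassifier",
    "scaled_attention",
    "multi_head_forward",
    "attention_distribution",
    "train_and_extract",
]


@dataclass
class AttnConfig:
    """Hyperparameters of the attention classifier.

    Defaults follow the reference configuration: 128 heads of key dimension
    2 (model width 256), batch size 8, dropout 0.9, Adam at learning rate
    0.01, 10-fold cross-validation.
    """

    n_heads: int = 128
    d_k: int = 2
    dropout: float = 0.9
    batch_size: int = 8
    learning_rate: float = 0.01
    max_epochs: int = 100
    patience: int = 10
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heads < 1 or self.d_k < 1:
            raise ValueError("n_heads and d_k must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    @property
    def model_width(self) -> int:
        return self.n_heads * self.d_k


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, d_k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention.

    ``weights = softmax(Q K^T / sqrt(d_k))`` row-wise, ``output = weights V``.
    Works on single matrices (R, d_k) or batched stacks (..., R, d_k).
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-2] != K.shape[-2] or Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must have matching shapes")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    weights = _softmax(scores, axis=-1)
    return weights, weights @ V


def attention_distribution(per_head_weights) -> np.ndarray:
    """Element-wise mean of H row-stochastic head weight matrices."""
    heads = np.asarray(per_head_weights, dtype=float)
    if heads.ndim == 2:
        heads = heads[None]
    if heads.shape[0] == 0:
        raise ValueError("at least one attention head required")
    return heads.mean(axis=0)


class SelfAttentionClassifier:
    """Single-layer multi-head self-attention binary classifier."""

    PARAM_NAMES = (
        "W_in", "b_in", "W_q", "W_k", "W_v", "W_o", "b_o",
        "W_1", "b_1", "W_2", "b_2",
    )

    def __init__(self, n_rois: int, cfg: AttnConfig, seed: int | None = None):
        self.n_rois = n_rois
        self.cfg = cfg
        D = cfg.model_width
        rng = np.random.default_rng(cfg.seed if seed is None else seed)

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        self.params: dict[str, np.ndarray] = {
            "W_in": glorot(n_rois, D), "b_in": np.zeros(D),
            "W_q": glorot(D, D), "W_k": glorot(D, D), "W_v": glorot(D, D),
            "W_o": glorot(D, D), "b_o": np.zeros(D),
            "W_1": glorot(D, D), "b_1": np.zeros(D),
            "W_2": glorot(D, 2), "b_2": np.zeros(2),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ---- forward ---------------------------------------------------------

    def _split_heads(self, x: np.ndarray) -> np.ndarray:
        # (B, R, D) -> (B, H, R, d_k)
        B, R, _ = x.shape
        H, dk = self.cfg.n_heads, self.cfg.d_k
        return x.reshape(B, R, H, dk).transpose(0, 2, 1, 3)

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Forward pass on a batch ``X`` of shape (B, R, R).

        Returns (logits, cache); the cache holds every intermediate needed
        for the backward pass, including the per-head attention weights
        under ``"A"`` with shape (B, H, R, R).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        B, R, F = X.shape
        if R != self.n_rois or F != self.n_rois:
            raise ValueError(
                f"expected (B, {self.n_rois}, {self.n_rois}) inputs, got {X.shape}"
            )
        p = self.params
        H, dk, D = self.cfg.n_heads, self.cfg.d_k, self.cfg.model_width

        T0 = X @ p["W_in"] + p["b_in"]                      # (B, R, D)
        Qf, Kf, Vf = T0 @ p["W_q"], T0 @ p["W_k"], T0 @ p["W_v"]
        Q, K, V = (self._split_heads(a) for a in (Qf, Kf, Vf))
        A, headed = scaled_attention(Q, K, V, dk)           # (B,H,R,R), (B,H,R,dk)
        O = headed.transpose(0, 2, 1, 3).reshape(B, R, D)   # concat heads
        O2 = O @ p["W_o"] + p["b_o"]
        Z1 = O2 @ p["W_1"] + p["b_1"]
        Hh = np.maximum(Z1, 0.0)
        if train and self.cfg.dropout > 0:
            rng = dropout_rng or np.random.default_rng()
            keep = 1.0 - self.cfg.dropout
            mask = (rng.random(Hh.shape) < keep) / keep
            Hd = Hh * mask
        else:
            mask = None
            Hd = Hh
        pooled = Hd.mean(axis=1)                            # (B, D)
        logits = pooled @ p["W_2"] + p["b_2"]
        cache = dict(X=X, T0=T0, Q=Q, K=K, V=V, A=A, O=O, O2=O2,
                     Z1=Z1, Hh=Hh, mask=mask, Hd=Hd, pooled=pooled)
        return logits, cache

    # ---- loss / backward -------------------------------------------------

    @staticmethod
    def cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
        """Mean two-class cross-entropy (stable log-sum-exp form)."""
        m = logits.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
        return float(np.mean(lse - logits[np.arange(len(y)), y]))

    def backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        """Analytic gradients of the mean cross-entropy wrt all parameters."""
        p = self.params
        B, R, D = cache["T0"].shape
        H, dk = self.cfg.n_heads, self.cfg.d_k

        probs = _softmax(cache["pooled"] @ p["W_2"] + p["b_2"])
        probs[np.arange(B), y] -= 1.0
        dlogits = probs / B                                  # (B, 2)

        g: dict[str, np.ndarray] = {}
        g["W_2"] = cache["pooled"].T @ dlogits
        g["b_2"] = dlogits.sum(axis=0)
        dpooled = dlogits @ p["W_2"].T                       # (B, D)
        dHd = np.repeat(dpooled[:, None, :], R, axis=1) / R
        dHh = dHd if cache["mask"] is None else dHd * cache["mask"]
        dZ1 = dHh * (cache["Z1"] > 0)
        g["W_1"] = np.einsum("brd,bre->de", cache["O2"], dZ1)
        g["b_1"] = dZ1.sum(axis=(0, 1))
        dO2 = dZ1 @ p["W_1"].T
        g["W_o"] = np.einsum("brd,bre->de", cache["O"], dO2)
        g["b_o"] = dO2.sum(axis=(0, 1))
        dO = dO2 @ p["W_o"].T                                # (B, R, D)
        dHeaded = dO.reshape(B, R, H, dk).transpose(0, 2, 1, 3)

        A, V, Q, K = cache["A"], cache["V"], cache["Q"], cache["K"]
        dA = dHeaded @ np.swapaxes(V, -1, -2)                # (B, H, R, R)
        dV = np.swapaxes(A, -1, -2) @ dHeaded
        # softmax backward, row-wise
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS /= np.sqrt(dk)
        dQ = dS @ K
        dK = np.swapaxes(dS, -1, -2) @ Q

        def merge_heads(x: np.ndarray) -> np.ndarray:
            return x.transpose(0, 2, 1, 3).reshape(B, R, D)

        dQf, dKf, dVf = merge_heads(dQ), merge_heads(dK), merge_heads(dV)
        T0 = cache["T0"]
        g["W_q"] = np.einsum("brd,bre->de", T0, dQf)
        g["W_k"] = np.einsum("brd,bre->de", T0, dKf)
        g["W_v"] = np.einsum("brd,bre->de", T0, dVf)
        dT0 = dQf @ p["W_q"].T + dKf @ p["W_k"].T + dVf @ p["W_v"].T
        g["W_in"] = np.einsum("brf,brd->fd", cache["X"], dT0)
        g["b_in"] = dT0.sum(axis=(0, 1))
        return g

    def adam_step(self, grads: dict[str, np.ndarray],
                  beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._adam_t += 1
        lr = self.cfg.learning_rate
        t = self._adam_t
        for k, gk in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk**2
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            if not np.isfinite(self.params[k]).all():
                raise RuntimeError(f"non-finite parameter {k} after Adam step {t}")

    # ---- training --------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> list[float]:
        """Mini-batch Adam training with early stopping.

        Stops when the monitored loss (validation loss if a validation set
        is given, else training loss) fails to improve for ``patience``
        epochs; restores the best parameters. Returns the per-epoch
        monitored losses.
        """
        cfg = self.cfg
        rng = rng or np.random.default_rng(cfg.seed)
        n = len(y)
        best_loss = np.inf
        best_params: dict[str, np.ndarray] | None = None
        wait = 0
        history: list[float] = []
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits, cache = self.forward(X[idx], train=True, dropout_rng=rng)
                loss = self.cross_entropy(logits, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss at epoch {_epoch}")
                self.adam_step(self.backward(cache, y[idx]))
            if X_val is not None and len(X_val):
                logits, _ = self.forward(X_val)
                monitored = self.cross_entropy(logits, np.asarray(y_val))
            else:
                logits, _ = self.forward(X)
                monitored = self.cross_entropy(logits, y)
            history.append(monitored)
            if monitored < best_loss - 1e-6:
                best_loss = monitored
                best_params = {k: v.copy() for k, v in self.params.items()}
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        if best_params is not None:
            self.params = best_params
        return history

    def predict(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X)
        return logits.argmax(axis=1)

    def attention_matrices(self, X: np.ndarray) -> np.ndarray:
        """Per-head attention weights in evaluation mode, (B, H, R, R)."""
        _, cache = self.forward(X)
        return cache["A"]


def multi_head_forward(
    tokens: np.ndarray, model: SelfAttentionClassifier
) -> tuple[np.ndarray, np.ndarray]:
    """One subject's forward pass returning (logits, per-head weights).

    ``tokens`` is the subject's R-by-R input matrix; the H weight matrices
    come back with shape (H, R, R).
    """
    logits, cache = model.forward(tokens)
    return logits[0], cache["A"][0]


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, Fcn):
        return x.adjacency.astype(float)
    if isinstance(x, ConnectivityMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def train_and_extract(
    inputs,
    groups: list[str],
    cfg: AttnConfig,
    subject_ids: list[str] | None = None,
    roi_labels: list[str] | None = None,
) -> tuple[float, list[AttentionMatrix]]:
    """Cross-validated training plus attention-matrix extraction.

    Runs stratified k-fold cross-validation (mean held-out accuracy is the
    reported score), then trains a final model on the full cohort and feeds
    every subject through it in evaluation mode to obtain its attention
    distribution matrix.

    Parameters
    ----------
    inputs : sequence of Fcn | ConnectivityMatrix | ndarray
        One R-by-R matrix per subject.
    groups : list of str
        Group label per subject; exactly two distinct labels required.
    """
    X = np.stack([_as_matrix(m) for m in inputs])
    n, R = X.shape[0], X.shape[1]
    classes = sorted(set(groups))
    if len(classes) != 2:
        raise ValueError(f"exactly two groups required, got {classes}")
    y = np.array([classes.index(g) for g in groups])
    if subject_ids is None:
        subject_ids = [f"S{i:03d}" for i in range(n)]
    if roi_labels is None:
        first = inputs[0]
        roi_labels = (
            list(first.roi_labels)
            if isinstance(first, (Fcn, ConnectivityMatrix))
            else [f"ROI_{j + 1:03d}" for j in range(R)]
        )

    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        # early stopping monitors a validation split carved out of the
        # training fold; the held-out fold is touched only for the final
        # accuracy (otherwise epoch selection would leak into the score)
        if len(tr) >= 10 and np.bincount(y[tr]).min() >= 2:
            tr_in, val = train_test_split(
                tr, test_size=0.2, stratify=y[tr],
                random_state=cfg.seed + 500 + fold,
            )
        else:
            tr_in, val = tr, None
        model = SelfAttentionClassifier(R, cfg, seed=cfg.seed + 1000 + fold)
        model.fit(X[tr_in], y[tr_in],
                  X[val] if val is not None else None,
                  y[val] if val is not None else None,
                  rng=np.random.default_rng(cfg.seed + 2000 + fold))
        acc = float((model.predict(X[te]) == y[te]).mean())
        accs.append(acc)
        logger.info("fold %d/%d accuracy %.3f", fold + 1, cfg.cv_folds, acc)
    cv_accuracy = float(np.mean(accs))

    final = SelfAttentionClassifier(R, cfg, seed=cfg.seed + 3000)
    final.fit(X, y, rng=np.random.default_rng(cfg.seed + 4000))
    comparison = (classes[0], classes[1])
    matrices = []
    for i in range(n):
        heads = final.attention_matrices(X[i])[0]
        matrices.append(
            AttentionMatrix(
                values=attention_distribution(heads),
                subject_id=subject_ids[i],
                group=groups[i],
                roi_labels=roi_labels,
                comparison=comparison,
            )
        )
    return cv_accuracy, matrices
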