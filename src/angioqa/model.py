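"""Occlusion-outcome prediction: dense network + Monte-Carlo cross-validation.

The classifier maps relative (post/pre) QA biomarkers of an aneurysm to the
probability of the undesired six-month outcome, failure to occlude (label 1,
the positive class for every metric here).  The network is a small dense
architecture implemented directly in numpy: an input dense layer and one
hidden layer of 256 units each with Swish activation and L1-L2 weight
penalties, a 10 % dropout layer after the hidden layer, and a single sigmoid
output unit, trained with Adam (lr 1e-3) on binary cross-entropy for at most
300 epochs with early stopping on validation loss (patience 15, best weights
restored) and learning-rate reduction by 0.1 after 3 stagnant epochs.

Features are z-scored with statistics of the training split only — QA
parameters span orders of magnitude in their native units and an unscaled
fit would be dominated by the largest one.

Evaluation follows the Monte-Carlo cross-validation (MCCV) protocol:
repeated independent stratified 80/20 train/test splits (the training side
split 80/20 again into train/validation), a fresh seeded model per split,
and mean +/- sd aggregation of accuracy, AUROC (rank statistic), sensitivity,
specificity and the 0.5-threshold confusion matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .tdc import InvalidInputError

#: Default model feature set (relative post/pre values).
DEFAULT_FEATURES = ("cor", "ttp", "mtt", "ph", "auc", "max_df")
#: Extended set adding the four windowed AUC ratios.
EXTENDED_FEATURES = DEFAULT_FEATURES + ("auc_05", "auc_10", "auc_15", "auc_20")

FEATURE_SETS = {"default": DEFAULT_FEATURES, "extended": EXTENDED_FEATURES}


class TrainingError(ValueError):
    """Raised when the training set cannot support a fit (e.g. single class)."""


@dataclasses.dataclass(frozen=True)
class DNNConfig:
    hidden_width: int = 256
    n_hidden: int = 1  # hidden layers beyond the equally wide input layer
    activation: str = "swish"
    l1: float = 1e-5
    l2: float = 1e-4
    dropout_rate: float = 0.10
    learning_rate: float = 0.001
    max_epochs: int = 300
    early_stop_patience: int = 15
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise InvalidInputError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning_rate must be > 0")
        if self.activation != "swish":
            raise InvalidInputError("only the swish activation is supported")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _swish(z: np.ndarray) -> np.ndarray:
    return z * _sigmoid(z)


def _swish_grad(z: np.ndarray) -> np.ndarray:
    s = _sigmoid(z)
    return s * (1.0 + z * (1.0 - s))


class DNNClassifier:
    """Dense Swish network P(failure | features), trained with Adam + BCE.

    Not constructed directly in normal use — see :func:`build_and_train`.
    """

    def __init__(self, n_features: int, cfg: DNNConfig):
        self.cfg = cfg
        self.n_features = n_features
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD77]))
        widths = [n_features] + [cfg.hidden_width] * (1 + cfg.n_hidden) + [1]
        self.W, self.b = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._rng = rng
        self.mean_ = np.zeros(n_features)
        self.scale_ = np.ones(n_features)
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": [], "lr": []}

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        cache = {"a": [X], "z": [], "mask": None}
        a = X
        n_act = len(self.W) - 1  # all but the output layer use swish
        for li in range(n_act):
            z = a @ self.W[li] + self.b[li]
            cache["z"].append(z)
            a = _swish(z)
            cache["a"].append(a)
        if training and self.cfg.dropout_rate > 0:
            mask = self._rng.random(a.shape) >= self.cfg.dropout_rate
            a = a * mask / (1.0 - self.cfg.dropout_rate)
            cache["mask"] = mask
            cache["a"][-1] = a
        z_out = a @ self.W[-1] + self.b[-1]
        cache["z"].append(z_out)
        p = _sigmoid(z_out)
        return p, cache

    def _backward(self, p: np.ndarray, y: np.ndarray, cache) -> tuple[list, list]:
        B = y.shape[0]
        delta = (p - y[:, None]) / B  # dBCE/dz_out
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for li in range(len(self.W) - 1, -1, -1):
            a_prev = cache["a"][li]
            gW[li] = a_prev.T @ delta + self.cfg.l1 * np.sign(self.W[li]) + 2 * self.cfg.l2 * self.W[li]
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = delta @ self.W[li].T
                if li == len(self.W) - 1 and cache["mask"] is not None:
                    delta = delta * cache["mask"] / (1.0 - self.cfg.dropout_rate)
                delta = delta * _swish_grad(cache["z"][li - 1])
        return gW, gb

    def _bce(self, p: np.ndarray, y: np.ndarray) -> float:
        eps = 1e-12
        p = np.clip(p.ravel(), eps, 1 - eps)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, X_val: np.ndarray, y_val: np.ndarray) -> "DNNClassifier":
        cfg = self.cfg
        if len(np.unique(y)) < 2:
            raise TrainingError("training set contains a single class")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.mean_) / self.scale_
        Xv = (X_val - self.mean_) / self.scale_

        # Adam state
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        step = 0

        best_val = np.inf
        best_weights = None
        stale_stop = 0
        stale_lr = 0
        n = Xs.shape[0]
        order_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0D0]))

        for _epoch in range(cfg.max_epochs):
            order = order_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                p, cache = self._forward(Xs[idx], training=True)
                gW, gb = self._backward(p, y[idx], cache)
                step += 1
                for li in range(len(self.W)):
                    mW[li] = beta1 * mW[li] + (1 - beta1) * gW[li]
                    vW[li] = beta2 * vW[li] + (1 - beta2) * gW[li] ** 2
                    mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
                    vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
                    mh = mW[li] / (1 - beta1**step)
                    vh = vW[li] / (1 - beta2**step)
                    self.W[li] -= lr * mh / (np.sqrt(vh) + eps)
                    mhb = mb[li] / (1 - beta1**step)
                    vhb = vb[li] / (1 - beta2**step)
                    self.b[li] -= lr * mhb / (np.sqrt(vhb) + eps)
                epoch_loss += self._bce(p, y[idx]) * idx.size
            p_val, _ = self._forward(Xv, training=False)
            val_loss = self._bce(p_val, y_val)
            self.history["loss"].append(epoch_loss / n)
            self.history["val_loss"].append(val_loss)
            self.history["lr"].append(lr)

            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best_weights = ([w.copy() for w in self.W], [b.copy() for b in self.b])
                stale_stop = 0
                stale_lr = 0
            else:
                stale_stop += 1
                stale_lr += 1
                if stale_lr >= cfg.lr_reduce_patience:
                    lr = max(lr * cfg.lr_reduce_factor, 1e-6)
                    stale_lr = 0
                if stale_stop >= cfg.early_stop_patience:
                    break
        if best_weights is not None:
            self.W, self.b = best_weights
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of failure to occlude for each row."""
        Xs = (np.asarray(X, float) - self.mean_) / self.scale_
        p, _ = self._forward(Xs, training=False)
        return p.ravel()

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Serialize weights, standardization and config to an .npz file."""
        import json as _json

        arrays = {f"W{i}": w for i, w in enumerate(self.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.b)})
        arrays["mean"] = self.mean_
        arrays["scale"] = self.scale_
        arrays["config_json"] = np.frombuffer(
            _json.dumps(dataclasses.asdict(self.cfg)).encode(), dtype=np.uint8
        )
        arrays["feature_cols_json"] = np.frombuffer(
            _json.dumps(list(getattr(self, "feature_cols", []))).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "DNNClassifier":
        import json as _json

        data = np.load(path)
        cfg = DNNConfig(**_json.loads(bytes(data["config_json"]).decode()))
        model = cls(int(data["W0"].shape[0]), cfg)
        model.W = [data[f"W{i}"] for i in range(len(model.W))]
        model.b = [data[f"b{i}"] for i in range(len(model.b))]
        model.mean_ = data["mean"]
        model.scale_ = data["scale"]
        cols = _json.loads(bytes(data["feature_cols_json"]).decode())
        if cols:
            model.feature_cols = cols
        return model


# ---------------------------------------------------------------------------
# Splits, training entry point, metrics
# ---------------------------------------------------------------------------

def split_stratified(
    table: pd.DataFrame,
    test_frac: float = 0.2,
    val_frac_of_train: float = 0.2,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified (train, val, test) partition of the cohort table.

    80/20 train/test, then 80/20 train/validation inside the training side;
    label proportions are preserved within one sample per stratum and the
    three parts are disjoint and exhaustive.
    """
    y = table[label_col]
    trainval, test = train_test_split(
        table, test_size=test_frac, stratify=y, random_state=seed % (2**32)
    )
    train, val = train_test_split(
        trainval,
        test_size=val_frac_of_train,
        stratify=trainval[label_col],
        random_state=(seed + 1) % (2**32),
    )
    return train, val, test


def build_and_train(
    train: pd.DataFrame,
    val: pd.DataFrame,
    cfg: DNNConfig = DNNConfig(),
    feature_cols=DEFAULT_FEATURES,
    label_col: str = "label",
) -> DNNClassifier:
    """Train a classifier on the train split, early-stopped on the val split.

    Standardization statistics come from the train split only and travel with
    the model.
    """
    feature_cols = list(feature_cols)
    for df, name in ((train, "train"), (val, "val")):
        if df[feature_cols].isna().any().any():
            raise InvalidInputError(f"{name} split contains missing feature values")
    model = DNNClassifier(len(feature_cols), cfg)
    model.feature_cols = feature_cols
    model.fit(
        train[feature_cols].to_numpy(float),
        train[label_col].to_numpy(int),
        val[feature_cols].to_numpy(float),
        val[label_col].to_numpy(int),
    )
    return model


def evaluate(model: DNNClassifier, test: pd.DataFrame, label_col: str = "label") -> dict:
    """Test-set metrics with failure to occlude (label 1) as the positive class.

    AUROC is the rank (Mann-Whitney) statistic with midrank tie handling;
    the confusion matrix uses a 0.5 probability threshold.
    """
    X = test[list(model.feature_cols)].to_numpy(float)
    y = test[label_col].to_numpy(int)
    p = model.predict_proba(X)
    pred = (p >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    if len(np.unique(y)) < 2:
        auroc = np.nan
    else:
        auroc = float(roc_auc_score(y, p))
    return {
        "accuracy": (tp + tn) / max(len(y), 1),
        "auroc": auroc,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "confusion": np.array([[tn, fp], [fn, tp]]),
    }


@dataclasses.dataclass
class MCCVReport:
    """Per-split metrics and their mean +/- sd aggregates."""

    per_split: pd.DataFrame
    summary: dict[str, tuple[float, float]]
    n_splits: int

    def __str__(self):
        lines = [f"MCCV over {self.n_splits} splits"]
        for k, (m, s) in self.summary.items():
            lines.append(f"  {k:12s} {m:.3f} +/- {s:.3f}")
        return "\n".join(lines)


def mccv(
    table: pd.DataFrame,
    cfg: DNNConfig = DNNConfig(),
    feature_cols=DEFAULT_FEATURES,
    n_splits: int = 10,
    seed: int = 0,
    label_col: str = "label",
) -> MCCVReport:
    """Monte-Carlo cross-validation: independent stratified splits, a fresh
    seeded model per split, mean +/- sd aggregation."""
    split_seeds = np.random.SeedSequence([seed, 0x3CC7]).generate_state(2 * n_splits)
    rows = []
    for i in range(n_splits):
        tr, va, te = split_stratified(
            table, seed=int(split_seeds[2 * i]) % (2**31), label_col=label_col
        )
        cfg_i = dataclasses.replace(cfg, seed=int(split_seeds[2 * i + 1]) % (2**31))
        model = build_and_train(tr, va, cfg_i, feature_cols, label_col)
        m = evaluate(model, te, label_col)
        rows.append(
            {
                "split": i,
                "accuracy": m["accuracy"],
                "auroc": m["auroc"],
                "sensitivity": m["sensitivity"],
                "specificity": m["specificity"],
                "tn": m["confusion"][0, 0],
                "fp": m["confusion"][0, 1],
                "fn": m["confusion"][1, 0],
                "tp": m["confusion"][1, 1],
            }
        )
    per_split = pd.DataFrame(rows)
    summary = {
        k: (float(per_split[k].mean()), float(per_split[k].std(ddof=1)) if n_splits > 1 else 0.0)
        for k in ("accuracy", "auroc", "sensitivity", "specificity")
    }
    return MCCVReport(per_split=per_split, summary=summary, n_splits=n_splits)
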