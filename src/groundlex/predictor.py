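"""Feed-forward predictor from (textual, visual) word vectors to concept
norms.

Architecture: two input branches — textual ``d_text_in -> d_text_hidden``
and visual ``d_vis_in -> d_vis_hidden``, both ReLU — concatenated and
mapped by a linear output layer to the ``d_out`` norm attributes.  Norm
values live on a bounded real scale (0-6 by default), so the output stays
linear rather than saturating a squashing nonlinearity.  Training
minimizes mean squared error with Adam (learning rate 0.001), weights
drawn by the Glorot normalized-initialization heuristic.

Modality masking.  An absent modality is fed as a zero vector.  The
branch hidden layers deliberately carry no bias term: a zero input then
produces an exactly-zero branch activation (zero contribution at the
merge) and exactly-zero gradients for every parameter of that branch —
its input weights (zero input), and its output-layer columns (zero
activation).  Under Adam a zero gradient yields a zero update, so
training exclusively on masked items leaves the branch bit-identical to
its initialization, and predicting with a masked modality is the same
code path as predicting with an explicit all-zeros vector.  Only the
output layer has a bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkConfig",
    "PredictionModel",
    "TrainingSet",
    "NormNetRegressor",
    "VARIANT_EPOCHS",
    "init_network",
    "train_network",
    "predict_vector",
]

#: Epoch counts selected by grid search in the reference experiments
#: (lowest cross-validated MSE per model variant).
VARIANT_EPOCHS: dict[str, int] = {
    "hybrid": 19,
    "dual_coding": 17,
    "textual": 17,
    "visual": 10,
    "indirect_grounding": 20,
    "indirect_visual": 16,
}


@dataclass(frozen=True)
class NetworkConfig:
    d_text_in: int = 300
    d_vis_in: int = 2048
    d_text_hidden: int = 150
    d_vis_hidden: int = 150
    d_out: int = 65
    learning_rate: float = 0.001
    epochs: int = 20
    batch_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("d_text_in", "d_vis_in", "d_text_hidden", "d_vis_hidden", "d_out"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch_size")


@dataclass
class PredictionModel:
    """Network parameters plus the configuration that shaped them."""

    config: NetworkConfig
    W_text: np.ndarray  # (d_text_in, d_text_hidden), no bias
    W_vis: np.ndarray  # (d_vis_in, d_vis_hidden), no bias
    W_out: np.ndarray  # (d_text_hidden + d_vis_hidden, d_out)
    b_out: np.ndarray  # (d_out,)
    loss_trace: list[float] = field(default_factory=list)

    def copy(self) -> "PredictionModel":
        return PredictionModel(
            config=self.config,
            W_text=self.W_text.copy(),
            W_vis=self.W_vis.copy(),
            W_out=self.W_out.copy(),
            b_out=self.b_out.copy(),
            loss_trace=list(self.loss_trace),
        )


@dataclass
class TrainingSet:
    """Aligned training arrays; absent modalities are all-zero rows.

    ``text_mask`` / ``vis_mask`` record which items supplied each
    modality (an all-zero row with mask True is a legitimate zero
    vector and treated identically).
    """

    words: list[str]
    X_text: np.ndarray  # (n, d_text_in)
    X_vis: np.ndarray  # (n, d_vis_in)
    Y: np.ndarray  # (n, d_out)
    text_mask: np.ndarray  # (n,) bool
    vis_mask: np.ndarray  # (n,) bool

    @classmethod
    def from_items(
        cls,
        items: list[tuple[str, np.ndarray | None, np.ndarray | None, np.ndarray]],
        d_text: int,
        d_vis: int,
    ) -> "TrainingSet":
        n = len(items)
        if n == 0:
            raise ValueError("empty training set")
        d_out = np.asarray(items[0][3]).shape[0]
        X_text = np.zeros((n, d_text))
        X_vis = np.zeros((n, d_vis))
        Y = np.zeros((n, d_out))
        tm = np.zeros(n, dtype=bool)
        vm = np.zeros(n, dtype=bool)
        words = []
        for i, (w, t, v, y) in enumerate(items):
            words.append(w)
            if t is None and v is None:
                raise ValueError(f"item {w!r} has no input modality")
            if t is not None:
                t = np.asarray(t, dtype=np.float64)
                if t.shape != (d_text,):
                    raise ValueError(f"textual vector for {w!r} has shape {t.shape}, expected ({d_text},)")
                X_text[i] = t
                tm[i] = True
            if v is not None:
                v = np.asarray(v, dtype=np.float64)
                if v.shape != (d_vis,):
                    raise ValueError(f"visual vector for {w!r} has shape {v.shape}, expected ({d_vis},)")
                X_vis[i] = v
                vm[i] = True
            y = np.asarray(y, dtype=np.float64)
            if y.shape != (d_out,):
                raise ValueError(f"target for {w!r} has shape {y.shape}, expected ({d_out},)")
            Y[i] = y
        return cls(words=words, X_text=X_text, X_vis=X_vis, Y=Y, text_mask=tm, vis_mask=vm)

    def __len__(self) -> int:
        return len(self.words)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_network(cfg: NetworkConfig, seed: int) -> PredictionModel:
    """Glorot-uniform weights, zero output bias, reproducible per seed."""
    rng = np.random.default_rng(seed)
    W_text = _glorot(rng, cfg.d_text_in, cfg.d_text_hidden)
    W_vis = _glorot(rng, cfg.d_vis_in, cfg.d_vis_hidden)
    W_out = _glorot(rng, cfg.d_text_hidden + cfg.d_vis_hidden, cfg.d_out)
    b_out = np.zeros(cfg.d_out)
    return PredictionModel(config=cfg, W_text=W_text, W_vis=W_vis, W_out=W_out, b_out=b_out)


def _forward(model: PredictionModel, X_text: np.ndarray, X_vis: np.ndarray):
    h_text = np.maximum(X_text @ model.W_text, 0.0)
    h_vis = np.maximum(X_vis @ model.W_vis, 0.0)
    h = np.concatenate([h_text, h_vis], axis=1)
    return h_text, h_vis, h @ model.W_out + model.b_out


def train_network(
    model: PredictionModel,
    data: TrainingSet,
    epochs: int | None = None,
    seed: int = 0,
) -> PredictionModel:
    """Adam on minibatch MSE; returns a trained copy with a per-epoch loss trace.

    Items are reshuffled each epoch from the seeded generator.  Masked
    modalities are zero rows in the training arrays; by construction of
    the architecture they contribute nothing and receive no gradient.
    """
    cfg = model.config
    if data.X_text.shape[1] != cfg.d_text_in or data.X_vis.shape[1] != cfg.d_vis_in:
        raise ValueError("training data dimensions do not match the network config")
    if data.Y.shape[1] != cfg.d_out:
        raise ValueError(f"targets have {data.Y.shape[1]} attributes, config expects {cfg.d_out}")
    epochs = cfg.epochs if epochs is None else int(epochs)
    model = model.copy()
    rng = np.random.default_rng(seed)
    params = [model.W_text, model.W_vis, model.W_out, model.b_out]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t_step = 0
    n = len(data)
    ht = cfg.d_text_hidden
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            Xt, Xv, Y = data.X_text[idx], data.X_vis[idx], data.Y[idx]
            h_text, h_vis, pred = _forward(model, Xt, Xv)
            err = pred - Y
            b = len(idx)
            epoch_losses.append(float(np.mean(err**2)))
            # dL/dpred for L = mean over (batch, dims)
            d_pred = (2.0 / (b * cfg.d_out)) * err
            h = np.concatenate([h_text, h_vis], axis=1)
            gW_out = h.T @ d_pred
            gb_out = d_pred.sum(axis=0)
            d_h = d_pred @ model.W_out.T
            d_ht = d_h[:, :ht] * (h_text > 0.0)
            d_hv = d_h[:, ht:] * (h_vis > 0.0)
            gW_text = Xt.T @ d_ht
            gW_vis = Xv.T @ d_hv
            grads = [gW_text, gW_vis, gW_out, gb_out]
            t_step += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - cfg.beta2**t_step) / (1 - cfg.beta1**t_step)
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= cfg.beta1
                mi += (1 - cfg.beta1) * g
                vi *= cfg.beta2
                vi += (1 - cfg.beta2) * g**2
                p -= lr_t * mi / (np.sqrt(vi) + cfg.eps)
        model.loss_trace.append(float(np.mean(epoch_losses)))
    return model


def predict_vector(
    model: PredictionModel,
    textual: np.ndarray | None,
    visual: np.ndarray | None,
) -> np.ndarray:
    """Deterministic forward pass for one word; masked modality = zeros."""
    cfg = model.config
    if textual is None and visual is None:
        raise ValueError("at least one input modality is required")
    t = np.zeros(cfg.d_text_in) if textual is None else np.asarray(textual, dtype=np.float64)
    v = np.zeros(cfg.d_vis_in) if visual is None else np.asarray(visual, dtype=np.float64)
    if t.shape != (cfg.d_text_in,) or v.shape != (cfg.d_vis_in,):
        raise ValueError("input dimensions do not match the network config")
    _, _, out = _forward(model, t[None, :], v[None, :])
    return out[0]


class NormNetRegressor:
    """Scikit-learn style regressor wrapping the two-branch network.

    ``X`` is an ``(n, d_text_in + d_vis_in)`` array with the textual
    block first; an absent modality is encoded as an all-NaN block (or
    equivalently all zeros — the two are proven-identical code paths).
    ``y`` is ``(n, d_out)``.  Compatible with sklearn ``clone``, grid
    search and pipelines via ``get_params`` / ``set_params``.
    """

    def __init__(
        self,
        d_text_in: int = 300,
        d_vis_in: int = 2048,
        d_text_hidden: int = 150,
        d_vis_hidden: int = 150,
        learning_rate: float = 0.001,
        epochs: int = 20,
        batch_size: int = 32,
        random_state: int | None = None,
    ) -> None:
        self.d_text_in = d_text_in
        self.d_vis_in = d_vis_in
        self.d_text_hidden = d_text_hidden
        self.d_vis_hidden = d_vis_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # -- sklearn protocol -------------------------------------------------
    _param_names = (
        "d_text_in",
        "d_vis_in",
        "d_text_hidden",
        "d_vis_hidden",
        "learning_rate",
        "epochs",
        "batch_size",
        "random_state",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "NormNetRegressor":
        for k, val in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r} for NormNetRegressor")
            setattr(self, k, val)
        return self

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.d_text_in + self.d_vis_in:
            raise ValueError(
                f"X must have {self.d_text_in + self.d_vis_in} columns "
                f"(textual {self.d_text_in} then visual {self.d_vis_in})"
            )
        Xt = np.nan_to_num(X[:, : self.d_text_in], nan=0.0)
        Xv = np.nan_to_num(X[:, self.d_text_in :], nan=0.0)
        return Xt, Xv

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NormNetRegressor":
        Xt, Xv = self._split(X)
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != Xt.shape[0]:
            raise ValueError("X and y have inconsistent numbers of rows")
        if Xt.shape[0] == 0:
            raise ValueError("cannot fit on an empty training set")
        cfg = NetworkConfig(
            d_text_in=self.d_text_in,
            d_vis_in=self.d_vis_in,
            d_text_hidden=self.d_text_hidden,
            d_vis_hidden=self.d_vis_hidden,
            d_out=y.shape[1],
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
        )
        seed = 0 if self.random_state is None else int(self.random_state)
        model = init_network(cfg, seed=seed)
        data = TrainingSet(
            words=[str(i) for i in range(Xt.shape[0])],
            X_text=Xt,
            X_vis=Xv,
            Y=y,
            text_mask=np.any(Xt != 0, axis=1),
            vis_mask=np.any(Xv != 0, axis=1),
        )
        self.model_ = train_network(model, data, seed=seed + 1)
        self.loss_curve_ = list(self.model_.loss_trace)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("NormNetRegressor is not fitted")
        Xt, Xv = self._split(X)
        _, _, out = _forward(self.model_, Xt, Xv)
        return out

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean per-row Pearson correlation between prediction and target."""
        from .evaluation import score_predictions

        preds = self.predict(X)
        y = np.asarray(y, dtype=np.float64)
        rs = [score_predictions(p, t)[0] for p, t in zip(preds, y)]
        return float(np.nanmean(rs))


# ---------------------------------------------------------------------------
# Serialization (portable JSON layout, version-tagged)

_FORMAT_VERSION = 1


def save_model(model: PredictionModel, path) -> None:
    import json

    payload = {
        "format_version": _FORMAT_VERSION,
        "config": {
            k: getattr(model.config, k)
            for k in (
                "d_text_in",
                "d_vis_in",
                "d_text_hidden",
                "d_vis_hidden",
                "d_out",
                "learning_rate",
                "epochs",
                "batch_size",
            )
        },
        "W_text": model.W_text.tolist(),
        "W_vis": model.W_vis.tolist(),
        "W_out": model.W_out.tolist(),
        "b_out": model.b_out.tolist(),
        "loss_trace": model.loss_trace,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> PredictionModel:
    import json

    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {payload.get('format_version')}")
    cfg = NetworkConfig(**payload["config"])
    return PredictionModel(
        config=cfg,
        W_text=np.asarray(payload["W_text"], dtype=np.float64),
        W_vis=np.asarray(payload["W_vis"], dtype=np.float64),
        W_out=np.asarray(payload["W_out"], dtype=np.float64),
        b_out=np.asarray(payload["b_out"], dtype=np.float64),
        loss_trace=list(payload.get("loss_trace", [])),
    )
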