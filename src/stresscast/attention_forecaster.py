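"""Attention-augmented LSTM forecaster on the reconstructed phase space.

The model classifies the next day's stress class from a delay-embedded
stress sequence.  Its layers, in order:

* **dimension attention** — a tanh gate ``DA = tanh(X^T w_DA + b_DA)`` over
  the d embedding coordinates; the phase-space matrix is reweighted
  column-wise, ``X' = X ⊙ DA``, letting the model emphasise informative
  delay coordinates;
* an **LSTM** over the N attended phase-space vectors;
* **temporal attention** — ``TA = softmax(H w_TA + b_TA)`` over the N time
  steps, pooling the hidden states into ``I = H^T TA``;
* a softmax head giving class probabilities for day n+1.

Range forecasts are produced recursively: the predicted class is mapped back
to a representative raw level, appended to the sequence, and the model is
re-applied, m times.

The *DL-only* ablation skips reconstruction and dimension attention, feeding
the raw zero-padded sequence as scalar steps.  Everything is plain float64
numpy with hand-derived gradients and an Adam optimizer, so training is
exactly reproducible from a seed on any machine.

Inputs are zero-padded to ``max_len`` (default 44) in two ways — zeros in
front and zeros behind — and both variants are used: as separate rows during
training, and averaged at inference.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, PredictionError
from .phase_space import reconstruct
from .sequence_io import UNKNOWN, ForecastResult, LabelScheme, StressSequence

__all__ = [
    "ModelConfig",
    "AttentionForecaster",
    "pad_variants",
    "dimension_attend",
    "encode_recurrent",
    "temporal_attend",
    "classify",
    "train",
    "forecast_range_dl",
    "ablate",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the forecaster.

    ``tau`` and ``d`` fix the embedding for the phase-space path; with
    ``use_phase_space=False`` (the DL-only ablation) the raw padded sequence
    is fed as scalar steps and dimension attention is inapplicable.
    """

    num_class: int = 2
    hidden_size: int = 8
    max_len: int = 44
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 500
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    tau: int = 1
    d: int = 4
    use_phase_space: bool = True
    use_da: bool = True
    use_ta: bool = True
    min_prefix: int = 8

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.use_phase_space and self.max_len - (self.d - 1) * self.tau < 2:
            raise ValueError("max_len too short for the chosen embedding")

    @property
    def input_dim(self) -> int:
        return self.d if self.use_phase_space else 1

    @property
    def n_steps(self) -> int:
        if self.use_phase_space:
            return self.max_len - (self.d - 1) * self.tau
        return self.max_len


def ablate(config: ModelConfig, no_da: bool = False, no_ta: bool = False) -> ModelConfig:
    """Config variant with dimension and/or temporal attention removed."""
    return dataclasses.replace(
        config,
        use_da=config.use_da and not no_da,
        use_ta=config.use_ta and not no_ta,
    )


# ---------------------------------------------------------------------------
# layer primitives (stateless; also used by the model internally)
# ---------------------------------------------------------------------------


def pad_variants(levels: Sequence[float], max_len: int = 44) -> tuple[np.ndarray, np.ndarray]:
    """Zero-pad a sequence to max_len in front and in back.

    Returns ``(front_padded, back_padded)``; both equal the input when the
    sequence already has length max_len.
    """
    x = np.asarray(levels, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("cannot pad an empty sequence")
    if x.size > max_len:
        raise InsufficientDataError(f"sequence length {x.size} exceeds max_len={max_len}")
    pad = max_len - x.size
    return np.concatenate([np.zeros(pad), x]), np.concatenate([x, np.zeros(pad)])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dimension_attend(
    X: np.ndarray, w_da: np.ndarray, b_da: float
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise attention over embedding coordinates.

    ``DA = tanh(X^T w_da + b_da)`` (one gate in (-1,1) per coordinate) and
    ``X' = X ⊙ DA`` broadcast over time.  Accepts (N,d) or batched (B,N,d).
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    a = np.einsum("bnd,n->bd", X, w_da) + b_da
    DA = np.tanh(a)
    Xp = X * DA[:, None, :]
    if single:
        return Xp[0], DA[0]
    return Xp, DA


def encode_recurrent(
    Xp: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Standard LSTM over the step axis, zero initial state; returns H."""
    single = Xp.ndim == 2
    if single:
        Xp = Xp[None]
    B, N, _ = Xp.shape
    h = Wh.shape[0]
    hs = np.zeros((B, h))
    cs = np.zeros((B, h))
    H = np.empty((B, N, h))
    for t in range(N):
        z = Xp[:, t] @ Wx + hs @ Wh + b
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h : 2 * h])
        g = np.tanh(z[:, 2 * h : 3 * h])
        o = _sigmoid(z[:, 3 * h :])
        cs = f * cs + i * g
        hs = o * np.tanh(cs)
        H[:, t] = hs
    return H[0] if single else H


def temporal_attend(
    H: np.ndarray, w_ta: np.ndarray, b_ta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Softmax attention over time: TA sums to 1; I = sum_t TA_t h_t."""
    single = H.ndim == 2
    if single:
        H = H[None]
    logits = H @ w_ta + b_ta
    TA = _softmax(logits, axis=1)
    I = np.einsum("bnh,bn->bh", H, TA)
    if single:
        return I[0], TA[0]
    return I, TA


def classify(I: np.ndarray, Ws: np.ndarray, bs: np.ndarray) -> np.ndarray:
    """Softmax head: class probabilities from the pooled representation."""
    return _softmax(np.atleast_2d(I) @ Ws + bs, axis=1).squeeze()


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class AttentionForecaster:
    """Next-day stress classifier with recursive range forecasting."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.history: dict = {}
        rng = np.random.default_rng(config.seed)
        N, d, h, K = config.n_steps, config.input_dim, config.hidden_size, config.num_class

        def glorot(*shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-lim, lim, size=shape)

        self.params = {
            "w_da": glorot(N, 1).ravel(),
            "b_da": np.zeros(1),
            "Wx": glorot(d, 4 * h),
            "Wh": glorot(h, 4 * h),
            "b": np.zeros(4 * h),
            "w_ta": glorot(h, 1).ravel(),
            "b_ta": np.zeros(1),
            "Ws": glorot(h, K),
            "bs": np.zeros(K),
        }
        # forget-gate bias at 1: standard LSTM initialisation
        self.params["b"][h : 2 * h] = 1.0

    # -- encoding -----------------------------------------------------------

    def _embed(self, levels: Sequence[float]) -> np.ndarray:
        """One padded sequence -> model input matrix (n_steps, input_dim)."""
        cfg = self.config
        x = np.asarray(levels, dtype=float)
        if x.size != cfg.max_len:
            raise InsufficientDataError("sequence must be padded to max_len first")
        if cfg.use_phase_space:
            return reconstruct(x, cfg.tau, cfg.d).vectors
        return x[:, None]

    def input_rows(self, levels: Sequence[float]) -> np.ndarray:
        """Both pad variants of a (possibly short) sequence, embedded."""
        cfg = self.config
        x = np.asarray(levels, dtype=float)
        if x.size > cfg.max_len:
            x = x[-cfg.max_len :]  # sliding window over the most recent days
        front, back = pad_variants(x, cfg.max_len)
        return np.stack([self._embed(front), self._embed(back)])

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, want_cache: bool = False):
        cfg, p = self.config, self.params
        B, N, d = X.shape
        h = cfg.hidden_size
        use_da = cfg.use_da and cfg.use_phase_space
        if use_da:
            DA = np.tanh(np.einsum("bnd,n->bd", X, p["w_da"]) + p["b_da"][0])
            Xp = X * DA[:, None, :]
        else:
            DA, Xp = None, X
        hs = np.zeros((B, h))
        cs = np.zeros((B, h))
        H = np.empty((B, N, h))
        steps = []
        for t in range(N):
            z = Xp[:, t] @ p["Wx"] + hs @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_new = f * cs + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if want_cache:
                steps.append((hs, cs, i, f, g, o, tc))
            hs, cs = h_new, c_new
            H[:, t] = h_new
        if cfg.use_ta:
            TA = _softmax(H @ p["w_ta"] + p["b_ta"][0], axis=1)
        else:
            TA = np.full((B, N), 1.0 / N)
        I = np.einsum("bnh,bn->bh", H, TA)
        logits = I @ p["Ws"] + p["bs"]
        P = _softmax(logits, axis=1)
        cache = (X, DA, Xp, H, TA, I, steps) if want_cache else None
        return P, cache

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        P, _ = self._forward(X)
        return float(-np.mean(np.log(P[np.arange(len(y)), y] + 1e-300)))

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        cfg, p = self.config, self.params
        B, N, d = X.shape
        h = cfg.hidden_size
        use_da = cfg.use_da and cfg.use_phase_space
        P, cache = self._forward(X, want_cache=True)
        Xraw, DA, Xp, H, TA, I, steps = cache
        loss = float(-np.mean(np.log(P[np.arange(B), y] + 1e-300)))

        g = {k: np.zeros_like(v) for k, v in p.items()}
        dz = P.copy()
        dz[np.arange(B), y] -= 1.0
        dz /= B
        g["Ws"] = I.T @ dz
        g["bs"] = dz.sum(axis=0)
        dI = dz @ p["Ws"].T

        dH = TA[:, :, None] * dI[:, None, :]
        if cfg.use_ta:
            dTA = np.einsum("bnh,bh->bn", H, dI)
            dtl = TA * (dTA - (TA * dTA).sum(axis=1, keepdims=True))
            g["w_ta"] = np.einsum("bnh,bn->h", H, dtl)
            g["b_ta"] = np.array([dtl.sum()])
            dH += dtl[:, :, None] * p["w_ta"][None, None, :]

        dXp = np.zeros_like(Xp)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(N - 1, -1, -1):
            h_prev, c_prev, i, f, gg, o, tc = steps[t]
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * gg
            df = dc * c_prev
            dgg = dc * i
            dc_next = dc * f
            dzc = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dgg * (1 - gg * gg),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            g["Wx"] += Xp[:, t].T @ dzc
            g["Wh"] += h_prev.T @ dzc
            g["b"] += dzc.sum(axis=0)
            dXp[:, t] = dzc @ p["Wx"].T
            dh_next = dzc @ p["Wh"].T

        if use_da:
            dDA = (Xraw * dXp).sum(axis=1)  # (B, d)
            da = dDA * (1.0 - DA * DA)
            g["w_da"] = np.einsum("bnd,bd->n", Xraw, da)
            g["b_da"] = np.array([da.sum()])
        return loss, g

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        verbose: bool = False,
    ) -> dict:
        """Adam / cross-entropy training with early stopping.

        ``X`` is (rows, n_steps, input_dim), ``y`` integer classes.  A
        ``val_fraction`` split (rows held out at random, seed-controlled)
        drives early stopping with the configured patience; the parameters
        giving the best validation loss are restored.  Returns the history
        dict (also stored on the model).
        """
        cfg = self.config
        if len(X) == 0:
            raise InsufficientDataError("empty training set")
        rng = np.random.default_rng(cfg.seed + 1)
        order = rng.permutation(len(X))
        n_val = int(round(cfg.val_fraction * len(X)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(tr_idx) == 0:
            tr_idx, val_idx = order, order[:0]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_state = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        wait = 0
        history: dict = {"train_loss": [], "val_loss": [], "train_acc": []}
        for epoch in range(cfg.epochs):
            perm = rng.permutation(len(Xtr))
            ep_loss = 0.0
            for start in range(0, len(perm), cfg.batch_size):
                sel = perm[start : start + cfg.batch_size]
                loss, grads = self.loss_and_grads(Xtr[sel], ytr[sel])
                ep_loss += loss * len(sel)
                step += 1
                for k in self.params:
                    m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
                    v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = m_state[k] / (1 - beta1**step)
                    v_hat = v_state[k] / (1 - beta2**step)
                    self.params[k] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            ep_loss /= len(Xtr)
            history["train_loss"].append(ep_loss)
            P, _ = self._forward(Xtr)
            history["train_acc"].append(float(np.mean(P.argmax(axis=1) == ytr)))
            if len(Xval):
                val_loss = self.loss(Xval, yval)
            else:
                val_loss = ep_loss
            history["val_loss"].append(val_loss)
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: train {ep_loss:.4f} val {val_loss:.4f}")
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        self.params = best_params
        self.history = history
        return history

    # -- inference ----------------------------------------------------------

    def predict_proba(self, levels: Sequence[float]) -> np.ndarray:
        """Class probabilities for day n+1, averaged over both pad variants."""
        rows = self.input_rows(levels)
        P, _ = self._forward(rows)
        return P.mean(axis=0)

    def forecast_range(
        self, seq: StressSequence, m: int, scheme: LabelScheme
    ) -> ForecastResult:
        """Recursive m-day forecast.

        The predicted class is re-embedded as the representative raw level of
        that class under the active label scheme before predicting the next
        day.
        """
        if m < 1:
            raise PredictionError("horizon m must be >= 1")
        if scheme.num_class != self.config.num_class:
            raise PredictionError("label scheme does not match the model head")
        levels = list(seq.levels)
        classes: list[int] = []
        out_levels: list[int] = []
        probs = np.empty((m, self.config.num_class))
        for step in range(m):
            pr = self.predict_proba(levels)
            cls = int(np.argmax(pr))
            level = scheme.representative_level(cls)
            probs[step] = pr
            classes.append(cls)
            out_levels.append(level)
            levels.append(level)
        method = "dl-chaos" if self.config.use_phase_space else "dl"
        return ForecastResult(
            user_id=seq.user_id,
            classes=classes,
            probabilities=probs,
            levels=out_levels,
            method=method,
        )

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AttentionForecaster":
        payload = json.loads(Path(path).read_text())
        model = cls(ModelConfig(**payload["config"]))
        model.params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return model


# ---------------------------------------------------------------------------
# dataset construction and module-level convenience wrappers
# ---------------------------------------------------------------------------


def build_training_rows(
    sequences: Sequence[StressSequence],
    scheme: LabelScheme,
    config: ModelConfig,
    max_prefix: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Next-day prediction rows from every usable prefix of every sequence.

    For each prefix (first p days, ``min_prefix <= p < n``) whose next-day
    level is known, both zero-pad variants are embedded and added with the
    next day's class as target.  Days with unknown targets are skipped.
    """
    model = AttentionForecaster(config)  # embedding geometry only
    rows, targets = [], []
    for seq in sequences:
        hi = min(seq.n - 1, max_prefix if max_prefix is not None else seq.n - 1)
        for p in range(config.min_prefix, hi + 1):
            label = scheme.class_of(seq.levels[p])
            if label == UNKNOWN:
                continue
            pair = model.input_rows(seq.levels[:p])
            rows.extend(pair)
            targets.extend([label, label])
    if not rows:
        raise InsufficientDataError("no usable (prefix, next-day label) pairs")
    return np.stack(rows), np.asarray(targets, dtype=int)


def train(
    sequences: Sequence[StressSequence],
    scheme: LabelScheme,
    config: ModelConfig,
    max_prefix: int | None = None,
    verbose: bool = False,
) -> AttentionForecaster:
    """Build training rows from sequences and fit a fresh model."""
    X, y = build_training_rows(sequences, scheme, config, max_prefix)
    model = AttentionForecaster(config)
    model.fit(X, y, verbose=verbose)
    return model


def forecast_range_dl(
    model: AttentionForecaster, seq: StressSequence, m: int, scheme: LabelScheme
) -> ForecastResult:
    return model.forecast_range(seq, m, scheme)
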