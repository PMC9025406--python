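"""Recurrent visit-sequence classifiers (LSTM / vanilla RNN), pure NumPy.

Each training instance is a date-ordered sequence of visits; a visit is a
set of integer feature tokens. Token embeddings are summed (optionally
averaged) within a visit, the visit vectors are fed through a stacked
recurrent network, and the final hidden state is mapped to a sigmoid risk
score — the probability of a suicide-related event within the outcome
horizon. Training minimises binary cross-entropy with Adam, with early
stopping on validation AUROC (``patience`` epochs without improvement; the
best-validation weights are retained).

The implementation is self-contained NumPy: forward and
backward-through-time passes are hand-written, batches are right-aligned
and masked so that a sample's score does not depend on how much padding its
batch required, and everything is deterministic under a fixed seed
(single-threaded BLAS assumed for bit-reproducibility).

Default hyperparameters follow the reference configuration for this class
of model: embedding 128, hidden 128, dropout 0.2 between recurrent layers,
2 layers, input size 30,000, early-stopping patience 3; evaluation is
AUROC, equal to the Mann-Whitney pair statistic
P(score_case > score_control) + 0.5 * P(tie).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .encoding import EncodedSample


@dataclass
class ModelConfig:
    architecture: str = "lstm"  # "lstm" | "rnn"
    embed_dim: int = 128
    hidden_size: int = 128
    dropout: float = 0.2
    num_layers: int = 2
    input_size: int = 30_000
    patience: int = 3
    max_epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 64
    visit_aggregation: str = "sum"  # "sum" | "mean"
    #: dropout on the summed visit embeddings (the between-layer dropout
    #: only engages for num_layers >= 2)
    input_dropout: float = 0.0
    weight_decay: float = 0.0
    #: add a linear read-out from the pooled (sequence-summed) visit
    #: embeddings alongside the recurrent read-out. Risk that is additive
    #: on the logit scale — the standard epidemiological assumption — is
    #: then representable exactly instead of through the saturating cell
    #: state, which sharpens perturbation attributions for heavy-exposure
    #: histories.
    linear_bypass: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ("lstm", "rnn"):
            raise ValueError("architecture must be 'lstm' or 'rnn'")
        if not (0.0 <= self.dropout < 1.0) or not (0.0 <= self.input_dropout < 1.0):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if min(self.embed_dim, self.hidden_size, self.num_layers, self.input_size) <= 0:
            raise ValueError("embed_dim, hidden_size, num_layers, input_size must be > 0")
        if self.visit_aggregation not in ("sum", "mean"):
            raise ValueError("visit_aggregation must be 'sum' or 'mean'")


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def pack_batch(samples: list[EncodedSample], input_size: int):
    """Right-aligned dense batch: token lists + mask.

    Returns ``(flat_b, flat_t, flat_tok, visit_sizes, mask)`` where the flat
    arrays address every (sample, timestep, token) occurrence, and
    ``mask[b, t]`` is 1.0 where sample *b* has a real visit at step *t*.
    """
    B = len(samples)
    T = max((len(s.visits) for s in samples), default=0) or 1
    mask = np.zeros((B, T))
    fb, ft, ftok = [], [], []
    sizes = np.ones((B, T))
    for b, s in enumerate(samples):
        off = T - len(s.visits)
        for j, (_days, toks) in enumerate(s.visits):
            t = off + j
            mask[b, t] = 1.0
            sizes[b, t] = len(toks)
            for tok in toks:
                if not (1 <= tok < input_size):
                    raise ValueError(f"token index {tok} outside [1, {input_size})")
                fb.append(b)
                ft.append(t)
                ftok.append(tok)
    return (
        np.asarray(fb, dtype=np.intp),
        np.asarray(ft, dtype=np.intp),
        np.asarray(ftok, dtype=np.intp),
        sizes,
        mask,
    )


class SequenceClassifier:
    """Embedding + stacked masked LSTM/RNN + sigmoid read-out."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, H, L, V = config.embed_dim, config.hidden_size, config.num_layers, config.input_size
        G = 4 if config.architecture == "lstm" else 1
        self.params: dict[str, np.ndarray] = {}
        self.params["E"] = rng.normal(0.0, 0.1, size=(V, D))
        self.params["E"][0] = 0.0  # padding row, never referenced
        for l in range(L):
            din = D if l == 0 else H
            k = 1.0 / np.sqrt(H)
            self.params[f"Wx{l}"] = rng.uniform(-k, k, size=(din, G * H))
            self.params[f"Wh{l}"] = rng.uniform(-k, k, size=(H, G * H))
            b = np.zeros(G * H)
            if config.architecture == "lstm":
                b[H:2 * H] = 1.0  # forget-gate bias
            self.params[f"b{l}"] = b
        self.params["w_out"] = rng.uniform(-k, k, size=(H,))
        self.params["b_out"] = np.zeros(1)
        if config.linear_bypass:
            self.params["u_out"] = np.zeros(D)
        self._train_rng = np.random.default_rng(config.seed + 1)

    # -- forward ------------------------------------------------------------

    def _embed(self, batch):
        fb, ft, ftok, sizes, mask = batch
        B, T = mask.shape
        X = np.zeros((B, T, self.config.embed_dim))
        if len(fb):
            np.add.at(X, (fb, ft), self.params["E"][ftok])
        if self.config.visit_aggregation == "mean":
            X /= sizes[:, :, None]
        return X

    def _forward(self, batch, training: bool):
        cfg = self.config
        fb, ft, ftok, sizes, mask = batch
        B, T = mask.shape
        H = cfg.hidden_size
        X = self._embed(batch)
        cache = {"X0": X, "mask": mask, "drop": [], "indrop": None}
        if training and cfg.input_dropout > 0:
            keep = 1.0 - cfg.input_dropout
            indrop = (self._train_rng.random(X.shape) < keep) / keep
            X = X * indrop
            cache["indrop"] = indrop
        layer_in = X
        for l in range(cfg.num_layers):
            Wx, Wh, b = self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.zeros((B, T, H))
            m = mask[:, :, None]
            if cfg.architecture == "lstm":
                gates = np.zeros((B, T, 4 * H))
                ccand = np.zeros((B, T, H))
                cs = np.zeros((B, T, H))
                for t in range(T):
                    a = layer_in[:, t] @ Wx + h @ Wh + b
                    i = _sigmoid(a[:, :H])
                    f = _sigmoid(a[:, H:2 * H])
                    g = np.tanh(a[:, 2 * H:3 * H])
                    o = _sigmoid(a[:, 3 * H:])
                    cc = f * c + i * g
                    hh = o * np.tanh(cc)
                    mt = m[:, t]
                    h = mt * hh + (1 - mt) * h
                    c = mt * cc + (1 - mt) * c
                    gates[:, t] = np.concatenate([i, f, g, o], axis=1)
                    ccand[:, t] = cc
                    hs[:, t] = h
                    cs[:, t] = c
                cache[f"gates{l}"] = gates
                cache[f"ccand{l}"] = ccand
                cache[f"cs{l}"] = cs
            else:
                for t in range(T):
                    a = layer_in[:, t] @ Wx + h @ Wh + b
                    hh = np.tanh(a)
                    mt = m[:, t]
                    h = mt * hh + (1 - mt) * h
                    hs[:, t] = h
            cache[f"in{l}"] = layer_in
            cache[f"hs{l}"] = hs
            layer_in = hs
            if training and cfg.dropout > 0 and l < cfg.num_layers - 1:
                keep = 1.0 - cfg.dropout
                dmask = (self._train_rng.random(hs.shape) < keep) / keep
                layer_in = hs * dmask
                cache["drop"].append(dmask)
            elif l < cfg.num_layers - 1:
                cache["drop"].append(None)
            cache[f"out{l}"] = layer_in
        h_last = layer_in[:, -1]
        logits = h_last @ self.params["w_out"] + self.params["b_out"][0]
        if cfg.linear_bypass:
            pooled = cache["in0"].sum(axis=1)  # masked steps carry zero input
            logits = logits + pooled @ self.params["u_out"]
            cache["pooled"] = pooled
        cache["h_last"] = h_last
        return logits, cache

    def predict(self, samples: list[EncodedSample], batch_size: int = 512) -> np.ndarray:
        """Risk scores in [0, 1], order-preserving, deterministic."""
        out = np.empty(len(samples))
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            batch = pack_batch(chunk, self.config.input_size)
            logits, _ = self._forward(batch, training=False)
            out[start:start + len(chunk)] = _sigmoid(logits)
        return out

    # -- backward -----------------------------------------------------------

    def _backward(self, batch, cache, dlogits):
        cfg = self.config
        fb, ft, ftok, sizes, mask = batch
        B, T = mask.shape
        H = cfg.hidden_size
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["w_out"] = cache["h_last"].T @ dlogits
        grads["b_out"] = np.array([dlogits.sum()])
        d_out = np.zeros((B, T, H))
        d_out[:, -1] = np.outer(dlogits, self.params["w_out"])
        d_bypass = None
        if cfg.linear_bypass:
            grads["u_out"] = cache["pooled"].T @ dlogits
            # gradient into every (real) timestep of the first layer's input
            d_bypass = np.outer(dlogits, self.params["u_out"])[:, None, :] * mask[:, :, None]
        for l in range(cfg.num_layers - 1, -1, -1):
            if l < cfg.num_layers - 1 and cache["drop"][l] is not None:
                d_hs = d_out * cache["drop"][l]
            else:
                d_hs = d_out
            Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
            layer_in = cache[f"in{l}"]
            hs = cache[f"hs{l}"]
            m = mask[:, :, None]
            d_in = np.zeros_like(layer_in)
            dh_next = np.zeros((B, H))
            if cfg.architecture == "lstm":
                gates, ccand, cs = cache[f"gates{l}"], cache[f"ccand{l}"], cache[f"cs{l}"]
                dc_next = np.zeros((B, H))
                for t in range(T - 1, -1, -1):
                    mt = m[:, t]
                    dh = d_hs[:, t] + dh_next
                    dc = dc_next
                    i = gates[:, t, :H]
                    f = gates[:, t, H:2 * H]
                    g = gates[:, t, 2 * H:3 * H]
                    o = gates[:, t, 3 * H:]
                    cc = ccand[:, t]
                    c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H))
                    h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))
                    dhh = mt * dh
                    tc = np.tanh(cc)
                    dcc = mt * dc + dhh * o * (1 - tc ** 2)
                    do = dhh * tc
                    di = dcc * g
                    df = dcc * c_prev
                    dg = dcc * i
                    da = np.concatenate(
                        [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                        axis=1,
                    )
                    grads[f"Wx{l}"] += layer_in[:, t].T @ da
                    grads[f"Wh{l}"] += h_prev.T @ da
                    grads[f"b{l}"] += da.sum(axis=0)
                    d_in[:, t] = da @ Wx.T
                    dh_next = (1 - mt) * dh + da @ Wh.T
                    dc_next = (1 - mt) * dc + dcc * f
            else:
                for t in range(T - 1, -1, -1):
                    mt = m[:, t]
                    dh = d_hs[:, t] + dh_next
                    h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))
                    # where mt == 1, hs[:, t] is exactly tanh(a); where mt == 0
                    # the whole term is zeroed by mt anyway
                    hh = hs[:, t]
                    da = mt * dh * (1 - hh ** 2)
                    grads[f"Wx{l}"] += layer_in[:, t].T @ da
                    grads[f"Wh{l}"] += h_prev.T @ da
                    grads[f"b{l}"] += da.sum(axis=0)
                    d_in[:, t] = da @ Wx.T
                    dh_next = (1 - mt) * dh + da @ Wh.T
            d_out = d_in
        dX = d_out
        if d_bypass is not None:
            dX = dX + d_bypass
        if cache["indrop"] is not None:
            dX = dX * cache["indrop"]
        if cfg.visit_aggregation == "mean":
            dX = dX / sizes[:, :, None]
        if len(fb):
            np.add.at(grads["E"], ftok, dX[fb, ft])
        grads["E"][0] = 0.0
        return grads

    def loss_and_grads(self, samples: list[EncodedSample], labels: np.ndarray):
        """Mean binary cross-entropy and parameter gradients for one batch."""
        batch = pack_batch(samples, self.config.input_size)
        logits, cache = self._forward(batch, training=True)
        p = _sigmoid(logits)
        eps = 1e-12
        loss = -np.mean(labels * np.log(p + eps) + (1 - labels) * np.log(1 - p + eps))
        dlogits = (p - labels) / len(labels)
        return loss, self._backward(batch, cache, dlogits)


def auroc(labels, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals P(score_case > score_control) + 0.5 * P(tie) over all
    case/control pairs.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auroc needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_valid_auroc: float = float("nan")


def train_model(
    config: ModelConfig,
    train_samples: list[EncodedSample],
    valid_samples: list[EncodedSample],
) -> tuple[SequenceClassifier, TrainingLog]:
    """Fit with Adam + early stopping on validation AUROC.

    Stops after ``config.patience`` consecutive epochs without improvement
    and restores the best-validation weights.
    """
    config.validate()
    if not train_samples or not valid_samples:
        raise ValueError("empty train or validation partition")
    y_train = np.array([s.label for s in train_samples], dtype=float)
    y_valid = np.array([s.label for s in valid_samples], dtype=float)
    if len(np.unique(y_train)) < 2 or len(np.unique(y_valid)) < 2:
        raise ValueError("training and validation labels must contain both classes")

    model = SequenceClassifier(config)
    rng = np.random.default_rng(config.seed + 2)
    mstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    vstate = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    log = TrainingLog()
    best_params = None
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = model.loss_and_grads(
                [train_samples[i] for i in idx], y_train[idx]
            )
            losses.append(loss)
            step += 1
            for k, g in grads.items():
                if config.weight_decay > 0:
                    g = g + config.weight_decay * model.params[k]
                mstate[k] = b1 * mstate[k] + (1 - b1) * g
                vstate[k] = b2 * vstate[k] + (1 - b2) * g * g
                mhat = mstate[k] / (1 - b1 ** step)
                vhat = vstate[k] / (1 - b2 ** step)
                model.params[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
            model.params["E"][0] = 0.0
        val_auc = auroc(y_valid, model.predict(valid_samples))
        log.epochs.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                           "valid_auroc": val_auc})
        if best_params is None or val_auc > log.best_valid_auroc:
            log.best_valid_auroc = val_auc
            log.best_epoch = epoch
            best_params = copy.deepcopy(model.params)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.params = best_params
    return model, log


@dataclass
class RunReport:
    """AUROC across repeated seeded runs (validation and held-out test)."""

    seeds: list[int]
    valid_aurocs: list[float]
    test_aurocs: list[float]
    epochs_trained: list[int]

    @property
    def valid_mean(self) -> float:
        return float(np.mean(self.valid_aurocs))

    @property
    def valid_std(self) -> float:
        return float(np.std(self.valid_aurocs, ddof=1))

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_aurocs))

    @property
    def test_std(self) -> float:
        return float(np.std(self.test_aurocs, ddof=1))

    def to_dict(self) -> dict:
        return {
            "seeds": self.seeds,
            "valid_auroc": self.valid_aurocs,
            "test_auroc": self.test_aurocs,
            "valid_mean": self.valid_mean,
            "valid_std": self.valid_std,
            "test_mean": self.test_mean,
            "test_std": self.test_std,
            "epochs_trained": self.epochs_trained,
        }


def repeat_runs(
    config: ModelConfig,
    train_samples: list[EncodedSample],
    valid_samples: list[EncodedSample],
    test_samples: list[EncodedSample],
    n_runs: int = 10,
    seeds: list[int] | None = None,
) -> RunReport:
    """Repeat training with different seeds to estimate AUROC spread.

    Runs differ only in the RNG seed (initialisation, shuffling, dropout).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 to estimate a standard deviation")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    y_test = np.array([s.label for s in test_samples], dtype=float)
    report = RunReport([], [], [], [])
    for s in seeds:
        cfg = dataclasses.replace(config, seed=s)
        model, log = train_model(cfg, train_samples, valid_samples)
        report.seeds.append(s)
        report.valid_aurocs.append(log.best_valid_auroc)
        report.test_aurocs.append(auroc(y_test, model.predict(test_samples)))
        report.epochs_trained.append(len(log.epochs))
    return report
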