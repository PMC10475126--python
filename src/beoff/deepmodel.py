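"""Fusion-embedding recurrent regressor for the off:on-target ratio.

The guide and off-target encodings are embedded with two tables that share
the same initialisation settings, fused by elementwise summation, passed
through a stacked bidirectional LSTM, and pooled three ways -- final hidden
state, positionwise max, and additive-attention weighting -- before a fully
connected head with a sigmoid squashes the concatenated features to a ratio
in (0, 1). Training minimises a mean squared error in which each sample is
weighted by the inverse within-batch prevalence of its mutation type, so
rare off-target classes are not drowned out by the mismatch-heavy library.

Everything runs on the package's own reverse-mode autodiff core
(:mod:`beoff.autodiff`); training is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import spearmanr

from .autodiff import Tensor, concatenate, softmax_masked
from .seqrep import GuideTargetPair, encode_pairs

PAD_INDEX = 0


@dataclass
class ModelConfig:
    """Architecture and optimisation hyperparameters.

    The defaults mirror the published architecture: embedding dimension 256,
    two bidirectional LSTM layers of 512 hidden units, dropout 0.5, a fully
    connected head 3072 -> 1536 -> 1 (i.e. 6H -> 3H -> 1), and an Adam
    learning-rate ladder 1e-3 -> 1e-4 -> 1e-5 -> 5e-6 stepped down when the
    internal-validation Spearman plateaus.
    """

    embedding_dim: int = 256
    hidden_units: int = 512
    num_layers: int = 2
    dropout: float = 0.5
    attention_dim: int = 128
    lr_schedule: tuple[float, ...] = (1e-3, 1e-4, 1e-5, 5e-6)
    batch_size: int = 512
    max_epochs: int = 100
    plateau_patience: int = 3
    early_stop_patience: int = 10
    seed: int = 0

    @property
    def feature_width(self) -> int:
        # h_Last, F_MaxPool and F_AttentionPool each span 2H
        return 6 * self.hidden_units

    @property
    def head_hidden(self) -> int:
        return 3 * self.hidden_units

    @classmethod
    def small(cls, seed: int = 0) -> "ModelConfig":
        """Reduced configuration used for the synthetic benchmark and tests."""
        return cls(
            embedding_dim=32,
            hidden_units=48,
            num_layers=2,
            dropout=0.2,
            attention_dim=32,
            batch_size=256,
            max_epochs=50,
            plateau_patience=3,
            early_stop_patience=8,
            seed=seed,
        )


@dataclass
class FeatureBundle:
    """Pooled biLSTM features for one batch."""

    H: Tensor            # (B, T, 2H) per-position bidirectional states
    h_last: Tensor       # (B, 2H) final forward & backward states
    max_pool: Tensor     # (B, 2H)
    attention_pool: Tensor  # (B, 2H)
    attention_weights: np.ndarray  # (B, T), zeros on pads, rows sum to 1
    concat: Tensor       # (B, 6H)


class UninitializedModelError(RuntimeError):
    pass


def fuse_embeddings(e1: Tensor, e2: Tensor) -> Tensor:
    """Fuse the two embedded sequences by elementwise summation."""
    if e1.shape != e2.shape:
        raise ValueError(f"embedding shapes differ: {e1.shape} vs {e2.shape}")
    return e1 + e2


def weighted_mse_loss(predictions: Tensor, targets: np.ndarray, mutation_types) -> Tensor:
    """Inverse-prevalence weighted mean squared error.

    With n samples in the batch and n_k of type k (prevalence p_k = n_k / n),
    each sample of type k carries weight (1/p_k) / sum_j n_j (1/p_j) * n,
    which reduces to n / (K * n_k) for K distinct types present -- so the
    weights always average to exactly 1 within the batch.
    """
    types = np.asarray(mutation_types)
    n = len(types)
    if n == 0:
        raise ValueError("empty batch")
    if predictions.data.shape[0] != n or len(targets) != n:
        raise ValueError("predictions, targets and mutation_types must align")
    labels, counts = np.unique(types, return_counts=True)
    k = len(labels)
    per_type = {lab: n / (k * cnt) for lab, cnt in zip(labels, counts)}
    w = np.array([per_type[t] for t in types])
    resid = predictions - np.asarray(targets, dtype=float)
    return (Tensor(w) * resid * resid).mean()


def batch_type_weights(mutation_types) -> np.ndarray:
    """The per-sample weights used by :func:`weighted_mse_loss` (mean 1)."""
    types = np.asarray(mutation_types)
    labels, counts = np.unique(types, return_counts=True)
    k, n = len(labels), len(types)
    per_type = {lab: n / (k * cnt) for lab, cnt in zip(labels, counts)}
    return np.array([per_type[t] for t in types])


# ---------------------------------------------------------------------------
# model


class OffTargetModel:
    """The fusion-embedding biLSTM regressor."""

    def __init__(self, config: ModelConfig, _init: bool = True):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._trained = False
        if _init:
            self._init_params(np.random.default_rng(config.seed))

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        m, H = cfg.embedding_dim, cfg.hidden_units

        def uniform(shape, k):
            return Tensor(rng.uniform(-k, k, size=shape), requires_grad=True)

        # two embedding tables, identical initialisation settings, separate draws
        self.params["emb1"] = Tensor(rng.normal(0.0, 1.0, size=(6, m)), requires_grad=True)
        self.params["emb2"] = Tensor(rng.normal(0.0, 1.0, size=(6, m)), requires_grad=True)
        for layer in range(cfg.num_layers):
            in_dim = m if layer == 0 else 2 * H
            k = 1.0 / np.sqrt(H)
            for d in ("f", "b"):
                self.params[f"lstm{layer}{d}_Wx"] = uniform((in_dim, 4 * H), k)
                self.params[f"lstm{layer}{d}_Wh"] = uniform((H, 4 * H), k)
                bias = rng.uniform(-k, k, size=4 * H)
                bias[H:2 * H] += 1.0  # forget-gate bias
                self.params[f"lstm{layer}{d}_b"] = Tensor(bias, requires_grad=True)
        a = cfg.attention_dim
        self.params["attn_W"] = uniform((2 * H, a), 1.0 / np.sqrt(2 * H))
        self.params["attn_b"] = Tensor(np.zeros(a), requires_grad=True)
        self.params["attn_v"] = uniform((a, 1), 1.0 / np.sqrt(a))
        self.params["head_W1"] = uniform((cfg.feature_width, cfg.head_hidden), 1.0 / np.sqrt(cfg.feature_width))
        self.params["head_b1"] = Tensor(np.zeros(cfg.head_hidden), requires_grad=True)
        self.params["head_W2"] = uniform((cfg.head_hidden, 1), 1.0 / np.sqrt(cfg.head_hidden))
        self.params["head_b2"] = Tensor(np.zeros(1), requires_grad=True)

    # -- forward ------------------------------------------------------------

    def embed(self, x1: np.ndarray, x2: np.ndarray) -> Tensor:
        """Embed both token sequences and fuse them by summation."""
        e1 = self.params["emb1"].take_rows(x1)
        e2 = self.params["emb2"].take_rows(x2)
        return fuse_embeddings(e1, e2)

    def _lstm_direction(self, X: Tensor, lengths: np.ndarray, layer: int, direction: str):
        """Run one LSTM direction over (B, T, in); returns outputs and final state.

        Padded steps (t >= length) are masked so the carried state freezes at
        the last real position; the backward direction reads each sequence
        reversed within its true length.
        """
        cfg = self.config
        H = cfg.hidden_units
        B, T, _ = X.shape
        if direction == "b":
            rev = np.arange(T)[None, :].repeat(B, axis=0)
            for s in range(B):
                L = lengths[s]
                rev[s, :L] = np.arange(L - 1, -1, -1)
            X = X[np.arange(B)[:, None], rev]
        Wx = self.params[f"lstm{layer}{direction}_Wx"]
        Wh = self.params[f"lstm{layer}{direction}_Wh"]
        b = self.params[f"lstm{layer}{direction}_b"]
        in_dim = X.shape[-1]
        gates_x = X.reshape(B * T, in_dim) @ Wx + b  # precompute input projections
        gates_x = gates_x.reshape(B, T, 4 * H)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        step_mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
        outs = []
        for t in range(T):
            gates = gates_x[:, t, :] + h @ Wh
            i = gates[:, 0 * H:1 * H].sigmoid()
            f = gates[:, 1 * H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = step_mask[:, t][:, None]
            c = c_new * m + c * (1.0 - m)
            h = h_new * m + h * (1.0 - m)
            outs.append(h.reshape(B, 1, H))
        out = concatenate(outs, axis=1)  # (B, T, H)
        if direction == "b":
            out = out[np.arange(B)[:, None], rev]  # restore original positions
        return out, h

    def extract_features(self, E: Tensor, lengths: np.ndarray, train: bool = False,
                         rng: np.random.Generator | None = None) -> FeatureBundle:
        """Stacked biLSTM plus the three pooling operations."""
        lengths = np.asarray(lengths)
        if np.any(lengths <= 0):
            raise ValueError("true lengths must be positive")
        cfg = self.config
        B, T, _ = E.shape
        if np.any(lengths > T):
            raise ValueError("true_length exceeds padded length")
        X = E
        finals = None
        for layer in range(cfg.num_layers):
            out_f, fin_f = self._lstm_direction(X, lengths, layer, "f")
            out_b, fin_b = self._lstm_direction(X, lengths, layer, "b")
            X = concatenate([out_f, out_b], axis=-1)
            finals = (fin_f, fin_b)
            if train and cfg.dropout > 0 and layer < cfg.num_layers - 1:
                keep = 1.0 - cfg.dropout
                mask = (rng.random(X.shape) < keep) / keep
                X = X * mask
        Hmat = X  # (B, T, 2H)
        pad_mask = (np.arange(T)[None, :] < lengths[:, None])  # (B, T)
        h_last = concatenate(list(finals), axis=-1)  # (B, 2H)
        neg = np.where(pad_mask, 0.0, -1e30)[:, :, None]
        max_pool = (Hmat + neg).max(axis=1)
        scores = ((Hmat @ self.params["attn_W"] + self.params["attn_b"]).tanh()
                  @ self.params["attn_v"]).reshape(B, T)
        alpha = softmax_masked(scores, pad_mask, axis=-1)
        attn_pool = (alpha.reshape(B, T, 1) * Hmat).sum(axis=1)
        c = concatenate([h_last, max_pool, attn_pool], axis=-1)
        return FeatureBundle(Hmat, h_last, max_pool, attn_pool, alpha.data.copy(), c)

    def _head(self, c: Tensor, train: bool, rng: np.random.Generator | None) -> Tensor:
        cfg = self.config
        z = (c @ self.params["head_W1"] + self.params["head_b1"]).relu()
        if train and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            mask = (rng.random(z.shape) < keep) / keep
            z = z * mask
        out = z @ self.params["head_W2"] + self.params["head_b2"]
        return out.reshape(out.shape[0]).sigmoid()

    def forward(self, x1: np.ndarray, x2: np.ndarray, lengths: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        E = self.embed(x1, x2)
        bundle = self.extract_features(E, lengths, train=train, rng=rng)
        return self._head(bundle.concat, train=train, rng=rng)

    def forward_from_embedding(self, E: Tensor, lengths: np.ndarray) -> Tensor:
        """Evaluation-mode forward starting from a fused embedding matrix."""
        bundle = self.extract_features(E, lengths, train=False)
        return self._head(bundle.concat, train=False, rng=None)

    # -- prediction with webserver overrides --------------------------------

    def predict(self, pairs: list[GuideTargetPair], editor: str | None = None,
                window: tuple[int, int] = (3, 9), batch_size: int = 512) -> np.ndarray:
        """Predicted off:on ratios with the rule-based post-processing.

        A pair identical to its on-target is forced to 1; for a known editor
        (``"ABE"`` or ``"CBE"``) an off-target without an editable nucleotide
        (A resp. C) inside the editing window is forced to 0. ``window`` is
        1-based and inclusive on the protospacer.
        """
        if not self._trained:
            raise UninitializedModelError(
                "model weights are untrained; call train() or load a checkpoint, "
                "or construct with explicit weights for testing"
            )
        preds = np.empty(len(pairs))
        for start in range(0, len(pairs), batch_size):
            chunk = pairs[start:start + batch_size]
            x1, x2, lengths = encode_pairs(chunk)
            preds[start:start + len(chunk)] = self.forward(x1, x2, lengths).data
        return apply_overrides(preds, pairs, editor=editor, window=window)

    def mark_trained(self) -> None:
        """Declare the current weights usable for prediction (tests, loading)."""
        self._trained = True

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "OffTargetModel":
        with np.load(path) as data:
            raw = json.loads(bytes(data["__config__"].tobytes()).decode())
            raw["lr_schedule"] = tuple(raw["lr_schedule"])
            model = cls(ModelConfig(**raw), _init=False)
            for k in data.files:
                if k != "__config__":
                    model.params[k] = Tensor(data[k], requires_grad=True)
        model.mark_trained()
        return model


def editable_in_window(offtarget_seq: str, editor: str, window: tuple[int, int]) -> bool:
    base = {"ABE": "A", "CBE": "C"}[editor.upper()]
    lo, hi = window
    return base in offtarget_seq[lo - 1:hi]


def apply_overrides(predictions: np.ndarray, pairs: list[GuideTargetPair],
                    editor: str | None, window: tuple[int, int] = (3, 9)) -> np.ndarray:
    out = predictions.copy()
    for idx, p in enumerate(pairs):
        if p.offtarget_seq == p.guide_seq:
            out[idx] = 1.0
        elif editor is not None and not editable_in_window(p.offtarget_seq, editor, window):
            out[idx] = 0.0
    return out


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class PairDataset:
    """Aligned pairs with clipped regression targets and group labels."""

    pairs: list[GuideTargetPair]
    ratios: np.ndarray       # raw off:on ratios (may exceed 1)
    groups: np.ndarray = field(default=None)

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.groups is None:
            self.groups = np.array([p.group_id for p in self.pairs])
        if len(self.pairs) != len(self.ratios) or len(self.pairs) != len(self.groups):
            raise ValueError("pairs, ratios and groups must align")

    @property
    def targets(self) -> np.ndarray:
        """Training targets: ratios clipped to the sigmoid codomain [0, 1]."""
        return np.clip(self.ratios, 0.0, 1.0)

    @property
    def mutation_types(self) -> np.ndarray:
        return np.array([p.mutation_type for p in self.pairs])

    def __len__(self):
        return len(self.pairs)


class GroupOverlapError(ValueError):
    pass


def group_kfold(groups: np.ndarray, n_splits: int = 10, seed: int = 0):
    """Group-count-balanced k-fold splits.

    Unique on-target groups are shuffled and divided into ``n_splits`` chunks
    of (near-)equal *group count* -- 1110 groups at 10 folds give exactly 111
    test and 999 training groups per fold -- and every pair of a test group
    lands in that fold's test side. This matches the screen's splitting
    arithmetic; scikit-learn's GroupKFold balances sample counts instead.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    order = np.random.default_rng(seed).permutation(uniq)
    out = []
    for chunk in np.array_split(order, n_splits):
        test_mask = np.isin(groups, chunk)
        out.append((np.where(~test_mask)[0], np.where(test_mask)[0]))
    return out


def check_group_disjoint(groups: np.ndarray, train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    overlap = set(groups[train_idx]) & set(groups[test_idx])
    if overlap:
        raise GroupOverlapError(
            f"{len(overlap)} on-target groups appear in both partitions, e.g. "
            f"{sorted(overlap)[:3]}"
        )


def train_model(dataset: PairDataset, split: tuple[np.ndarray, np.ndarray],
                config: ModelConfig, validation_fraction: float = 0.1):
    """Train the regressor on the train side of a group-disjoint split.

    Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts with
    the learning rate, weighted training loss and internal-validation
    Spearman. The learning rate steps down the configured ladder whenever the
    validation Spearman plateaus, and training stops early once the ladder is
    exhausted and patience runs out. The best-validation weights are restored.
    """
    train_idx, test_idx = np.asarray(split[0]), np.asarray(split[1])
    check_group_disjoint(dataset.groups, train_idx, test_idx)
    rng = np.random.default_rng(config.seed)

    # carve an internal validation set out of the training groups
    train_groups = np.unique(dataset.groups[train_idx])
    n_val = max(1, int(round(validation_fraction * len(train_groups))))
    val_groups = set(rng.choice(train_groups, size=n_val, replace=False))
    is_val = np.array([dataset.groups[i] in val_groups for i in train_idx])
    val_idx = train_idx[is_val]
    fit_idx = train_idx[~is_val]

    model = OffTargetModel(config)
    x1, x2, lengths = encode_pairs(dataset.pairs)
    targets = dataset.targets
    types = dataset.mutation_types

    def predict_eval(idx: np.ndarray) -> np.ndarray:
        out = np.empty(len(idx))
        for s in range(0, len(idx), config.batch_size):
            sub = idx[s:s + config.batch_size]
            out[s:s + len(sub)] = model.forward(x1[sub], x2[sub], lengths[sub]).data
        return out

    opt = Adam(model.params, lr=config.lr_schedule[0])
    stage = 0
    best_spear, best_params, since_improve = -np.inf, None, 0
    log = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(fit_idx)
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            sub = order[s:s + config.batch_size]
            opt.zero_grad()
            pred = model.forward(x1[sub], x2[sub], lengths[sub], train=True, rng=rng)
            loss = weighted_mse_loss(pred, targets[sub], types[sub])
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_pred = predict_eval(val_idx)
        rho = spearmanr(val_pred, targets[val_idx]).statistic
        rho = -np.inf if np.isnan(rho) else float(rho)
        log.append({
            "epoch": epoch, "lr": opt.lr,
            "train_loss": epoch_loss / max(n_batches, 1),
            "val_spearman": rho,
        })
        if rho > best_spear + 1e-4:
            best_spear = rho
            best_params = {k: v.data.copy() for k, v in model.params.items()}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.plateau_patience and stage < len(config.lr_schedule) - 1:
                stage += 1
                opt.lr = config.lr_schedule[stage]
                since_improve = 0
            elif since_improve >= config.early_stop_patience:
                break
    if best_params is not None:
        for k, v in best_params.items():
            model.params[k].data = v
    model.mark_trained()
    return model, log


# ---------------------------------------------------------------------------
# integrated gradients on the embedding layer


def attribute(model: OffTargetModel, pairs: list[GuideTargetPair], steps: int = 50,
              batch_size: int = 256) -> list[np.ndarray]:
    """Per-position integrated-gradients attribution on the fused embedding.

    The path runs from the all-pad baseline embedding to the input embedding;
    a midpoint Riemann sum over ``steps`` points approximates the integral.
    Scores at each position are the attribution summed over embedding
    dimensions; each pair yields a vector of its true (unpadded) length.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not model._trained:
        raise UninitializedModelError("attribution requires trained weights")
    results: list[np.ndarray] = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        x1, x2, lengths = encode_pairs(chunk)
        E_in = model.embed(x1, x2).data
        pad = np.full_like(x1, PAD_INDEX)
        E_base = model.embed(pad, pad).data
        delta = E_in - E_base
        grad_sum = np.zeros_like(E_in)
        for k in range(steps):
            alpha = (k + 0.5) / steps
            E = Tensor(E_base + alpha * delta, requires_grad=True)
            out = model.forward_from_embedding(E, lengths)
            out.sum().backward()
            grad_sum += E.grad
        attr = (delta * grad_sum / steps).sum(axis=-1)  # (B, T)
        for row, L in zip(attr, lengths):
            results.append(row[:L].copy())
    return results


def attribution_profile(pairs: list[GuideTargetPair], scores: list[np.ndarray]) -> "pd.DataFrame":
    """Cohort attribution: per alignment column, mean score at mutated vs
    matched positions, stratified by mutation type."""
    import pandas as pd

    rows = []
    for p, sc in zip(pairs, scores):
        for col, (a, b) in enumerate(zip(p.aligned_guide, p.aligned_off)):
            rows.append({
                "mutation_type": p.mutation_type,
                "column": col,
                "mutated": a != b,
                "score": float(sc[col]),
            })
    df = pd.DataFrame(rows)
    return (
        df.groupby(["mutation_type", "column", "mutated"])["score"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
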