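"""The hybrid classifier: a dense branch over the 35 engineered features
fused with an embedding + bidirectional LSTM branch over the raw sequence.

Three ablation modes mirror the feature study:

* ``"MS"``   — manually selected features only (dense branch alone),
* ``"AE"``   — auto-embedding features only (embedding + BiLSTM alone),
* ``"MS+AE"`` — both branches, fused by concatenation (the full model).

The sequence branch embeds each residue index into a learned ``embed_dim``
vector (padding index 0 is masked) and runs an LSTM over the sequence in
both directions; the two final hidden states are concatenated. The merged
representation passes through a fully connected head ending in a single
logistic output, the probability that the peptide is an ACP. Training
minimizes binary cross-entropy with Adam and early stopping on validation
loss. The manual features are z-scored with training-set statistics that
are frozen into the trained model (molecular weight is ~10^3 while PAAC
components are ~10^-2; without scaling one feature would swamp the rest).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import (
    ChargeParams,
    PAACParams,
    featurize_dataset,
    index_encode,
    manual_features,
)
from .io import LabeledDataset, Peptide
from .nn import LSTM, Adam, Dense, Dropout, Embedding, bce_loss, sigmoid

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1
MODES = ("MS", "AE", "MS+AE")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults: 50-dimensional embedding, 64 LSTM units per direction,
    dense branch 64->32, merged head 64->32->1, dropout 0.3, Adam at 1e-3,
    batch size 32, up to 200 epochs with patience 20. All knobs are
    exposed so the architecture can be reshaped freely.
    """

    mode: str = "MS+AE"
    max_len: int = 100
    embed_dim: int = 50
    rnn_units: int = 64
    ms_dense: tuple[int, int] = (64, 32)
    head_dense: tuple[int, int] = (64, 32)
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    threshold: float = 0.5
    n_manual: int = 35

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.max_len < 1 or self.embed_dim < 1 or self.rnn_units < 1:
            raise ValueError("max_len, embed_dim and rnn_units must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def uses_manual(self) -> bool:
        return "MS" in self.mode

    @property
    def uses_sequence(self) -> bool:
        return "AE" in self.mode


@dataclass(frozen=True)
class Prediction:
    """Score (ACP probability) and thresholded label for one peptide."""

    id: str
    score: float
    label: int  # 1 iff score strictly exceeds the threshold


def _reverse_padded(idx: np.ndarray) -> np.ndarray:
    """Reverse the valid (non-zero) prefix of each row, keeping trailing
    padding in place, so the backward LSTM reads residues last-to-first."""
    rev = np.zeros_like(idx)
    for b in range(idx.shape[0]):
        L = int((idx[b] > 0).sum())
        rev[b, :L] = idx[b, :L][::-1]
    return rev


class HybridNet:
    """The computation graph; parameters initialized from ``config.seed``."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.layers: dict[str, object] = {}
        merged_in = 0
        if config.uses_manual:
            d1, d2 = config.ms_dense
            self.layers["ms1"] = Dense(rng, config.n_manual, d1, relu=True)
            self.layers["ms2"] = Dense(rng, d1, d2, relu=True)
            merged_in += d2
        if config.uses_sequence:
            self.layers["embed"] = Embedding(rng, 21, config.embed_dim)
            self.layers["lstm_f"] = LSTM(rng, config.embed_dim, config.rnn_units)
            self.layers["lstm_b"] = LSTM(rng, config.embed_dim, config.rnn_units)
            merged_in += 2 * config.rnn_units
        h1, h2 = config.head_dense
        self.layers["head1"] = Dense(rng, merged_in, h1, relu=True)
        self.layers["head2"] = Dense(rng, h1, h2, relu=True)
        self.layers["out"] = Dense(rng, h2, 1, relu=False)
        self.drop = Dropout(config.dropout)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}/{k}": v
            for name, layer in self.layers.items()
            for k, v in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}/{k}": v
            for name, layer in self.layers.items()
            for k, v in layer.grads.items()
        }

    def zero_grad(self) -> None:
        for layer in self.layers.values():
            layer.zero_grad()

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # -- forward / backward -------------------------------------------------
    def forward(
        self,
        Xm: np.ndarray | None,
        Xe: np.ndarray | None,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Returns (logits, penultimate activations, cache). ``rng`` enables
        dropout (training); pass None for deterministic inference."""
        cfg = self.config
        cache: dict = {}
        parts = []
        if cfg.uses_manual:
            a1, cache["ms1"] = self.layers["ms1"].forward(Xm)
            a1, cache["ms_drop"] = self.drop.forward(a1, rng)
            a2, cache["ms2"] = self.layers["ms2"].forward(a1)
            parts.append(a2)
        if cfg.uses_sequence:
            mask = (Xe > 0).astype(float)
            emb_f, idx_f = self.layers["embed"].forward(Xe)
            h_f, cache["lstm_f"] = self.layers["lstm_f"].forward(emb_f, mask)
            rev = _reverse_padded(Xe)
            emb_b, idx_b = self.layers["embed"].forward(rev)
            h_b, cache["lstm_b"] = self.layers["lstm_b"].forward(emb_b, mask)
            cache["seq"] = (emb_f, idx_f, emb_b, idx_b)
            parts.append(np.concatenate([h_f, h_b], axis=1))
        merged = np.concatenate(parts, axis=1)
        cache["split"] = [p.shape[1] for p in parts]
        g1, cache["head1"] = self.layers["head1"].forward(merged)
        g1, cache["head_drop"] = self.drop.forward(g1, rng)
        penult, cache["head2"] = self.layers["head2"].forward(g1)
        logits, cache["out"] = self.layers["out"].forward(penult)
        return logits[:, 0], penult, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> None:
        cfg = self.config
        dpen = self.layers["out"].backward(dlogits[:, None], cache["out"])
        dg1 = self.layers["head2"].backward(dpen, cache["head2"])
        dg1 = Dropout.backward(dg1, cache["head_drop"])
        dmerged = self.layers["head1"].backward(dg1, cache["head1"])
        splits = np.cumsum(cache["split"])[:-1]
        parts = np.split(dmerged, splits, axis=1)
        i = 0
        if cfg.uses_manual:
            da2 = parts[i]
            i += 1
            da1 = self.layers["ms2"].backward(da2, cache["ms2"])
            da1 = Dropout.backward(da1, cache["ms_drop"])
            self.layers["ms1"].backward(da1, cache["ms1"])
        if cfg.uses_sequence:
            dh = parts[i]
            H = cfg.rnn_units
            emb_f, idx_f, emb_b, idx_b = cache["seq"]
            dXf = self.layers["lstm_f"].backward(dh[:, :H], emb_f, cache["lstm_f"])
            dXb = self.layers["lstm_b"].backward(dh[:, H:], emb_b, cache["lstm_b"])
            self.layers["embed"].backward(dXf, idx_f)
            self.layers["embed"].backward(dXb, idx_b)


@dataclass
class TrainedModel:
    """A trained hybrid classifier plus everything needed to reuse it:
    config, weights, per-epoch history, and the frozen z-scoring statistics
    of the manual features."""

    config: ModelConfig
    net: HybridNet
    history: dict[str, list[float]]
    manual_mean: np.ndarray
    manual_std: np.ndarray
    paac_params: PAACParams = field(default_factory=PAACParams)
    charge_params: ChargeParams = field(default_factory=ChargeParams)

    # -- low-level scoring on featurized matrices ---------------------------
    def score_matrices(
        self, Xm: np.ndarray | None, Xe: np.ndarray | None
    ) -> np.ndarray:
        if self.config.uses_manual:
            Xm = (Xm - self.manual_mean) / self.manual_std
        logits, _, _ = self.net.forward(Xm, Xe, rng=None)
        return sigmoid(logits)

    def _featurize(
        self, peptides: Sequence[Peptide]
    ) -> tuple[np.ndarray | None, np.ndarray | None]:
        Xm = None
        Xe = None
        if self.config.uses_manual:
            Xm = np.array(
                [
                    manual_features(p.seq, self.paac_params, self.charge_params).to_array()
                    for p in peptides
                ]
            )
        if self.config.uses_sequence:
            Xe = np.array(
                [index_encode(p.seq, self.config.max_len).indices for p in peptides]
            )
        return Xm, Xe

    # -- public API ---------------------------------------------------------
    def predict(
        self, peptides: Sequence[Peptide], threshold: float | None = None
    ) -> list[Prediction]:
        """Score each peptide; label 1 (ACP) iff score strictly exceeds the
        threshold, so a score of exactly 0.5 is called non-ACP."""
        threshold = self.config.threshold if threshold is None else threshold
        Xm, Xe = self._featurize(peptides)
        scores = self.score_matrices(Xm, Xe)
        return [
            Prediction(id=p.id, score=float(s), label=int(s > threshold))
            for p, s in zip(peptides, scores)
        ]

    def extract_inner(self, peptides: Sequence[Peptide]) -> np.ndarray:
        """Activations of the layer just before the output unit ("media
        vectors"), one row per peptide — the representation used for 2-D
        visualization of class separation."""
        Xm, Xe = self._featurize(peptides)
        if self.config.uses_manual:
            Xm = (Xm - self.manual_mean) / self.manual_std
        _, penult, _ = self.net.forward(Xm, Xe, rng=None)
        return penult

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: weights + config + normalization
        statistics + format version."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.config),
            "history": self.history,
            "paac": {"lam": self.paac_params.lam, "w": self.paac_params.w},
            "charge_ph": self.charge_params.ph,
        }
        arrays = {f"param::{k}": v for k, v in self.net.parameters().items()}
        np.savez(
            Path(path),
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            manual_mean=self.manual_mean,
            manual_std=self.manual_std,
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"checkpoint format version {meta.get('format_version')} "
                    f"not supported (expected {CHECKPOINT_FORMAT_VERSION})"
                )
            cfg_dict = meta["config"]
            cfg_dict["ms_dense"] = tuple(cfg_dict["ms_dense"])
            cfg_dict["head_dense"] = tuple(cfg_dict["head_dense"])
            config = ModelConfig(**cfg_dict)
            net = HybridNet(config)
            params = net.parameters()
            for key in data.files:
                if key.startswith("param::"):
                    name = key[len("param::") :]
                    params[name][...] = data[key]
            model = cls(
                config=config,
                net=net,
                history=meta["history"],
                manual_mean=data["manual_mean"],
                manual_std=data["manual_std"],
                paac_params=PAACParams(lam=meta["paac"]["lam"], w=meta["paac"]["w"]),
                charge_params=ChargeParams(ph=meta["charge_ph"]),
            )
        return model


def build(config: ModelConfig) -> HybridNet:
    """Construct an untrained network for the configured ablation mode."""
    return HybridNet(config)


def _epoch_eval(
    net: HybridNet, Xm: np.ndarray | None, Xe: np.ndarray | None, y: np.ndarray
) -> tuple[float, float]:
    logits, _, _ = net.forward(Xm, Xe, rng=None)
    loss, _ = bce_loss(logits, y)
    acc = float(np.mean((sigmoid(logits) > 0.5) == y))
    return loss, acc


def train(
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: ModelConfig,
    net: HybridNet | None = None,
    paac_params: PAACParams | None = None,
    charge_params: ChargeParams | None = None,
) -> TrainedModel:
    """Train the hybrid classifier.

    ``train_data``/``val_data`` are ``(manual, encoded, labels)`` triples as
    produced by :func:`acpfuse.features.featurize_dataset`. Minimizes binary
    cross-entropy with Adam; stops early when validation loss has not
    improved for ``config.patience`` epochs and restores the best-epoch
    weights. Deterministic for a fixed seed (single-threaded numpy).
    """
    Xm_tr, Xe_tr, y_tr = train_data
    Xm_va, Xe_va, y_va = val_data
    if len(y_tr) == 0:
        raise ValueError("empty training set")
    if len(y_va) == 0:
        raise ValueError("empty validation set")
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set must contain both classes")

    mean = Xm_tr.mean(axis=0)
    std = Xm_tr.std(axis=0)
    std[std == 0.0] = 1.0
    if config.uses_manual:
        Xm_tr_n = (Xm_tr - mean) / std
        Xm_va_n = (Xm_va - mean) / std
    else:
        Xm_tr_n = Xm_va_n = None
    if not config.uses_sequence:
        Xe_tr = Xe_va = None

    net = net or HybridNet(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)  # shuffling + dropout stream

    n = len(y_tr)
    y_tr = y_tr.astype(float)
    y_va = y_va.astype(float)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    best_loss = np.inf
    best_params: dict[str, np.ndarray] | None = None
    best_epoch = -1
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            bXm = Xm_tr_n[batch] if Xm_tr_n is not None else None
            bXe = Xe_tr[batch] if Xe_tr is not None else None
            net.zero_grad()
            logits, _, cache = net.forward(bXm, bXe, rng=rng)
            loss, dlogits = bce_loss(logits, y_tr[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            net.backward(dlogits, cache)
            opt.step(net.gradients())

        tr_loss, tr_acc = _epoch_eval(net, Xm_tr_n, Xe_tr, y_tr)
        va_loss, va_acc = _epoch_eval(net, Xm_va_n, Xe_va, y_va)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        logger.debug(
            "epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
            epoch, tr_loss, tr_acc, va_loss, va_acc,
        )
        if va_loss < best_loss:
            best_loss = va_loss
            best_params = copy.deepcopy(net.parameters())
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    if best_params is not None:
        for k, v in net.parameters().items():
            v[...] = best_params[k]

    return TrainedModel(
        config=config,
        net=net,
        history=history,
        manual_mean=mean,
        manual_std=std,
        paac_params=paac_params or PAACParams(),
        charge_params=charge_params or ChargeParams(),
    )


def train_on_datasets(
    train_ds: LabeledDataset,
    val_ds: LabeledDataset,
    config: ModelConfig,
    paac_params: PAACParams | None = None,
    charge_params: ChargeParams | None = None,
) -> TrainedModel:
    """Convenience wrapper: featurize two labeled datasets (max_len taken
    from the config) and train."""
    tr = featurize_dataset(train_ds, paac_params, charge_params, max_len=config.max_len)
    va = featurize_dataset(val_ds, paac_params, charge_params, max_len=config.max_len)
    return train(tr, va, config, paac_params=paac_params, charge_params=charge_params)
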