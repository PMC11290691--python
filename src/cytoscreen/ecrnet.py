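"""Contrastive ROI classifier with a labeled memory bank and momentum encoder.

A query encoder maps each ROI canvas to (a) class logits and (b) an
L2-normalized embedding.  A second, *momentum* encoder — updated as an
exponential moving average of the query encoder, never by gradients —
produces "key" embeddings that are pushed with their labels into a
fixed-capacity FIFO memory bank.  Two instances with the same label form
a positive pair regardless of staining style, so the label-contrastive
loss

    L_con = -log [ sum_{i: y_i = y} exp(sim(q, k_i)/tau)
                   / sum_i exp(sim(q, k_i)/tau) ]

pulls same-class embeddings together across the whole bank.  Similarity
is cosine (dot product of unit vectors).  The training objective is

    L_total = L_cla + beta * L_con

with L_cla the ordinary cross-entropy of the classifier head.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn

BENIGN, MALIGNANT = "benign", "malignant"
LABEL_TO_INT = {BENIGN: 0, MALIGNANT: 1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


class NoPositiveKeyError(ValueError):
    """Raised when the bank holds no key sharing the query's label."""


@dataclass(frozen=True)
class ContrastConfig:
    tau: float = 0.07
    m: float = 0.9
    beta_loss: float = 0.5
    sim: str = "cosine"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 <= self.m < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.beta_loss < 0:
            raise ValueError("beta_loss must be >= 0")


@dataclass
class LabeledKey:
    embedding: np.ndarray
    label: int


class MemoryBank:
    """Fixed-capacity FIFO of (embedding, label) pairs, index-aligned."""

    def __init__(self, capacity: int = 4096):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._queue: deque[LabeledKey] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._queue)

    def enqueue(self, keys) -> "MemoryBank":
        """Append keys in order; oldest entries are evicted past capacity.

        Non-normalized embeddings are normalized with a warning.
        """
        for key in keys:
            if isinstance(key, tuple):
                key = LabeledKey(np.asarray(key[0], dtype=np.float64), int(key[1]))
            emb = np.asarray(key.embedding, dtype=np.float64)
            norm = np.linalg.norm(emb)
            if abs(norm - 1.0) > 1e-6:
                warnings.warn("memory-bank key was not unit-norm; normalizing")
                emb = emb / (norm + 1e-12)
            self._queue.append(LabeledKey(emb, int(key.label)))
        return self

    @property
    def embeddings(self) -> np.ndarray:
        if not self._queue:
            return np.zeros((0, 0))
        return np.stack([k.embedding for k in self._queue])

    @property
    def labels(self) -> np.ndarray:
        return np.array([k.label for k in self._queue], dtype=int)


def momentum_update(theta_k, theta_q, m: float):
    """EMA update theta_k <- m * theta_k + (1 - m) * theta_q (elementwise)."""
    if not 0.0 <= m < 1.0:
        raise ValueError("momentum must lie in [0, 1)")
    tk = np.asarray(theta_k, dtype=np.float64)
    tq = np.asarray(theta_q, dtype=np.float64)
    if tk.shape != tq.shape:
        raise ValueError("parameter shape mismatch")
    return m * tk + (1.0 - m) * tq


def label_contrastive_loss(q, y, bank: MemoryBank,
                           cfg: ContrastConfig = ContrastConfig()) -> float:
    """Label-supervised contrastive loss of query `q` against the bank.

    Nonnegative; exactly 0 when every bank key shares label `y`; equals
    -log(n_pos / n) whenever all similarities are equal.
    """
    if len(bank) == 0:
        raise NoPositiveKeyError("memory bank is empty")
    labels = bank.labels
    pos = labels == int(y)
    if not pos.any():
        raise NoPositiveKeyError(f"no key with label {y} in bank")
    q = np.asarray(q, dtype=np.float64)
    if cfg.sim == "cosine":
        q = q / (np.linalg.norm(q) + 1e-12)
    sims = bank.embeddings @ q
    z = sims / cfg.tau
    zmax = z.max()
    log_all = np.log(np.exp(z - zmax).sum()) + zmax
    log_pos = np.log(np.exp(z[pos] - zmax).sum()) + zmax
    return float(log_all - log_pos)


def classifier_loss(probs, labels, eps: float = 1e-12) -> float:
    """Mean cross-entropy -1/|Q| sum log p[true class]."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    p_true = np.clip(probs[np.arange(len(labels)), labels], eps, 1.0)
    return float(-np.log(p_true).mean())


def total_cls_loss(l_cla: float, l_con: float, beta_loss: float = 0.5) -> float:
    """Combined objective L_cla + beta * L_con."""
    return float(l_cla) + float(beta_loss) * float(l_con)


# ---------------------------------------------------------------------
# encoder network
# ---------------------------------------------------------------------

class RoiEncoder(nn.Module):
    """Compact convolutional encoder: conv/pool stages, GAP, two heads.

    A deeper VGG-style stack can be requested with n_stages; the default
    is sized for CPU-scale experiments.
    """

    def __init__(self, base_channels: int = 8, embed_dim: int = 128,
                 n_classes: int = 2, n_stages: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = [
            nn.Conv2d(3 if s == 0 else base_channels * 2 ** (s - 1),
                      base_channels * 2**s, 3, rng)
            for s in range(n_stages)
        ]
        feat = base_channels * 2 ** (n_stages - 1)
        self.proj = nn.Linear(feat, embed_dim, rng)
        self.cls = nn.Linear(feat, n_classes, rng)

    def __call__(self, x: nn.Tensor):
        """Return (logits, unit-norm embedding)."""
        h = x
        for conv in self.convs:
            h = nn.maxpool2(conv(h).relu())
        f = nn.global_avg_pool(h)
        logits = self.cls(f)
        emb = self.proj(f)
        norm = ((emb * emb).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        return logits, emb / norm


def _contrastive_graph(emb: nn.Tensor, labels: np.ndarray, bank: MemoryBank,
                       tau: float) -> nn.Tensor:
    """Mean label-contrastive loss over a batch, differentiable in emb."""
    bank_e = nn.Tensor(bank.embeddings.astype(emb.data.dtype))
    bank_y = bank.labels
    z = (emb @ bank_e.transpose(1, 0)) * (1.0 / tau)  # (B, n)
    shift = nn.Tensor(z.data.max(axis=1, keepdims=True))
    ez = (z - shift).exp()
    pos_mask = (labels[:, None] == bank_y[None, :]).astype(emb.data.dtype)
    log_all = ez.sum(axis=1).log()
    log_pos = (ez * nn.Tensor(pos_mask)).sum(axis=1).log()
    return (log_all - log_pos).mean()


# ---------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------

@dataclass
class ClassifierOutput:
    probabilities: np.ndarray  # over (benign, malignant)
    label: str


def _prep_rois(rois, input_size: int) -> np.ndarray:
    """Stack ROI canvases into a (N, 3, s, s) float batch in [0, 1]."""
    arrs = []
    for r in rois:
        a = r.canvas if hasattr(r, "canvas") else np.asarray(r)
        if a.shape[0] != input_size or a.shape[1] != input_size:
            a = resize(a, (input_size, input_size), order=1, preserve_range=True,
                       anti_aliasing=a.shape[0] > input_size)
        arrs.append(a.astype(np.float32) / 255.0)
    return np.stack(arrs).transpose(0, 3, 1, 2)


class ClumpClassifier:
    """Model object for the contrastive ROI-classification stage."""

    def __init__(self, input_size: int = 64, base_channels: int = 8,
                 embed_dim: int = 128, n_classes: int = 2, n_stages: int = 4,
                 tau: float = 0.07, momentum: float = 0.9, beta_loss: float = 0.5,
                 bank_capacity: int = 4096, lr: float = 5e-3,
                 batch_size: int = 32, seed: int = 0):
        self.config = dict(input_size=input_size, base_channels=base_channels,
                           embed_dim=embed_dim, n_classes=n_classes,
                           n_stages=n_stages, tau=tau, momentum=momentum,
                           beta_loss=beta_loss, bank_capacity=bank_capacity,
                           lr=lr, batch_size=batch_size, seed=seed)
        self.contrast = ContrastConfig(tau=tau, m=momentum, beta_loss=beta_loss)
        self.input_size = input_size
        self.n_classes = n_classes
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed
        self.encoder = RoiEncoder(base_channels, embed_dim, n_classes, n_stages, seed)
        self.key_encoder = RoiEncoder(base_channels, embed_dim, n_classes, n_stages, seed)
        self.key_encoder.load_state_dict(self.encoder.state_dict())
        self.bank = MemoryBank(bank_capacity)
        self.canvas_size: int | None = None

    def fit(self, rois, labels=None, epochs: int = 10, seed: int | None = None,
            val_rois=None, val_labels=None, verbose: bool = False) -> "ClassificationResults":
        """Train query encoder by Adam; key encoder follows by EMA.

        Per step: encode queries, compute cross-entropy plus (once the
        bank holds every class) the label-contrastive term, update the
        query net, EMA-update the key net, and enqueue the batch's key
        embeddings with their labels.
        """
        if labels is None:
            labels = [r.label for r in rois]
        y = np.array([LABEL_TO_INT.get(l, l) for l in labels], dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed + 1)
        first = rois[0].canvas if hasattr(rois[0], "canvas") else np.asarray(rois[0])
        self.canvas_size = int(first.shape[0])
        x = _prep_rois(rois, self.input_size)
        opt = nn.Adam(self.encoder.parameters(), lr=self.lr)
        history = {"loss": [], "cls_loss": [], "con_loss": [], "val_accuracy": []}
        n = x.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            ep = {"loss": [], "cls": [], "con": []}
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = nn.Tensor(x[idx])
                yb = y[idx]
                logits, emb = self.encoder(xb)
                onehot = np.zeros((len(idx), self.n_classes), dtype=np.float32)
                onehot[np.arange(len(idx)), yb] = 1.0
                l_cla = -(nn.Tensor(onehot) * nn.log_softmax(logits, axis=1)).sum() * (
                    1.0 / len(idx)
                )
                warm = len(self.bank) > 0 and all(
                    (self.bank.labels == c).any() for c in range(self.n_classes)
                )
                if warm and self.contrast.beta_loss > 0:
                    l_con = _contrastive_graph(emb, yb, self.bank, self.contrast.tau)
                    loss = l_cla + l_con * self.contrast.beta_loss
                    ep["con"].append(l_con.item())
                else:
                    loss = l_cla
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep["cls"].append(l_cla.item())
                ep["loss"].append(loss.item())
                # EMA update of the key encoder, then enqueue fresh keys
                for pk, pq in zip(self.key_encoder.parameters(),
                                  self.encoder.parameters()):
                    pk.data = momentum_update(pk.data, pq.data, self.contrast.m).astype(
                        pk.data.dtype
                    )
                _, key_emb = self.key_encoder(xb)
                self.bank.enqueue(
                    [LabeledKey(e, int(lbl)) for e, lbl in zip(key_emb.data, yb)]
                )
            history["loss"].append(float(np.mean(ep["loss"])))
            history["cls_loss"].append(float(np.mean(ep["cls"])))
            history["con_loss"].append(float(np.mean(ep["con"])) if ep["con"] else None)
            if val_rois is not None:
                history["val_accuracy"].append(
                    self._accuracy(val_rois, val_labels)
                )
            if verbose:
                print(f"epoch {epoch + 1}/{epochs} loss={history['loss'][-1]:.4f}")
        return ClassificationResults(model=self, history=history)

    def _accuracy(self, rois, labels) -> float:
        y = np.array([LABEL_TO_INT.get(l, l) for l in labels], dtype=int)
        pred = np.array([LABEL_TO_INT[self.classify(r).label] for r in rois])
        return float((pred == y).mean())

    def predict_proba(self, rois) -> np.ndarray:
        x = _prep_rois(rois, self.input_size)
        out = []
        for start in range(0, x.shape[0], 256):
            logits, _ = self.encoder(nn.Tensor(x[start : start + 256]))
            e = np.exp(logits.data - logits.data.max(axis=1, keepdims=True))
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out)

    def classify(self, roi) -> ClassifierOutput:
        """Class probabilities + label for one ROI; ties go to malignant."""
        a = roi.canvas if hasattr(roi, "canvas") else np.asarray(roi)
        if self.canvas_size is not None and a.shape[0] != self.canvas_size:
            warnings.warn(
                f"ROI canvas {a.shape[0]}px differs from the {self.canvas_size}px "
                "canvas seen in training; resizing"
            )
        probs = self.predict_proba([roi])[0]
        label = MALIGNANT if probs[1] >= probs[0] else BENIGN
        return ClassifierOutput(probabilities=probs, label=label)

    # -- persistence ---------------------------------------------------
    def save(self, path: str):
        base = path[:-4] if path.endswith(".npz") else path
        np.savez(base + ".npz", *self.encoder.state_dict())
        with open(base + ".json", "w") as fh:
            json.dump(self.config, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "ClumpClassifier":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            config = json.load(fh)
        model = cls(**config)
        with np.load(base + ".npz") as data:
            state = [data[f"arr_{i}"] for i in range(len(data.files))]
        model.encoder.load_state_dict(state)
        model.key_encoder.load_state_dict(state)
        return model


@dataclass
class ClassificationResults:
    """Fit results for the ROI classifier."""

    model: ClumpClassifier
    history: dict = field(default_factory=dict)

    @property
    def final_loss(self) -> float:
        return self.history["loss"][-1]

    @property
    def val_accuracy(self) -> float | None:
        va = self.history.get("val_accuracy") or []
        return va[-1] if va else None

    def classify(self, roi) -> ClassifierOutput:
        return self.model.classify(roi)

    def evaluate(self, rois, labels) -> float:
        return self.model._accuracy(rois, labels)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Contrastive ROI classification fit",
            "=" * 44,
            f"encoder input: {cfg['input_size']}px   embed dim: {cfg['embed_dim']}",
            f"tau: {cfg['tau']}   momentum: {cfg['momentum']}   "
            f"beta: {cfg['beta_loss']}",
            f"memory bank: {len(self.model.bank)}/{cfg['bank_capacity']} keys",
            f"optimizer: Adam(lr={cfg['lr']})   batch size: {cfg['batch_size']}",
            f"epochs run: {len(self.history['loss'])}",
            f"final training loss: {self.final_loss:.4f}",
        ]
        if self.val_accuracy is not None:
            lines.append(f"validation accuracy: {self.val_accuracy:.4f}")
        return "\n".join(lines)


def train_classifier(rois, labels=None, config: dict | None = None,
                     **fit_kwargs) -> ClassificationResults:
    """Functional wrapper: build a ClumpClassifier and fit it."""
    model = ClumpClassifier(**(config or {}))
    return model.fit(rois, labels, **fit_kwargs)


def classify(model, roi) -> ClassifierOutput:
    m = model.model if isinstance(model, ClassificationResults) else model
    return m.classify(roi)
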