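"""Cell-clump segmentation network: nested dense skips, channel attention,
multi-level semantic supervision and a hybrid Dice + cross-entropy loss.

Topology.  The network is a nested U-Net over a triangular grid of nodes
x[i][j] (depth row i = 0..d, column j), where

    x[i][0] = H(D(x[i-1][0]))                               (encoder chain)
    x[i][j] = H([x[i][0], ..., x[i][j-1], U(x[i+1][j-1])])  (j > 0)

with H a convolution block + ReLU, D 2x max pooling, U 2x nearest
upsampling and [.] channel concatenation.  Row i halves the spatial size
i times; the grid holds (d+1)(d+2)/2 nodes.

Channel attention.  At the bottleneck x[d][0] with K channels, a K x K
affinity matrix M is formed from pairwise channel dot products and
row-softmaxed; the output is a residual reweighting

    E_b = beta * sum_a M_ba x_a + x_b

with the scalar `beta` learned from an initial value of 0, so attention
is the identity at initialization and is blended in gradually.

Supervision.  Each top-row decoder node x[0][j] (j = 1..d) feeds a 1x1
convolution side head; the side loss is the alpha-weighted sum of the
per-level hybrid losses (weights default to the last d of 0.1, 0.3, 0.6,
0.9, shallowest first).  The hybrid per-pixel loss combines cross
entropy and a soft Dice term,

    L = -(1/N) sum_c sum_n [ t log p + 2 t p / (t^2 + p^2 + eps) ],

so a perfect prediction attains the value -1.  The total loss is the
hybrid loss of the final output plus the side loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .tileprep import ImageTile

EPS_DICE = 1e-7

DEFAULT_ALPHAS = (0.1, 0.3, 0.6, 0.9)


# ---------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------

def channel_attention(x, beta: float = 0.0, literal_eq2: bool = False):
    """Residual channel attention on a (K, H, W) or (N, K, H, W) map.

    Returns (E, M) where M is the channel-affinity matrix after the
    softmax over the source channel a.  `literal_eq2` switches to the
    printed variant whose normalizer uses exp(x_b . x_b) only (rows then
    do not generally sum to 1).
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    n, k, h, w = x.shape
    if k == 0:
        raise ValueError("channel attention needs K >= 1 channels")
    f = x.reshape(n, k, h * w)
    s = f @ np.swapaxes(f, 1, 2)  # s[b, a] = x_b . x_a
    if literal_eq2:
        diag = np.einsum("nkk->nk", s)[:, :, None]  # x_b . x_b per row b
        m = np.exp(s - diag) / k
    else:
        m = np.exp(s - s.max(axis=2, keepdims=True))
        m /= m.sum(axis=2, keepdims=True)
    e = beta * (m @ f) + f
    e = e.reshape(n, k, h, w)
    if squeeze:
        return e[0], m[0]
    return e, m


class ChannelAttention(nn.Module):
    """Trainable channel-attention module with beta initialized at 0."""

    def __init__(self, literal_eq2: bool = False, dtype=np.float32):
        self.beta = nn.Tensor(np.zeros((), dtype=dtype), requires_grad=True)
        self.literal_eq2 = literal_eq2

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, k, h, w = x.shape
        f = x.reshape(n, k, h * w)
        s = f @ f.transpose(0, 2, 1)
        if self.literal_eq2:
            diag = nn.Tensor(np.einsum("nkk->nk", s.data)[:, :, None])
            m = (s - diag).exp() * (1.0 / k)
        else:
            m = nn.softmax(s, axis=2)
        e = self.beta * (m @ f) + f
        return e.reshape(n, k, h, w)


# ---------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------

def hybrid_loss(t, p, eps: float = EPS_DICE) -> float:
    """Hybrid cross-entropy + soft-Dice loss on one-hot target t and
    probability map p.

    Arrays share a shape whose leading axis indexes the C classes
    (scalars are allowed, C = 1); N is the per-class element count.
    Probabilities are clamped to [eps, 1].  The minimum, at p = t, is -1.
    """
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if t.shape != p.shape:
        raise ValueError("shape mismatch between target and prediction")
    c = t.shape[0] if t.ndim > 0 else 1
    n = t.size / c if t.size else 1
    pc = np.clip(p, eps, 1.0)
    ce = t * np.log(pc)
    dsc = 2.0 * t * p / (t * t + p * p + eps)
    return float(-(ce + dsc).sum() / n)


@dataclass(frozen=True)
class MSSConfig:
    """Weights for the multi-level semantic supervision side heads."""

    alphas: tuple[float, ...] = DEFAULT_ALPHAS

    def __post_init__(self):
        if any(a <= 0 for a in self.alphas):
            raise ValueError("all alphas must be positive")


def side_loss(side_outputs, target, cfg: MSSConfig = MSSConfig()) -> float:
    """Alpha-weighted sum of per-level hybrid losses.

    `side_outputs` holds one probability map per supervised level, each
    at target resolution; level count must match len(cfg.alphas).
    """
    if len(side_outputs) != len(cfg.alphas):
        raise ValueError(
            f"{len(side_outputs)} side outputs but {len(cfg.alphas)} alphas"
        )
    return float(sum(a * hybrid_loss(target, s) for a, s in zip(cfg.alphas, side_outputs)))


def total_seg_loss(final_loss: float, side_loss_value: float, depth: int = 4,
                   literal_eq6: bool = False) -> float:
    """Combine final-output and side losses.

    Default: L = L_TP + L_side.  The literal printed form sums the same
    pair over all depth rows, i.e. multiplies by d.
    """
    if literal_eq6:
        return depth * (final_loss + side_loss_value)
    return final_loss + side_loss_value


def _hybrid_loss_graph(t_onehot: np.ndarray, logits: nn.Tensor,
                       eps: float = EPS_DICE) -> nn.Tensor:
    """Autodiff version of the hybrid loss on (N, C, H, W) logits."""
    t = nn.Tensor(t_onehot.astype(logits.data.dtype))
    p = nn.softmax(logits, axis=1)
    ce = t * nn.log_softmax(logits, axis=1)
    dsc = (2.0 * t * p) / (t * t + p * p + eps)
    n_pix = t_onehot.size / t_onehot.shape[1]
    return -(ce + dsc).sum() * (1.0 / n_pix)


# ---------------------------------------------------------------------
# network
# ---------------------------------------------------------------------

def grid_nodes(depth: int) -> list[tuple[int, int]]:
    """Valid (row i, column j) node indices of the nested topology."""
    return [(i, j) for i in range(depth + 1) for j in range(depth + 1 - i)]


class CMUNet(nn.Module):
    """Nested U-Net with channel attention and deep supervision heads."""

    def __init__(self, depth: int = 4, base_channels: int = 8, in_channels: int = 3,
                 n_classes: int = 2, ca: bool = True, mss: bool = True,
                 alphas: tuple[float, ...] | None = None,
                 literal_eq2: bool = False, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.n_classes = n_classes
        self.use_ca = ca
        self.use_mss = mss
        self.widths = [base_channels * 2**i for i in range(depth + 1)]
        self.blocks = {}
        for i, j in grid_nodes(depth):
            if i == 0 and j == 0:
                cin = in_channels
            elif j == 0:
                cin = self.widths[i - 1]
            else:
                cin = j * self.widths[i] + self.widths[i + 1]
            self.blocks[f"x{i}{j}"] = nn.Conv2d(cin, self.widths[i], 3, rng)
        self.attention = ChannelAttention(literal_eq2) if ca else None
        self.heads = {
            f"s{j}": nn.Conv2d(self.widths[0], n_classes, 1, rng)
            for j in range(1, depth + 1)
        }
        if alphas is None:
            alphas = DEFAULT_ALPHAS[-depth:]
        self.mss_cfg = MSSConfig(alphas=tuple(alphas)) if mss else None

    def node_input_channels(self, i: int, j: int) -> int:
        return self.blocks[f"x{i}{j}"].weight.shape[1]

    def node_forward(self, grid: dict, i: int, j: int, x: nn.Tensor | None = None) -> nn.Tensor:
        """Compute node x[i][j] from already-computed parents in `grid`."""
        if j == 0:
            if i == 0:
                if x is None:
                    raise ValueError("root node needs the input image")
                inp = x
            else:
                if (i - 1, 0) not in grid:
                    raise KeyError(f"parent ({i-1},0) not computed")
                inp = nn.maxpool2(grid[(i - 1, 0)])
        else:
            parents = [(i, k) for k in range(j)] + [(i + 1, j - 1)]
            missing = [p for p in parents if p not in grid]
            if missing:
                raise KeyError(f"parents {missing} not computed")
            inp = nn.concat(
                [grid[(i, k)] for k in range(j)] + [nn.upsample2(grid[(i + 1, j - 1)])],
                axis=1,
            )
        out = self.blocks[f"x{i}{j}"](inp).relu()
        if j == 0 and i == self.depth and self.attention is not None:
            out = self.attention(out)
        return out

    def forward(self, x: nn.Tensor):
        """Return (final logits, [side logits j=1..d], node grid)."""
        grid: dict = {}
        for i in range(self.depth + 1):
            grid[(i, 0)] = self.node_forward(grid, i, 0, x=x)
        for j in range(1, self.depth + 1):
            for i in range(self.depth + 1 - j):
                grid[(i, j)] = self.node_forward(grid, i, j)
        sides = [self.heads[f"s{j}"](grid[(0, j)]) for j in range(1, self.depth + 1)]
        return sides[-1], sides, grid

    def loss(self, logits_final: nn.Tensor, sides: list[nn.Tensor],
             t_onehot: np.ndarray, literal_eq6: bool = False) -> nn.Tensor:
        l_tp = _hybrid_loss_graph(t_onehot, logits_final)
        if self.mss_cfg is not None:
            l_side = None
            for a, s in zip(self.mss_cfg.alphas, sides):
                term = _hybrid_loss_graph(t_onehot, s) * a
                l_side = term if l_side is None else l_side + term
            total = l_tp + l_side
        else:
            total = l_tp
        if literal_eq6:
            total = total * float(self.depth)
        return total


# ---------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------

def _prep_images(images) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr.transpose(0, 3, 1, 2)  # NCHW


def _onehot(masks: np.ndarray, n_classes: int = 2) -> np.ndarray:
    m = np.asarray(masks).astype(np.int64)
    out = np.zeros((m.shape[0], n_classes) + m.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = m == c
    return out


class CellClumpSegmenter:
    """Statsmodels-style model object for the segmentation stage.

    Construct with architecture/optimization settings, call
    :meth:`fit` on image/mask arrays to obtain a
    :class:`SegmentationResults`.
    """

    def __init__(self, depth: int = 2, base_channels: int = 8, n_classes: int = 2,
                 ca: bool = True, mss: bool = True, alphas=None,
                 lr: float = 5e-3, batch_size: int = 32,
                 literal_eq2: bool = False, literal_eq6: bool = False, seed: int = 0):
        self.config = dict(depth=depth, base_channels=base_channels,
                           n_classes=n_classes, ca=ca, mss=mss,
                           alphas=None if alphas is None else list(alphas),
                           lr=lr, batch_size=batch_size,
                           literal_eq2=literal_eq2, literal_eq6=literal_eq6,
                           seed=seed)
        self.net = CMUNet(depth=depth, base_channels=base_channels,
                          n_classes=n_classes, ca=ca, mss=mss, alphas=alphas,
                          literal_eq2=literal_eq2, seed=seed)
        self.lr = lr
        self.batch_size = batch_size
        self.literal_eq6 = literal_eq6
        self.seed = seed

    def fit(self, images, masks, epochs: int = 10,
            val_images=None, val_masks=None, seed: int | None = None,
            verbose: bool = False) -> "SegmentationResults":
        """Train with Adam on the combined hybrid + side loss."""
        if len(images) == 0:
            raise ValueError("empty training manifest")
        seed = self.seed if seed is None else seed
        rng = np.random.default_rng(seed + 1)
        x = _prep_images(images)
        t = _onehot(masks, self.net.n_classes)
        opt = nn.Adam(self.net.parameters(), lr=self.lr)
        history = {"loss": [], "val_dice": []}
        n = x.shape[0]
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = nn.Tensor(x[idx])
                final, sides, _ = self.net.forward(xb)
                loss = self.net.loss(final, sides, t[idx], self.literal_eq6)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            history["loss"].append(float(np.mean(losses)))
            if val_images is not None:
                history["val_dice"].append(
                    float(np.mean([
                        _dice_pair(self.segment(im), vm)
                        for im, vm in zip(val_images, val_masks)
                    ]))
                )
            if verbose:
                vd = history["val_dice"][-1] if history["val_dice"] else float("nan")
                print(f"epoch {epoch + 1}/{epochs} loss={history['loss'][-1]:.4f} "
                      f"val_dice={vd:.4f}")
        return SegmentationResults(model=self, history=history)

    def predict_proba(self, tile) -> np.ndarray:
        """Per-pixel foreground probability for one tile (HxWx3 or ImageTile)."""
        px = tile.pixels if isinstance(tile, ImageTile) else np.asarray(tile)
        h, w = px.shape[:2]
        m = 2**self.net.depth
        ph = (m - h % m) % m
        pw = (m - w % m) % m
        if ph or pw:
            px = np.pad(px, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        x = _prep_images(px[None])
        final, _, _ = self.net.forward(nn.Tensor(x))
        e = np.exp(final.data - final.data.max(axis=1, keepdims=True))
        prob = (e / e.sum(axis=1, keepdims=True))[0, 1]
        return prob[:h, :w]

    def segment(self, tile, threshold: float = 0.5) -> np.ndarray:
        """Binary mask: foreground probability strictly above `threshold`."""
        return self.predict_proba(tile) > threshold

    # -- persistence ---------------------------------------------------
    def save(self, path: str):
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 *self.net.state_dict())
        side = (path[:-4] if path.endswith(".npz") else path) + ".json"
        with open(side, "w") as fh:
            json.dump(self.config, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "CellClumpSegmenter":
        base = path[:-4] if path.endswith(".npz") else path
        with open(base + ".json") as fh:
            config = json.load(fh)
        model = cls(**config)
        with np.load(base + ".npz") as data:
            model.net.load_state_dict([data[f"arr_{i}"] for i in range(len(data.files))])
        return model


def _dice_pair(pred_mask, true_mask) -> float:
    from .evalmetrics import dice

    return dice(true_mask, pred_mask)


@dataclass
class SegmentationResults:
    """Fit results: trained model, training history and diagnostics."""

    model: CellClumpSegmenter
    history: dict = field(default_factory=dict)

    @property
    def final_loss(self) -> float:
        return self.history["loss"][-1]

    @property
    def val_dice(self) -> float | None:
        vd = self.history.get("val_dice") or []
        return vd[-1] if vd else None

    def segment(self, tile, threshold: float = 0.5) -> np.ndarray:
        return self.model.segment(tile, threshold)

    def evaluate(self, images, masks, threshold: float = 0.5) -> float:
        """Mean Dice over an image/mask set."""
        return float(np.mean([
            _dice_pair(self.model.segment(im, threshold), m)
            for im, m in zip(images, masks)
        ]))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Cell-clump segmentation fit",
            "=" * 44,
            f"depth: {cfg['depth']}   base channels: {cfg['base_channels']}",
            f"channel attention: {cfg['ca']}   deep supervision: {cfg['mss']}",
            f"optimizer: Adam(lr={cfg['lr']})   batch size: {cfg['batch_size']}",
            f"epochs run: {len(self.history['loss'])}",
            f"final training loss: {self.final_loss:.4f}",
        ]
        if self.val_dice is not None:
            lines.append(f"validation Dice: {self.val_dice:.4f}")
        return "\n".join(lines)


def train_segmenter(images, masks, config: dict | None = None,
                    **fit_kwargs) -> SegmentationResults:
    """Functional wrapper: build a CellClumpSegmenter and fit it."""
    model = CellClumpSegmenter(**(config or {}))
    return model.fit(images, masks, **fit_kwargs)
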