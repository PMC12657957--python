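"""Conditional double-headed sequence model of ribosome dwell profiles.

The model embeds each codon token and adds a learned embedding of the
deprivation-condition identifier at every position.  A stack of
bidirectional relative-position multi-head attention blocks (the
Transformer-XL parameterization) — or, alternatively, a bidirectional
recurrent backbone with the same input/output contract — produces
per-position states from which two linear heads read out:

* the control head predicts the control footprint profile, and
* the difference head predicts the deprivation-minus-control profile.

The deprivation-condition prediction is their sum by construction.

Attention scores follow e_ij = (x_i W^Q + u)(x_j W_E^K)^T
+ (x_i W^Q + v)(r_{i-j} W_R^K)^T with sinusoidal relative encodings
r_{i-j}, scaled by 1/sqrt(d_head), normalized with a softmax over keys.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

from .autodiff import Adam, Tensor, band_gather, no_grad, softmax  # noqa: F401
from .core_io import CONDITION_INDEX, CODON_INDEX, CodonSequence

logger = logging.getLogger("ribodwell")

MAAPE_EPS = 1e-6  # denominator guard; the raw definition divides by y

# Layer-norm variance floor.  Deliberately large: the integrated-gradients
# path runs from a zero embedding, where normalization is degenerate; a
# larger floor widens that transition so a 64-point midpoint rule resolves
# it (completeness holds to <1%), at no measurable cost to fit quality.
LN_EPS = 1e-2


@dataclass
class ModelConfig:
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 128
    backbone: str = "transformer"  # or "birnn"
    dropout: float = 0.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.backbone == "transformer" and self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.backbone not in ("transformer", "birnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PredictionPair:
    """Per-position outputs of the two heads; the DC profile is their sum."""

    y_ctrl: np.ndarray
    y_delta: np.ndarray

    @property
    def y_dc(self) -> np.ndarray:
        return self.y_ctrl + self.y_delta


_REL_CACHE: dict = {}


def relative_encoding(n: int, d: int, dtype=np.float64) -> np.ndarray:
    """Sinusoidal encodings of the relative distances -(n-1) .. n-1."""
    key = (n, d, np.dtype(dtype).str)
    hit = _REL_CACHE.get(key)
    if hit is not None:
        return hit
    dist = np.arange(-(n - 1), n, dtype=np.float64)
    inv_freq = 1.0 / (10000.0 ** (np.arange(0, d, 2, dtype=np.float64) / d))
    ang = dist[:, None] * inv_freq[None, :]
    out = np.zeros((dist.size, d))
    out[:, 0::2] = np.sin(ang)
    out[:, 1::2] = np.cos(ang)
    out = out.astype(dtype)
    if len(_REL_CACHE) > 64:
        _REL_CACHE.clear()
    _REL_CACHE[key] = out
    return out


class DwellModel:
    """Parameter container plus forward pass; trained elsewhere."""

    def __init__(self, config: ModelConfig, params: dict | None = None):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        if params is not None:
            self.params = {k: Tensor(v.astype(self.dtype), requires_grad=True) for k, v in params.items()}
        else:
            self.params = self._init_params()

    # -- parameters ----------------------------------------------------------

    def _init_params(self) -> dict:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        D, H = cfg.d_model, cfg.n_heads
        dh = D // H if cfg.backbone == "transformer" else None
        p: dict[str, np.ndarray] = {}

        def mat(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / math.sqrt(shape[0])
            return rng.normal(0.0, scale, size=shape)

        p["codon_emb"] = rng.normal(0.0, 0.1, size=(64, D))
        p["cond_emb"] = rng.normal(0.0, 0.1, size=(len(CONDITION_INDEX), D))
        for i in range(cfg.n_layers):
            pre = f"layer{i}."
            if cfg.backbone == "transformer":
                for w in ("Wq", "Wke", "Wv", "Wkr", "Wo"):
                    p[pre + w] = mat(D, D)
                p[pre + "u"] = rng.normal(0.0, 0.02, size=(H, dh))
                p[pre + "v"] = rng.normal(0.0, 0.02, size=(H, dh))
                p[pre + "ff_W1"] = mat(D, cfg.d_ff)
                p[pre + "ff_b1"] = np.zeros(cfg.d_ff)
                p[pre + "ff_W2"] = mat(cfg.d_ff, D)
                p[pre + "ff_b2"] = np.zeros(D)
                for ln in ("ln1", "ln2"):
                    p[pre + ln + "_g"] = np.ones(D)
                    p[pre + ln + "_b"] = np.zeros(D)
            else:
                for direc in ("fwd", "bwd"):
                    p[pre + direc + "_Wx"] = mat(D, D)
                    p[pre + direc + "_Wh"] = mat(D, D)
                    p[pre + direc + "_b"] = np.zeros(D)
                p[pre + "proj"] = mat(2 * D, D)
        p["lnf_g"] = np.ones(D)
        p["lnf_b"] = np.zeros(D)
        p["head_ctrl_w"] = rng.normal(0.0, 0.02, size=(D, 1))
        p["head_ctrl_b"] = np.zeros(1)
        p["head_delta_w"] = rng.normal(0.0, 0.02, size=(D, 1))
        p["head_delta_b"] = np.zeros(1)
        return {k: Tensor(v.astype(self.dtype), requires_grad=True) for k, v in p.items()}

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict):
        for k, v in state.items():
            self.params[k].data = v.astype(self.dtype).copy()

    # -- forward -------------------------------------------------------------

    def _ln(self, x: Tensor, g: Tensor, b: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + LN_EPS).sqrt() * g + b

    def embed(self, tokens: np.ndarray, cond_ids: np.ndarray) -> Tensor:
        """Per-position input: codon embedding plus condition embedding.

        tokens: int array [B, n]; cond_ids: int array [B].
        """
        x = self.params["codon_emb"][tokens]
        c = self.params["cond_emb"][cond_ids]
        return x + c.reshape(c.shape[0], 1, c.shape[1])

    def _attend(self, xn: Tensor, i_layer: int, mask_bias: np.ndarray | None):
        """Relative multi-head attention on normalized input.

        Returns the concatenated per-head context (before the output
        projection) and the attention weights (as a plain array).
        """
        cfg = self.config
        B, n, D = xn.shape
        H = cfg.n_heads
        dh = D // H
        P = self.params
        pre = f"layer{i_layer}."

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, n, H, dh).transpose(0, 2, 1, 3)  # [B,H,n,dh]

        q = heads(xn @ P[pre + "Wq"])
        k = heads(xn @ P[pre + "Wke"])
        v = heads(xn @ P[pre + "Wv"])

        R = Tensor(relative_encoding(n, D, self.dtype))
        r_proj = (R @ P[pre + "Wkr"]).reshape(2 * n - 1, H, dh).transpose(1, 0, 2)

        u = P[pre + "u"].reshape(1, H, 1, dh)
        vb = P[pre + "v"].reshape(1, H, 1, dh)
        scale = 1.0 / math.sqrt(dh)  # applied to the query side of both terms
        content = ((q + u) * scale) @ k.transpose(0, 1, 3, 2)  # [B,H,n,n]
        qr = ((q + vb) * scale) @ r_proj.transpose(0, 2, 1)  # [B,H,n,2n-1]
        # gather the diagonal band: score_rel[i, j] = qr[i, i - j + n - 1]
        rel = band_gather(qr, n)
        e = content + rel
        if mask_bias is not None:
            e = e + Tensor(mask_bias)
        alpha = softmax(e, axis=-1)
        ctx = (alpha @ v).transpose(0, 2, 1, 3).reshape(B, n, D)
        return ctx, alpha.data

    def _birnn_layer(self, x: Tensor, i_layer: int) -> Tensor:
        B, n, D = x.shape
        P = self.params
        pre = f"layer{i_layer}."
        outs = {}
        for direc, order in (("fwd", range(n)), ("bwd", range(n - 1, -1, -1))):
            Wx, Wh, b = P[pre + direc + "_Wx"], P[pre + direc + "_Wh"], P[pre + direc + "_b"]
            h = Tensor(np.zeros((B, D), dtype=self.dtype))
            states = [None] * n
            for t in order:
                h = (x[:, t, :] @ Wx + h @ Wh + b).tanh()
                states[t] = h.reshape(B, 1, D)
            from .autodiff import cat

            outs[direc] = cat(states, axis=1)
        from .autodiff import cat

        both = cat([outs["fwd"], outs["bwd"]], axis=2)
        return both @ P[pre + "proj"]

    def backbone_forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """Run the backbone stack on embedded input [B, n, D] -> [B, n, D]."""
        if x.shape[1] == 0:
            raise ValueError("zero-length sequence")
        cfg = self.config
        P = self.params
        mask_bias = None
        if mask is not None and not mask.all():
            mask_bias = np.where(mask, 0.0, -1e9).astype(self.dtype)
            mask_bias = mask_bias[:, None, None, :]
        for i in range(cfg.n_layers):
            pre = f"layer{i}."
            if cfg.backbone == "transformer":
                xn = self._ln(x, P[pre + "ln1_g"], P[pre + "ln1_b"])
                ctx, _ = self._attend(xn, i, mask_bias)
                x = x + ctx @ P[pre + "Wo"]
                xn = self._ln(x, P[pre + "ln2_g"], P[pre + "ln2_b"])
                ff = (xn @ P[pre + "ff_W1"] + P[pre + "ff_b1"]).gelu()
                x = x + ff @ P[pre + "ff_W2"] + P[pre + "ff_b2"]
            else:
                x = x + self._birnn_layer(x, i)
        return self._ln(x, P["lnf_g"], P["lnf_b"])

    def forward_from_embedding(self, x: Tensor, mask: np.ndarray | None = None):
        h = self.backbone_forward(x, mask)
        B, n, D = h.shape
        yc = (h @ self.params["head_ctrl_w"]).reshape(B, n) + self.params["head_ctrl_b"]
        yd = (h @ self.params["head_delta_w"]).reshape(B, n) + self.params["head_delta_b"]
        return yc, yd

    def forward(self, tokens: np.ndarray, cond_ids: np.ndarray, mask: np.ndarray | None = None):
        return self.forward_from_embedding(self.embed(tokens, cond_ids), mask)

    # -- inference convenience -------------------------------------------------

    def predict(self, seq: CodonSequence, cond: str) -> PredictionPair:
        tokens = seq.token_ids()[None, :]
        cond_ids = np.array([CONDITION_INDEX[cond]])
        yc, yd = self.fast_forward(tokens, cond_ids)
        return PredictionPair(yc[0].astype(float), yd[0].astype(float))

    def predict_tokens(self, tokens: np.ndarray, cond: str):
        """Batched inference on equal-length token arrays [B, n] (one condition)."""
        cond_ids = np.full(tokens.shape[0], CONDITION_INDEX[cond])
        yc, yd = self.fast_forward(tokens, cond_ids)
        return yc.astype(float), yd.astype(float)

    # -- graph-free inference path (same math as forward; no tape, in-place) ---

    def _np(self, name: str) -> np.ndarray:
        return self.params[name].data

    def _ln_np(self, x, g, b):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        var += LN_EPS
        np.sqrt(var, out=var)
        xc /= var
        xc *= g
        xc += b
        return xc

    def fast_forward(self, tokens: np.ndarray, cond_ids: np.ndarray, mask: np.ndarray | None = None):
        """Inference-only forward identical to ``forward`` (checked in tests)."""
        cfg = self.config
        if cfg.backbone != "transformer":
            with no_grad():
                yc, yd = self.forward(tokens, cond_ids, mask)
            return yc.data.copy(), yd.data.copy()
        B, n = tokens.shape
        D, H = cfg.d_model, cfg.n_heads
        dh = D // H
        scale = 1.0 / math.sqrt(dh)
        x = self._np("codon_emb")[tokens] + self._np("cond_emb")[cond_ids][:, None, :]
        R = relative_encoding(n, D, self.dtype)
        ii = np.arange(n)[:, None]
        band = (Ellipsis, ii, ii - np.arange(n)[None, :] + n - 1)
        mask_bias = None
        if mask is not None and not mask.all():
            mask_bias = np.where(mask, 0.0, -1e9).astype(self.dtype)[:, None, None, :]
        for i in range(cfg.n_layers):
            pre = f"layer{i}."

            def heads(t):
                return np.ascontiguousarray(t.reshape(B, n, H, dh).transpose(0, 2, 1, 3))

            xn = self._ln_np(x, self._np(pre + "ln1_g"), self._np(pre + "ln1_b"))
            q = heads(xn @ self._np(pre + "Wq"))
            k = heads(xn @ self._np(pre + "Wke"))
            v = heads(xn @ self._np(pre + "Wv"))
            r_proj = (
                (R @ self._np(pre + "Wkr")).reshape(2 * n - 1, H, dh).transpose(1, 2, 0)
            )
            qu = (q + self._np(pre + "u")[None, :, None, :]) * scale
            qv = (q + self._np(pre + "v")[None, :, None, :]) * scale
            e = qu @ k.swapaxes(-1, -2)
            e += (qv @ r_proj)[band]
            if mask_bias is not None:
                e += mask_bias
            e -= e.max(axis=-1, keepdims=True)
            np.exp(e, out=e)
            e /= e.sum(axis=-1, keepdims=True)
            ctx = (e @ v).transpose(0, 2, 1, 3).reshape(B, n, D)
            x = x + ctx @ self._np(pre + "Wo")
            xn = self._ln_np(x, self._np(pre + "ln2_g"), self._np(pre + "ln2_b"))
            h1 = xn @ self._np(pre + "ff_W1")
            h1 += self._np(pre + "ff_b1")
            # tanh-form gelu, same constants as the tape op
            c = 0.7978845608028654
            inner = h1 * h1
            inner *= 0.044715 * c * h1
            inner += c * h1
            np.tanh(inner, out=inner)
            inner += 1.0
            inner *= 0.5 * h1
            x = x + inner @ self._np(pre + "ff_W2") + self._np(pre + "ff_b2")
        h = self._ln_np(x, self._np("lnf_g"), self._np("lnf_b"))
        yc = (h @ self._np("head_ctrl_w")).reshape(B, n) + self._np("head_ctrl_b")
        yd = (h @ self._np("head_delta_w")).reshape(B, n) + self._np("head_delta_b")
        return yc, yd


# ---------------------------------------------------------------------------
# metrics (plain numpy; missing values excluded pairwise)


def _pair(y, y_hat):
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    m = ~np.isnan(y) & ~np.isnan(y_hat)
    return y[m], y_hat[m]


def pcc(y, y_hat) -> float:
    """Pearson correlation; NaN when fewer than 2 pairs or zero variance."""
    a, b = _pair(y, y_hat)
    if a.size < 2:
        return float("nan")
    ac, bc = a - a.mean(), b - b.mean()
    den = math.sqrt((ac * ac).sum() * (bc * bc).sum())
    if den == 0.0:
        return float("nan")
    return float((ac * bc).sum() / den)


def scc(y, y_hat) -> float:
    """Spearman correlation with midranks for ties."""
    a, b = _pair(y, y_hat)
    if a.size < 2:
        return float("nan")
    return pcc(rankdata(a), rankdata(b))


def mse(y, y_hat) -> float:
    a, b = _pair(y, y_hat)
    return float(np.mean((a - b) ** 2))


def maape(y, y_hat, eps: float = MAAPE_EPS) -> float:
    """Mean arctangent absolute percentage error, in percent.

    Bounded by 100*pi/2 per position; the denominator is guarded by `eps`
    because observed counts can be exactly zero.
    """
    a, b = _pair(y, y_hat)
    return float(100.0 / a.size * np.arctan(np.abs(a - b) / np.maximum(np.abs(a), eps)).sum())


# ---------------------------------------------------------------------------
# training loss (autodiff graph)


def _pearson_term(target: np.ndarray, pred_slice: Tensor) -> Tensor | None:
    """Differentiable Pearson r of a prediction against a fixed target.

    Returns None when the target side is degenerate (fewer than two
    annotated positions or zero variance); the caller counts that term as 0.
    """
    m = ~np.isnan(target)
    if m.sum() < 2:
        return None
    t = target[m]
    tc = t - t.mean()
    tss = float((tc * tc).sum())
    if tss == 0.0:
        return None
    idx = np.nonzero(m)[0]
    x = pred_slice[idx]
    xc = x - x.mean()
    num = (xc * Tensor(tc.astype(pred_slice.data.dtype))).sum()
    den = ((xc * xc).sum() * tss + 1e-12).sqrt()
    return num / den


def sample_loss(y_ctrl, y_delta, y_dc, pred_ctrl: Tensor, pred_delta: Tensor) -> Tensor:
    """Training loss for one sample:

    L = 3 - r(y_CTRL, yhat_CTRL) - r(y_dD, yhat_dD) - r(y_DC, yhat_DC)
        + MAE(y_DC, yhat_DC)

    computed over pairwise-annotated positions.  A correlation term whose
    target is degenerate contributes zero (logged once per run elsewhere).
    """
    pred_dc = pred_ctrl + pred_delta
    total = Tensor(np.asarray(3.0, dtype=pred_ctrl.data.dtype))
    for target, pred in ((y_ctrl, pred_ctrl), (y_delta, pred_delta), (y_dc, pred_dc)):
        r = _pearson_term(np.asarray(target, dtype=float), pred)
        if r is not None:
            total = total - r
    m = ~np.isnan(np.asarray(y_dc, dtype=float))
    if m.any():
        idx = np.nonzero(m)[0]
        t = np.asarray(y_dc, dtype=float)[m].astype(pred_ctrl.data.dtype)
        total = total + (pred_dc[idx] - Tensor(t)).abs().mean()
    return total
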