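"""Transformer encoder mapping stacked BOLD windows to DCM parameters.

The observed T x S BOLD matrix is cut into W overlapping windows of length N
(95% overlap by default) and stacked into a W x N x S batch.  Each encoder
layer applies Across-Sample Attention (ASA, an unmasked N x N attention over
time points), then Across-Node Attention (ANA, an S x S attention over
regions whose scores are masked by the hypothesis graph), then a
feed-forward sublayer along the region axis — each wrapped in a residual
connection and layer normalization.  At the last layer the ASA and ANA
outputs are pooled separately and passed through single-layer summary heads:
the ASA head emits the raw signal-specific parameters (sigma, lambda, mu per
region) and the ANA head emits one raw value per permitted connectivity
edge.  Raw values are squashed into their bounds (logistic for rates, tanh
scaled by a_max for edges), so masked edges decode to exactly zero and every
decoded parameter respects its box constraint at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from .graph import NetworkGraph
from .params import ConnectivityParams, NeuronalParams, ParamBounds

__all__ = [
    "SequenceBatch",
    "EncoderConfig",
    "AttentionMaps",
    "Theta",
    "positional_encoding",
    "window_series",
    "sdpa",
    "TransformerEncoder",
]


@dataclass
class SequenceBatch:
    """Stacked overlapping windows of a BOLD series."""

    windows: np.ndarray  # (W, N, S)
    N: int
    stride: int
    pad_len: int
    source_T: int

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@dataclass
class EncoderConfig:
    """Architecture and decoding configuration of the encoder.

    The model dimension always equals the number of regions S, so the
    per-region identity of the features is preserved through the stack.
    """

    layers: int = 2
    n_heads: int = 1
    d_ff: int | None = None  # defaults to 4*S
    bounds: ParamBounds = field(default_factory=ParamBounds)
    seed: int = 0
    init_scale: float = 0.25  # multiplier on the scaled-uniform weight init
    use_positional: bool = True
    diagonal_embedding: bool = True  # False: full S x S embedding (ablation)
    estimate_b: bool = False
    estimate_c: bool = False

    def to_dict(self) -> dict:
        return {
            "layers": self.layers,
            "heads": self.n_heads,
            "d_ff": self.d_ff,
            "bounds": {
                "sigma": list(self.bounds.sigma),
                "lambda": list(self.bounds.lambda_),
                "mu": list(self.bounds.mu),
                "a_max": self.bounds.a_max,
            },
            "seed": self.seed,
            "use_positional": self.use_positional,
            "diagonal_embedding": self.diagonal_embedding,
            "estimate_b": self.estimate_b,
            "estimate_c": self.estimate_c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        bounds = ParamBounds()
        if "bounds" in d:
            b = d["bounds"]
            bounds = ParamBounds(
                sigma=tuple(b.get("sigma", bounds.sigma)),
                lambda_=tuple(b.get("lambda", bounds.lambda_)),
                mu=tuple(b.get("mu", bounds.mu)),
                a_max=float(b.get("a_max", bounds.a_max)),
            )
        return cls(
            layers=int(d.get("layers", 2)),
            n_heads=int(d.get("heads", 1)),
            d_ff=d.get("d_ff"),
            bounds=bounds,
            seed=int(d.get("seed", 0)),
            use_positional=bool(d.get("use_positional", True)),
            diagonal_embedding=bool(d.get("diagonal_embedding", True)),
            estimate_b=bool(d.get("estimate_b", False)),
            estimate_c=bool(d.get("estimate_c", False)),
        )


@dataclass
class AttentionMaps:
    """Final-layer attention matrices, for inspection."""

    asa: np.ndarray  # (W, N, N) row-stochastic
    ana: np.ndarray  # (W, S, S) row-stochastic over permitted entries


@dataclass
class Theta:
    """Raw and decoded parameter vector produced by the encoder."""

    raw: np.ndarray
    vector: np.ndarray  # decoded flat theta (pack_theta layout)
    neuronal: NeuronalParams
    conn: ConnectivityParams
    tensor: "Tensor" = None  # decoded theta as an autodiff node


def positional_encoding(N: int, d: int) -> np.ndarray:
    """Sinusoidal positional encoding, entries in [-1, 1]."""
    if d < 1:
        raise ValueError("d must be >= 1")
    pe = np.zeros((N, d))
    pos = np.arange(N)[:, None].astype(float)
    i = np.arange(0, d, 2).astype(float)
    angle = pos / (10000.0 ** (i / d))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : pe[:, 1::2].shape[1]])
    return pe


def window_series(Y: np.ndarray, N: int, overlap: float = 0.95) -> SequenceBatch:
    """Cut a T x S series into overlapping length-N windows.

    Windows start at multiples of ``stride = max(1, round((1-overlap)*N))``
    and continue until the series is covered; only the final window may be
    zero-padded.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be T x S")
    T = Y.shape[0]
    if N < 2:
        raise ValueError("window length N must be >= 2")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if N > 4 * T:
        raise ValueError(f"window length N={N} too long for series of length T={T}")
    stride = max(1, int(round((1.0 - overlap) * N)))
    starts = []
    k = 0
    while True:
        start = k * stride
        starts.append(start)
        if start + N >= T:
            break
        k += 1
    windows = np.zeros((len(starts), N, Y.shape[1]))
    pad_len = 0
    for w, start in enumerate(starts):
        chunk = Y[start : start + N]
        windows[w, : chunk.shape[0]] = chunk
        if w == len(starts) - 1:
            pad_len = N - chunk.shape[0]
    return SequenceBatch(windows, N, stride, pad_len, T)


def sdpa(Q, K, V, mask: np.ndarray | None = None, scale: float | None = None):
    """Scaled dot-product attention: A = softmax(Q K^T / sqrt(d_k) + mask).

    Accepts numpy arrays or Tensors; returns ``(A, A @ V)`` in kind.
    """
    as_np = not isinstance(Q, Tensor)
    Qt, Kt, Vt = (Tensor._lift(x) for x in (Q, K, V))
    d_k = Qt.shape[-1]
    if Kt.shape[-1] != d_k or Kt.shape[-2] != Vt.shape[-2]:
        raise ValueError("inconsistent Q/K/V inner dimensions")
    scale = 1.0 / np.sqrt(d_k) if scale is None else scale
    scores = (Qt @ Kt.swapaxes(-1, -2)) * scale
    A = scores.softmax(mask=mask)
    out = A @ Vt
    if as_np:
        return A.data, out.data
    return A, out


class TransformerEncoder:
    """Graph-masked alternating-attention encoder with summary heads."""

    def __init__(self, graph: NetworkGraph, N: int, cfg: EncoderConfig | None = None):
        self.graph = graph
        self.cfg = cfg or EncoderConfig()
        self.S = graph.n_regions
        self.N = N
        self.d_ff = self.cfg.d_ff or 4 * self.S
        if self.S % self.cfg.n_heads != 0:
            raise ValueError("n_heads must divide the number of regions")
        self.n_edges = graph.n_a_edges
        if self.cfg.estimate_b:
            self.n_edges += graph.n_b_edges
        if self.cfg.estimate_c:
            self.n_edges += len(graph.c_edges)
        self._ana_mask = graph.attention_mask()
        self._pe = positional_encoding(N, self.S) if self.cfg.use_positional else None
        self.weights: dict[str, Tensor] = {}
        self._init_weights()

    # -- weights -----------------------------------------------------------
    def _init_weights(self):
        rng = np.random.default_rng(self.cfg.seed)
        S, d_ff = self.S, self.d_ff

        def uniform(fan_in, fan_out, shape):
            a = self.cfg.init_scale * np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-a, a, size=shape)

        w = {}
        if self.cfg.diagonal_embedding:
            w["embed"] = np.ones(S)
        else:
            w["embed"] = np.eye(S) + 0.01 * rng.standard_normal((S, S))
        for layer in range(self.cfg.layers):
            p = f"l{layer}_"
            for name in ("asa_Wq", "asa_Wk", "asa_Wv", "asa_Wo",
                         "ana_Wq", "ana_Wk", "ana_Wv", "ana_Wo"):
                w[p + name] = uniform(S, S, (S, S))
            w[p + "ffn_W1"] = uniform(S, d_ff, (S, d_ff))
            w[p + "ffn_b1"] = np.zeros(d_ff)
            w[p + "ffn_W2"] = uniform(d_ff, S, (d_ff, S))
            w[p + "ffn_b2"] = np.zeros(S)
            for ln in ("ln1", "ln2", "ln3"):
                w[p + ln + "_g"] = np.ones(S)
                w[p + ln + "_b"] = np.zeros(S)
        # Summary heads start at zero so the initial decoded parameters are
        # the canonical neutral point (rates at the midpoint of their bounds,
        # all connectivity edges 0) for every seed.
        w["summ_asa_W"] = np.zeros((S, 3 * S))
        w["summ_asa_b"] = np.zeros(3 * S)
        w["summ_ana_W"] = np.zeros((S, max(self.n_edges, 1)))
        w["summ_ana_b"] = np.zeros(max(self.n_edges, 1))
        self.weights = {k: Tensor(v, requires_grad=True) for k, v in w.items()}

    # -- sublayers ---------------------------------------------------------
    def _ln(self, x: Tensor, prefix: str) -> Tensor:
        return x.layer_norm(self.weights[prefix + "_g"], self.weights[prefix + "_b"])

    def embed(self, windows: np.ndarray) -> Tensor:
        """Scale each region's channel (diagonal embedding), add positions."""
        x = Tensor(windows)
        if self.cfg.diagonal_embedding:
            out = x * self.weights["embed"]
        else:
            out = x @ self.weights["embed"]
        if self._pe is not None:
            out = out + Tensor(self._pe)
        return out

    def asa_block(self, F: Tensor, layer: int):
        """Multi-head attention over the time axis; residual + LN."""
        p = f"l{layer}_"
        Q = F @ self.weights[p + "asa_Wq"]
        K = F @ self.weights[p + "asa_Wk"]
        V = F @ self.weights[p + "asa_Wv"]
        h = self.cfg.n_heads
        d_h = self.S // h
        outs, maps = [], []
        for i in range(h):
            Qh = Q.slice_last(i * d_h, (i + 1) * d_h)
            Kh = K.slice_last(i * d_h, (i + 1) * d_h)
            Vh = V.slice_last(i * d_h, (i + 1) * d_h)
            A, out = sdpa(Qh, Kh, Vh)
            outs.append(out)
            maps.append(A.data)
        out = outs[0] if h == 1 else concat(outs, axis=-1)
        out = out @ self.weights[p + "asa_Wo"]
        A_asa = maps[0] if h == 1 else np.mean(maps, axis=0)
        return self._ln(F + out, p + "ln1"), A_asa

    def ana_block(self, F: Tensor, layer: int):
        """Graph-masked attention over the region axis, then FFN; each with
        residual + LN."""
        p = f"l{layer}_"
        Q = F @ self.weights[p + "ana_Wq"]
        K = F @ self.weights[p + "ana_Wk"]
        V = F @ self.weights[p + "ana_Wv"]
        Qt = Q.swapaxes(-1, -2)  # (W, S, N)
        Kt = K.swapaxes(-1, -2)
        Vt = V.swapaxes(-1, -2)
        A_ana, out_t = sdpa(Qt, Kt, Vt, mask=self._ana_mask)
        out = out_t.swapaxes(-1, -2) @ self.weights[p + "ana_Wo"]
        x = self._ln(F + out, p + "ln2")
        # feed-forward along the region axis
        hmid = (x @ self.weights[p + "ffn_W1"] + self.weights[p + "ffn_b1"]).relu()
        ff = hmid @ self.weights[p + "ffn_W2"] + self.weights[p + "ffn_b2"]
        x = self._ln(x + ff, p + "ln3")
        return x, A_ana

    def forward(self, batch: SequenceBatch):
        """Run the L-layer stack; returns (H_asa, H_ana, AttentionMaps).

        The ASA output feeds the ANA module in every layer; at the last layer
        the two branch outputs are kept separate.
        """
        if batch.n_windows == 0:
            raise ValueError("empty sequence batch")
        x = self.embed(batch.windows)
        H_asa = x
        A_asa = A_ana = None
        for layer in range(self.cfg.layers):
            H_asa, A_asa = self.asa_block(x, layer)
            x, A_ana = self.ana_block(H_asa, layer)
        return H_asa, x, AttentionMaps(asa=A_asa, ana=A_ana.data)

    def summarize_and_decode(self, H_asa: Tensor, H_ana: Tensor) -> Theta:
        """Pool the branches, apply the summary heads, squash into bounds."""
        S = self.S
        pooled_asa = H_asa.mean(axis=(0, 1)).reshape(1, S)
        pooled_ana = H_ana.mean(axis=(0, 1)).reshape(1, S)
        raw_asa = (
            pooled_asa @ self.weights["summ_asa_W"] + self.weights["summ_asa_b"]
        ).reshape(3 * S)
        raw_ana = (
            pooled_ana @ self.weights["summ_ana_W"] + self.weights["summ_ana_b"]
        ).reshape(max(self.n_edges, 1))
        lo, hi = self.cfg.bounds.as_arrays(S)
        rates = Tensor(lo) + Tensor(hi - lo) * raw_asa.sigmoid()
        if self.n_edges > 0:
            edges = raw_ana.slice_last(0, self.n_edges).tanh() * self.cfg.bounds.a_max
            theta_t = concat([rates, edges], axis=-1)
        else:
            theta_t = rates
        raw = np.concatenate([raw_asa.data, raw_ana.data[: self.n_edges]])
        from .params import unpack_theta

        neuronal, conn = unpack_theta(
            theta_t.data,
            self.graph,
            estimate_b=self.cfg.estimate_b,
            estimate_c=self.cfg.estimate_c,
        )
        return Theta(
            raw=raw,
            vector=theta_t.data.copy(),
            neuronal=neuronal,
            conn=conn,
            tensor=theta_t,
        )

    def encode(self, batch: SequenceBatch):
        """Full pass: windows -> theta (+ attention maps)."""
        H_asa, H_ana, maps = self.forward(batch)
        theta = self.summarize_and_decode(H_asa, H_ana)
        return theta, maps
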