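"""Hypothesis graphs: which directed connections the model is allowed to use.

The cognitive hypothesis enters the estimator twice — as the support of the
connectivity matrices (A, B, C) in the generative model, and as the binary
mask applied to the across-node attention scores in the encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkGraph"]


@dataclass
class NetworkGraph:
    """Binary masks of permitted connections for an S-region network.

    ``a_mask[j, k] == 1`` means the directed edge k -> j is permitted (region k
    influences region j).  The diagonal is always zero: self-influence is
    carried by the per-region self-connection rate sigma, not by A.
    ``b_masks`` holds one S x S mask per modulatory channel and ``c_mask`` is
    S x n_driving.
    """

    n_regions: int
    a_mask: np.ndarray
    b_masks: list = field(default_factory=list)
    c_mask: np.ndarray | None = None
    region_labels: list | None = None

    def __post_init__(self):
        S = self.n_regions
        self.a_mask = np.asarray(self.a_mask, dtype=np.int8)
        if self.a_mask.shape != (S, S):
            raise ValueError("a_mask must be S x S")
        if not np.isin(self.a_mask, (0, 1)).all():
            raise ValueError("a_mask must be binary")
        if np.any(np.diag(self.a_mask) != 0):
            raise ValueError("a_mask diagonal must be zero (self-influence lives in sigma)")
        self.b_masks = [np.asarray(b, dtype=np.int8) for b in self.b_masks]
        for b in self.b_masks:
            if b.shape != (S, S) or not np.isin(b, (0, 1)).all():
                raise ValueError("each b_mask must be a binary S x S matrix")
        if self.c_mask is not None:
            self.c_mask = np.asarray(self.c_mask, dtype=np.int8)
            if self.c_mask.ndim != 2 or self.c_mask.shape[0] != S:
                raise ValueError("c_mask must be S x n_driving")
            if not np.isin(self.c_mask, (0, 1)).all():
                raise ValueError("c_mask must be binary")
        if self.region_labels is None:
            self.region_labels = [f"R{j + 1}" for j in range(S)]
        self._warn_unreachable()

    def _warn_unreachable(self):
        if self.c_mask is None:
            return
        driven = set(np.where(self.c_mask.any(axis=1))[0])
        frontier = list(driven)
        while frontier:
            k = frontier.pop()
            for j in np.where(self.a_mask[:, k])[0]:
                if j not in driven:
                    driven.add(int(j))
                    frontier.append(int(j))
        missing = [self.region_labels[j] for j in range(self.n_regions) if j not in driven]
        if missing:
            warnings.warn(
                f"regions not reachable from any driving input: {missing}",
                stacklevel=3,
            )

    # -- edge bookkeeping -------------------------------------------------
    @property
    def a_edges(self) -> np.ndarray:
        """Permitted A edges as an (E, 2) array of (dst, src) index pairs.

        Row-major order over the mask; this fixes the layout of the
        connectivity block of the parameter vector theta.
        """
        rows, cols = np.nonzero(self.a_mask)
        return np.stack([rows, cols], axis=1)

    @property
    def n_a_edges(self) -> int:
        return int(self.a_mask.sum())

    def b_edges(self, m: int) -> np.ndarray:
        rows, cols = np.nonzero(self.b_masks[m])
        return np.stack([rows, cols], axis=1)

    @property
    def n_b_edges(self) -> int:
        return int(sum(b.sum() for b in self.b_masks))

    @property
    def c_edges(self) -> np.ndarray:
        if self.c_mask is None:
            return np.zeros((0, 2), dtype=int)
        rows, cols = np.nonzero(self.c_mask)
        return np.stack([rows, cols], axis=1)

    def attention_mask(self) -> np.ndarray:
        """Additive pre-softmax mask for across-node attention.

        Permitted set is the A edges plus the diagonal (every region may
        attend to itself, so no row is fully masked); entries are 0 where
        permitted and -inf elsewhere.
        """
        permitted = (self.a_mask.astype(bool)) | np.eye(self.n_regions, dtype=bool)
        mask = np.where(permitted, 0.0, -np.inf)
        return mask

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "regions": list(self.region_labels),
            "a_edges": [[int(src), int(dst)] for dst, src in self.a_edges],
        }
        if self.b_masks:
            d["b_edges"] = [
                [[int(src), int(dst)] for dst, src in self.b_edges(m)]
                for m in range(len(self.b_masks))
            ]
        if self.c_mask is not None:
            d["c_edges"] = [[int(region), int(channel)] for region, channel in self.c_edges]
            d["stimuli"] = int(self.c_mask.shape[1])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkGraph":
        labels = list(d["regions"])
        S = len(labels)
        a_mask = np.zeros((S, S), dtype=np.int8)
        for src, dst in d.get("a_edges", []):
            if src == dst:
                raise ValueError(f"self-edge [{src}, {dst}] not permitted in a_edges")
            a_mask[dst, src] = 1
        b_masks = []
        for ch in d.get("b_edges", []):
            b = np.zeros((S, S), dtype=np.int8)
            for src, dst in ch:
                b[dst, src] = 1
            b_masks.append(b)
        c_mask = None
        if "c_edges" in d:
            n_drive = int(d.get("stimuli", max(ch for _, ch in d["c_edges"]) + 1))
            c_mask = np.zeros((S, n_drive), dtype=np.int8)
            for region, channel in d["c_edges"]:
                c_mask[region, channel] = 1
        return cls(S, a_mask, b_masks, c_mask, labels)
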