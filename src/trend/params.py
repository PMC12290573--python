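"""Parameter containers for the neuronal / hemodynamic state-space models.

The estimated parameter vector theta is laid out as

    [sigma (S), lambda (S), mu (S), A edges (E_A), B edges, C edges]

where the edge blocks follow the row-major order of the corresponding graph
masks.  ``pack_theta`` / ``unpack_theta`` convert between this flat layout and
the structured containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph import NetworkGraph

__all__ = [
    "NeuronalParams",
    "ConnectivityParams",
    "HemoParams",
    "ParamBounds",
    "pack_theta",
    "unpack_theta",
    "theta_size",
]


@dataclass
class NeuronalParams:
    """Per-region signal-specific rates (all 1/s, strictly positive).

    sigma : excitatory self-connection (decay) rate
    lambda_ : inhibitory gain (rate at which inhibition tracks excitation)
    mu : inhibitory-to-excitatory connection strength
    """

    sigma: np.ndarray
    lambda_: np.ndarray
    mu: np.ndarray

    def __post_init__(self):
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.lambda_ = np.atleast_1d(np.asarray(self.lambda_, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if not (self.sigma.shape == self.lambda_.shape == self.mu.shape):
            raise ValueError("sigma, lambda_, mu must have identical shapes")
        if np.any(self.sigma <= 0) or np.any(self.lambda_ <= 0) or np.any(self.mu <= 0):
            raise ValueError("neuronal rates must be strictly positive")

    @property
    def n_regions(self) -> int:
        return self.sigma.size

    @classmethod
    def default(cls, S: int) -> "NeuronalParams":
        # generation defaults: sigma=0.5, lambda=0.2, mu=1.0 per region
        return cls(np.full(S, 0.5), np.full(S, 0.2), np.full(S, 1.0))


@dataclass
class ConnectivityParams:
    """Connectivity matrices (1/s); support restricted to the graph masks."""

    A: np.ndarray
    B: list = field(default_factory=list)
    C: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = [np.asarray(b, dtype=float) for b in self.B]
        if self.C is not None:
            self.C = np.asarray(self.C, dtype=float)

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    def validate(self, graph: NetworkGraph, a_max: float = 1.0):
        if np.any((graph.a_mask == 0) & (self.A != 0)):
            raise ValueError("A has support outside the permitted mask")
        if np.any(np.abs(self.A) > a_max + 1e-12):
            raise ValueError(f"|A| entries must not exceed a_max={a_max}")
        for b, m in zip(self.B, graph.b_masks):
            if np.any((m == 0) & (b != 0)):
                raise ValueError("B has support outside the permitted mask")
        if self.C is not None and graph.c_mask is not None:
            if np.any((graph.c_mask == 0) & (self.C != 0)):
                raise ValueError("C has support outside the permitted mask")


@dataclass
class HemoParams:
    """Neurovascular and balloon-model constants (shared across regions).

    phi : vasoactive signal decay / flow relaxation rate (1/s)
    tau_mtt : mean transit time of the venous compartment (s)
    tau_visc : viscoelastic time constant of the veins (s); 0 for the S-DCM
        variant, which assumes the steady-state flow-volume power law
    alpha : Grubb flow-volume exponent
    e0 : resting oxygen extraction fraction
    v0 : resting venous blood volume fraction (%)
    k1, k2, k3 : BOLD signal coefficients
    kappa, gamma : S-DCM vasoactive decay and flow-feedback rates (1/s)
    """

    phi: float = 0.6
    tau_mtt: float = 2.0
    tau_visc: float = 4.0
    alpha: float = 0.32
    e0: float = 0.4
    v0: float = 4.0
    k1: float = 4.92
    k2: float = 0.57
    k3: float = 0.46
    kappa: float = 0.65
    gamma: float = 0.41

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.e0 < 1:
            raise ValueError("e0 must lie in (0, 1)")
        if self.tau_mtt <= 0 or self.tau_visc < 0 or self.v0 <= 0:
            raise ValueError("tau_mtt > 0, tau_visc >= 0, v0 > 0 required")

    def for_variant(self, variant: str) -> "HemoParams":
        if variant == "sdcm":
            return replace(self, tau_visc=0.0)
        return self


@dataclass
class ParamBounds:
    """Box constraints for the decoded signal-specific parameters (1/s)."""

    sigma: tuple = (0.1, 1.5)
    lambda_: tuple = (0.05, 1.0)
    mu: tuple = (0.1, 2.0)
    a_max: float = 1.0

    def as_arrays(self, S: int) -> tuple:
        lo = np.concatenate(
            [np.full(S, self.sigma[0]), np.full(S, self.lambda_[0]), np.full(S, self.mu[0])]
        )
        hi = np.concatenate(
            [np.full(S, self.sigma[1]), np.full(S, self.lambda_[1]), np.full(S, self.mu[1])]
        )
        return lo, hi


def theta_size(graph: NetworkGraph, estimate_b: bool = False, estimate_c: bool = False) -> int:
    n = 3 * graph.n_regions + graph.n_a_edges
    if estimate_b:
        n += graph.n_b_edges
    if estimate_c:
        n += len(graph.c_edges)
    return n


def pack_theta(
    neuronal: NeuronalParams,
    conn: ConnectivityParams,
    graph: NetworkGraph,
    estimate_b: bool = False,
    estimate_c: bool = False,
) -> np.ndarray:
    S = graph.n_regions
    parts = [neuronal.sigma, neuronal.lambda_, neuronal.mu]
    parts.append(conn.A[graph.a_mask.astype(bool)])
    if estimate_b:
        for m, mask in enumerate(graph.b_masks):
            parts.append(conn.B[m][mask.astype(bool)])
    if estimate_c:
        parts.append(conn.C[graph.c_mask.astype(bool)])
    return np.concatenate([np.atleast_1d(p) for p in parts])


def unpack_theta(
    theta: np.ndarray,
    graph: NetworkGraph,
    estimate_b: bool = False,
    estimate_c: bool = False,
    c_fill: float = 1.0,
) -> tuple:
    """Inverse of :func:`pack_theta`.

    Unestimated C entries are filled with ``c_fill`` on the permitted support
    (benchmark convention: unit driving weights).
    """
    S = graph.n_regions
    theta = np.asarray(theta, dtype=float)
    if theta.size != theta_size(graph, estimate_b, estimate_c):
        raise ValueError("theta has wrong length for this graph/configuration")
    neuronal = NeuronalParams(theta[:S], theta[S : 2 * S], theta[2 * S : 3 * S])
    pos = 3 * S
    A = np.zeros((S, S))
    A[graph.a_mask.astype(bool)] = theta[pos : pos + graph.n_a_edges]
    pos += graph.n_a_edges
    B = []
    for mask in graph.b_masks:
        b = np.zeros((S, S))
        if estimate_b:
            n = int(mask.sum())
            b[mask.astype(bool)] = theta[pos : pos + n]
            pos += n
        B.append(b)
    if graph.c_mask is not None:
        C = np.zeros(graph.c_mask.shape)
        if estimate_c:
            n = int(graph.c_mask.sum())
            C[graph.c_mask.astype(bool)] = theta[pos : pos + n]
            pos += n
        else:
            C[graph.c_mask.astype(bool)] = c_fill
    else:
        C = None
    return neuronal, ConnectivityParams(A, B, C)
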