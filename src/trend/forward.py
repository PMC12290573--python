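"""Forward generative models mapping stimuli and parameters to BOLD signals.

Two variants are implemented:

* ``pdcm`` — two-state excitatory/inhibitory neuronal model with adaptive
  dynamics, feedforward neurovascular coupling, and a balloon model with
  viscoelastic venous effects.  Reproduces the initial overshoot and the
  poststimulus undershoot of sustained-stimulation BOLD responses.
* ``sdcm`` — classical single-state neuronal model with feedback flow
  regulation (kappa, gamma) and no viscoelastic effect.

State per region: x_E, x_I (neuronal activity), s (vasoactive signal),
f (normalized inflow), v (normalized venous volume), q (normalized
deoxyhemoglobin).  Resting state is (0, 0, 0, 1, 1, 1) and zero stimulus
keeps the system there exactly.

Equations (per region j, with u the input channels):

    dx_E/dt = -sigma x_E - mu x_I + [(A + sum_m u_m B^m) x_E]_j + [C u_drv]_j
    dx_I/dt = lambda (x_E - x_I)                      (pdcm only; sdcm: x_I=0)
    ds/dt   = x_E - phi s                             (pdcm)
            = x_E - kappa s - gamma (f - 1)           (sdcm)
    df/dt   = phi (s - (f - 1))                       (pdcm)
            = s                                       (sdcm)
    dv/dt   = (f - v^(1/alpha)) / (tau_mtt + tau_visc)
    dq/dt   = [ f E(f)/E0 - (v^(1/alpha) + tau_visc dv/dt) q/v ] / tau_mtt
    y       = V0 [ k1 (1-q) + k2 (1 - q/v) + k3 (1-v) ]

with the oxygen extraction fraction E(f) = 1 - (1-E0)^(1/f).

Integration is fixed-step Heun (explicit trapezoid) on the ``dt_sim``\ngrid (default 10 ms),
discretize-then-differentiate: the integrator optionally propagates exact
forward sensitivities of the Euler map with respect to the estimated
parameters, so gradients agree with finite differences of the discrete
integrator itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .graph import NetworkGraph
from .params import ConnectivityParams, HemoParams, NeuronalParams
from .stimulus import StimulusDesign

__all__ = [
    "BOLDTimeSeries",
    "DivergenceError",
    "oxygen_extraction",
    "neuronal_drift",
    "hemo_drift",
    "bold_observation",
    "integrate",
    "add_measurement_noise",
]

VARIANT_PDCM = 0
VARIANT_SDCM = 1


class DivergenceError(RuntimeError):
    """Raised when a trajectory leaves the physical domain (f, v, q > 0)."""

    def __init__(self, t_fail: float, detail: str = ""):
        self.t_fail = t_fail
        super().__init__(f"state diverged at t={t_fail:.3f} s {detail}".rstrip())


@dataclass
class BOLDTimeSeries:
    """Sampled multiregion BOLD signal in percent signal change."""

    Y: np.ndarray  # (T, S)
    tr: float
    region_labels: list | None = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a T x S matrix")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("BOLD samples must be finite")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.region_labels is None:
            self.region_labels = [f"R{j + 1}" for j in range(self.Y.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]

    @property
    def n_regions(self) -> int:
        return self.Y.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.tr


# ---------------------------------------------------------------------------
# scalar reference implementations (unit-testable closed forms)
# ---------------------------------------------------------------------------

def oxygen_extraction(f, e0: float):
    """Oxygen extraction fraction E(f) = 1 - (1-E0)^(1/f).

    Decreasing in inflow f (extraction per unit blood drops as flow rises);
    E(1) = E0, E(f) -> 1 as f -> 0+, E(f) -> 0 as f -> infinity.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("inflow f must be strictly positive")
    if not 0 < e0 < 1:
        raise ValueError("e0 must lie in (0, 1)")
    return 1.0 - (1.0 - e0) ** (1.0 / f)


def neuronal_drift(
    x_e: np.ndarray,
    x_i: np.ndarray,
    u: np.ndarray,
    neuronal: NeuronalParams,
    conn: ConnectivityParams,
    design: StimulusDesign | None = None,
) -> tuple:
    """Two-state excitatory/inhibitory drift (bilinear in the inputs).

    ``u`` holds all channel amplitudes; modulatory channels scale the B
    matrices, driving channels enter through C.  With no design given, all
    channels are treated as driving.
    """
    x_e = np.asarray(x_e, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if not (np.all(np.isfinite(x_e)) and np.all(np.isfinite(x_i)) and np.all(np.isfinite(u))):
        raise FloatingPointError("nonfinite neuronal state or input")
    if design is None:
        drive_idx = list(range(u.size))
        mod_idx = []
    else:
        drive_idx = design.driving_channels
        mod_idx = design.modulatory_channels
    M = conn.A.copy()
    for m_local, m in enumerate(mod_idx):
        if m_local < len(conn.B):
            M = M + u[m] * conn.B[m_local]
    dx_e = -neuronal.sigma * x_e - neuronal.mu * x_i + M @ x_e
    if conn.C is not None and len(drive_idx) > 0:
        dx_e = dx_e + conn.C @ u[drive_idx]
    dx_i = neuronal.lambda_ * (x_e - x_i)
    return dx_e, dx_i


def hemo_drift(state: dict, x_e: np.ndarray, hemo: HemoParams, variant: str = "pdcm") -> dict:
    """Drift of the vascular states (s, f, v, q) for one variant."""
    s, f, v, q = (np.asarray(state[k], dtype=float) for k in ("s", "f", "v", "q"))
    if np.any(f <= 0) or np.any(v <= 0):
        raise DivergenceError(np.nan, "(f or v non-positive)")
    hp = hemo.for_variant(variant)
    if variant == "pdcm":
        ds = x_e - hp.phi * s
        df = hp.phi * (s - (f - 1.0))
    elif variant == "sdcm":
        ds = x_e - hp.kappa * s - hp.gamma * (f - 1.0)
        df = s
    else:
        raise ValueError(f"unknown variant {variant!r}")
    w = v ** (1.0 / hp.alpha)
    tau_tot = hp.tau_mtt + hp.tau_visc
    dv = (f - w) / tau_tot
    e_f = oxygen_extraction(f, hp.e0)
    dq = (f * e_f / hp.e0 - (w + hp.tau_visc * dv) * q / v) / hp.tau_mtt
    return {"s": ds, "f": df, "v": dv, "q": dq}


def bold_observation(v, q, hemo: HemoParams):
    """BOLD percent signal change from normalized volume and dHb content."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0):
        raise ValueError("v must be strictly positive")
    return hemo.v0 * (
        hemo.k1 * (1.0 - q) + hemo.k2 * (1.0 - q / v) + hemo.k3 * (1.0 - v)
    )


# ---------------------------------------------------------------------------
# Euler integrator with exact discrete forward sensitivities (numba)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _eval_drift(
    X,            # (6, S) state rows: xE, xI, s, f, v, q
    Z,            # (6, S, P) sensitivities (P may be 0)
    u_mod, u_drv,  # channel amplitudes at this time
    A, Bstack, C, sigma, lam, mu,
    phi, tau_mtt, tau_visc, alpha, e0, v0, k1, k2, k3, kappa, gamma,
    variant,
    a_dst, a_src, b_dst, b_src, b_ch, c_dst, c_ch,
    D,            # (6, S) output drifts
    ZD,           # (6, S, P) output sensitivity drifts
):
    """Vector field and its exact parameter-sensitivity field.

    Returns False when the state is outside the physical domain
    (f, v, q must stay strictly positive)."""
    S = sigma.shape[0]
    M = Bstack.shape[0]
    K = C.shape[1]
    P = Z.shape[2]
    E_A = a_dst.shape[0]
    E_B = b_dst.shape[0]
    E_C = c_dst.shape[0]
    iA = 3 * S
    iB = iA + E_A
    iC = iB + E_B

    xE, xI, s, f, v, q = X[0], X[1], X[2], X[3], X[4], X[5]
    for j in range(S):
        if not (
            np.isfinite(xE[j]) and np.isfinite(s[j])
            and f[j] > 0.0 and v[j] > 0.0 and q[j] > 0.0
        ):
            return False

    inv_alpha = 1.0 / alpha
    beta = np.log(1.0 - e0)
    tv = 0.0 if variant == 1 else tau_visc
    tau_tot = tau_mtt + tv

    # effective connectivity at this time
    if M > 0:
        Meff = A.copy()
        for m in range(M):
            um = u_mod[m]
            if um != 0.0:
                for r in range(S):
                    for c in range(S):
                        Meff[r, c] += um * Bstack[m, r, c]
    else:
        Meff = A

    wprime = np.empty(S)
    dGdf = np.empty(S)
    dHdf = np.empty(S)
    dHdv = np.empty(S)
    dHdq = np.empty(S)
    for j in range(S):
        acc = 0.0
        for c in range(S):
            acc += Meff[j, c] * xE[c]
        drive = 0.0
        for c in range(K):
            drive += C[j, c] * u_drv[c]
        if variant == 0:
            D[0, j] = -sigma[j] * xE[j] - mu[j] * xI[j] + acc + drive
            D[1, j] = lam[j] * (xE[j] - xI[j])
            D[2, j] = xE[j] - phi * s[j]
            D[3, j] = phi * (s[j] - (f[j] - 1.0))
        else:
            D[0, j] = -sigma[j] * xE[j] + acc + drive
            D[1, j] = 0.0
            D[2, j] = xE[j] - kappa * s[j] - gamma * (f[j] - 1.0)
            D[3, j] = s[j]

        w = v[j] ** inv_alpha
        dv = (f[j] - w) / tau_tot
        D[4, j] = dv
        ebf = np.exp(beta / f[j])
        Ef = 1.0 - ebf
        D[5, j] = (f[j] * Ef / e0 - (w + tv * dv) * q[j] / v[j]) / tau_mtt

        if P > 0:
            wprime[j] = inv_alpha * v[j] ** (inv_alpha - 1.0)
            dEdf = ebf * beta / (f[j] * f[j])
            dGdf[j] = (Ef + f[j] * dEdf) / e0
            dvdv = -wprime[j] / tau_tot
            dvdf = 1.0 / tau_tot
            dHdf[j] = tv * dvdf * q[j] / v[j]
            dHdv[j] = (wprime[j] + tv * dvdv) * q[j] / v[j] - (
                w + tv * dv
            ) * q[j] / (v[j] * v[j])
            dHdq[j] = (w + tv * dv) / v[j]

    if P > 0:
        ZxE, ZxI, Zs, Zf, Zv, Zq = Z[0], Z[1], Z[2], Z[3], Z[4], Z[5]
        for j in range(S):
            for p in range(P):
                acc = 0.0
                for c in range(S):
                    acc += Meff[j, c] * ZxE[c, p]
                if variant == 0:
                    ZD[0, j, p] = -sigma[j] * ZxE[j, p] - mu[j] * ZxI[j, p] + acc
                    ZD[1, j, p] = lam[j] * (ZxE[j, p] - ZxI[j, p])
                    ZD[2, j, p] = ZxE[j, p] - phi * Zs[j, p]
                    ZD[3, j, p] = phi * (Zs[j, p] - Zf[j, p])
                else:
                    ZD[0, j, p] = -sigma[j] * ZxE[j, p] + acc
                    ZD[1, j, p] = 0.0
                    ZD[2, j, p] = ZxE[j, p] - kappa * Zs[j, p] - gamma * Zf[j, p]
                    ZD[3, j, p] = Zs[j, p]
                ZD[4, j, p] = (Zf[j, p] - wprime[j] * Zv[j, p]) / tau_tot
                ZD[5, j, p] = (
                    (dGdf[j] - dHdf[j]) * Zf[j, p]
                    - dHdv[j] * Zv[j, p]
                    - dHdq[j] * Zq[j, p]
                ) / tau_mtt
        # parameter-explicit terms
        for j in range(S):
            ZD[0, j, j] += -xE[j]                    # d/dsigma_j
            if variant == 0:
                ZD[0, j, 2 * S + j] += -xI[j]        # d/dmu_j
                ZD[1, j, S + j] += xE[j] - xI[j]     # d/dlambda_j
        for e in range(E_A):
            ZD[0, a_dst[e], iA + e] += xE[a_src[e]]
        for e in range(E_B):
            um = u_mod[b_ch[e]]
            if um != 0.0:
                ZD[0, b_dst[e], iB + e] += um * xE[b_src[e]]
        for e in range(E_C):
            ZD[0, c_dst[e], iC + e] += u_drv[c_ch[e]]
    return True


@njit(cache=False)
def _heun_core(
    A, Bstack, C, sigma, lam, mu,
    U_mod, U_drv,
    dt, n_steps,
    sample_steps,
    phi, tau_mtt, tau_visc, alpha, e0, v0, k1, k2, k3, kappa, gamma,
    variant,
    a_dst, a_src, b_dst, b_src, b_ch, c_dst, c_ch,
    n_params,
):
    """Fixed-step Heun (explicit trapezoid) integration from rest, sampling
    BOLD (and its parameter sensitivities) on the TR grid."""
    S = sigma.shape[0]
    T = sample_steps.shape[0]
    P = n_params

    X = np.zeros((6, S))
    X[3:] = 1.0  # f, v, q start at rest
    Z = np.zeros((6, S, P))
    D1 = np.zeros((6, S))
    D2 = np.zeros((6, S))
    ZD1 = np.zeros((6, S, P))
    ZD2 = np.zeros((6, S, P))

    Y = np.zeros((T, S))
    dY = np.zeros((T, S, P))

    k_samp = 0
    for i in range(n_steps):
        if k_samp < T and sample_steps[k_samp] == i:
            for j in range(S):
                vj = X[4, j]
                qj = X[5, j]
                Y[k_samp, j] = v0 * (
                    k1 * (1.0 - qj) + k2 * (1.0 - qj / vj) + k3 * (1.0 - vj)
                )
                if P > 0:
                    dyq = v0 * (-k1 - k2 / vj)
                    dyv = v0 * (k2 * qj / (vj * vj) - k3)
                    for p in range(P):
                        dY[k_samp, j, p] = dyq * Z[5, j, p] + dyv * Z[4, j, p]
            k_samp += 1

        ok = _eval_drift(
            X, Z, U_mod[i], U_drv[i],
            A, Bstack, C, sigma, lam, mu,
            phi, tau_mtt, tau_visc, alpha, e0, v0, k1, k2, k3, kappa, gamma,
            variant, a_dst, a_src, b_dst, b_src, b_ch, c_dst, c_ch,
            D1, ZD1,
        )
        if not ok:
            return Y, dY, False, i * dt
        Xs = X + dt * D1
        Zs = Z + dt * ZD1
        # second stage reuses the left-edge input value, so boxcar edges
        # are resolved identically on every integration grid
        ok = _eval_drift(
            Xs, Zs, U_mod[i], U_drv[i],
            A, Bstack, C, sigma, lam, mu,
            phi, tau_mtt, tau_visc, alpha, e0, v0, k1, k2, k3, kappa, gamma,
            variant, a_dst, a_src, b_dst, b_src, b_ch, c_dst, c_ch,
            D2, ZD2,
        )
        if not ok:
            return Y, dY, False, (i + 1) * dt
        X += 0.5 * dt * (D1 + D2)
        Z += 0.5 * dt * (ZD1 + ZD2)
        for j in range(S):
            if not (
                np.isfinite(X[0, j]) and np.isfinite(X[2, j])
                and X[3, j] > 0.0 and X[4, j] > 0.0 and X[5, j] > 0.0
            ):
                return Y, dY, False, (i + 1) * dt

    return Y, dY, True, -1.0


def _edge_index_arrays(graph: NetworkGraph, estimate_b: bool, estimate_c: bool):
    a = graph.a_edges
    a_dst = np.ascontiguousarray(a[:, 0], dtype=np.int64)
    a_src = np.ascontiguousarray(a[:, 1], dtype=np.int64)
    if estimate_b and graph.b_masks:
        dsts, srcs, chs = [], [], []
        for m in range(len(graph.b_masks)):
            for dst, src in graph.b_edges(m):
                dsts.append(dst)
                srcs.append(src)
                chs.append(m)
        b_dst = np.array(dsts, dtype=np.int64)
        b_src = np.array(srcs, dtype=np.int64)
        b_ch = np.array(chs, dtype=np.int64)
    else:
        b_dst = b_src = b_ch = np.zeros(0, dtype=np.int64)
    if estimate_c and graph.c_mask is not None:
        ce = graph.c_edges
        c_dst = np.ascontiguousarray(ce[:, 0], dtype=np.int64)
        c_ch = np.ascontiguousarray(ce[:, 1], dtype=np.int64)
    else:
        c_dst = c_ch = np.zeros(0, dtype=np.int64)
    return a_dst, a_src, b_dst, b_src, b_ch, c_dst, c_ch


def integrate(
    graph: NetworkGraph,
    neuronal: NeuronalParams,
    conn: ConnectivityParams,
    design: StimulusDesign,
    tr: float,
    hemo: HemoParams | None = None,
    variant: str = "pdcm",
    dt_sim: float | None = None,
    return_sensitivities: bool = False,
    estimate_b: bool = False,
    estimate_c: bool = False,
):
    """Integrate the generative model and sample BOLD at every TR.

    Returns a :class:`BOLDTimeSeries`; with ``return_sensitivities=True``
    returns ``(ts, dY)`` where ``dY`` has shape (T, S, P) and P follows the
    theta layout [sigma, lambda, mu, A edges(, B edges, C edges)].
    """
    if variant not in ("pdcm", "sdcm"):
        raise ValueError(f"unknown variant {variant!r}")
    hemo = HemoParams() if hemo is None else hemo
    dt = design.dt_sim if dt_sim is None else dt_sim
    if dt > tr + 1e-12:
        raise ValueError("dt_sim must not exceed the sampling TR")
    conn.validate(graph, a_max=np.inf)  # support check; bound enforced by decoder

    S = graph.n_regions
    n_steps = int(round(design.total_duration / dt))
    T = int(np.floor(design.total_duration / tr + 1e-9))
    sample_steps = np.round(np.arange(T) * tr / dt).astype(np.int64)
    if sample_steps.size and sample_steps[-1] >= n_steps:
        sample_steps = np.clip(sample_steps, 0, n_steps - 1)

    U = design.on_grid(dt)
    U_drv = np.ascontiguousarray(U[:, design.driving_channels], dtype=np.float64)
    U_mod = np.ascontiguousarray(U[:, design.modulatory_channels], dtype=np.float64)
    M = U_mod.shape[1]
    Bstack = np.zeros((M, S, S))
    for m in range(M):
        if m < len(conn.B):
            Bstack[m] = conn.B[m]
    C = conn.C if conn.C is not None else np.zeros((S, 0))
    C = np.ascontiguousarray(np.asarray(C, dtype=np.float64))

    a_dst, a_src, b_dst, b_src, b_ch, c_dst, c_ch = _edge_index_arrays(
        graph, estimate_b, estimate_c
    )
    n_params = 0
    if return_sensitivities:
        n_params = 3 * S + a_dst.size + b_dst.size + c_dst.size

    Y, dY, ok, t_fail = _heun_core(
        np.ascontiguousarray(conn.A, dtype=np.float64),
        np.ascontiguousarray(Bstack),
        C,
        np.ascontiguousarray(neuronal.sigma, dtype=np.float64),
        np.ascontiguousarray(neuronal.lambda_, dtype=np.float64),
        np.ascontiguousarray(neuronal.mu, dtype=np.float64),
        U_mod,
        U_drv,
        float(dt),
        n_steps,
        sample_steps,
        hemo.phi, hemo.tau_mtt, hemo.tau_visc, hemo.alpha, hemo.e0,
        hemo.v0, hemo.k1, hemo.k2, hemo.k3, hemo.kappa, hemo.gamma,
        VARIANT_PDCM if variant == "pdcm" else VARIANT_SDCM,
        a_dst, a_src, b_dst, b_src, b_ch, c_dst, c_ch,
        n_params,
    )
    if not ok:
        raise DivergenceError(
            t_fail,
            f"(variant={variant}, sigma={np.round(neuronal.sigma, 3)}, "
            f"A={np.round(conn.A, 3)})",
        )
    ts = BOLDTimeSeries(Y, tr, list(graph.region_labels))
    if return_sensitivities:
        return ts, dY
    return ts


def add_measurement_noise(
    ts: BOLDTimeSeries, cnr: float, seed: int | None = None
) -> BOLDTimeSeries:
    """Add i.i.d. zero-mean Gaussian noise per region at a target CNR.

    CNR is defined as sd(signal) / sd(noise), so each region receives noise
    with standard deviation sd(region signal) / cnr.
    """
    if cnr is None or np.isinf(cnr):
        return BOLDTimeSeries(ts.Y.copy(), ts.tr, list(ts.region_labels))
    if cnr <= 0:
        raise ValueError("cnr must be positive")
    sd = ts.Y.std(axis=0, ddof=0)
    if np.any(sd == 0):
        flat = [ts.region_labels[j] for j in np.where(sd == 0)[0]]
        raise ValueError(f"constant signal in region(s) {flat}: CNR undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(ts.Y.shape) * (sd / cnr)
    return BOLDTimeSeries(ts.Y + noise, ts.tr, list(ts.region_labels))
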