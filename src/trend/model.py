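"""End-to-end estimator: Transformer encoder with a P-DCM decoder.

:class:`TREND` is the model object (data + hypothesis graph + stimulus
design); :meth:`TREND.fit` runs the autoencoder-style optimization loop and
returns a :class:`TRENDResults` carrying the decoded parameters, the loss
trajectory, the reconstructed BOLD series, and the attention maps.

Each iteration: the observed series is windowed and encoded to a parameter
vector theta, theta drives the P-DCM forward integrator over the full run,
the mean-squared error between generated and observed BOLD is computed, and
its gradient — analytic forward sensitivities through the integrator chained
with reverse-mode autodiff through the encoder — updates the encoder weights
by gradient descent with momentum.  Stopping: ``max_iter`` iterations or an
absolute loss change below ``tol``; the best-loss iterate is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import SGDMomentum
from .encoder import AttentionMaps, EncoderConfig, Theta, TransformerEncoder, window_series
from .forward import BOLDTimeSeries, DivergenceError, integrate
from .graph import NetworkGraph
from .params import HemoParams
from .stimulus import StimulusDesign

__all__ = ["FitConfig", "FitResult", "TREND", "TRENDResults", "loss", "reconstruct"]


@dataclass
class FitConfig:
    """Optimization settings for the end-to-end loop."""

    max_iter: int = 100
    tol: float = 1e-5
    lr: float = 0.4
    momentum: float = 0.8
    n_window: int | None = None  # default min(60, T)
    overlap: float = 0.95
    seed: int = 0
    step_clip: float = 0.12  # trust region on the decoded-theta step
    gn_damping: float = 1e-2  # initial Levenberg-style damping of the GN scaling
    adapt_damping: bool = True  # LM schedule: shrink on improvement, grow on failure
    max_backoff: int = 5

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


def loss(y_pred: np.ndarray, y_obs: np.ndarray) -> float:
    """Mean squared error over all samples and regions."""
    a = y_pred.Y if isinstance(y_pred, BOLDTimeSeries) else np.asarray(y_pred, float)
    b = y_obs.Y if isinstance(y_obs, BOLDTimeSeries) else np.asarray(y_obs, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


class TREND:
    """Effective-connectivity model for a multiregion BOLD observation.

    Parameters
    ----------
    endog : (T, S) array or BOLDTimeSeries
        Observed BOLD in percent signal change.
    graph : NetworkGraph
        Hypothesis graph of permitted connections.
    design : StimulusDesign
        Experimental inputs (driving / modulatory boxcars).
    tr : float, optional
        Sampling interval in seconds (required when ``endog`` is an array).
    hemo : HemoParams, optional
        Hemodynamic constants of the P-DCM decoder.
    encoder_config : EncoderConfig, optional
    """

    def __init__(
        self,
        endog,
        graph: NetworkGraph,
        design: StimulusDesign,
        tr: float | None = None,
        hemo: HemoParams | None = None,
        encoder_config: EncoderConfig | None = None,
        dt_sim: float | None = None,
    ):
        if isinstance(endog, BOLDTimeSeries):
            self.obs = endog
        else:
            if tr is None:
                raise ValueError("tr is required when endog is a plain array")
            self.obs = BOLDTimeSeries(np.asarray(endog, float), tr)
        if self.obs.n_regions != graph.n_regions:
            raise ValueError("observation and graph disagree on the number of regions")
        expected_T = int(np.floor(design.total_duration / self.obs.tr + 1e-9))
        if self.obs.n_samples != expected_T:
            raise ValueError(
                f"observation has {self.obs.n_samples} samples but the design "
                f"duration implies {expected_T} at TR={self.obs.tr}"
            )
        if np.allclose(self.obs.Y, 0.0):
            raise ValueError("all-zero observation: nothing to fit")
        self.graph = graph
        self.design = design
        self.hemo = hemo or HemoParams()
        self.encoder_config = encoder_config or EncoderConfig()
        self.dt_sim = dt_sim

    @classmethod
    def from_dataframe(cls, df, graph: NetworkGraph, design: StimulusDesign, **kw):
        """Build from a DataFrame with a ``time`` column and one column per
        region (column order must match the graph's region order)."""
        cols = [c for c in df.columns if c != "time"]
        tr = kw.pop("tr", None)
        if tr is None:
            t = np.asarray(df["time"], float)
            tr = float(np.median(np.diff(t)))
        return cls(df[cols].to_numpy(float), graph, design, tr=tr, **kw)

    def _forward(self, theta: Theta, with_sens: bool):
        return integrate(
            self.graph,
            theta.neuronal,
            theta.conn,
            self.design,
            self.obs.tr,
            hemo=self.hemo,
            variant="pdcm",
            dt_sim=self.dt_sim,
            return_sensitivities=with_sens,
            estimate_b=self.encoder_config.estimate_b,
            estimate_c=self.encoder_config.estimate_c,
        )

    def fit(self, config: FitConfig | None = None, **kwargs) -> "TRENDResults":
        """Run the end-to-end optimization; returns the best-loss iterate."""
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a FitConfig or keyword overrides, not both")
        T = self.obs.n_samples
        n_window = config.n_window or min(60, T)
        batch = window_series(self.obs.Y, n_window, config.overlap)

        enc_cfg = self.encoder_config
        if enc_cfg.seed != config.seed:
            # the fit seed governs all randomness, including weight init
            from dataclasses import replace

            enc_cfg = replace(enc_cfg, seed=config.seed)
        encoder = TransformerEncoder(self.graph, batch.N, enc_cfg)
        opt = SGDMomentum(encoder.weights, lr=config.lr, momentum=config.momentum)

        norm = T * self.obs.n_regions
        loss_curve: list[float] = []
        grad_norms: list[float] = []
        best = None
        prev_loss = None
        stop_reason = f"max_iter={config.max_iter} reached"
        converged = False
        tol_hits = 0
        last_step: dict | None = None
        damping = config.gn_damping

        it = 0
        while it < config.max_iter:
            rejected = 0
            while True:
                try:
                    theta, maps = encoder.encode(batch)
                    ts_pred, dY = self._forward(theta, with_sens=True)
                    break
                except DivergenceError as err:
                    # reject the offending weight step and retry at half size
                    rejected += 1
                    if last_step is None or rejected > config.max_backoff:
                        raise DivergenceError(
                            err.t_fail,
                            f"(aborted after {rejected - 1} step rejections "
                            f"at iteration {it})",
                        ) from err
                    opt.undo(last_step)
                    last_step = {k: 0.5 * v for k, v in last_step.items()}
                    opt.apply(last_step)
            it += 1
            residual = ts_pred.Y - self.obs.Y
            cur_loss = float(np.mean(residual**2))
            g_theta = (2.0 / norm) * np.einsum("ts,tsp->p", residual, dY)
            # Diagonal Gauss-Newton scaling: the loss curvature w.r.t. theta
            # spans orders of magnitude across parameter families; dividing by
            # the damped squared-sensitivity diagonal equalizes step sizes.
            # Damping follows a Levenberg-Marquardt schedule.
            if config.adapt_damping and prev_loss is not None:
                if cur_loss < prev_loss:
                    damping = max(damping / 1.5, 1e-4)
                else:
                    damping = min(damping * 2.0, 1.0)
            curv = (2.0 / norm) * np.einsum("tsp,tsp->p", dY, dY)
            g_theta = g_theta / (curv + damping * max(curv.max(), 1e-30))

            loss_curve.append(cur_loss)
            if best is None or cur_loss < best[0]:
                best = (cur_loss, theta, ts_pred, maps, it - 1)
            # converged when the loss change stays below tol on two
            # consecutive iterations (guards against transient plateaus)
            if prev_loss is not None and abs(prev_loss - cur_loss) < config.tol:
                tol_hits += 1
                if tol_hits >= 2:
                    converged = True
                    stop_reason = f"|delta loss| < tol at iteration {it - 1}"
                    break
            else:
                tol_hits = 0
            prev_loss = cur_loss

            opt.zero_grad()
            theta.tensor.backward(g_theta)
            grad_norms.append(
                np.sqrt(
                    sum(
                        float((t.grad**2).sum())
                        for t in encoder.weights.values()
                        if t.grad is not None
                    )
                )
            )
            # Trust region in decoded-parameter space: shrink the weight step
            # until no decoded theta coordinate moves more than step_clip.
            # The encoder map is nonlinear, so enforce by measurement.
            step = opt.propose()
            opt.apply(step)
            if config.step_clip is not None:
                for _ in range(8):
                    theta_try, _ = encoder.encode(batch)
                    dmax = float(np.max(np.abs(theta_try.vector - theta.vector)))
                    if dmax <= config.step_clip * 1.05:
                        break
                    opt.undo(step)
                    scale = 0.9 * config.step_clip / dmax
                    step = {k: v * scale for k, v in step.items()}
                    opt.apply(step)
            last_step = step

        best_loss, best_theta, best_pred, best_maps, best_iter = best
        return TRENDResults(
            model=self,
            theta=best_theta,
            loss_curve=np.array(loss_curve),
            fittedvalues=best_pred,
            maps=best_maps,
            converged=converged,
            stop_reason=stop_reason,
            best_iter=best_iter,
            seed=config.seed,
            config=config,
            grad_norms=np.array(grad_norms),
        )


@dataclass
class TRENDResults:
    """Decoded estimates and diagnostics from a TREND fit."""

    model: TREND
    theta: Theta
    loss_curve: np.ndarray
    fittedvalues: BOLDTimeSeries
    maps: AttentionMaps
    converged: bool
    stop_reason: str
    best_iter: int
    seed: int
    config: FitConfig
    grad_norms: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def params(self) -> np.ndarray:
        """Flat decoded theta (sigma, lambda, mu, connectivity edges)."""
        return self.theta.vector

    @property
    def connectivity(self) -> np.ndarray:
        """Estimated A matrix (S x S, zeros off the permitted support)."""
        return self.theta.conn.A

    @property
    def neuronal(self):
        return self.theta.neuronal

    @property
    def loss(self) -> float:
        return float(self.loss_curve[self.best_iter])

    def reconstruct(
        self, design: StimulusDesign | None = None, tr: float | None = None
    ) -> BOLDTimeSeries:
        """Forward-generate BOLD from the fitted parameters."""
        design = design or self.model.design
        tr = tr or self.model.obs.tr
        return integrate(
            self.model.graph,
            self.theta.neuronal,
            self.theta.conn,
            design,
            tr,
            hemo=self.model.hemo,
            variant="pdcm",
            dt_sim=self.model.dt_sim,
        )

    def summary(self) -> str:
        g = self.model.graph
        lines = []
        lines.append("TREND effective-connectivity fit")
        lines.append("=" * 48)
        lines.append(f"regions: {g.n_regions}   permitted A edges: {g.n_a_edges}")
        lines.append(
            f"iterations: {len(self.loss_curve)} (best at {self.best_iter})   "
            f"converged: {self.converged}"
        )
        lines.append(f"stop: {self.stop_reason}")
        lines.append(f"final loss (MSE): {self.loss:.6g}")
        lines.append("-" * 48)
        lines.append("signal-specific parameters (1/s)")
        lines.append(f"{'region':>8} {'sigma':>8} {'lambda':>8} {'mu':>8}")
        n = self.theta.neuronal
        for j, lab in enumerate(g.region_labels):
            lines.append(
                f"{lab:>8} {n.sigma[j]:8.3f} {n.lambda_[j]:8.3f} {n.mu[j]:8.3f}"
            )
        lines.append("-" * 48)
        lines.append("effective connectivity (1/s)")
        A = self.theta.conn.A
        for dst, src in g.a_edges:
            lines.append(
                f"  {g.region_labels[src]} -> {g.region_labels[dst]}: "
                f"{A[dst, src]: .4f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs reconstructed BOLD per region."""
        import matplotlib.pyplot as plt

        obs = self.model.obs
        S = obs.n_regions
        if ax is None:
            _, axes = plt.subplots(S, 1, sharex=True, figsize=(8, 2 * S))
        else:
            axes = ax
        axes = np.atleast_1d(axes)
        t = obs.time
        for j in range(S):
            axes[j].plot(t, obs.Y[:, j], label="observed")
            axes[j].plot(t, self.fittedvalues.Y[:, j], "k--", label="fitted")
            axes[j].set_ylabel(obs.region_labels[j])
        axes[0].legend(loc="upper right")
        axes[-1].set_xlabel("time (s)")
        return axes


# -- spec-style functional façade ------------------------------------------

def fit(
    y_obs: BOLDTimeSeries,
    graph: NetworkGraph,
    design: StimulusDesign,
    enc_cfg: EncoderConfig | None = None,
    fit_cfg: FitConfig | None = None,
    hemo: HemoParams | None = None,
) -> TRENDResults:
    model = TREND(y_obs, graph, design, hemo=hemo, encoder_config=enc_cfg)
    return model.fit(fit_cfg or FitConfig())


def reconstruct(result: TRENDResults, design: StimulusDesign, tr: float) -> BOLDTimeSeries:
    return result.reconstruct(design, tr)


FitResult = TRENDResults
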