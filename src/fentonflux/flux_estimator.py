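"""Neural flux estimation over a factor-graph metabolic map.

Each reaction module m gets a small fully connected network
``f_m : R^{i_m} -> R_{>=0}`` mapping its member genes' (log-standardised)
expression in a sample to a nonnegative flux.  All networks are trained
jointly, full batch, by minimising

    L = sum_j sum_{k in balanced} ( sum_{m in F_in(k)} Flux_{m,j}
                                  - sum_{m' in F_out(k)} Flux_{m',j} )^2
        + lambda * sum_j ( sum_m Flux_{m,j} - TA_j )^2

where TA_j, the total-activity surrogate, anchors the otherwise
scale-free balance problem (the all-zero flux field satisfies balance
exactly).  TA defaults to the summed expression of all map genes in the
sample, rescaled to cohort mean 1.

Architecture: input i_m -> 8 -> 4 -> 1 with tanh hidden activations and an
absolute-value output, so predicted fluxes are nonnegative by construction.
The networks are tiny, so forward/backward passes and the Adam update are
implemented directly on numpy arrays; training is full-batch and
deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolic_map import MetabolicMap

__all__ = [
    "FluxModel",
    "compute_total_activity",
    "imbalance_loss",
    "total_loss",
    "train",
    "predict_flux",
]

log = logging.getLogger(__name__)

_HIDDEN = (8, 4)


# --------------------------------------------------------------------------
# losses (pure functions of a flux matrix; used by the trainer and by tests)
# --------------------------------------------------------------------------

def compute_total_activity(
    expression: pd.DataFrame,
    map_: MetabolicMap,
    constant: float | None = None,
    rescale_mean: float | None = 1.0,
) -> pd.Series:
    """Per-sample total-activity surrogate TA_j.

    Default mode sums the expression of every map-member gene present in the
    matrix and rescales the cohort to mean ``rescale_mean`` (pass ``None``
    to keep raw sums).  ``constant`` short-circuits to a constant TA.
    """
    if constant is not None:
        return pd.Series(float(constant), index=expression.columns, name="TA")
    genes = [g for g in map_.genes() if g in expression.index]
    if not genes:
        raise ValueError("no map genes present in the expression matrix")
    ta = expression.loc[genes].sum(axis=0).astype(float)
    if rescale_mean is not None and ta.mean() > 0:
        ta = ta * (rescale_mean / ta.mean())
    ta.name = "TA"
    return ta


def imbalance_loss(flux: pd.DataFrame, map_: MetabolicMap) -> float:
    """Sum of squared (influx - outflux) over balanced pools and samples."""
    S = map_.stoichiometry_matrix(balanced_only=True)
    F = flux.loc[S.columns].to_numpy(dtype=float)
    R = S.to_numpy() @ F
    return float(np.sum(R * R))


def total_loss(
    flux: pd.DataFrame,
    map_: MetabolicMap,
    ta: pd.Series,
    lam: float = 1.0,
) -> float:
    """Imbalance loss plus the lambda-weighted total-activity anchor."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    t = flux.sum(axis=0).to_numpy(dtype=float) - ta.to_numpy(dtype=float)
    return imbalance_loss(flux, map_) + lam * float(np.sum(t * t))


# --------------------------------------------------------------------------
# per-module network
# --------------------------------------------------------------------------

class _ModuleNet:
    """i_m -> 8 -> 4 -> 1 tanh MLP with |.| output; manual backprop."""

    def __init__(self, n_in: int, rng: np.random.Generator):
        h1, h2 = _HIDDEN
        s1 = 1.0 / np.sqrt(n_in)
        s2 = 1.0 / np.sqrt(h1)
        s3 = 1.0 / np.sqrt(h2)
        self.params = [
            rng.normal(0.0, s1, size=(h1, n_in)),
            np.zeros(h1),
            rng.normal(0.0, s2, size=(h2, h1)),
            np.zeros(h2),
            rng.normal(0.0, s3, size=h2),
            np.array(0.1),  # output bias away from the |.| kink
        ]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """X is (n_in, N); returns flux (N,) and caches activations."""
        W1, b1, W2, b2, w3, b3 = self.params
        self._X = X
        self._H1 = np.tanh(W1 @ X + b1[:, None])
        self._H2 = np.tanh(W2 @ self._H1 + b2[:, None])
        self._y = w3 @ self._H2 + float(b3)
        return np.abs(self._y)

    def backward(self, dflux: np.ndarray) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. params, given dL/dflux (N,)."""
        W1, b1, W2, b2, w3, b3 = self.params
        dy = dflux * np.sign(self._y)
        dw3 = self._H2 @ dy
        db3 = np.array(dy.sum())
        dH2 = np.outer(w3, dy) * (1.0 - self._H2**2)
        dW2 = dH2 @ self._H1.T
        db2 = dH2.sum(axis=1)
        dH1 = (W2.T @ dH2) * (1.0 - self._H1**2)
        dW1 = dH1 @ self._X.T
        db1 = dH1.sum(axis=1)
        return [dW1, db1, dW2, db2, dw3, db3]


@dataclass
class FluxModel:
    """Trained per-module networks plus the preprocessing state."""

    map: MetabolicMap
    nets: dict[str, _ModuleNet]
    module_genes: dict[str, list[str]]
    gene_mean: pd.Series
    gene_sd: pd.Series
    lam: float
    epochs_run: int
    final_loss: float
    seed: int
    flux_scale: float = 1.0
    architecture: str = field(default="fc %d-%d-1, tanh, |.| output" % _HIDDEN)

    def _standardise(self, expression: pd.DataFrame) -> pd.DataFrame:
        genes = self.gene_mean.index
        missing = [g for g in genes if g not in expression.index]
        X = expression.reindex(genes).fillna(0.0)
        if missing:
            log.warning("imputing %d missing map genes as zero", len(missing))
        Z = np.log1p(X)
        return (Z.sub(self.gene_mean, axis=0)).div(self.gene_sd, axis=0)

    def predict(self, expression: pd.DataFrame, normalize: bool = True) -> pd.DataFrame:
        return predict_flux(self, expression, normalize=normalize)


def _prepare_inputs(
    map_: MetabolicMap, expression: pd.DataFrame
) -> tuple[dict[str, list[str]], pd.Series, pd.Series]:
    module_genes: dict[str, list[str]] = {}
    for mod in map_.modules:
        present = [g for g in mod.genes if g in expression.index]
        if not present:
            log.warning(
                "module %r: no member genes in the matrix; all imputed as zero",
                mod.name,
            )
        module_genes[mod.name] = list(mod.genes)
    genes = map_.genes()
    X = expression.reindex(genes).fillna(0.0)
    Z = np.log1p(X)
    mean = Z.mean(axis=1)
    sd = Z.std(axis=1).replace(0.0, 1.0).fillna(1.0)
    return module_genes, mean, sd


def train(
    map_: MetabolicMap,
    expression: pd.DataFrame,
    lam: float = 1.0,
    epochs: int = 1000,
    seed: int = 0,
    lr: float = 3e-2,
    ta: pd.Series | None = None,
    early_stop_tol: float = 1e-6,
    early_stop_window: int = 50,
    lr_decay: float = 0.01,
) -> tuple[FluxModel, list[float]]:
    """Fit the per-module networks by full-batch Adam on the total loss.

    The learning rate follows a cosine schedule from ``lr`` down to
    ``lr_decay * lr`` over the epoch budget, so late epochs polish rather
    than oscillate.  Returns the trained model and the per-epoch loss trace
    (entry 0 is the loss at initialisation).  Deterministic given ``seed``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    present = [g for g in map_.genes() if g in expression.index]
    if not present:
        raise ValueError("expression matrix contains no map genes")
    module_genes, mean, sd = _prepare_inputs(map_, expression)
    Z = ((np.log1p(expression.reindex(mean.index).fillna(0.0))).sub(mean, axis=0)).div(
        sd, axis=0
    )
    if ta is None:
        ta = compute_total_activity(expression, map_)
    ta_vec = ta.to_numpy(dtype=float)
    n_samples = Z.shape[1]

    modules = map_.module_names
    Sb = map_.stoichiometry_matrix(balanced_only=True).to_numpy()
    rng = np.random.default_rng(seed)
    nets = {m: _ModuleNet(len(module_genes[m]), rng) for m in modules}
    inputs = {m: Z.loc[module_genes[m]].to_numpy(dtype=float) for m in modules}

    # Adam state
    mom = {m: [np.zeros_like(p) for p in nets[m].params] for m in modules}
    vel = {m: [np.zeros_like(p) for p in nets[m].params] for m in modules}
    b1, b2, eps = 0.9, 0.999, 1e-8

    trace: list[float] = []
    F = np.empty((len(modules), n_samples))
    step = 0
    for epoch in range(epochs + 1):
        for i, m in enumerate(modules):
            F[i] = nets[m].forward(inputs[m])
        R = Sb @ F
        t = F.sum(axis=0) - ta_vec
        loss = float(np.sum(R * R) + lam * np.sum(t * t))
        if not np.isfinite(loss):
            raise FloatingPointError(f"loss became non-finite at epoch {epoch}")
        trace.append(loss)
        if epoch == epochs:
            break
        if (
            len(trace) > early_stop_window
            and trace[-1 - early_stop_window] > 0
            and abs(trace[-1 - early_stop_window] - trace[-1])
            <= early_stop_tol * trace[-1 - early_stop_window]
        ):
            break
        dF = 2.0 * (Sb.T @ R) + 2.0 * lam * t[None, :]
        step += 1
        frac = epoch / max(epochs - 1, 1)
        lr_t = lr * (lr_decay + (1 - lr_decay) * 0.5 * (1 + np.cos(np.pi * frac)))
        for i, m in enumerate(modules):
            grads = nets[m].backward(dF[i])
            for p, g, mo, ve in zip(nets[m].params, grads, mom[m], vel[m]):
                mo *= b1
                mo += (1 - b1) * g
                ve *= b2
                ve += (1 - b2) * g * g
                mhat = mo / (1 - b1**step)
                vhat = ve / (1 - b2**step)
                p -= lr_t * mhat / (np.sqrt(vhat) + eps)

    total = F.sum(axis=0).mean()
    scale = float(ta_vec.mean() / total) if total > 0 else 1.0
    model = FluxModel(
        map=map_,
        nets=nets,
        module_genes=module_genes,
        gene_mean=mean,
        gene_sd=sd,
        lam=lam,
        epochs_run=len(trace) - 1,
        final_loss=trace[-1],
        seed=seed,
        flux_scale=scale,
    )
    return model, trace


def predict_flux(
    model: FluxModel, expression: pd.DataFrame, normalize: bool = True
) -> pd.DataFrame:
    """Nonnegative module-by-sample flux matrix for a cohort.

    With ``normalize`` the fluxes are multiplied by the scale fitted at
    training time so the training cohort's mean total flux equals the mean
    total activity (fluxes are relative levels up to this hyperparameter).
    All-zero expression yields the networks' bias floor, still nonnegative.
    """
    Z = model._standardise(expression)
    out = {}
    for m, net in model.nets.items():
        X = Z.loc[model.module_genes[m]].to_numpy(dtype=float)
        out[m] = net.forward(X)
    F = pd.DataFrame(out, index=expression.columns).T
    if normalize:
        F = F * model.flux_scale
    return F
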