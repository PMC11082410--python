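"""Synthetic cohorts with known ground truth.

Real inputs to this kind of analysis are bulk tumour transcriptomes; here we
emulate them.  A cohort is built in two steps: first nonnegative module
fluxes that satisfy flux balance on every balanced metabolite pool of a map,
then gene expression in which each module's member genes are noisy monotone
functions of that module's flux.  A separate generator plants a linear
relation between gene-set enrichment scores and a Fenton-flux vector, and a
shuffling perturbation destroys the gene-module dependency in a chosen
fraction of samples (the robustness probe for the flux estimator).

Generative choices (documented in the methods note): source-module fluxes
are LogNormal(0, 0.5^2), sink shares of each pool are Dirichlet, per-gene
loadings are Uniform(0.5, 2), and expression noise is multiplicative
lognormal.  All generators are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metabolic_map import MetabolicMap

__all__ = [
    "GenerationError",
    "SyntheticCohort",
    "generate_fluxes",
    "generate_expression",
    "generate_rm_cohort",
    "shuffle_perturbation",
    "generate_cohort",
]


class GenerationError(RuntimeError):
    """The map's balance structure cannot be satisfied by the generator."""


@dataclass
class SyntheticCohort:
    """A simulated cohort with its generating ground truth."""

    expression: pd.DataFrame  # gene x sample, nonnegative
    true_flux: pd.DataFrame  # module x sample, nonnegative
    true_rm_support: set[str] = field(default_factory=set)
    true_beta: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _pure_sources(map_: MetabolicMap) -> set[str]:
    balanced = set(map_.balanced_set)
    return {
        m.name for m in map_.modules if not (balanced & set(m.consumes))
    }


def _balanced_topo_order(map_: MetabolicMap) -> list[str]:
    """Order balanced pools so every producer is assigned before its pool.

    Pool k depends on pool k' when some producer of k consumes k'.  The
    shipped iron/ROS map is acyclic at this level; a cycle is an error.
    """
    balanced = list(map_.balanced_set)
    deps: dict[str, set[str]] = {k: set() for k in balanced}
    for k in balanced:
        producers, _ = map_.fin_fout(k)
        for p in producers:
            for k2 in map_.module(p).consumes:
                if k2 in deps and k2 != k:
                    deps[k].add(k2)
    order: list[str] = []
    remaining = list(balanced)
    while remaining:
        ready = [k for k in remaining if deps[k] <= set(order)]
        if not ready:
            raise GenerationError(
                f"cyclic balance dependencies among {sorted(remaining)}"
            )
        order.append(ready[0])
        remaining.remove(ready[0])
    return order


def generate_fluxes(
    map_: MetabolicMap,
    n_samples: int,
    seed: int = 0,
    slack: float = 0.0,
    source_sigma: float = 0.5,
    dirichlet_alpha: float = 2.0,
) -> pd.DataFrame:
    """Nonnegative module-by-sample fluxes satisfying balance within slack.

    Source modules (those consuming no balanced pool) draw LogNormal(0,
    ``source_sigma``^2) fluxes; each balanced pool's influx is then
    apportioned to its not-yet-assigned consumers by Dirichlet shares.  When
    a pool's already-committed consumption exceeds its provisional influx,
    the pool's dedicated source modules are scaled up to cover it.  With
    ``slack`` > 0 each freshly assigned consumer flux is jittered by a
    Uniform(-slack, slack) factor, so the per-pool residual stays within
    ``slack`` x influx.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    modules = map_.module_names
    flux = pd.DataFrame(np.nan, index=modules, columns=range(n_samples))
    pure = _pure_sources(map_)
    for name in modules:
        if name in pure:
            flux.loc[name] = rng.lognormal(0.0, source_sigma, size=n_samples)

    for met in _balanced_topo_order(map_):
        producers, consumers = map_.fin_fout(met)
        if not consumers:
            raise GenerationError(f"balanced pool {met!r} has no consumers")
        influx = flux.loc[producers].sum(axis=0).to_numpy()
        assigned = [c for c in consumers if not np.isnan(flux.loc[c]).any()]
        unassigned = [c for c in consumers if c not in assigned]
        committed = (
            flux.loc[assigned].sum(axis=0).to_numpy() if assigned else np.zeros(n_samples)
        )
        if not unassigned:
            raise GenerationError(
                f"all consumers of {met!r} already committed; cannot balance"
            )
        deficit = influx <= committed
        if deficit.any():
            # scale up sources dedicated to this pool to cover commitments
            dedicated = [
                p
                for p in producers
                if p in pure and map_.module(p).produces == [met]
            ]
            if not dedicated:
                raise GenerationError(
                    f"pool {met!r}: committed consumption exceeds influx and no "
                    "dedicated source module can be rescaled"
                )
            src = flux.loc[dedicated].sum(axis=0).to_numpy()
            fixed = influx - src
            margin = 1.0 + rng.uniform(0.2, 1.0, size=n_samples)
            target = np.where(deficit, (committed - fixed) * margin, src)
            scale = np.where(deficit & (src > 0), target / np.maximum(src, 1e-300), 1.0)
            for p in dedicated:
                flux.loc[p] = flux.loc[p].to_numpy() * scale
            influx = flux.loc[producers].sum(axis=0).to_numpy()
        residual = influx - committed
        shares = rng.dirichlet(np.full(len(unassigned), dirichlet_alpha), size=n_samples).T
        values = shares * residual[None, :]
        if slack > 0:
            values = values * (1.0 + rng.uniform(-slack, slack, size=values.shape))
        for i, c in enumerate(unassigned):
            flux.loc[c] = values[i]

    if flux.isna().any().any():
        missing = flux.index[flux.isna().any(axis=1)].tolist()
        raise GenerationError(f"modules never assigned a flux: {missing}")
    flux.columns = [f"S{j}" for j in range(n_samples)]
    return flux


def _synth_gene_name(module: str, i: int) -> str:
    stem = "".join(ch if ch.isalnum() else "_" for ch in module.upper())
    return f"{stem}_SYN{i}"


def generate_expression(
    true_flux: pd.DataFrame,
    map_: MetabolicMap,
    genes_per_module: int | None = None,
    link: str = "linear",
    noise_sd: float = 0.1,
    seed: int = 0,
    loading_range: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Gene-by-sample expression driven by module fluxes.

    Each module gene g in module m gets ``loading_g * link(flux_m) * eps``
    with lognormal multiplicative noise ``eps = exp(N(0, noise_sd^2))``.
    Gene names come from map membership, padded with synthetic symbols when
    ``genes_per_module`` exceeds the membership size.  A gene shared by two
    modules accumulates both contributions.
    """
    if link not in ("linear", "log"):
        raise ValueError("link must be 'linear' or 'log'")
    rng = np.random.default_rng(seed)
    samples = list(true_flux.columns)
    rows: dict[str, np.ndarray] = {}
    for mod in map_.modules:
        genes = list(mod.genes)
        if genes_per_module is not None:
            if genes_per_module < 1:
                raise ValueError("genes_per_module must be >= 1")
            genes = genes[:genes_per_module]
            while len(genes) < genes_per_module:
                genes.append(_synth_gene_name(mod.name, len(genes) + 1))
        f = true_flux.loc[mod.name].to_numpy(dtype=float)
        base = f if link == "linear" else np.log1p(f)
        for g in genes:
            loading = rng.uniform(*loading_range)
            noise = (
                np.exp(rng.normal(0.0, noise_sd, size=len(samples)))
                if noise_sd > 0
                else 1.0
            )
            contrib = loading * base * noise
            rows[g] = rows.get(g, np.zeros(len(samples))) + contrib
    return pd.DataFrame(rows, index=samples).T


def generate_rm_cohort(
    n_samples: int,
    rm_names: list[str],
    support: set[str] | list[str],
    beta: dict[str, float] | list[float],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Enrichment-score matrix plus a linearly coupled Fenton-flux vector.

    Scores are i.i.d. standard normal; the Fenton vector is
    ``sum_r beta_r * score_r + N(0, noise_sd)`` over the supported sets.
    """
    support = list(support)
    if not set(support) <= set(rm_names):
        raise ValueError("support must be a subset of rm_names")
    if not isinstance(beta, dict):
        beta = dict(zip(support, beta, strict=True))
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame(
        rng.standard_normal((len(rm_names), n_samples)),
        index=rm_names,
        columns=[f"S{j}" for j in range(n_samples)],
    )
    fenton = np.zeros(n_samples)
    for r in support:
        fenton += beta[r] * scores.loc[r].to_numpy()
    if noise_sd > 0:
        fenton = fenton + rng.normal(0.0, noise_sd, size=n_samples)
    return scores, pd.Series(fenton, index=scores.columns, name="fenton")


def shuffle_perturbation(
    expression: pd.DataFrame,
    fraction: float,
    seed: int = 0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Permute each gene's values within a random subset of samples.

    ``floor(fraction * N)`` samples are chosen; inside that subset every
    targeted gene row is independently permuted, so per-gene marginals over
    the cohort are preserved while the gene-module dependency is destroyed
    in the perturbed samples.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = expression.copy()
    n = expression.shape[1]
    k = int(np.floor(fraction * n))
    if k < 2:
        return out
    chosen = rng.choice(n, size=k, replace=False)
    targets = expression.index if genes is None else [g for g in genes if g in expression.index]
    cols = out.columns[chosen]
    for g in targets:
        vals = out.loc[g, cols].to_numpy()
        out.loc[g, cols] = vals[rng.permutation(k)]
    return out


def generate_cohort(
    map_: MetabolicMap,
    n_samples: int = 500,
    seed: int = 0,
    noise_sd: float = 0.2,
    slack: float = 0.0,
    genes_per_module: int | None = None,
    link: str = "linear",
) -> SyntheticCohort:
    """Fluxes + expression in one call (the standard study conditions)."""
    flux = generate_fluxes(map_, n_samples, seed=seed, slack=slack)
    expr = generate_expression(
        flux,
        map_,
        genes_per_module=genes_per_module,
        link=link,
        noise_sd=noise_sd,
        seed=seed + 1,
    )
    return SyntheticCohort(expression=expr, true_flux=flux, seed=seed)
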