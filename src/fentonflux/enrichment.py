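"""Single-sample gene-set enrichment (ssGSEA running-sum scores).

The level of each reprogrammed metabolism (RM) in a sample is summarised by
the ssGSEA enrichment score: genes are ranked by descending expression and
the score is the integral of the running difference between the
``|expr|^alpha``-weighted cumulative fraction of set genes and the
unweighted cumulative fraction of non-set genes,

    ES = sum_{i=1..G} [ P_hit(i) - P_miss(i) ].

This is the running-sum integral convention (not the KS extremum of cohort
GSEA).  Ties in expression are broken by gene-symbol lexicographic order so
scores are deterministic.  ``alpha`` defaults to 0.75.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneSetCollection",
    "load_gene_sets",
    "write_gene_sets",
    "default_gene_sets",
    "ssgsea_score",
    "score_matrix",
]

GeneSetCollection = dict[str, list[str]]


def load_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> genes..."""
    collection: GeneSetCollection = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if name in collection:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
        collection[name] = genes
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "RM", *genes]) for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def default_gene_sets() -> GeneSetCollection:
    """The bundled 43 reprogrammed-metabolism gene sets."""
    with resources.as_file(
        resources.files("fentonflux.data").joinpath("rm_gene_sets.gmt")
    ) as p:
        return load_gene_sets(p)


def ssgsea_score(
    expression: pd.Series, gene_set: list[str], alpha: float = 0.75
) -> float:
    """ssGSEA running-sum enrichment score for one sample and one set.

    Returns NaN with a warning when no set gene is present in the vector.
    """
    present = set(gene_set) & set(expression.index)
    if not present:
        warnings.warn(
            "no gene of the set is present in the expression vector", stacklevel=2
        )
        return float("nan")
    # descending expression, ties broken by ascending gene symbol
    order = sorted(expression.index, key=lambda g: (-expression[g], g))
    values = expression.reindex(order).to_numpy(dtype=float)
    in_set = np.array([g in present for g in order])
    n = len(order)
    n_miss = n - int(in_set.sum())
    weights = np.where(in_set, np.abs(values) ** alpha, 0.0)
    wsum = weights.sum()
    if wsum == 0:  # all set genes at zero expression with alpha > 0
        weights = in_set.astype(float)
        wsum = weights.sum()
    p_hit = np.cumsum(weights) / wsum
    if n_miss == 0:
        p_miss = np.zeros(n)
    else:
        p_miss = np.cumsum(~in_set) / n_miss
    return float(np.sum(p_hit - p_miss))


def score_matrix(
    expression: pd.DataFrame,
    collection: GeneSetCollection,
    alpha: float = 0.75,
    normalize: bool = False,
) -> pd.DataFrame:
    """RM-by-sample enrichment scores.

    With ``normalize`` each set's scores are divided by (max - min) across
    samples, the usual cross-cohort comparability rescaling; off by default.
    """
    es = pd.DataFrame(
        {
            sample: {
                name: ssgsea_score(expression[sample], genes, alpha=alpha)
                for name, genes in collection.items()
            }
            for sample in expression.columns
        }
    )
    es = es.loc[list(collection), list(expression.columns)]
    if normalize:
        spread = es.max(axis=1) - es.min(axis=1)
        spread = spread.replace(0.0, 1.0)
        es = es.div(spread, axis=0)
    return es
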