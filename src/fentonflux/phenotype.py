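"""Cohort phenotype statistics.

Derived quantities linking predicted fluxes to tumour phenotypes: the
relative Fenton level (Fenton flux as a share of the five cytosolic-iron
outfluxes), the growth rate implied by a median tumour doubling time
(365 / days, per year), top/bottom quantile stratification of a cohort, and
the Mann-Whitney rank-sum test used for every differential comparison.

The Mann-Whitney U uses midranks for ties; P values come from exact
enumeration of all rank assignments when ``n_a + n_b <= 16`` and otherwise
from the normal approximation with tie and continuity corrections.
scipy's implementation serves as an independent cross-check in the test
suite, not as the implementation.
"""

from __future__ import annotations

import warnings
from importlib import resources
from itertools import combinations
from math import comb, erf, floor, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .association import pearson

__all__ = [
    "load_phenotype_table",
    "relative_fenton_level",
    "growth_rate",
    "stratify_quartiles",
    "mann_whitney",
    "correlate_phenotype",
    "bh_adjust",
]


def load_phenotype_table(path: str | Path | None = None) -> pd.DataFrame:
    """Per-cancer-type phenotype table; the default bundles the median
    doubling times (days) of the 11 subtypes. Metastasis rates, whose
    source data are not bundled, may be supplied in an extra column."""
    if path is None:
        text = (
            resources.files("fentonflux.data").joinpath("doubling_times.tsv").read_text()
        )
        import io

        df = pd.read_csv(io.StringIO(text), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if "doubling_days" in df.columns and (df["doubling_days"] <= 0).any():
        raise ValueError("doubling times must be positive")
    return df.set_index("type")


def relative_fenton_level(
    outfluxes: pd.Series | dict[str, float], fenton_name: str = "Fenton reaction"
) -> float:
    """Fenton flux as a fraction of the summed cytosolic-iron outfluxes.

    ``outfluxes`` holds the five outflux values (Fenton among them).
    Returns NaN when all outfluxes are zero.
    """
    s = pd.Series(outfluxes, dtype=float)
    if fenton_name not in s.index:
        raise KeyError(f"{fenton_name!r} not among the outfluxes")
    if (s < 0).any():
        raise ValueError("outfluxes must be nonnegative")
    total = float(s.sum())
    if total == 0:
        return float("nan")
    return float(s[fenton_name]) / total


def growth_rate(doubling_days: float) -> float:
    """Tumour growth rate per year, 365 / median doubling time in days."""
    if doubling_days <= 0:
        raise ValueError("doubling time must be positive")
    return 365.0 / doubling_days


def stratify_quartiles(
    values: pd.Series, q: float = 0.25
) -> tuple[list[str], list[str]]:
    """Top and bottom ``floor(q*n)`` sample labels by value.

    Ties are broken by sample label (ascending), so the split is
    deterministic; an all-equal vector still splits, with a warning.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    k = floor(q * len(values))
    if k < 1:
        raise ValueError(f"n={len(values)} too small for q={q}")
    if values.nunique() == 1:
        warnings.warn("all values equal; split is label-ordered", stacklevel=2)
    order = sorted(values.index, key=lambda s: (values[s], s))
    low = order[:k]
    high = sorted(order[-k:], key=lambda s: (-values[s], s))
    return high, low


def _normal_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum()) - n_a * (n_a + 1) / 2.0


def mann_whitney(a, b, exact_limit: int = 16) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with a two-sided P value.

    Exact enumeration of all C(n_a+n_b, n_a) rank assignments when the
    pooled size is at most ``exact_limit``; otherwise the tie-corrected
    normal approximation with continuity correction.  Returns (U_a, P).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = _u_statistic(ranks[:n_a], n_a, n_b)
    mean_u = n_a * n_b / 2.0

    if n_a + n_b <= exact_limit:
        # exchangeability under H0: every choice of n_a pooled ranks is
        # equally likely; two-sided P = 2 * min tail, capped at 1
        n = n_a + n_b
        count_le = 0
        count_ge = 0
        for idx in combinations(range(n), n_a):
            u = _u_statistic(ranks[list(idx)], n_a, n_b)
            if u <= u_a + 1e-9:
                count_le += 1
            if u >= u_a - 1e-9:
                count_ge += 1
        total = comb(n, n_a)
        p = min(1.0, 2.0 * min(count_le, count_ge) / total)
        return u_a, p

    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n_a + n_b
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sd = sqrt(n_a * n_b / 12.0 * ((n + 1) - tie_term))
    if sd == 0:
        return u_a, 1.0
    z = (abs(u_a - mean_u) - 0.5) / sd
    return u_a, min(1.0, 2.0 * _normal_sf(max(z, 0.0)))


def correlate_phenotype(per_type_stat, phenotype) -> tuple[float, float]:
    """Pearson correlation of a per-type statistic with a phenotype."""
    return pearson(per_type_stat, phenotype)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted P values (optional, for many-test panels)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
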