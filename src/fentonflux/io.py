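"""Table formats, run configuration and the end-to-end pipeline driver.

Expression tables are TSV/CSV with gene symbols in the first column and one
column per sample, on the TPM scale (an FPKM converter is provided).  The
pipeline chains: map -> flux-model training -> flux prediction -> ssGSEA
scoring -> per-type L1 association -> contribution summary (-> phenotype
correlation when a phenotype table is given), writing each stage's table
plus a manifest so a rerun with the same config reproduces every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import contribution_summary, lasso_fit, pearson
from .enrichment import default_gene_sets, load_gene_sets, score_matrix
from .flux_estimator import predict_flux, train
from .metabolic_map import FENTON_MODULE, MetabolicMap, default_map, load_map
from .phenotype import growth_rate, load_phenotype_table, relative_fenton_level

__all__ = [
    "read_expression",
    "write_expression",
    "fpkm_to_tpm",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample numeric matrix from TSV/CSV.

    First column: gene symbols (duplicates collapsed by sum, with a
    warning); header row: sample identifiers.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression table")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        for col in bad:
            non_num = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            rows = df.index[non_num].tolist()[:3]
            raise ValueError(f"{path}: non-numeric value in column {col!r}, rows {rows}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        log.warning("collapsing %d duplicated gene symbols by sum: %s", len(dups), dups[:5])
        df = df.groupby(level=0, sort=False).sum()
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep)


def fpkm_to_tpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rescaling FPKM -> TPM; every column then sums to 1e6."""
    if (matrix < 0).any().any():
        raise ValueError("FPKM matrix must be nonnegative")
    sums = matrix.sum(axis=0)
    if (sums == 0).any():
        zero_cols = sums.index[sums == 0].tolist()
        raise ValueError(f"all-zero sample columns: {zero_cols}")
    return matrix.div(sums, axis=1) * 1e6


@dataclass
class RunConfig:
    """Everything one pipeline run needs; echoed into the output manifest."""

    expression_path: str
    out_dir: str
    map_path: str | None = None  # None -> bundled iron/ROS map
    gene_set_path: str | None = None  # None -> bundled 43 RM sets
    sample_type_path: str | None = None  # TSV sample<TAB>type for per-type fits
    phenotype_path: str | None = None
    lam: float = 1.0
    epochs: int = 1000
    seed: int = 0
    alpha: float = 0.75
    q: float = 0.25
    fpkm_input: bool = False
    normalize_es: bool = False
    pooled_fit: bool = False
    bh_correction: bool = False

    def validate(self) -> None:
        for name in ("expression_path", "map_path", "gene_set_path",
                     "sample_type_path", "phenotype_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def _coverage(expression: pd.DataFrame, genes: list[str], label: str) -> float:
    present = sum(g in expression.index for g in genes)
    frac = present / len(genes) if genes else 0.0
    log.info("%s gene coverage: %d/%d (%.0f%%)", label, present, len(genes), 100 * frac)
    return frac


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the outputs; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load inputs"
    try:
        map_: MetabolicMap = (
            default_map() if config.map_path is None else load_map(config.map_path)
        )
        sets = (
            default_gene_sets()
            if config.gene_set_path is None
            else load_gene_sets(config.gene_set_path)
        )
        expr = read_expression(config.expression_path)
        if config.fpkm_input:
            expr = fpkm_to_tpm(expr)
        _coverage(expr, map_.genes(), "map")
        all_set_genes = sorted({g for gs in sets.values() for g in gs})
        _coverage(expr, all_set_genes, "gene-set")

        stage = "flux estimation"
        log.info("stage: %s", stage)
        model, trace = train(
            map_, expr, lam=config.lam, epochs=config.epochs, seed=config.seed
        )
        flux = predict_flux(model, expr)
        flux.to_csv(out / "flux.tsv", sep="\t")

        stage = "enrichment scoring"
        log.info("stage: %s", stage)
        es = score_matrix(expr, sets, alpha=config.alpha, normalize=config.normalize_es)
        es.to_csv(out / "es.tsv", sep="\t")

        stage = "association"
        log.info("stage: %s", stage)
        fenton = flux.loc[FENTON_MODULE]
        if es.isna().any().any():
            dropped = es.index[es.isna().any(axis=1)].tolist()
            log.warning(
                "dropping %d gene sets with missing scores before association",
                len(dropped),
            )
            es = es.dropna(axis=0, how="any")
            if es.empty:
                raise ValueError("no gene set has complete scores")
        if config.sample_type_path and not config.pooled_fit:
            types = pd.read_csv(
                config.sample_type_path, sep="\t", index_col=0
            ).iloc[:, 0]
            fits = {}
            for t, samples in types.groupby(types).groups.items():
                cols = [s for s in samples if s in es.columns]
                if len(cols) < 20:
                    log.warning("type %s: only %d samples; skipped", t, len(cols))
                    continue
                fits[str(t)] = lasso_fit(
                    fenton[cols], es[cols], seed=config.seed
                )
        else:
            fits = {"pooled": lasso_fit(fenton, es, seed=config.seed)}
        summary = contribution_summary(fits, min_rate=0.0 if len(fits) == 1 else 0.4)
        summary.to_frame().to_csv(out / "association_summary.tsv", sep="\t")

        stage = "phenotype"
        report_rows = []
        if config.phenotype_path:
            log.info("stage: %s", stage)
            pheno = load_phenotype_table(config.phenotype_path)
            outflux = map_.iron_outflux_modules()
            rel = flux.loc[outflux].pipe(
                lambda f: f.loc[FENTON_MODULE] / f.sum(axis=0)
            )
            report_rows.append(
                {"statistic": "mean_relative_fenton_level", "value": float(rel.mean())}
            )
            if "doubling_days" in pheno.columns and len(pheno) >= 3:
                rates = pheno["doubling_days"].map(growth_rate)
                report_rows.append(
                    {"statistic": "mean_growth_rate_per_year", "value": float(rates.mean())}
                )
        pd.DataFrame(report_rows).to_csv(out / "phenotype_report.tsv", sep="\t", index=False)

        manifest = {
            "package": "fentonflux",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "n_genes": int(expr.shape[0]),
            "n_samples": int(expr.shape[1]),
            "epochs_run": model.epochs_run,
            "final_loss": model.final_loss,
            "loss_trace_head": trace[:5],
            "loss_trace_tail": trace[-5:],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
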