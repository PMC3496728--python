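"""End-to-end orchestration: Ct table in, rhythm summary out.

``analyze_dataset`` runs the full in-memory chain —

    quantify (ddCt) -> z-score -> aggregate colonies
    -> cosinor fit (Monte-Carlo and/or least-squares) of the mean profile
    -> per-colony fits (phase-consistency flag)
    -> two-way ANOVA (colony + timepoint)
    -> permutation p for the cosine fit -> classification -> summary table

— and ``run_pipeline`` wraps it with file I/O, logging and per-stage TSV
outputs.  All randomness (Monte-Carlo search, permutations) derives from the
single config seed; per-gene streams are spawned deterministically so the
result is independent of evaluation order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cosinor, qpcr, rhythm
from .io import read_ct_table, write_tsv

__all__ = ["PipelineConfig", "analyze_dataset", "run_pipeline"]

log = logging.getLogger("antclock")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    ct_table: str | Path
    reference_gene: str = "EF1a"
    calibrator_rule: str = "mean_over_time"
    fit_method: str = "mc"
    search: str = "phase"
    n_sims: int = 100_000
    top_k: int = 400
    n_perm: int = 999
    rule: str = "p_only"
    seed: int = 0
    out_dir: str | Path = "antclock_results"

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _gene_seed(seed: int, gene: str) -> int:
    """Stable per-gene substream seed (independent of gene iteration order)."""
    h = hashlib.sha256(f"{seed}:{gene}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def analyze_dataset(
    ct: pd.DataFrame,
    reference_gene: str = "EF1a",
    calibrator_rule: str = "mean_over_time",
    fit_method: str = "mc",
    search: str = "phase",
    n_sims: int = 100_000,
    top_k: int = 400,
    n_perm: int = 999,
    rule: str = "p_only",
    seed: int = 0,
) -> dict:
    """Run the full analysis on an in-memory Ct table.

    Returns a dict with the per-stage products: ``expression`` (per-colony
    tidy table), ``aggregate`` (cross-colony mean profile), ``fits`` and
    ``colony_fits`` (CosinorFit objects), ``anovas``, ``cosine_pvalues``,
    ``fit_table`` (tidy fit parameters) and ``summary`` (one row per gene).
    """
    if fit_method not in ("mc", "ls"):
        raise ValueError(f"unknown fit_method {fit_method!r}")
    expression = qpcr.expression_series(ct, reference_gene, calibrator_rule)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aggregate = qpcr.aggregate_colonies(expression)

    genes = sorted(expression["gene"].unique())
    fits: dict[str, cosinor.CosinorFit] = {}
    colony_fits: dict[str, dict[str, cosinor.CosinorFit]] = {}
    anovas: dict[str, rhythm.AnovaResult] = {}
    pvals: dict[str, float] = {}
    fit_rows = []

    for gene in genes:
        gseed = _gene_seed(seed, gene)
        agg = aggregate[aggregate["gene"] == gene].sort_values("zt")
        zts = agg["zt"].to_numpy(float)
        y = agg["mean_z"].to_numpy(float)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if fit_method == "mc":
                fit = cosinor.fit_mc(zts, y, n_sims=n_sims, top_k=top_k, seed=gseed, search=search)
            else:
                fit = cosinor.fit_ls(zts, y)
            pvals[gene] = cosinor.fit_pvalue(zts, y, fit.r2, n_perm=n_perm, seed=gseed)
            fits[gene] = fit

            colony_fits[gene] = {}
            sub = expression[expression["gene"] == gene]
            for colony, cdf in sub.groupby("colony"):
                cdf = cdf.sort_values("zt")
                colony_fits[gene][colony] = cosinor.fit_ls(
                    cdf["zt"].to_numpy(float), cdf["zscore"].to_numpy(float)
                )

        n_colonies = expression[expression["gene"] == gene]["colony"].nunique()
        if n_colonies >= 2:
            anovas[gene] = rhythm.two_way_anova(
                expression[expression["gene"] == gene], value_col="zscore"
            )
        else:
            raise ValueError(
                f"gene {gene!r} has {n_colonies} colony; the two-way ANOVA needs >= 2"
            )

        scopes = [("across", fits[gene], pvals[gene])] + [
            (colony, f, np.nan) for colony, f in sorted(colony_fits[gene].items())
        ]
        for scope, f, p in scopes:
            fit_rows.append(
                {
                    "gene": gene,
                    "colony_scope": scope,
                    "mesor": f.params.mesor,
                    "amplitude": f.params.amplitude,
                    "acrophase": f.params.acrophase,
                    "peak_zt": f.peak_zt_grid,
                    "r2": f.r2,
                    "r2_adj": f.r2_adj,
                    "amplitude_pt": f.amplitude_pt,
                    "p_value": p,
                    "method": f.method,
                    "n_sims": f.n_sims,
                    "top_k": f.top_k,
                    "seed": f.seed,
                }
            )

    summary = rhythm.summarize(fits, anovas, pvals, colony_fits, rule=rule)
    summary.insert(len(summary.columns), "seed", seed)
    return {
        "expression": expression,
        "aggregate": aggregate,
        "fits": fits,
        "colony_fits": colony_fits,
        "anovas": anovas,
        "cosine_pvalues": pvals,
        "fit_table": pd.DataFrame(fit_rows),
        "summary": summary,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """File-to-file pipeline run: read Ct table, analyze, write stage TSVs.

    Writes ``expression.tsv``, ``aggregate.tsv``, ``fits.tsv``,
    ``anova.tsv``, ``summary.tsv`` and ``run_info.json`` (seed and config
    hash) into ``config.out_dir`` and returns the in-memory results dict.
    """
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        ct = read_ct_table(config.ct_table)
        log.info("read %d Ct records from %s", len(ct), config.ct_table)
        stage = "analyze"
        results = analyze_dataset(
            ct,
            reference_gene=config.reference_gene,
            calibrator_rule=config.calibrator_rule,
            fit_method=config.fit_method,
            search=config.search,
            n_sims=config.n_sims,
            top_k=config.top_k,
            n_perm=config.n_perm,
            rule=config.rule,
            seed=config.seed,
        )
        stage = "write"
        anova_rows = [
            {
                "gene": g,
                "f_timepoint": a.f_timepoint,
                "p_timepoint": a.p_timepoint,
                "f_colony": a.f_colony,
                "p_colony": a.p_colony,
                "df_timepoint": a.df_timepoint,
                "df_colony": a.df_colony,
                "df_resid": a.df_resid,
            }
            for g, a in sorted(results["anovas"].items())
        ]
        write_tsv(results["expression"], out_dir / "expression.tsv")
        write_tsv(results["aggregate"], out_dir / "aggregate.tsv")
        write_tsv(results["fit_table"], out_dir / "fits.tsv")
        write_tsv(pd.DataFrame(anova_rows), out_dir / "anova.tsv")
        write_tsv(results["summary"], out_dir / "summary.tsv")
        info = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": {k: str(v) for k, v in asdict(config).items()},
            "n_records": int(len(ct)),
            "n_genes": int(results["summary"].shape[0]),
        }
        with open(out_dir / "run_info.json", "w", encoding="utf-8") as fh:
            json.dump(info, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log.info("pipeline finished in %.2f s -> %s", time.perf_counter() - t0, out_dir)
    return results
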