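"""Orchestration of the three analyses: diversity report, IM fit,
bottleneck fit.  Thin, deterministic wrappers around the library stages
with TSV report writers; the command-line layer sits on top of this."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abc as abcmod
from .coalsim import SampleConfig
from .seq_data import MultiLocusDataset, validate_dataset
from .sumstats import (
    SpeciesSites,
    neutrality_panel,
    panel_frame,
    phi_st,
    summarize_bottleneck,
    summarize_im,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_diversity_report",
    "run_im_fit",
    "run_bottleneck_fit",
    "convert_generations_to_years",
]


@dataclass
class RunConfig:
    """Settings shared by the analysis stages.

    Desk-profile defaults (20,000 simulations, 200 retained) keep a full
    fit in the minutes range; the paper-scale profile is 500,000 / 5,000.
    """

    seed: int = 1
    n_sims: int = 20_000
    n_retain: int = 200
    permutations: int = 1000
    generation_time: float = 50.0  # years per generation
    mu: float = 1e-8
    method: str = "glm"
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)
            self.out_dir.mkdir(parents=True, exist_ok=True)


def convert_generations_to_years(value: float, generation_time: float) -> float:
    """Exact scaling of a time in generations to years."""
    if value < 0:
        raise ValueError("time in generations must be >= 0")
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    return value * generation_time


def _write(df: pd.DataFrame, cfg: RunConfig, name: str) -> None:
    if cfg.out_dir is not None:
        df.to_csv(cfg.out_dir / name, sep="\t", index=False, na_rep="NA",
                  float_format="%.6g")


def run_diversity_report(ds: MultiLocusDataset, cfg: RunConfig) -> dict:
    """Per-locus neutrality panels per species and pooled, plus Phi_ST.

    Returns a dict with DataFrames ``panel_<species>`` / ``panel_pooled``,
    species-level silent and total per-site diversity, and the multilocus
    Phi_ST with its permutation p-value.
    """
    report = validate_dataset(ds)
    if not report.ok:
        raise ValueError(f"invalid dataset: {report}")
    out: dict = {"validation": str(report)}
    frames = {}
    for scope in [*ds.species_labels, "pooled"]:
        panels = []
        for aln in ds.alignments:
            if scope == "pooled":
                rows = None
            else:
                rows = aln.rows_for_samples(ds.sample_ids_for_species(scope))
            panels.append(neutrality_panel(aln, rows=rows))
        frames[scope] = panel_frame(panels)
    for scope, df in frames.items():
        out[f"panel_{scope}"] = df
        _write(df, cfg, f"panel_{scope}.tsv")
    weights = [a.locus.length_bp for a in ds.alignments]
    for sp in ds.species_labels:
        df = frames[sp]
        out[f"pi_total_{sp}"] = float(np.average(df["pi_site"], weights=weights))
        out[f"pi_silent_{sp}"] = float(np.average(df["pi_silent"], weights=weights))
    phi, p = phi_st(ds, n_permutations=cfg.permutations, seed=cfg.seed)
    out["phi_st"] = phi
    out["phi_st_p"] = p
    if cfg.out_dir is not None:
        (cfg.out_dir / "phi_st.tsv").write_text(
            f"phi_st\tp_value\n{phi:.6g}\t{p:.6g}\n"
        )
    return out


def _sample_config_from(ds: MultiLocusDataset, model: str) -> SampleConfig:
    lengths = tuple(a.locus.length_bp for a in ds.alignments)
    first = ds.alignments[0]
    if model == "IM":
        labels = ds.species_labels
        n = tuple(
            len(first.rows_for_samples(ds.sample_ids_for_species(sp)))
            for sp in labels
        )
    else:
        n = (first.n_sequences,)
    return SampleConfig(locus_lengths=lengths, n_per_deme=n)


def _fit(
    ds: MultiLocusDataset,
    cfg: RunConfig,
    model: str,
    priors: abcmod.PriorSpec | None,
    scope: str = "pooled",
) -> dict:
    t0 = time.time()
    if model == "IM":
        priors = priors or abcmod.default_im_priors()
        observed = summarize_im(ds)
        sim_cfg = _sample_config_from(ds, "IM")
    else:
        priors = priors or abcmod.default_bottleneck_priors()
        per_locus = [SpeciesSites.from_alignment(a, ds) for a in ds.alignments]
        observed = summarize_bottleneck(per_locus, scope=scope)
        full = _sample_config_from(ds, "BOTTLENECK")
        if scope == "pooled":
            n = (ds.alignments[0].n_sequences,)
        else:
            n = (
                len(
                    ds.alignments[0].rows_for_samples(
                        ds.sample_ids_for_species(scope)
                    )
                ),
            )
        sim_cfg = SampleConfig(locus_lengths=full.locus_lengths, n_per_deme=n)
    if not observed.valid:
        raise ValueError(
            "observed summary vector has undefined components "
            "(insufficient variation in the dataset)"
        )
    if cfg.n_sims < 1000:
        logger.warning(
            "reference table of only %d simulations; posteriors will be rough",
            cfg.n_sims,
        )
    table = abcmod.build_reference_table(
        model, priors, cfg.n_sims, sim_cfg, cfg.seed, mu=cfg.mu
    )
    retained = abcmod.reject_nearest(table, observed, cfg.n_retain)
    post = abcmod.glm_adjust(
        retained, observed, priors, seed=cfg.seed, method=cfg.method
    )
    df = post.table(generation_time=cfg.generation_time)
    runtime = time.time() - t0
    logger.info(
        "%s fit (%s): %d simulated, %d invalid, %d retained, %.1fs, seed=%d",
        model,
        scope,
        table.n_rows,
        table.n_rows - table.n_valid,
        cfg.n_retain,
        runtime,
        cfg.seed,
    )
    return {
        "posterior": post,
        "table": df,
        "observed": observed,
        "reference": table,
        "runtime_s": runtime,
        "scope": scope,
    }


def run_im_fit(
    ds: MultiLocusDataset, cfg: RunConfig, priors: abcmod.PriorSpec | None = None
) -> dict:
    """ABC fit of the isolation-with-migration model; parameter table with
    posterior mode and 95% HPD per parameter, T also in years."""
    res = _fit(ds, cfg, "IM", priors)
    _write(res["table"], cfg, "im_fit.tsv")
    _write_grids(res["posterior"], cfg, "im")
    return res


def run_bottleneck_fit(
    ds: MultiLocusDataset,
    cfg: RunConfig,
    scope: str = "pooled",
    priors: abcmod.PriorSpec | None = None,
) -> dict:
    """ABC fit of the three-epoch bottleneck model for one scope
    (a species label or "pooled"); batch over the three scopes by calling
    once per scope."""
    res = _fit(ds, cfg, "BOTTLENECK", priors, scope=scope)
    _write(res["table"], cfg, f"bottleneck_fit_{scope}.tsv")
    _write_grids(res["posterior"], cfg, f"bottleneck_{scope}")
    return res


def _write_grids(post, cfg: RunConfig, tag: str) -> None:
    if cfg.out_dir is None:
        return
    for name, m in post.marginals.items():
        pd.DataFrame({"value": m.grid, "density": m.density}).to_csv(
            cfg.out_dir / f"density_{tag}_{name}.tsv", sep="\t", index=False
        )
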