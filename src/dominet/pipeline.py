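"""End-to-end orchestration: cohort -> networks -> centrality -> statistics.

The pipeline mirrors the study workflow: build per-subject binary networks
from regional time series, compute centralities (DomiRank plus classical
metrics), run the multi-site mega-analysis per contrast, simulate targeted
attacks, optionally classify diagnosis / predict cognition, and associate
the group-difference map with gene expression.  Every stage is deterministic
given the config seed and writes plain-text artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as cohort_mod
from .centrality import (
    CLASSICAL_METRICS,
    DomiRankParams,
    classical_centralities,
    domirank_solve,
    select_sigma,
    sigma_feasible_interval,
)
from .mega import MegaResult, mega_contrast
from .network import BinaryNetwork, FCMatrix, ThresholdConfig, compute_fc, threshold_mst
from .prediction import loso_classify, loso_regress_scores
from .robustness import lcc_area, mean_curve, targeted_attack_curve
from .transcriptomics import pls_fit, pls_permutation, rank_top_genes

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "build_networks",
    "centrality_tables",
    "similarity_map",
    "density_sweep",
]


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run (synthetic preset or user data)."""

    density: float = 0.04
    density_sweep: list[float] = field(default_factory=list)
    metrics: tuple[str, ...] = ("DomiRank", "Degree", "Strength")
    contrasts: list[tuple[str, str]] = field(default_factory=lambda: [("HC", "AD")])
    fdr_q: float = 0.05
    sigma_mode: str = "fixed_fraction"  # or "scan"
    sigma_fraction: float = 0.5
    run_prediction: bool = False
    run_pls: bool = False
    n_genes: int = 500
    pls_permutations: int = 500
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        fields = {k: v for k, v in vars(self).items() if k != "output_dir"}
        payload = json.dumps(fields, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def build_networks(
    time_series: list[np.ndarray],
    subject_ids: list[str],
    cfg: ThresholdConfig,
) -> list[BinaryNetwork]:
    nets = []
    for ts, sid in zip(time_series, subject_ids):
        fc = compute_fc(ts, subject_id=sid)
        nets.append(threshold_mst(fc, cfg))
    return nets


def _domirank_values(net: BinaryNetwork, mode: str, fraction: float) -> np.ndarray:
    if mode == "scan":
        sigma, _, _ = select_sigma(net)
    else:
        feas = sigma_feasible_interval(net)
        sigma = fraction * feas.upper_bound
    return domirank_solve(net, DomiRankParams(sigma=sigma), check_feasible=False)


def centrality_tables(
    networks: list[BinaryNetwork],
    metrics: tuple[str, ...],
    sigma_mode: str = "fixed_fraction",
    sigma_fraction: float = 0.5,
) -> dict[str, np.ndarray]:
    """Subjects x regions value matrix per requested metric."""
    classical = tuple(m for m in metrics if m in CLASSICAL_METRICS)
    out: dict[str, list[np.ndarray]] = {m: [] for m in metrics}
    for net in networks:
        if "DomiRank" in metrics:
            out["DomiRank"].append(_domirank_values(net, sigma_mode, sigma_fraction))
        if classical:
            vals = classical_centralities(net, metrics=classical)
            for m in classical:
                out[m].append(vals[m])
    return {m: np.vstack(v) for m, v in out.items() if v}


def similarity_map(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation between two regional maps (NaN if either constant)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != b.size:
        raise ValueError("maps have different lengths")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def density_sweep(
    time_series: list[np.ndarray],
    subject_ids: list[str],
    subjects: pd.DataFrame,
    densities: list[float],
    metrics: tuple[str, ...] = ("DomiRank",),
    contrast: tuple[str, str] = ("HC", "AD"),
    sigma_fraction: float = 0.5,
) -> pd.DataFrame:
    """Pairwise spatial correlation of difference maps across densities.

    For each density the full pipeline is rerun and the contrast's combined-z
    map recomputed; the output matrix reports map-to-map Pearson r.
    """
    maps = {}
    for d in densities:
        nets = build_networks(time_series, subject_ids, ThresholdConfig(density=d))
        tables = centrality_tables(nets, metrics, sigma_fraction=sigma_fraction)
        mega = mega_contrast(tables[metrics[0]], subjects, contrast=contrast)
        maps[d] = mega.combined_z
    out = pd.DataFrame(
        [[similarity_map(maps[a], maps[b]) for b in densities] for a in densities],
        index=densities,
        columns=densities,
    )
    return out


def run_pipeline(
    config: PipelineConfig,
    cohort: "cohort_mod.SyntheticCohort | None" = None,
) -> dict:
    """Execute all stages and return (and optionally write) a summary report.

    When no cohort is supplied, an effect-planted preset mirroring the
    seven-site design is generated from ``config.seed``.
    """
    if cohort is None:
        cc = cohort_mod.mcadi_like(
            effect_regions=tuple(range(5, 246, 25))[:10],
            region_delta={"MCI": -0.25, "AD": -0.5},
            seed=config.seed,
        )
        cohort = cohort_mod.generate_cohort(cc)

    subjects = cohort.subject_table()
    subject_ids = [s.subject_id for s in cohort.subjects]

    nets = build_networks(
        cohort.time_series, subject_ids, ThresholdConfig(density=config.density)
    )
    tables = centrality_tables(
        nets, config.metrics, sigma_mode=config.sigma_mode,
        sigma_fraction=config.sigma_fraction,
    )

    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(subject_ids),
        "n_regions": nets[0].n_nodes,
        "n_edges": nets[0].n_edges,
        "stages": {},
    }

    mega_results: dict[str, MegaResult] = {}
    for contrast in config.contrasts:
        key = f"{contrast[0]}_vs_{contrast[1]}"
        mega = mega_contrast(
            tables[config.metrics[0]], subjects, contrast=contrast, q=config.fdr_q
        )
        mega_results[key] = mega
        summary["stages"][f"mega_{key}"] = {
            "n_significant": int(mega.significant.sum()),
            "significant_regions": (np.flatnonzero(mega.significant) + 1).tolist(),
        }

    # group-level robustness for the primary metric, HC vs AD groups
    primary = config.metrics[0]
    curves = {}
    for grp in ("HC", "AD"):
        idx = np.flatnonzero(subjects["diagnosis"] == grp)
        if idx.size:
            subject_curves = [
                targeted_attack_curve(nets[i], tables[primary][i], metric_name=primary)
                for i in idx
            ]
            gc = mean_curve(subject_curves, metric_name=primary)
            curves[grp] = gc
            summary["stages"][f"robustness_{grp}"] = {"lcc_area": lcc_area(gc)}

    if config.run_prediction:
        mask = np.asarray(subjects["diagnosis"].isin(["HC", "AD"]))
        rep = loso_classify(
            tables[primary][mask],
            np.asarray(subjects["diagnosis"])[mask],
            np.asarray(subjects["site"])[mask],
            seed=config.seed,
        )
        reg = loso_regress_scores(
            tables[primary][mask],
            np.asarray(subjects["mmse"], dtype=float)[mask],
            np.asarray(subjects["site"])[mask],
        )
        summary["stages"]["prediction"] = {
            **{k: float(v) for k, v in rep.mean_metrics.items()},
            "mmse_r": reg["r"],
            "mmse_rmse": reg["rmse"],
            "mmse_r2": reg["r2"],
        }

    if config.run_pls:
        key = f"{config.contrasts[0][0]}_vs_{config.contrasts[0][1]}"
        zmap = mega_results[key].combined_z
        genes, signal_mask = cohort_mod.generate_gene_expression(
            n_regions=zmap.size,
            n_genes=config.n_genes,
            signal_map=zmap,
            n_signal_genes=max(config.n_genes // 10, 1),
            signal_weight=0.8,
            seed=config.seed,
        )
        res = pls_fit(zmap, genes)
        perm_p = pls_permutation(zmap, genes, B=config.pls_permutations, seed=config.seed)
        top = rank_top_genes(res, k=min(50, config.n_genes))
        summary["stages"]["pls"] = {
            "pls1_x_variance": float(res.x_variance_explained[0]),
            "pls1_response_r": res.component1_response_r,
            "permutation_p": perm_p,
            "top_gene_signal_fraction": float(
                np.mean([g in set(np.array(res.gene_names)[signal_mask]) for g in top])
            ),
        }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, mega in mega_results.items():
            mega.to_frame().to_csv(outdir / f"mega_{key}.tsv", sep="\t", index=False)
        for grp, curve in curves.items():
            pd.DataFrame(
                {
                    "fraction_removed": curve.fractions_removed,
                    "lcc_fraction": curve.lcc_fraction,
                    "metric": curve.ranking_metric,
                }
            ).to_csv(outdir / f"attack_{grp}.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
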