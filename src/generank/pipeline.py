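"""End-to-end studies: the replication study and the crossover experiment.

``run_replication_study`` mirrors the replicate design of mini-exome
workshops: one genotype study, many phenotype replicates, the four analysis
datasets, all scoring methods and endpoints, top-N causal counts per
replicate, replicate-averaged means and mixed-model scenario contrasts.

``run_crossover_experiment`` runs the case-control grid that isolates the
MS-vs-HT crossover: a fixed block of null genes per cell plus a causal gene
resimulated per replicate; the causal gene's rank distribution per method
summarises each cell.  Null genes (and their scores) are shared across the
cells of a (markers-per-gene, sample-size) group, since they do not depend
on the causal gene's parameters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._glm import logistic_marginal_stats
from .datasets import build_analysis_dataset
from .evaluation import (
    DEFAULT_TOPN,
    average_over_replicates,
    compare_scenarios_mixed_model,
    count_causal_topn,
    permutation_pvalues,
    rank_genes,
)
from .scoring import endpoint_model, score_all_genes, scores_to_frame
from .simulate import (
    CaseControlScenario,
    ExomeConfig,
    case_control_status,
    simulate_causal_gene,
    simulate_exome,
    simulate_null_genes,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)


def derive_seed(*parts: int) -> int:
    """Deterministic child seed from (master seed, indices), below 2^31."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Configuration of a full replication study."""

    exome: ExomeConfig = field(default_factory=ExomeConfig)
    replicates: int = 10
    methods: tuple[str, ...] = ("MS", "HT", "MV", "LA")
    endpoints: tuple[str, ...] = ("Q1", "Q2", "AFF")
    cutoffs: tuple[float, ...] = (0.01, 0.05)
    rare_flags: tuple[bool, ...] = (True, False)
    topn: tuple[int, ...] = DEFAULT_TOPN
    perm_B: int = 0
    seed: int = 0
    outdir: str | Path = "generank_run"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["exome"] = dict(self.exome.__dict__)
        d["outdir"] = str(self.outdir)
        return d


def run_replication_study(cfg: RunConfig) -> dict:
    """Simulate, build, score, evaluate; write all tables to cfg.outdir.

    Per-replicate phenotype seeds derive deterministically from the master
    seed, so re-running the same configuration reproduces every table.
    Failures inside one replicate are logged and skipped; the summary then
    notes the missing cells.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[tuple[str, float]] = []
    conf_hash = io.config_hash(cfg.to_dict())
    meta = {"config_hash": conf_hash, "seed": cfg.seed}

    exome_cfg = replace(cfg.exome, seed=derive_seed(cfg.seed, 0))
    study, truth = simulate_exome(exome_cfg)
    io.write_genotypes(outdir / "genotypes.tsv", study, meta)
    io.write_markers(outdir / "markers.tsv", study, meta)
    io.write_truth(outdir / "truth.tsv", truth, meta)
    stages.append(("simulate_exome", time.time() - t0))

    t1 = time.time()
    datasets = {}
    for cutoff in cfg.cutoffs:
        for include_rare in cfg.rare_flags:
            ds = build_analysis_dataset(study, cutoff, include_rare)
            datasets[ds.label] = ds
            io.write_analysis_dataset(outdir / f"dataset_{ds.label.replace('%', 'pct')}", ds)
    stages.append(("build_datasets", time.time() - t1))

    t2 = time.time()
    rep_seeds = [derive_seed(cfg.seed, 1, r) for r in range(cfg.replicates)]
    result_rows, score_frames, failures = [], [], []
    for r, rep_seed in enumerate(rep_seeds):
        phenotypes = simulate_phenotypes(study, truth, exome_cfg, seed=rep_seed)
        for endpoint in cfg.endpoints:
            model = endpoint_model(endpoint)
            causal = truth.causal_genes(endpoint)
            for label, ds in datasets.items():
                for method in cfg.methods:
                    try:
                        scores = score_all_genes(
                            ds, model, method, phenotypes, seed=rep_seed
                        )
                        ranked = rank_genes(scores)
                        counts = count_causal_topn(ranked, causal, cfg.topn)
                    except Exception as exc:
                        logger.warning(
                            "replicate %d %s/%s/%s failed: %s", r, label, endpoint, method, exc
                        )
                        failures.append((r, label, endpoint, method, str(exc)))
                        continue
                    if r == 0:
                        score_frames.append(scores_to_frame(scores, label))
                    for n, count in counts.items():
                        result_rows.append(
                            {
                                "method": method,
                                "cutoff": ds.cutoff,
                                "includes_rare": ds.includes_rare,
                                "endpoint": endpoint,
                                "replicate": r,
                                "topn": n,
                                "count": count,
                            }
                        )
    results = pd.DataFrame(result_rows)
    io.write_phenotypes(outdir / "scenario_results.tsv", results, meta)
    if score_frames:
        io.write_phenotypes(
            outdir / "gene_scores_rep0.tsv", pd.concat(score_frames, ignore_index=True), meta
        )
    stages.append(("score_and_evaluate", time.time() - t2))

    t3 = time.time()
    means = average_over_replicates(results) if len(results) else pd.DataFrame()
    io.write_phenotypes(outdir / "mean_counts.tsv", means, meta)
    contrasts = pd.DataFrame()
    if cfg.replicates >= 2 and not failures and len(results):
        contrasts = compare_scenarios_mixed_model(results)
        io.write_phenotypes(outdir / "scenario_contrasts.tsv", contrasts, meta)
    stages.append(("summaries", time.time() - t3))

    perm = pd.DataFrame()
    if cfg.perm_B:
        t4 = time.time()
        phenotypes = simulate_phenotypes(study, truth, exome_cfg, seed=rep_seeds[0])
        first_label = next(iter(datasets))
        perm_parts = []
        for endpoint in cfg.endpoints:
            if endpoint == "AFF":
                continue  # quantitative endpoints only, as in the reference workflow
            pp = permutation_pvalues(
                datasets[first_label],
                endpoint_model(endpoint),
                cfg.methods[0],
                phenotypes,
                B=cfg.perm_B,
                seed=derive_seed(cfg.seed, 2),
            )
            pp.insert(0, "endpoint", endpoint)
            perm_parts.append(pp)
        if perm_parts:
            perm = pd.concat(perm_parts, ignore_index=True)
            io.write_phenotypes(outdir / "permutation_p.tsv", perm, meta)
        stages.append(("permutation", time.time() - t4))

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": conf_hash,
        "replicate_seeds": rep_seeds,
        "version": "0.1.0",
        "n_failures": len(failures),
        "failures": failures,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(outdir / "run.log", "w") as fh:
        for stage, seconds in stages:
            fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')}\t{stage}\t{seconds:.2f}s\n")

    return {
        "results": results,
        "means": means,
        "contrasts": contrasts,
        "permutation": perm,
        "datasets": datasets,
        "study": study,
        "truth": truth,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# crossover experiment


def crossover_grid(
    n_causal_markers: tuple[int, ...] = (1, 2, 3),
    markers_per_gene: tuple[int, ...] = (2, 3, 5, 7),
    causal_mafs: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20, 0.40),
    odds_ratios: tuple[float, ...] = (1.2, 1.3, 1.5, 1.7),
    n_cases: tuple[int, ...] = (300, 1000),
    n_null_genes: int = 2000,
    n_causal_replicates: int = 1000,
    baseline_prevalence: float = 0.01,
) -> list[CaseControlScenario]:
    """The full scenario grid (cells with n_causal > markers are skipped)."""
    cells = []
    for k in n_causal_markers:
        for m in markers_per_gene:
            if k > m:
                continue
            for af in causal_mafs:
                for orr in odds_ratios:
                    for n in n_cases:
                        cells.append(
                            CaseControlScenario(
                                n_null_genes=n_null_genes,
                                markers_per_null_gene=m,
                                n_causal_markers=k,
                                causal_maf=af,
                                odds_ratio=orr,
                                n_cases=n,
                                n_causal_replicates=n_causal_replicates,
                                baseline_prevalence=baseline_prevalence,
                            )
                        )
    return cells


def _null_gene_scores(
    sc: CaseControlScenario, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """MS and HT scores of the scenario's null genes (computed once)."""
    study = simulate_null_genes(sc, seed=seed)
    y = case_control_status(sc)
    res = logistic_marginal_stats(study.genotypes, y, None)
    t = res["stat"]
    m = sc.markers_per_null_gene
    t_by_gene = t.reshape(sc.n_null_genes, m)
    with np.errstate(invalid="ignore"):
        ms = np.nanmax(np.abs(t_by_gene), axis=1)
    ht = np.empty(sc.n_null_genes)
    for g in range(sc.n_null_genes):
        cols = slice(g * m, (g + 1) * m)
        tg = t_by_gene[g]
        ok = np.isfinite(tg)
        if not ok.any():
            ht[g] = np.nan
            continue
        G = study.genotypes[:, cols].astype(float)[:, ok]
        R = np.corrcoef(G, rowvar=False) if ok.sum() > 1 else np.array([[1.0]])
        ht[g] = float(tg[ok] @ np.linalg.pinv(R, rcond=1e-10) @ tg[ok])
    return ms, ht


def _rank_among(null_scores: np.ndarray, s: float) -> float:
    finite = null_scores[np.isfinite(null_scores)]
    return 1.0 + float((finite > s).sum()) + 0.5 * float((finite == s).sum())


def run_crossover_experiment(
    cells: list[CaseControlScenario],
    n_replicates: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per grid cell: the causal gene's rank distribution under MS and HT.

    Null-gene scores are computed once per (markers-per-gene, sample-size)
    group and reused across that group's cells; each causal replicate draws
    fresh causal-gene genotypes given the fixed case/control status.
    Returns one row per cell with median ranks and MS-vs-HT win rates.
    """
    null_cache: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    for idx, sc in enumerate(cells):
        reps = n_replicates if n_replicates is not None else sc.n_causal_replicates
        key = (sc.markers_per_null_gene, sc.n_cases, sc.n_null_genes)
        if key not in null_cache:
            null_seed = derive_seed(seed, 7, *key)
            null_cache[key] = _null_gene_scores(sc, null_seed)
        null_ms, null_ht = null_cache[key]

        y = case_control_status(sc)
        m = sc.markers_per_null_gene
        # simulate all replicates, then one vectorised marginal pass
        blocks = [
            simulate_causal_gene(sc, seed=derive_seed(seed, 11, idx, r))[0]
            for r in range(reps)
        ]
        G_all = np.hstack(blocks)
        t_all = logistic_marginal_stats(G_all, y, None)["stat"].reshape(reps, m)

        ms_ranks = np.empty(reps)
        ht_ranks = np.empty(reps)
        for r in range(reps):
            tg = t_all[r]
            ok = np.isfinite(tg)
            ms_score = np.abs(tg[ok]).max() if ok.any() else np.nan
            ms_ranks[r] = (
                _rank_among(null_ms, ms_score) if np.isfinite(ms_score) else len(null_ms) + 1
            )
            if ok.any():
                G = blocks[r].astype(float)[:, ok]
                R = np.corrcoef(G, rowvar=False) if ok.sum() > 1 else np.array([[1.0]])
                ht_score = float(tg[ok] @ np.linalg.pinv(R, rcond=1e-10) @ tg[ok])
                ht_ranks[r] = _rank_among(null_ht, ht_score)
            else:
                ht_ranks[r] = len(null_ht) + 1

        rows.append(
            {
                "n_causal_markers": sc.n_causal_markers,
                "markers_per_gene": m,
                "causal_maf": sc.causal_maf,
                "odds_ratio": sc.odds_ratio,
                "n_cases": sc.n_cases,
                "n_replicates": reps,
                "median_rank_MS": float(np.median(ms_ranks)),
                "median_rank_HT": float(np.median(ht_ranks)),
                "ms_win_rate": float(np.mean(ms_ranks < ht_ranks)),
                "ht_win_rate": float(np.mean(ht_ranks < ms_ranks)),
            }
        )
        logger.info("crossover cell %d/%d done", idx + 1, len(cells))
    return pd.DataFrame(rows)


def crossover_summary(table: pd.DataFrame) -> dict:
    """Fraction of cells in which each method attains the better median rank."""
    single = table[table["n_causal_markers"] == 1]
    multi = table[table["n_causal_markers"] >= 2]
    out = {}
    if len(single):
        out["ms_better_single_frac"] = float(
            (single["median_rank_MS"] <= single["median_rank_HT"]).mean()
        )
        out["n_single_cells"] = int(len(single))
    if len(multi):
        out["ht_better_multi_frac"] = float(
            (multi["median_rank_HT"] <= multi["median_rank_MS"]).mean()
        )
        out["n_multi_cells"] = int(len(multi))
    return out
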