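"""Causal-gene characteristics and method-preference analysis.

For each causal gene the analysis records how many markers it carries, how
many of them are causal, and frequency-adjusted effect sizes
(|beta| * sd(genotype); under HWE the additive genotype SD is
sqrt(2 f (1 - f))).  Genes are then grouped by which scoring method ranked
them better -- the ratio of median ranks below 0.9 or above 1.1 defines a
clear preference -- and the characteristics are compared between groups
with a two-sided Mann-Whitney test (exact when sample sizes permit).
"""

from __future__ import annotations

import logging
import math
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .types import SUPERMARKER, AnalysisDataset, TruthTable

logger = logging.getLogger(__name__)


def median_rank_table(ranks: pd.DataFrame) -> pd.DataFrame:
    """Median rank per (gene, method, dataset) over replicates.

    ``ranks`` must carry columns gene_id, method, dataset, replicate, rank;
    missing ranks are excluded from that gene's median (logged).
    """
    frame = ranks.copy()
    n_missing = int(frame["rank"].isna().sum())
    if n_missing:
        logger.info("median_rank_table: excluding %d missing ranks", n_missing)
        frame = frame.dropna(subset=["rank"])
    out = (
        frame.groupby(["gene_id", "method", "dataset"])["rank"]
        .median()  # numpy midpoint convention for even counts
        .reset_index()
        .rename(columns={"rank": "median_rank"})
    )
    return out


class Preference(str, Enum):
    A_BETTER = "A_better"
    B_BETTER = "B_better"
    NEITHER = "neither"
    UNDETECTABLE = "undetectable"


def classify_method_preference(
    median_a: float,
    median_b: float,
    detect_threshold: float = 1000.0,
    ratio_low: float = 0.9,
    ratio_high: float = 1.1,
) -> Preference:
    """Classify which method detected a gene better from median ranks.

    Smaller rank is better.  ratio = median_A / median_B; below
    ``ratio_low`` method A wins, above ``ratio_high`` method B wins,
    otherwise neither.  A gene is undetectable unless at least one method
    achieves a median rank <= ``detect_threshold``.
    """
    if not (median_a >= 1 and median_b >= 1) or not (
        math.isfinite(median_a) and math.isfinite(median_b)
    ):
        raise ValueError("median ranks must be finite and >= 1")
    if min(median_a, median_b) > detect_threshold:
        return Preference.UNDETECTABLE
    ratio = median_a / median_b
    if ratio < ratio_low:
        return Preference.A_BETTER
    if ratio > ratio_high:
        return Preference.B_BETTER
    return Preference.NEITHER


def gene_characteristics(
    gene_id: str,
    truth: TruthTable,
    dataset: AnalysisDataset,
    endpoint: str,
) -> dict:
    """Characteristics of one gene in one analysis dataset.

    Effect sizes are frequency-adjusted: |beta| * sqrt(2 f (1-f)) for
    additive markers and |beta| * sd(indicator column) for supermarkers
    (whose generating beta is the mean beta of the contributing causal
    variants).  The strongest and second-strongest causal markers are
    ranked by this quantity.
    """
    if gene_id not in dataset.gene_to_cols:
        raise KeyError(f"gene {gene_id} not present in dataset {dataset.label}")
    cols = dataset.gene_to_cols[gene_id]
    markers = dataset.markers.iloc[cols]
    causal = truth.causal_markers(endpoint)
    causal_beta = dict(zip(causal["marker_id"], causal["beta"]))

    effects: list[tuple[float, float]] = []  # (adjusted effect, maf)
    n_causal = 0
    for local_idx, (_, rec) in enumerate(markers.iterrows()):
        if rec["func_class"] == SUPERMARKER:
            sources = [s for s in str(rec["source_variants"]).split(",") if s]
            betas = [abs(causal_beta[s]) for s in sources if s in causal_beta]
            if not betas:
                continue
            n_causal += 1
            col = dataset.genotypes[:, cols[local_idx]].astype(float)
            effects.append((float(np.mean(betas)) * float(col.std()), rec["maf"]))
        elif rec["marker_id"] in causal_beta:
            n_causal += 1
            f = float(rec["maf"])
            adj = abs(causal_beta[rec["marker_id"]]) * math.sqrt(2.0 * f * (1.0 - f))
            effects.append((adj, f))

    n_markers = len(cols)
    out = {
        "gene_id": gene_id,
        "markers_per_gene": n_markers,
        "causal_marker_count": n_causal,
        "causal_marker_pct": 100.0 * n_causal / n_markers if n_markers else np.nan,
        "strongest_effect": np.nan,
        "strongest_freq": np.nan,
        "second_relative_effect_pct": np.nan,
    }
    if effects:
        effects.sort(key=lambda e: -e[0])
        out["strongest_effect"] = effects[0][0]
        out["strongest_freq"] = effects[0][1]
        if len(effects) > 1 and effects[0][0] > 0:
            out["second_relative_effect_pct"] = 100.0 * effects[1][0] / effects[0][0]
    return out


def rank_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact enumeration when there are no ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if has_ties:
        # identical or tied samples: normal approximation without continuity
        # correction so that identical groups give p = 1 exactly
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    return float(res.pvalue)


CHARACTERISTIC_ROWS = [
    "markers_per_gene",
    "causal_marker_count",
    "causal_marker_pct",
    "strongest_effect",
    "strongest_freq",
    "second_relative_effect_pct",
]


def compare_groups(
    characteristics: pd.DataFrame,
    labels: pd.Series | dict,
    group_a: str = "A_better",
    group_b: str = "B_better",
) -> pd.DataFrame:
    """Group means (SD) and rank-based p-values per characteristic.

    ``labels`` maps gene_id to a preference label.  A group of fewer than
    two genes gets its mean reported with SD and p missing (the "NA"
    convention).
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    frame = characteristics.set_index("gene_id")
    genes_a = [g for g in frame.index if labels.get(g) == group_a]
    genes_b = [g for g in frame.index if labels.get(g) == group_b]

    rows = []
    for char in CHARACTERISTIC_ROWS:
        if char not in frame.columns:
            continue
        a = frame.loc[genes_a, char].dropna().to_numpy()
        b = frame.loc[genes_b, char].dropna().to_numpy()
        row = {
            "characteristic": char,
            "n_a": len(a),
            "n_b": len(b),
            "mean_a": float(np.mean(a)) if len(a) else np.nan,
            "sd_a": float(np.std(a, ddof=1)) if len(a) > 1 else np.nan,
            "mean_b": float(np.mean(b)) if len(b) else np.nan,
            "sd_b": float(np.std(b, ddof=1)) if len(b) > 1 else np.nan,
            "p": np.nan,
        }
        if len(a) >= 2 and len(b) >= 2:
            row["p"] = rank_test(a, b)
        rows.append(row)
    return pd.DataFrame(rows)
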