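"""Assembly of the four analysis datasets (CR1%, CR5%, C1%, C5%).

A variant is *common* when its in-sample MAF exceeds the cutoff (1% or 5%)
and *rare* when 0 < MAF <= cutoff.  The CR datasets keep all common variants
and add, per gene, a 0/1 "supermarker" indicating carriage of at least one
rare nonsynonymous minor allele (indicator collapsing); the C datasets drop
the supermarkers.  Markers with fewer than five minor alleles -- including
supermarkers -- are removed to stabilise regression fits, and genes left
without markers are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    DATASET_LABELS,
    NONSYNONYMOUS,
    SUPERMARKER,
    AnalysisDataset,
    GenotypeStudy,
)

MIN_MINOR_ALLELES = 5


def compute_maf(column: np.ndarray) -> tuple[float, int]:
    """Minor-allele frequency and minor-allele count of a genotype column.

    The allele frequency is ``sum(g) / (2n)``; when it exceeds 0.5 the minor
    allele is the reference allele and both frequency and count are flipped.
    Supermarker (0/1) columns go through the same formula on their 0/1
    coding.
    """
    g = np.asarray(column)
    if g.size == 0:
        raise ValueError("cannot compute MAF of an empty genotype column")
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotype entries must be in {0, 1, 2}")
    n = g.size
    count = int(g.sum())
    af = count / (2 * n)
    if af > 0.5:
        af = 1.0 - af
        count = 2 * n - count
    return af, count


def collapse_rare_variants(
    gene_genotypes: np.ndarray, variant_ids: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Indicator collapsing of a gene's qualifying rare variants.

    ``gene_genotypes`` holds only the gene's nonsynonymous variants with
    minor-allele frequency below the rare cutoff (the caller selects them).
    The supermarker is 1 for individuals carrying at least one minor allele
    across those variants, else 0.  Returns the 0/1 column and the list of
    contributing variant ids.
    """
    g = np.asarray(gene_genotypes)
    if g.ndim == 1:
        g = g[:, None]
    if g.shape[1] == 0:
        raise ValueError("no qualifying rare variants to collapse")
    super_col = (g.sum(axis=1) > 0).astype(np.int8)
    ids = list(variant_ids) if variant_ids is not None else []
    return super_col, ids


def build_analysis_dataset(
    study: GenotypeStudy,
    cutoff: float,
    include_rare: bool,
    *,
    allow_any_cutoff: bool = False,
) -> AnalysisDataset:
    """Build one analysis dataset from a genotype study.

    Keeps common variants (in-sample MAF > cutoff, any functional class);
    when ``include_rare`` adds one supermarker per gene with >=1 rare
    (0 < MAF <= cutoff) nonsynonymous variant; then removes every marker
    (supermarkers included) with fewer than five minor alleles and drops
    genes left without markers.
    """
    if cutoff not in (0.01, 0.05) and not allow_any_cutoff:
        raise ValueError(
            f"cutoff must be 0.01 or 0.05 (got {cutoff}); "
            "pass allow_any_cutoff=True to override"
        )

    maf = np.empty(study.n_markers)
    mac = np.empty(study.n_markers, dtype=int)
    for j in range(study.n_markers):
        maf[j], mac[j] = compute_maf(study.genotypes[:, j])

    is_common = maf > cutoff
    is_rare = (maf > 0) & (maf <= cutoff)
    is_nonsyn = (study.markers["func_class"] == NONSYNONYMOUS).to_numpy()

    columns: list[np.ndarray] = []
    rows: list[dict] = []
    for j in np.flatnonzero(is_common):
        columns.append(study.genotypes[:, j])
        rec = study.markers.iloc[j]
        rows.append(
            {
                "marker_id": rec["marker_id"],
                "gene_id": rec["gene_id"],
                "func_class": rec["func_class"],
                "maf": maf[j],
                "mac": mac[j],
                "source_variants": "",
            }
        )

    if include_rare:
        collapsible = is_rare & is_nonsyn
        for gene in study.gene_ids:
            cols = study.gene_columns(gene)
            qual = cols[collapsible[cols]]
            if qual.size == 0:
                continue  # nothing to collapse for this gene: no supermarker
            ids = study.markers["marker_id"].iloc[qual].tolist()
            super_col, _ = collapse_rare_variants(study.genotypes[:, qual], ids)
            s_maf, s_mac = compute_maf(super_col)
            columns.append(super_col)
            rows.append(
                {
                    "marker_id": f"{gene}::super",
                    "gene_id": gene,
                    "func_class": SUPERMARKER,
                    "maf": s_maf,
                    "mac": s_mac,
                    "source_variants": ",".join(ids),
                }
            )

    markers = pd.DataFrame(
        rows,
        columns=["marker_id", "gene_id", "func_class", "maf", "mac", "source_variants"],
    )
    matrix = (
        np.column_stack(columns).astype(np.int8)
        if columns
        else np.empty((study.n_individuals, 0), dtype=np.int8)
    )

    keep = markers["mac"].to_numpy() >= MIN_MINOR_ALLELES if len(markers) else np.array([], bool)
    markers = markers.loc[keep].reset_index(drop=True)
    matrix = matrix[:, keep]

    gene_to_cols = {
        gene: np.flatnonzero((markers["gene_id"] == gene).to_numpy())
        for gene in dict.fromkeys(markers["gene_id"])
    }

    label = DATASET_LABELS.get(
        (cutoff, include_rare),
        f"{'CR' if include_rare else 'C'}{cutoff * 100:g}%",
    )
    return AnalysisDataset(
        label=label,
        cutoff=cutoff,
        includes_rare=include_rare,
        genotypes=matrix,
        markers=markers,
        gene_to_cols=gene_to_cols,
    )


def build_all_datasets(study: GenotypeStudy) -> dict[str, AnalysisDataset]:
    """The four standard datasets keyed by label."""
    out = {}
    for cutoff in (0.01, 0.05):
        for include_rare in (True, False):
            ds = build_analysis_dataset(study, cutoff, include_rare)
            out[ds.label] = ds
    return out


def study_as_dataset(study: GenotypeStudy, label: str = "raw") -> AnalysisDataset:
    """Wrap a study as an unfiltered dataset (no cutoff, no collapsing).

    Used where scoring should see the simulated markers as-is, e.g. the
    case-control scenario whose markers are already 'common or collapsed'.
    """
    maf = np.empty(study.n_markers)
    mac = np.empty(study.n_markers, dtype=int)
    for j in range(study.n_markers):
        maf[j], mac[j] = compute_maf(study.genotypes[:, j])
    markers = study.markers.copy()
    markers["maf"] = maf
    markers["mac"] = mac
    markers["source_variants"] = ""
    gene_to_cols = {
        gene: np.flatnonzero((markers["gene_id"] == gene).to_numpy())
        for gene in dict.fromkeys(markers["gene_id"])
    }
    return AnalysisDataset(
        label=label,
        cutoff=0.0,
        includes_rare=False,
        genotypes=study.genotypes,
        markers=markers,
        gene_to_cols=gene_to_cols,
    )


def ld_supermarker_vs_common(dataset: AnalysisDataset) -> pd.DataFrame:
    """Per-gene maximum r^2 between the supermarker and the gene's common markers.

    r^2 is the squared Pearson correlation of genotype columns.  Genes
    lacking either a supermarker or a common marker are omitted; a
    zero-variance column makes r^2 undefined and is reported as NaN.
    """
    records = []
    is_super = (dataset.markers["func_class"] == SUPERMARKER).to_numpy()
    for gene, cols in dataset.gene_to_cols.items():
        sup = cols[is_super[cols]]
        com = cols[~is_super[cols]]
        if sup.size == 0 or com.size == 0:
            continue
        s = dataset.genotypes[:, sup[0]].astype(float)
        best = np.nan
        if s.std() > 0:
            r2s = []
            for j in com:
                c = dataset.genotypes[:, j].astype(float)
                if c.std() == 0:
                    continue
                r = np.corrcoef(s, c)[0, 1]
                r2s.append(r * r)
            if r2s:
                best = float(max(r2s))
        records.append({"gene_id": gene, "max_r2": best})
    return pd.DataFrame(records, columns=["gene_id", "max_r2"])
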