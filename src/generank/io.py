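"""Plain-text readers and writers (TSV, VCF, YAML config).

Tabular outputs are tab-separated with '#'-prefixed metadata lines at the
top (dataset label, config hash, seed) so every file is self-describing.
Genotypes travel as individuals x markers TSV with a header row of marker
ids; marker metadata, phenotypes and truth tables are ordinary TSV.
Simulated genotypes can also be exported as a minimal single-contig VCF;
VCF import requires complete GT fields (missing genotypes fail fast).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import AnalysisDataset, GenotypeStudy, TruthTable


def _write_with_meta(path: Path, frame: pd.DataFrame, meta: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: Path) -> pd.DataFrame:
    """Read a TSV written by this module, skipping '#' metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_genotypes(path: Path, study: GenotypeStudy, meta: dict | None = None) -> None:
    frame = pd.DataFrame(study.genotypes, columns=study.markers["marker_id"])
    _write_with_meta(path, frame, meta)


def write_markers(path: Path, study: GenotypeStudy, meta: dict | None = None) -> None:
    _write_with_meta(path, study.markers, meta)


def read_genotype_study(genotype_path: Path, marker_path: Path) -> GenotypeStudy:
    geno = read_table(genotype_path)
    markers = read_table(marker_path)
    if list(geno.columns) != list(markers["marker_id"]):
        raise ValueError("genotype columns and marker metadata rows disagree")
    return GenotypeStudy(genotypes=geno.to_numpy(dtype=np.int8), markers=markers)


def write_phenotypes(path: Path, phenotypes: pd.DataFrame, meta: dict | None = None) -> None:
    _write_with_meta(path, phenotypes, meta)


def read_phenotypes(path: Path) -> pd.DataFrame:
    return read_table(path)


def write_truth(path: Path, truth: TruthTable, meta: dict | None = None) -> None:
    rows = []
    for endpoint, frame in truth.effects.items():
        sub = frame.copy()
        sub.insert(0, "endpoint", endpoint)
        rows.append(sub)
    combined = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["endpoint", "gene_id", "marker_id", "beta"])
    )
    _write_with_meta(path, combined, meta)


def read_truth(path: Path) -> TruthTable:
    frame = read_table(path)
    effects = {
        endpoint: sub[["gene_id", "marker_id", "beta"]].reset_index(drop=True)
        for endpoint, sub in frame.groupby("endpoint")
    }
    return TruthTable(effects=effects)


def write_analysis_dataset(prefix: Path, dataset: AnalysisDataset) -> tuple[Path, Path]:
    """Write a dataset as genotype + marker-metadata TSV with a label header."""
    prefix = Path(prefix)
    meta = {
        "dataset": dataset.label,
        "cutoff": dataset.cutoff,
        "includes_rare": dataset.includes_rare,
    }
    geno_path = prefix.with_suffix(".genotypes.tsv")
    marker_path = prefix.with_suffix(".markers.tsv")
    frame = pd.DataFrame(dataset.genotypes, columns=dataset.markers["marker_id"])
    _write_with_meta(geno_path, frame, meta)
    _write_with_meta(marker_path, dataset.markers, meta)
    return geno_path, marker_path


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path: Path, study: GenotypeStudy, contig: str = "1") -> None:
    """Export simulated genotypes as a minimal diploid VCF (one contig,
    positions = 1-based marker index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = study.n_individuals
    samples = [f"IND{i:05d}" for i in range(n)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j in range(study.n_markers):
            rec = study.markers.iloc[j]
            gts = "\t".join(gt_map[int(g)] for g in study.genotypes[:, j])
            fh.write(
                f"{contig}\t{j + 1}\t{rec['marker_id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(vcf_path: Path, annotation_path: Path) -> GenotypeStudy:
    """Import biallelic sites from a VCF plus a variant annotation TSV.

    The annotation TSV must have columns ``marker_id``, ``gene_id``,
    ``func_class`` keyed by the VCF ID field.  Missing GT fields abort with
    an error rather than being imputed.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires the optional cyvcf2 dependency") from exc

    annotation = read_table(annotation_path).set_index("marker_id")
    columns, ids = [], []
    vcf = VCF(str(vcf_path))
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(f"variant {variant.ID} is not biallelic")
        gts = variant.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        if (gts == 2).any():
            raise ValueError(
                f"variant {variant.ID} has missing genotypes; "
                "generank does not impute -- clean the VCF first"
            )
        dosage = np.where(gts == 3, 2, gts).astype(np.int8)
        columns.append(dosage)
        ids.append(variant.ID)
    unknown = [i for i in ids if i not in annotation.index]
    if unknown:
        raise ValueError(f"variants missing from annotation: {unknown[:5]}")
    markers = annotation.loc[ids].reset_index()
    genotypes = np.column_stack(columns) if columns else np.empty((0, 0), dtype=np.int8)
    return GenotypeStudy(genotypes=genotypes, markers=markers)


# ---------------------------------------------------------------------------
# config


def load_config(path: Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
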