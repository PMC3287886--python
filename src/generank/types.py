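"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: phenotype endpoints analysed throughout the package
ENDPOINTS = ("Q1", "Q2", "AFF")

#: functional classes a marker can carry
NONSYNONYMOUS = "nonsynonymous"
SYNONYMOUS = "synonymous"
SUPERMARKER = "supermarker"

MARKER_COLUMNS = ["marker_id", "gene_id", "func_class", "maf"]


@dataclass
class GenotypeStudy:
    """Individuals x markers additive genotype matrix plus marker metadata.

    Parameters
    ----------
    genotypes
        Array of shape ``(n_individuals, n_markers)`` with entries in
        ``{0, 1, 2}`` (minor-allele dosage) or ``{0, 1}`` for carrier
        indicator columns.
    markers
        One row per genotype column, in column order.  Required columns:
        ``marker_id``, ``gene_id``, ``func_class``; optional ``maf`` holds
        the generating (true) minor-allele frequency when known.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D individuals x markers array")
        if len(self.markers) != self.genotypes.shape[1]:
            raise ValueError(
                f"marker table has {len(self.markers)} rows but genotype matrix "
                f"has {self.genotypes.shape[1]} columns"
            )
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        """Gene identifiers in first-appearance order."""
        return list(dict.fromkeys(self.markers["gene_id"]))

    def gene_columns(self, gene_id: str) -> np.ndarray:
        """Column indices of the markers assigned to ``gene_id``."""
        return np.flatnonzero((self.markers["gene_id"] == gene_id).to_numpy())


@dataclass
class TruthTable:
    """Which markers are causal for which endpoint, with effect sizes.

    ``effects`` maps an endpoint name to a frame with columns
    ``gene_id``, ``marker_id``, ``beta`` (nonzero, on the endpoint's scale:
    trait units per allele for quantitative traits, log odds ratio per
    allele for binary ones).
    """

    effects: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for endpoint, frame in self.effects.items():
            missing = {"gene_id", "marker_id", "beta"} - set(frame.columns)
            if missing:
                raise ValueError(f"truth table for {endpoint} lacks columns {missing}")
            if (frame["beta"] == 0).any():
                raise ValueError(f"truth table for {endpoint} contains beta == 0")

    def causal_genes(self, endpoint: str) -> list[str]:
        frame = self.effects.get(endpoint)
        if frame is None or frame.empty:
            return []
        return list(dict.fromkeys(frame["gene_id"]))

    def causal_markers(self, endpoint: str) -> pd.DataFrame:
        return self.effects.get(
            endpoint, pd.DataFrame(columns=["gene_id", "marker_id", "beta"])
        )

    def validate_against(self, study: GenotypeStudy) -> None:
        """Raise if any causal marker id is absent from the study."""
        known = set(study.markers["marker_id"])
        for endpoint, frame in self.effects.items():
            unknown = set(frame["marker_id"]) - known
            if unknown:
                raise ValueError(
                    f"truth table for {endpoint} references unknown markers: "
                    f"{sorted(unknown)[:5]}"
                )


DATASET_LABELS = {
    (0.01, True): "CR1%",
    (0.05, True): "CR5%",
    (0.01, False): "C1%",
    (0.05, False): "C5%",
}


@dataclass
class AnalysisDataset:
    """One of the four analysis datasets (CR1%, CR5%, C1%, C5%).

    Holds the filtered genotype matrix, marker metadata (including
    supermarker rows with their contributing variant ids) and the
    gene -> column-index map used by the scoring functions.
    """

    label: str
    cutoff: float
    includes_rare: bool
    genotypes: np.ndarray
    markers: pd.DataFrame  # marker_id, gene_id, func_class, maf, mac, source_variants
    gene_to_cols: dict[str, np.ndarray]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gene_to_cols)

    def gene_matrix(self, gene_id: str) -> np.ndarray:
        """Genotype submatrix (individuals x gene markers) for one gene."""
        return self.genotypes[:, self.gene_to_cols[gene_id]]
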