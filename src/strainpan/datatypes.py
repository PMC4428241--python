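"""Shared data containers for the gene-content variation pipeline.

The pipeline works at *gene resolution*: a reference genome is an ordered
list of genes on one or more contigs, a metagenomic sample contributes a
per-gene coverage record, and everything downstream (presence calls,
core/accessory labels, deletion blocks, distances) is derived from those
two objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

EXPECTED_MARKER_COUNT = 40  # universal single-copy marker genes per species

GENE_COLUMNS = ["gene_id", "contig_id", "start", "end", "ordinal", "is_marker"]
COVERAGE_COLUMNS = ["gene_id", "gene_length_bp", "covered_bp", "mean_depth"]


@dataclass
class ReferenceGeneSet:
    """Ordered genes on the contigs of one species' representative genome.

    Parameters
    ----------
    species_id
        Identifier of the species / representative genome.
    contigs
        Ordered ``(contig_id, length_bp)`` pairs.
    genes
        One row per gene with columns ``gene_id, contig_id, start, end,
        ordinal, is_marker``.  ``start``/``end`` are 1-based inclusive
        (GFF3 convention); ``ordinal`` is the 0-based within-contig gene
        index.  Rows are sorted by (contig order, start).
    """

    species_id: str
    contigs: list[tuple[str, int]]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"reference gene table missing columns: {missing}")
        contig_order = {cid: i for i, (cid, _) in enumerate(self.contigs)}
        unknown = set(self.genes["contig_id"]) - set(contig_order)
        if unknown:
            raise ValueError(f"genes on unknown contigs: {sorted(unknown)}")
        # canonical order: contig appearance order, then start coordinate
        key = self.genes["contig_id"].map(contig_order)
        self.genes = (
            self.genes.assign(_ck=key)
            .sort_values(["_ck", "start"], kind="stable")
            .drop(columns="_ck")
            .reset_index(drop=True)
        )
        for cid, sub in self.genes.groupby("contig_id", sort=False):
            ords = sub["ordinal"].to_numpy()
            if not np.array_equal(ords, np.arange(len(ords))):
                raise ValueError(
                    f"ordinal indices on contig {cid!r} are not consecutive from 0"
                )
        n_markers = int(self.genes["is_marker"].sum())
        if 0 < n_markers < EXPECTED_MARKER_COUNT:
            warnings.warn(
                f"{self.species_id}: only {n_markers} marker genes flagged "
                f"({EXPECTED_MARKER_COUNT} expected)",
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    @property
    def marker_ids(self) -> list[str]:
        return list(self.genes.loc[self.genes["is_marker"], "gene_id"])

    def contig_of(self) -> pd.Series:
        """contig_id per gene, in genome order."""
        return self.genes.set_index("gene_id")["contig_id"]


@dataclass
class CoverageProfile:
    """Per-gene coverage of one species' genome in one sample.

    ``genes`` has columns ``gene_id, gene_length_bp, covered_bp,
    mean_depth``.  Genome-wide breadth/depth are accepted when supplied
    (computed upstream from read mapping); otherwise they are approximated
    from the per-gene records weighted by gene length (intergenic regions
    are invisible at gene resolution).
    """

    sample_id: str
    individual_id: str
    species_id: str
    genes: pd.DataFrame
    genome_breadth: Optional[float] = None
    genome_mean_depth: Optional[float] = None
    species_abundance: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [c for c in COVERAGE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"coverage table missing columns: {missing}")
        bad = self.genes["covered_bp"] > self.genes["gene_length_bp"]
        if bool(bad.any()):
            ids = self.genes.loc[bad, "gene_id"].tolist()[:5]
            raise ValueError(f"covered_bp exceeds gene length for genes {ids}")
        if self.genes["covered_bp"].lt(0).any():
            raise ValueError("negative covered_bp")
        if self.genome_breadth is None:
            self.genome_breadth = float(
                self.genes["covered_bp"].sum() / self.genes["gene_length_bp"].sum()
            )
        if self.genome_mean_depth is None:
            w = self.genes["gene_length_bp"]
            self.genome_mean_depth = float((self.genes["mean_depth"] * w).sum() / w.sum())
        if not 0.0 <= self.genome_breadth <= 1.0:
            raise ValueError(f"genome_breadth {self.genome_breadth} outside [0, 1]")

    def covered_fraction(self) -> pd.Series:
        """covered_bp / gene_length_bp, indexed by gene_id."""
        g = self.genes
        return pd.Series(
            (g["covered_bp"] / g["gene_length_bp"]).to_numpy(),
            index=pd.Index(g["gene_id"]),
            name=self.sample_id,
        )


@dataclass
class FilterDecision:
    """Outcome of the three per-sample x species detection filters."""

    sample_id: str
    species_id: str
    breadth_pass: bool
    markers_pass: bool
    depth_pass: bool
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.breadth_pass and self.markers_pass and self.depth_pass


@dataclass
class PresenceMatrix:
    """Boolean genes x individuals table, rows in genome order."""

    species_id: str
    presence: pd.DataFrame  # index = gene_id (genome order), columns = individual ids

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)

    @property
    def individuals(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_individuals(self) -> int:
        return self.presence.shape[1]


@dataclass
class DeletionBlock:
    """Maximal run of absent genes in one individual within one contig."""

    sample_id: str
    contig_id: str
    first_gene_ordinal: int
    n_genes: int
    gene_ids: list[str]
    touches_contig_edge: bool
    block_class: str = "other"  # single | large | other
    counted: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("deletion block must contain at least one gene")
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length does not match n_genes")


@dataclass
class PairwiseDifference:
    """Gene-content difference between two presence sets.

    ``value`` is the symmetric difference divided by the union of present
    genes — the Jaccard distance on gene sets.
    """

    species_id: str
    id_a: str
    id_b: str
    comparison_class: str  # inter_individual | biological_replicate | technical_replicate | genome_pair
    n_union: int
    n_symmetric_difference: int

    @property
    def value(self) -> float:
        return self.n_symmetric_difference / self.n_union


@dataclass
class EnrichmentResult:
    """Fisher-exact enrichment of one functional category in accessory genes."""

    category: str
    n_accessory_in: int
    n_accessory_out: int
    n_core_in: int
    n_core_out: int
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")
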