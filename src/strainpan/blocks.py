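"""Gene deletion blocks: detection, classification, size spectrum.

A deletion block is a maximal run of contiguous absent genes in one
individual, relative to the reference gene order, confined to one contig
(runs never extend across contig boundaries, since gene adjacency is
unknown between contigs of a draft assembly).  A *single-gene* block is a
size-1 block whose flanking genes exist and are present; size-1 blocks
touching a contig edge are excluded from tallies so that contig breaks do
not inflate the single-gene count.  Blocks of >= 50 genes are *large*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import DeletionBlock, PresenceMatrix, ReferenceGeneSet

LARGE_BLOCK_MIN = 50


def find_deletion_blocks(
    presence: Sequence[bool] | pd.Series,
    reference: ReferenceGeneSet,
    sample_id: str = "",
) -> list[DeletionBlock]:
    """Maximal runs of absent genes within each contig.

    ``presence`` must be ordered as the reference genes.  Every absent
    gene ends up in exactly one block.
    """
    vec = np.asarray(presence, dtype=bool)
    if len(vec) != reference.n_genes:
        raise ValueError(
            f"presence vector has {len(vec)} entries but reference "
            f"{reference.species_id} has {reference.n_genes} genes"
        )
    gene_ids = reference.genes["gene_id"].to_numpy()
    contig_ids = reference.genes["contig_id"].to_numpy()
    out: list[DeletionBlock] = []
    offset = 0
    for cid, n_c in reference.genes.groupby("contig_id", sort=False).size().items():
        sub = vec[offset : offset + n_c]
        absent = ~sub
        # run boundaries of the absent mask
        edges = np.diff(np.concatenate([[0], absent.astype(int), [0]]))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)  # exclusive
        for s, e in zip(starts, ends):
            out.append(
                DeletionBlock(
                    sample_id=sample_id,
                    contig_id=cid,
                    first_gene_ordinal=int(s),
                    n_genes=int(e - s),
                    gene_ids=list(gene_ids[offset + s : offset + e]),
                    touches_contig_edge=bool(s == 0 or e == n_c),
                )
            )
        offset += n_c
    return out


def classify_blocks(
    blocks: Iterable[DeletionBlock],
    reference: ReferenceGeneSet,
    min_large: int = LARGE_BLOCK_MIN,
    flank_depth: int = 1,
    presence: Optional[Sequence[bool]] = None,
) -> list[DeletionBlock]:
    """Assign ``block_class`` and the counted/excluded flag in place.

    A size-1 block is *single* when its ``flank_depth`` nearest neighbours
    on each side exist and are present (for the default depth of 1,
    maximality already guarantees presence, so only existence — i.e. not
    touching a contig edge — matters).  Size-1 blocks at a contig edge are
    flagged ``counted=False``.  ``presence`` (reference gene order) is
    required for ``flank_depth > 1``.
    """
    if flank_depth < 1:
        raise ValueError("flank_depth must be >= 1")
    vec: Optional[np.ndarray] = None
    if flank_depth > 1:
        if presence is None:
            raise ValueError("flank_depth > 1 requires the presence vector")
        vec = np.asarray(presence, dtype=bool)
    contig_sizes = reference.genes.groupby("contig_id", sort=False).size().to_dict()
    contig_offsets: dict[str, int] = {}
    off = 0
    for cid, n_c in reference.genes.groupby("contig_id", sort=False).size().items():
        contig_offsets[cid] = off
        off += n_c
    out = []
    for b in blocks:
        b.counted = True
        if b.n_genes >= min_large:
            b.block_class = "large"
        elif b.n_genes == 1:
            n_c = contig_sizes[b.contig_id]
            s = b.first_gene_ordinal
            flanks_exist = (s - flank_depth >= 0) and (s + flank_depth <= n_c - 1)
            if b.touches_contig_edge:
                # contig-edge singletons are not counted, to avoid inflation
                b.block_class = "other"
                b.counted = False
            elif flanks_exist and (
                vec is None
                or (
                    vec[contig_offsets[b.contig_id] + s - flank_depth
                        : contig_offsets[b.contig_id] + s].all()
                    and vec[contig_offsets[b.contig_id] + s + 1
                            : contig_offsets[b.contig_id] + s + 1 + flank_depth].all()
                )
            ):
                b.block_class = "single"
            else:
                b.block_class = "other"
        else:
            b.block_class = "other"
        out.append(b)
    return out


@dataclass
class BlockSpectrum:
    """Block-size spectrum averaged across individuals.

    ``table`` rows are block sizes with total counts and the
    across-individual mean frequency of blocks (%) and mean fraction of
    deleted genes (%) at that size.
    """

    species_id: str
    table: pd.DataFrame  # size, n_blocks, n_genes, mean_block_freq_pct, mean_gene_fraction_pct
    n_individuals_counted: int


def block_size_spectrum(
    blocks_by_individual: Mapping[str, Sequence[DeletionBlock]],
    species_id: str = "",
    include_edge_multi: bool = True,
) -> BlockSpectrum:
    """Per-size block frequencies and deleted-gene fractions, averaged
    across individuals.

    Only counted blocks enter the tallies (contig-edge singletons are
    excluded by :func:`classify_blocks`); multi-gene edge-touching blocks
    are included by default and dropped when ``include_edge_multi`` is
    False.  Individuals with zero counted blocks are omitted from the
    averages with a warning.
    """
    if not blocks_by_individual:
        raise ValueError("need blocks for at least one individual")
    per_ind_freq: list[pd.Series] = []
    per_ind_genefrac: list[pd.Series] = []
    totals_blocks: dict[int, int] = {}
    totals_genes: dict[int, int] = {}
    skipped = []
    for ind, blocks in blocks_by_individual.items():
        sizes = [
            b.n_genes
            for b in blocks
            if b.counted and (include_edge_multi or b.n_genes == 1 or not b.touches_contig_edge)
        ]
        if not sizes:
            skipped.append(ind)
            continue
        counts = pd.Series(sizes).value_counts().sort_index()
        genes = counts * counts.index
        per_ind_freq.append(100.0 * counts / counts.sum())
        per_ind_genefrac.append(100.0 * genes / genes.sum())
        for s, c in counts.items():
            totals_blocks[int(s)] = totals_blocks.get(int(s), 0) + int(c)
            totals_genes[int(s)] = totals_genes.get(int(s), 0) + int(c * s)
    if skipped:
        warnings.warn(
            f"{len(skipped)} individual(s) with no counted deletion blocks "
            f"omitted from the spectrum mean: {skipped[:5]}",
            stacklevel=2,
        )
    if not per_ind_freq:
        table = pd.DataFrame(
            columns=["size", "n_blocks", "n_genes", "mean_block_freq_pct", "mean_gene_fraction_pct"]
        )
        return BlockSpectrum(species_id, table, 0)
    freq = pd.DataFrame(per_ind_freq).fillna(0.0)  # individuals x sizes
    genefrac = pd.DataFrame(per_ind_genefrac).fillna(0.0)
    sizes_sorted = sorted(totals_blocks)
    table = pd.DataFrame(
        {
            "size": sizes_sorted,
            "n_blocks": [totals_blocks[s] for s in sizes_sorted],
            "n_genes": [totals_genes[s] for s in sizes_sorted],
            "mean_block_freq_pct": [float(freq.get(s, pd.Series(0.0, index=freq.index)).mean()) for s in sizes_sorted],
            "mean_gene_fraction_pct": [float(genefrac.get(s, pd.Series(0.0, index=genefrac.index)).mean()) for s in sizes_sorted],
        }
    )
    return BlockSpectrum(species_id, table, len(per_ind_freq))


def detect_blocks_for_matrix(
    matrix: PresenceMatrix,
    reference: ReferenceGeneSet,
    min_large: int = LARGE_BLOCK_MIN,
    flank_depth: int = 1,
) -> dict[str, list[DeletionBlock]]:
    """Detect and classify blocks for every individual in a presence matrix."""
    out: dict[str, list[DeletionBlock]] = {}
    for ind in matrix.individuals:
        vec = matrix.presence[ind].to_numpy()
        blocks = find_deletion_blocks(vec, reference, sample_id=ind)
        classify_blocks(blocks, reference, min_large=min_large,
                        flank_depth=flank_depth, presence=vec)
        # partition check: block sizes must account for every absent gene
        assert sum(b.n_genes for b in blocks) == int((~matrix.presence[ind]).sum())
        out[ind] = blocks
    return out
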