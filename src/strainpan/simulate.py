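"""Synthetic strain-community generator with known ground truth.

Every downstream stage (presence calling, core/accessory classification,
rarefaction extrapolation, deletion-block detection, distances) is tested
against communities generated here, so no external metagenomes are needed.

Generative model
----------------
1.  A reference genome: ``n_genes`` non-overlapping genes laid consecutively
    on ``n_contigs`` contigs, with 40 universal single-copy marker genes
    spread across contigs.
2.  A cohort-level pool of candidate *deletion blocks*: blocks with sizes
    drawn from a mixture (singletons / geometric / large uniform) are placed
    uniformly at random, without overlap and without adjacency, until the
    pool covers the target accessory fraction of the genome.  Each block
    carries a deletion frequency ``q_b`` drawn uniformly from
    ``block_deletion_freq_range``.
3.  Per individual, each pool block is deleted independently with
    probability ``q_b``.  Genes never deleted in any individual are true
    core.  This two-level model gives each accessory gene a population
    frequency, which makes rarefaction curves saturate the way real
    pan-genome curves do; placing blocks independently per individual
    would instead give a singleton-dominated spectrum and near-linear
    curves.
4.  Coverage: present genes get covered fraction near 1 and depth near
    ``mean_depth``; absent genes get exactly 0 (plus noise).  Noise terms:

    * ``presence_noise`` — per-gene probability, in every sample, of a
      spurious flip of the covered fraction across the 0.40 decision
      boundary (read mis-assignment, mapping artefacts);
    * ``biological_noise`` — per-gene presence flip rate of a *non-primary
      time point* relative to the individual's strain truth (strain drift
      between time points); a biological replicate pair therefore differs
      at rate ~``biological_noise``;
    * ``technical_noise`` — per-lane flip rate of ``technical_noise / 2``
      applied to each lane of a multi-lane sample, so that any lane pair
      differs at rate ~``technical_noise``.  Single-lane samples carry no
      technical term (sequencing noise of a single reaction is part of
      ``presence_noise``);
    * ``spurious_coverage_rate`` — probability that an absent gene shows
      partial sub-threshold coverage (mis-assigned reads from orthologues
      of close relatives) and that a present gene is eroded to a covered
      fraction in (0.45, 0.85) (strain-variable gene ends).  Neither
      crosses the 0.40 boundary, so presence calls at the default cutoff
      are unaffected — but both make cutoffs far from 0.40 noisy, which
      is what the replicate-based cutoff calibration detects.

Marker genes are exempt from deletion and from false-absent flips: their
joint presence is the species-detection criterion, and the generator
models within-species gene content variation, not species mis-detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import CoverageProfile, DeletionBlock, ReferenceGeneSet
from . import io as spio

PRESENCE_CUTOFF = 0.40  # covered-fraction decision boundary emulated by the noise model


@dataclass
class BlockSizeDist:
    """Mixture over deletion-block sizes.

    ``w_single`` puts mass on size 1, ``w_geometric`` on a geometric
    distribution (mean ``geometric_mean``, support >= 1), ``w_large`` on a
    uniform over ``large_range`` (inclusive).  Defaults follow the reported
    spectrum shape: single-gene deletions most frequent, a geometric body,
    and a small mass of >= 50-gene blocks up to 175 genes.
    """

    w_single: float = 0.35
    w_geometric: float = 0.60
    w_large: float = 0.05
    geometric_mean: float = 4.0
    large_range: tuple[int, int] = (50, 175)

    def validate(self) -> None:
        weights = (self.w_single, self.w_geometric, self.w_large)
        if any(w < 0 for w in weights) or not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
            raise ValueError("block size mixture weights must be >= 0 and sum to 1")
        if self.geometric_mean < 1:
            raise ValueError("geometric_mean must be >= 1")
        lo, hi = self.large_range
        if not (1 <= lo <= hi):
            raise ValueError("large_range must satisfy 1 <= lo <= hi")

    def sample(self, rng: np.random.Generator) -> int:
        u = rng.random()
        if u < self.w_single:
            return 1
        if u < self.w_single + self.w_geometric:
            # geometric on {1,2,...} with mean m -> success prob 1/m
            return int(rng.geometric(1.0 / self.geometric_mean))
        return int(rng.integers(self.large_range[0], self.large_range[1] + 1))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic species cohort.

    Defaults emulate an abundant gut bacterial species: ~2,000 genes on a
    handful of contigs, 10 individuals, a ~32% accessory fraction, 50x
    sequencing depth, and technical < biological < inter-individual noise.
    """

    species_id: str = "species_01"
    n_species: int = 1
    n_individuals_per_species: int = 10
    n_contigs: int = 3
    n_genes: int = 2000
    gene_length_dist: tuple[float, float, float] = (900.0, 300.0, 150.0)  # mean, sd, min bp
    true_accessory_fraction: float = 0.32
    block_size_dist: BlockSizeDist = field(default_factory=BlockSizeDist)
    mean_depth: float = 50.0
    presence_noise: float = 0.002
    biological_noise: float = 0.01
    technical_noise: float = 0.001
    # sub-threshold spurious coverage of absent genes (mis-assigned reads
    # from orthologues of relatives); never crosses the decision boundary
    spurious_coverage_rate: float = 0.05
    seed: int = 0
    # population structure of accessory blocks
    block_deletion_freq_range: tuple[float, float] = (0.1, 0.9)
    placement: str = "uniform"  # "uniform" | "hotspot"
    n_hotspots: int = 5
    # replicate structure
    n_biological_replicate_individuals: int = 3
    n_technical_lanes: int = 4  # lanes of the first individual's primary sample
    n_marker_genes: int = 40
    # markers are laid out in operon-like clusters (ribosomal-protein style),
    # which leaves long marker-free stretches able to host large deletions
    n_marker_clusters: int = 8

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_marker_genes and self.n_genes < self.n_marker_genes:
            raise ValueError(
                f"n_genes={self.n_genes} cannot host {self.n_marker_genes} marker genes"
            )
        for name in ("true_accessory_fraction", "presence_noise", "biological_noise",
                     "technical_noise", "spurious_coverage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_contigs < 1 or self.n_contigs > self.n_genes:
            raise ValueError("need 1 <= n_contigs <= n_genes")
        if self.n_individuals_per_species < 1:
            raise ValueError("need at least one individual")
        lo, hi = self.block_deletion_freq_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("block_deletion_freq_range must satisfy 0 < lo <= hi <= 1")
        if self.placement not in {"uniform", "hotspot"}:
            raise ValueError("placement must be 'uniform' or 'hotspot'")
        self.block_size_dist.validate()


@dataclass
class TruthSet:
    """Ground truth for one synthetic species cohort."""

    reference: ReferenceGeneSet
    true_presence: pd.DataFrame  # index gene_id (genome order), columns individual ids, bool
    replicate_map: pd.DataFrame  # sample_id, individual_id, time_point, lane, replicate_class
    planted_blocks: list[DeletionBlock]  # per individual, sample_id = individual id
    block_frequencies: pd.Series  # deletion frequency per pool block (by pool index)
    true_accessory_fraction_realized: float

    @property
    def individuals(self) -> list[str]:
        return list(self.true_presence.columns)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def _place_marker_clusters(
    config: SimulationConfig,
    counts: np.ndarray,
    contig_first: np.ndarray,
    rng: np.random.Generator,
) -> set[int]:
    """Global gene indices of the marker genes.

    Markers are grouped into operon-like clusters of adjacent genes and the
    clusters are dealt round-robin across contigs (largest first), so every
    contig carries markers when there are at least as many clusters as
    contigs, while long marker-free stretches remain between clusters.
    """
    if not config.n_marker_genes:
        return set()
    n_clusters = max(1, min(config.n_marker_clusters, config.n_marker_genes))
    sizes = np.full(n_clusters, config.n_marker_genes // n_clusters)
    sizes[: config.n_marker_genes - sizes.sum()] += 1
    by_capacity = np.argsort(counts)[::-1]
    marker_idx: set[int] = set()
    for ci_rank, size in enumerate(sizes):
        ci = int(by_capacity[ci_rank % len(counts)])
        free = [
            s
            for s in range(counts[ci] - size + 1)
            if all(contig_first[ci] + s + j not in marker_idx for j in range(size))
        ]
        if free:
            s = int(rng.choice(free))
            marker_idx.update(contig_first[ci] + s + j for j in range(size))
        else:  # contig saturated: scatter the remainder anywhere
            pool = [g for g in range(int(counts.sum())) if g not in marker_idx]
            marker_idx.update(
                int(g) for g in rng.choice(pool, size=size, replace=False)
            )
    return marker_idx


def generate_reference(config: SimulationConfig) -> ReferenceGeneSet:
    """Lay ``n_genes`` consecutive non-overlapping genes on ``n_contigs``
    contigs and flag ``n_marker_genes`` single-copy markers, grouped into
    operon-like clusters spread across contigs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mean, sd, min_bp = config.gene_length_dist
    lengths = np.maximum(rng.normal(mean, sd, size=config.n_genes), min_bp).astype(int)
    gaps = rng.integers(20, 200, size=config.n_genes)

    # split genes across contigs: roughly equal shares with mild variation
    base = config.n_genes // config.n_contigs
    counts = np.full(config.n_contigs, base)
    counts[: config.n_genes - base * config.n_contigs] += 1
    if config.n_contigs > 1 and base > 3:
        jitter = rng.integers(-base // 4, base // 4 + 1, size=config.n_contigs)
        jitter -= jitter.sum() // config.n_contigs
        counts = np.maximum(counts + jitter, 1)
        while counts.sum() > config.n_genes:
            counts[int(np.argmax(counts))] -= 1
        while counts.sum() < config.n_genes:
            counts[int(np.argmin(counts))] += 1

    contig_first = np.concatenate([[0], np.cumsum(counts)[:-1]])
    marker_idx = _place_marker_clusters(config, counts, contig_first, rng)

    width = len(str(config.n_genes))
    rows = []
    contigs = []
    g = 0
    for ci, count in enumerate(counts):
        contig_id = f"{config.species_id}_c{ci + 1:02d}"
        pos = 1
        for k in range(count):
            start = pos + int(gaps[g])
            end = start + int(lengths[g]) - 1
            rows.append(
                (
                    f"{config.species_id}_g{g + 1:0{width}d}",
                    contig_id,
                    start,
                    end,
                    k,
                    g in marker_idx,
                )
            )
            pos = end
            g += 1
        contigs.append((contig_id, pos + 100))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "contig_id", "start", "end", "ordinal", "is_marker"]
    )
    return ReferenceGeneSet(species_id=config.species_id, contigs=contigs, genes=genes)


# ---------------------------------------------------------------------------
# Strain population
# ---------------------------------------------------------------------------

def _place_block_pool(
    reference: ReferenceGeneSet, config: SimulationConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Place candidate deletion blocks (global gene-index arrays) uniformly
    without overlap/adjacency until they cover the target accessory
    fraction.  Marker genes are never covered."""
    n = reference.n_genes
    target = int(round(config.true_accessory_fraction * n))
    if target == 0:
        return []
    slack = max(1, int(round(0.01 * n)))

    contig_ids = reference.genes["contig_id"].to_numpy()
    contig_start = {}
    contig_len = {}
    for cid in dict.fromkeys(contig_ids):
        idx = np.flatnonzero(contig_ids == cid)
        contig_start[cid] = int(idx[0])
        contig_len[cid] = len(idx)
    cids = list(contig_start)
    contig_weights = np.array([contig_len[c] for c in cids], dtype=float)
    contig_weights /= contig_weights.sum()

    marker_mask = reference.genes["is_marker"].to_numpy()
    blocked = marker_mask.copy()  # genes unavailable for placement
    hotspot_centres: Optional[np.ndarray] = None
    if config.placement == "hotspot":
        hotspot_centres = rng.integers(0, n, size=max(1, config.n_hotspots))

    pool: list[np.ndarray] = []
    covered = 0
    attempts = 0
    max_attempts = 200 * max(target, 100)
    while covered < target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not reach accessory fraction {config.true_accessory_fraction} "
                f"after {max_attempts} placement attempts (covered {covered}/{target} genes); "
                "lower the target or the block sizes"
            )
        size = config.block_size_dist.sample(rng)
        if covered + size > target + slack:
            continue  # would overshoot the target; redraw
        if hotspot_centres is not None and rng.random() < 0.8:
            centre = int(rng.choice(hotspot_centres))
            g0 = int(np.clip(centre + rng.integers(-50, 51), 0, n - 1))
            cid = contig_ids[g0]
            start_in_contig = g0 - contig_start[cid]
        else:
            cid = cids[int(rng.choice(len(cids), p=contig_weights))]
            if contig_len[cid] < size:
                continue
            start_in_contig = int(rng.integers(0, contig_len[cid] - size + 1))
        if start_in_contig + size > contig_len[cid]:
            continue
        lo = contig_start[cid] + start_in_contig
        hi = lo + size  # exclusive
        # forbid overlap and adjacency (so planted blocks stay maximal runs)
        check_lo = max(lo - 1, contig_start[cid])
        check_hi = min(hi + 1, contig_start[cid] + contig_len[cid])
        if blocked[check_lo:check_hi].any():
            continue
        blocked[lo:hi] = True
        pool.append(np.arange(lo, hi))
        covered += size
    return pool


def generate_strain_population(
    reference: ReferenceGeneSet,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> TruthSet:
    """Draw per-individual gene complements from the block-pool model and
    assemble the replicate structure."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = reference.n_genes
    n_ind = config.n_individuals_per_species
    pool = _place_block_pool(reference, config, rng)
    lo_q, hi_q = config.block_deletion_freq_range
    freqs = pd.Series(rng.uniform(lo_q, hi_q, size=len(pool)), name="deletion_frequency")

    individuals = [f"{reference.species_id}_ind{i + 1:02d}" for i in range(n_ind)]
    presence = np.ones((n, n_ind), dtype=bool)
    contig_ids = reference.genes["contig_id"].to_numpy()
    ordinals = reference.genes["ordinal"].to_numpy()
    gene_ids = reference.genes["gene_id"].to_numpy()
    contig_sizes = reference.genes.groupby("contig_id", sort=False).size().to_dict()

    planted: list[DeletionBlock] = []
    for j, ind in enumerate(individuals):
        if len(pool):
            deleted = rng.random(len(pool)) < freqs.to_numpy()
        else:
            deleted = np.zeros(0, dtype=bool)
        for b in np.flatnonzero(deleted):
            idx = pool[b]
            presence[idx, j] = False
            cid = contig_ids[idx[0]]
            first_ord = int(ordinals[idx[0]])
            planted.append(
                DeletionBlock(
                    sample_id=ind,
                    contig_id=cid,
                    first_gene_ordinal=first_ord,
                    n_genes=len(idx),
                    gene_ids=list(gene_ids[idx]),
                    touches_contig_edge=(
                        first_ord == 0 or first_ord + len(idx) == contig_sizes[cid]
                    ),
                )
            )

    true_presence = pd.DataFrame(presence, index=pd.Index(gene_ids, name="gene_id"),
                                 columns=individuals)
    realized = float((~true_presence).any(axis=1).sum() / n)

    # the multi-lane (technical) individual and the biological-replicate
    # individuals are disjoint, so each replicate class carries exactly one
    # noise term and equal rates give equal pair-difference distributions
    rep_rows = []
    for j, ind in enumerate(individuals):
        n_lanes = config.n_technical_lanes if j == 0 else 1
        for lane in range(1, max(n_lanes, 1) + 1):
            cls = "primary" if lane == 1 else "technical"
            rep_rows.append((f"{ind}_t0_l{lane}", ind, 0, lane, cls))
        if 1 <= j <= config.n_biological_replicate_individuals:
            rep_rows.append((f"{ind}_t1_l1", ind, 1, 1, "biological"))
    replicate_map = pd.DataFrame(
        rep_rows, columns=["sample_id", "individual_id", "time_point", "lane", "replicate_class"]
    )

    return TruthSet(
        reference=reference,
        true_presence=true_presence,
        replicate_map=replicate_map,
        planted_blocks=planted,
        block_frequencies=freqs,
        true_accessory_fraction_realized=realized,
    )


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------

def _coverage_from_calls(
    calls: np.ndarray,
    lengths: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    flipped: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Covered-bp and depth arrays realizing a call vector.

    Genes called present by a spurious flip sit just above the decision
    boundary with shallow depth; genuinely present genes are nearly fully
    covered at the sample's depth.
    """
    n = len(calls)
    frac = np.zeros(n)
    depth = np.zeros(n)
    present = calls
    genuine = present & ~flipped
    frac[genuine] = rng.uniform(0.85, 1.0, size=int(genuine.sum()))
    depth[genuine] = np.maximum(
        rng.normal(config.mean_depth, 0.15 * config.mean_depth, size=int(genuine.sum())), 1.0
    )
    spurious_present = present & flipped
    frac[spurious_present] = rng.uniform(0.42, 0.70, size=int(spurious_present.sum()))
    depth[spurious_present] = np.maximum(
        rng.normal(0.3 * config.mean_depth, 0.1 * config.mean_depth,
                   size=int(spurious_present.sum())), 1.0
    )
    spurious_absent = ~present & flipped
    frac[spurious_absent] = rng.uniform(0.02, 0.38, size=int(spurious_absent.sum()))
    depth[spurious_absent] = np.maximum(
        rng.normal(0.1 * config.mean_depth, 0.05 * config.mean_depth,
                   size=int(spurious_absent.sum())), 0.5
    )
    # mis-assigned reads give some absent genes partial sub-threshold
    # coverage, and some present genes are eroded (strain-variable ends,
    # partial homology) without dropping below the decision boundary
    if config.spurious_coverage_rate > 0:
        partial = (~present & ~flipped) & (
            rng.random(n) < config.spurious_coverage_rate
        )
        frac[partial] = rng.uniform(0.01, 0.35, size=int(partial.sum()))
        depth[partial] = np.maximum(
            rng.normal(0.05 * config.mean_depth, 0.02 * config.mean_depth,
                       size=int(partial.sum())), 0.5
        )
        eroded = genuine & (rng.random(n) < config.spurious_coverage_rate)
        frac[eroded] = rng.uniform(0.45, 0.85, size=int(eroded.sum()))
    covered = np.round(frac * lengths).astype(int)
    # rounding must not cross the decision boundary
    lim = np.ceil(PRESENCE_CUTOFF * lengths).astype(int)
    covered[present] = np.maximum(covered[present], lim[present])
    covered[~present] = np.minimum(covered[~present], lim[~present] - 1)
    covered = np.clip(covered, 0, lengths)
    depth[covered == 0] = 0.0
    return covered, depth


def simulate_coverage(
    truth: TruthSet,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[CoverageProfile]:
    """Emit one coverage profile per sample in the replicate map."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    ref = truth.reference
    lengths = ref.genes["end"].to_numpy() - ref.genes["start"].to_numpy() + 1
    marker = ref.genes["is_marker"].to_numpy()
    n = ref.n_genes

    multi_lane = set(
        truth.replicate_map.loc[truth.replicate_map["lane"] > 1, "individual_id"]
    )
    abundance = {
        ind: float(np.exp(rng.normal(-4.0, 0.8)))  # relative abundance, diagnostics only
        for ind in truth.individuals
    }

    # strain state per (individual, time point)
    states: dict[tuple[str, int], np.ndarray] = {}
    profiles: list[CoverageProfile] = []
    for row in truth.replicate_map.itertuples(index=False):
        key = (row.individual_id, row.time_point)
        if key not in states:
            base = truth.true_presence[row.individual_id].to_numpy().copy()
            if row.time_point > 0 and config.biological_noise > 0:
                drift = rng.random(n) < config.biological_noise
                drift &= ~marker
                base ^= drift
            states[key] = base
        state = states[key]

        flip_rate = config.presence_noise
        if row.individual_id in multi_lane and row.time_point == 0:
            flip_rate = flip_rate + config.technical_noise / 2.0
        flips = rng.random(n) < flip_rate
        flips &= ~(marker & state)  # never flip a present marker to absent
        calls = state ^ flips

        covered, depth = _coverage_from_calls(calls, lengths, config, rng, flips)
        profiles.append(
            CoverageProfile(
                sample_id=row.sample_id,
                individual_id=row.individual_id,
                species_id=ref.species_id,
                genes=pd.DataFrame(
                    {
                        "gene_id": ref.genes["gene_id"].to_numpy(),
                        "gene_length_bp": lengths,
                        "covered_bp": covered,
                        "mean_depth": depth,
                    }
                ),
                species_abundance=abundance[row.individual_id],
            )
        )
    return profiles


def simulate_species(config: SimulationConfig) -> tuple[ReferenceGeneSet, TruthSet, list[CoverageProfile]]:
    """Reference + truth + coverage for one species under one seed."""
    reference = generate_reference(config)
    rng = np.random.default_rng(config.seed + 1)
    truth = generate_strain_population(reference, config, rng)
    profiles = simulate_coverage(truth, config, rng)
    return reference, truth, profiles


# ---------------------------------------------------------------------------
# Study-level defaults: 11 abundant gut species
# ---------------------------------------------------------------------------

# (contigs, genes in reference, available individuals) for 11 abundant gut
# Bacteroidetes/Firmicutes species, mirroring typical representative-genome
# structure: single-contig closed genomes up to 71-contig drafts, 1.8k-5.8k
# genes, detection pools of 10-58 individuals.
STUDY_SPECIES_STRUCTURE: list[tuple[int, int, int]] = [
    (1, 2015, 16),
    (1, 1852, 22),
    (3, 2576, 13),
    (1, 2816, 11),
    (1, 2795, 58),
    (66, 5771, 15),
    (20, 3769, 10),
    (1, 2616, 29),
    (22, 4558, 32),
    (71, 5648, 41),
    (28, 3413, 32),
]


def default_study_configs(seed: int = 0, n_species: int = 11) -> list[SimulationConfig]:
    """Per-species configs for the default synthetic study: 11 species with
    accessory-fraction targets spread over 0.21-0.45 and genome structures
    drawn from the table above."""
    fractions = np.linspace(0.21, 0.45, n_species)
    configs = []
    for i in range(n_species):
        contigs, genes, pool = STUDY_SPECIES_STRUCTURE[i % len(STUDY_SPECIES_STRUCTURE)]
        configs.append(
            SimulationConfig(
                species_id=f"species_{i + 1:02d}",
                n_species=1,
                n_individuals_per_species=pool,
                n_contigs=contigs,
                n_genes=genes,
                true_accessory_fraction=float(fractions[i]),
                seed=seed * 1009 + i,
            )
        )
    return configs


def simulate_study(
    seed: int = 0,
    n_species: int = 11,
    configs: Optional[list[SimulationConfig]] = None,
) -> list[tuple[SimulationConfig, ReferenceGeneSet, TruthSet, list[CoverageProfile]]]:
    """Generate the full default study (11 species, pooled individuals,
    replicate structure) under one master seed."""
    if configs is None:
        configs = default_study_configs(seed=seed, n_species=n_species)
    out = []
    for cfg in configs:
        reference, truth, profiles = simulate_species(cfg)
        out.append((cfg, reference, truth, profiles))
    return out


def write_truth_tsv(truth: TruthSet, path) -> None:
    """Truth presence matrix as TSV (genes in genome order x individuals, 0/1)."""
    out = truth.true_presence.astype(int)
    out.index.name = "gene_id"
    out.to_csv(Path(path), sep="\t")


def write_simulation(
    config: SimulationConfig,
    out_dir,
) -> None:
    """Run one species simulation and write reference GFF3, truth matrix,
    replicate map and coverage TSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, truth, profiles = simulate_species(config)
    spio.write_gff3(reference, out / f"{config.species_id}.gff3")
    write_truth_tsv(truth, out / f"{config.species_id}.truth.tsv")
    spio.write_replicate_map(truth.replicate_map, out / f"{config.species_id}.replicates.tsv")
    spio.write_coverage_tsv(profiles, out / f"{config.species_id}.coverage.tsv")
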