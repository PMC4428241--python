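"""Gene presence calling and sample x species detection filters.

A gene is called present in a sample when reads cover at least 40% of its
length (inclusive boundary).  A sample x species combination is analyzed
only when (1) at least 40% of the genome is covered by at least one read,
(2) all flagged universal single-copy marker genes are called present, and
(3) the average genome coverage depth is at least 30x.  Species with fewer
than 10 passing individuals are excluded; otherwise 10 individuals are
drawn at random, one primary sample each (earliest time point, lowest
lane).

The 40% gene-length cutoff is calibrated by scanning cutoffs 0%..100% in
10% steps and choosing the one that minimizes the mean gene-content
difference between biological replicate pairs (ties go to the smallest
cutoff, which retains more genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import CoverageProfile, FilterDecision, PresenceMatrix, ReferenceGeneSet

DEFAULT_LENGTH_CUTOFF = 0.40
DEFAULT_BREADTH_MIN = 0.40
DEFAULT_DEPTH_MIN = 30.0
DEFAULT_COHORT_SIZE = 10
CALIBRATION_CUTOFFS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


def call_gene_presence(
    profile: CoverageProfile,
    reference: ReferenceGeneSet,
    length_cutoff: float = DEFAULT_LENGTH_CUTOFF,
) -> pd.Series:
    """Boolean presence vector over the reference genes, in genome order.

    A gene is present iff ``covered_bp / gene_length_bp >= length_cutoff``.
    At ``length_cutoff == 0`` the literal rule is vacuous, so presence
    degrades to "covered by at least one base" (``covered_bp > 0``), which
    keeps the call monotone in the cutoff.
    """
    if not 0.0 <= length_cutoff <= 1.0:
        raise ValueError(f"length_cutoff {length_cutoff} outside [0, 1]")
    ref_ids = reference.gene_ids
    prof_ids = pd.Index(profile.genes["gene_id"])
    unknown = prof_ids.difference(ref_ids)
    if len(unknown):
        raise ValueError(
            f"profile {profile.sample_id} contains genes not in reference "
            f"{reference.species_id}: {list(unknown[:5])}"
        )
    missing = ref_ids.difference(prof_ids)
    if len(missing):
        raise ValueError(
            f"profile {profile.sample_id} lacks coverage records for "
            f"{len(missing)} reference genes (e.g. {list(missing[:5])}); "
            "uncovered genes must be reported with covered_bp=0"
        )
    frac = profile.covered_fraction().reindex(ref_ids)
    covered = profile.genes.set_index("gene_id")["covered_bp"].reindex(ref_ids)
    if length_cutoff > 0:
        present = frac >= length_cutoff
    else:
        present = covered > 0
    present.name = profile.sample_id
    return present.astype(bool)


def filter_sample_species(
    profile: CoverageProfile,
    reference: ReferenceGeneSet,
    breadth_min: float = DEFAULT_BREADTH_MIN,
    depth_min: float = DEFAULT_DEPTH_MIN,
    length_cutoff: float = DEFAULT_LENGTH_CUTOFF,
) -> FilterDecision:
    """Apply the three detection filters to one sample x species profile.

    The decision depends only on this profile, never on other samples.
    """
    reasons: list[str] = []
    breadth_pass = bool(profile.genome_breadth >= breadth_min)
    if not breadth_pass:
        reasons.append(
            f"genome breadth {profile.genome_breadth:.3f} < {breadth_min:.2f}"
        )
    depth_pass = bool(profile.genome_mean_depth >= depth_min)
    if not depth_pass:
        reasons.append(
            f"mean genome depth {profile.genome_mean_depth:.1f}x < {depth_min:.0f}x"
        )
    marker_ids = reference.marker_ids
    if marker_ids:
        calls = call_gene_presence(profile, reference, length_cutoff)
        absent_markers = [m for m in marker_ids if not calls[m]]
        markers_pass = not absent_markers
        if not markers_pass:
            reasons.append(
                f"{len(absent_markers)}/{len(marker_ids)} marker genes absent "
                f"(e.g. {absent_markers[:3]})"
            )
    else:
        markers_pass = True
    return FilterDecision(
        sample_id=profile.sample_id,
        species_id=profile.species_id,
        breadth_pass=breadth_pass,
        markers_pass=markers_pass,
        depth_pass=depth_pass,
        reasons=reasons,
    )


@dataclass
class CohortSelection:
    """Result of per-species cohort selection."""

    species_id: str
    individuals: list[str]
    primary_samples: dict[str, str]  # individual -> chosen sample id
    excluded: bool = False
    reason: str = ""


def select_cohort(
    decisions: Iterable[FilterDecision],
    replicate_map: pd.DataFrame,
    k: int = DEFAULT_COHORT_SIZE,
    seed: int = 0,
) -> CohortSelection:
    """Choose ``k`` passing individuals uniformly at random (seeded), one
    primary sample per individual.

    An individual passes when its primary sample (earliest time point,
    lowest lane) passes the filters.  Species with fewer than ``k``
    passing individuals are excluded with a logged reason.
    """
    decisions = list(decisions)
    if not decisions:
        return CohortSelection("", [], {}, excluded=True, reason="no samples")
    species_id = decisions[0].species_id
    passed = {d.sample_id for d in decisions if d.passed}

    rep = replicate_map.sort_values(["individual_id", "time_point", "lane"], kind="stable")
    primary = rep.groupby("individual_id", sort=False).first().reset_index()
    passing = primary[primary["sample_id"].isin(passed)]
    if len(passing) < k:
        return CohortSelection(
            species_id,
            [],
            {},
            excluded=True,
            reason=(
                f"{len(passing)} passing individuals < minimum of {k}"
            ),
        )
    rng = np.random.default_rng(seed)
    ids = np.sort(passing["individual_id"].to_numpy())
    chosen = sorted(rng.choice(ids, size=k, replace=False).tolist())
    primary_samples = passing.set_index("individual_id")["sample_id"].to_dict()
    return CohortSelection(
        species_id,
        chosen,
        {i: primary_samples[i] for i in chosen},
    )


def build_presence_matrix(
    profiles: Sequence[CoverageProfile],
    reference: ReferenceGeneSet,
    selection: CohortSelection,
    length_cutoff: float = DEFAULT_LENGTH_CUTOFF,
) -> PresenceMatrix:
    """Presence matrix over the selected cohort (one column per individual,
    calls from its primary sample)."""
    by_sample = {p.sample_id: p for p in profiles}
    cols = {}
    for ind in selection.individuals:
        sample_id = selection.primary_samples[ind]
        cols[ind] = call_gene_presence(by_sample[sample_id], reference, length_cutoff)
    mat = pd.DataFrame(cols)
    mat.index.name = "gene_id"
    return PresenceMatrix(species_id=reference.species_id, presence=mat)


def calibrate_length_cutoff(
    replicate_pairs: Sequence[tuple[CoverageProfile, CoverageProfile]],
    reference: ReferenceGeneSet,
    cutoffs: Sequence[float] = CALIBRATION_CUTOFFS,
) -> tuple[float, pd.Series]:
    """Scan gene-length-coverage cutoffs and pick the one with the lowest
    mean gene-content difference between biological replicate pairs.

    Returns the chosen cutoff and the per-cutoff mean replicate
    difference.  Cutoffs at which some pair has an empty union of present
    genes are reported as NaN and excluded from the minimization.  Ties
    are broken toward the smallest minimizing cutoff.
    """
    from .compare import pairwise_difference  # local import: avoid cycle

    if not replicate_pairs:
        raise ValueError("calibration requires at least one replicate pair")
    means = {}
    for cutoff in cutoffs:
        vals = []
        for a, b in replicate_pairs:
            ca = call_gene_presence(a, reference, cutoff)
            cb = call_gene_presence(b, reference, cutoff)
            if not (ca | cb).any():
                vals.append(np.nan)
                continue
            vals.append(pairwise_difference(ca, cb, species_id=reference.species_id).value)
        means[float(cutoff)] = float(np.mean(vals))  # NaN poisons the cutoff
    curve = pd.Series(means, name="mean_replicate_difference")
    valid = curve.dropna()
    if valid.empty:
        raise ValueError("all cutoffs yield empty unions of present genes")
    best = valid.min()
    chosen = float(min(c for c, v in valid.items() if v == best))
    return chosen, curve


def filter_report(decisions: Iterable[FilterDecision]) -> pd.DataFrame:
    """Tabular filter report, one row per sample x species."""
    rows = []
    for d in decisions:
        rows.append(
            {
                "sample_id": d.sample_id,
                "species_id": d.species_id,
                "breadth_pass": d.breadth_pass,
                "markers_pass": d.markers_pass,
                "depth_pass": d.depth_pass,
                "passed": d.passed,
                "reasons": "; ".join(d.reasons),
            }
        )
    return pd.DataFrame(rows)
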