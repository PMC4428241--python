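import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from strainpan import CoverageProfile, ReferenceGeneSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_reference(
    contig_gene_counts,
    species_id="sp_test",
    gene_length=1000,
    gap=100,
    marker_indices=(),
):
    """Hand-built reference: equal-length genes laid consecutively per contig."""
    rows = []
    contigs = []
    g = 0
    markers = set(marker_indices)
    for ci, count in enumerate(contig_gene_counts):
        cid = f"{species_id}_c{ci + 1}"
        pos = 1
        for k in range(count):
            start = pos + gap
            end = start + gene_length - 1
            rows.append((f"g{g + 1:04d}", cid, start, end, k, g in markers))
            pos = end
            g += 1
        contigs.append((cid, pos + gap))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "contig_id", "start", "end", "ordinal", "is_marker"]
    )
    return ReferenceGeneSet(species_id=species_id, contigs=contigs, genes=genes)


def profile_from_fractions(reference, fractions, sample_id="s1", individual_id=None,
                           depth=50.0):
    """Coverage profile with the given covered fraction per gene (genome order)."""
    lengths = (reference.genes["end"] - reference.genes["start"] + 1).to_numpy()
    fr = np.asarray(fractions, dtype=float)
    covered = np.round(fr * lengths).astype(int)
    return CoverageProfile(
        sample_id=sample_id,
        individual_id=individual_id or sample_id,
        species_id=reference.species_id,
        genes=pd.DataFrame(
            {
                "gene_id": reference.genes["gene_id"].to_numpy(),
                "gene_length_bp": lengths,
                "covered_bp": covered,
                "mean_depth": np.where(covered > 0, depth, 0.0),
            }
        ),
    )


@pytest.fixture
def small_reference():
    return make_reference([6, 4], marker_indices=(0, 5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
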