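"""Readers and writers for the plain-text interchange formats.

Formats
-------
* reference annotation: GFF3 (``gene`` features, 1-based inclusive
  coordinates, marker genes tagged ``single_copy_marker=true``)
* per-gene coverage: TSV with columns ``sample_id, species_id, gene_id,
  gene_length_bp, covered_bp, mean_depth`` (+ optional genome-summary row
  keyed ``gene_id="_genome"`` carrying ``genome_breadth, genome_mean_depth,
  species_abundance``)
* presence matrix: TSV, rows = genes in genome order, columns = individuals,
  values 0/1
* replicate map: TSV with ``sample_id, individual_id, time_point, lane``
* deletion blocks: BED (0-based half-open gene-span coordinates)
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .datatypes import CoverageProfile, DeletionBlock, PresenceMatrix, ReferenceGeneSet

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# GFF3 reference annotation
# ---------------------------------------------------------------------------

def write_gff3(reference: ReferenceGeneSet, path: PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, length in reference.contigs:
            fh.write(f"##sequence-region {contig_id} 1 {length}\n")
        for row in reference.genes.itertuples(index=False):
            attrs = f"ID={row.gene_id};ordinal={row.ordinal}"
            if row.is_marker:
                attrs += ";single_copy_marker=true"
            fh.write(
                "\t".join(
                    [
                        row.contig_id,
                        "strainpan",
                        "gene",
                        str(int(row.start)),
                        str(int(row.end)),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _parse_gff3_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        if not chunk:
            continue
        key, _, val = chunk.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3(path: PathLike, species_id: Optional[str] = None) -> ReferenceGeneSet:
    """Load gene annotations from a GFF3 file into a :class:`ReferenceGeneSet`.

    Contig lengths are taken from ``##sequence-region`` pragmas when present,
    otherwise from the maximum gene end per contig.  Within-contig ordinals
    are recomputed from the sorted start coordinates, so hand-edited files
    without ``ordinal`` attributes are accepted.
    """
    path = Path(path)
    contig_lengths: dict[str, int] = {}
    contig_order: list[str] = []
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                    if parts[1] not in contig_order:
                        contig_order.append(parts[1])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9 or fields[2] != "gene":
                continue
            contig, _src, _type, start, end, _score, _strand, _phase, attrs = fields
            a = _parse_gff3_attributes(attrs)
            gene_id = a.get("ID")
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute in {path}")
            marker = a.get("single_copy_marker", "").lower() in {"true", "1", "yes"}
            rows.append((gene_id, contig, int(start), int(end), marker))
            if contig not in contig_order:
                contig_order.append(contig)
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    genes = pd.DataFrame(rows, columns=["gene_id", "contig_id", "start", "end", "is_marker"])
    genes["ordinal"] = 0
    order_key = {c: i for i, c in enumerate(contig_order)}
    genes = genes.sort_values(
        ["contig_id", "start"], key=lambda s: s.map(order_key) if s.name == "contig_id" else s,
        kind="stable",
    ).reset_index(drop=True)
    genes["ordinal"] = genes.groupby("contig_id", sort=False).cumcount()
    contigs = [
        (c, contig_lengths.get(c, int(genes.loc[genes["contig_id"] == c, "end"].max())))
        for c in contig_order
    ]
    return ReferenceGeneSet(
        species_id=species_id or path.stem,
        contigs=contigs,
        genes=genes[["gene_id", "contig_id", "start", "end", "ordinal", "is_marker"]],
    )


# ---------------------------------------------------------------------------
# Coverage TSV
# ---------------------------------------------------------------------------

_GENOME_ROW = "_genome"


def write_coverage_tsv(profiles: Iterable[CoverageProfile], path: PathLike) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "sample_id",
                "individual_id",
                "species_id",
                "gene_id",
                "gene_length_bp",
                "covered_bp",
                "mean_depth",
                "genome_breadth",
                "genome_mean_depth",
                "species_abundance",
            ]
        )
        for p in profiles:
            writer.writerow(
                [
                    p.sample_id,
                    p.individual_id,
                    p.species_id,
                    _GENOME_ROW,
                    "",
                    "",
                    "",
                    f"{p.genome_breadth:.6g}",
                    f"{p.genome_mean_depth:.6g}",
                    "" if p.species_abundance is None else f"{p.species_abundance:.6g}",
                ]
            )
            for row in p.genes.itertuples(index=False):
                writer.writerow(
                    [
                        p.sample_id,
                        p.individual_id,
                        p.species_id,
                        row.gene_id,
                        int(row.gene_length_bp),
                        int(row.covered_bp),
                        f"{row.mean_depth:.4g}",
                        "",
                        "",
                        "",
                    ]
                )


def read_coverage_tsv(path: PathLike) -> list[CoverageProfile]:
    df = pd.read_csv(Path(path), sep="\t", dtype={"gene_id": str})
    if "individual_id" not in df.columns:
        df["individual_id"] = df["sample_id"]
    profiles = []
    for (sample_id, species_id), sub in df.groupby(["sample_id", "species_id"], sort=False):
        genome = sub[sub["gene_id"] == _GENOME_ROW]
        genes = sub[sub["gene_id"] != _GENOME_ROW]
        kwargs: dict = {}
        if len(genome):
            g = genome.iloc[0]
            for col, name in [
                ("genome_breadth", "genome_breadth"),
                ("genome_mean_depth", "genome_mean_depth"),
                ("species_abundance", "species_abundance"),
            ]:
                if col in genome.columns and pd.notna(g[col]):
                    kwargs[name] = float(g[col])
        profiles.append(
            CoverageProfile(
                sample_id=str(sample_id),
                individual_id=str(genes["individual_id"].iloc[0]),
                species_id=str(species_id),
                genes=genes[["gene_id", "gene_length_bp", "covered_bp", "mean_depth"]]
                .astype({"gene_length_bp": int, "covered_bp": int, "mean_depth": float})
                .reset_index(drop=True),
                **kwargs,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Presence matrix TSV
# ---------------------------------------------------------------------------

def write_presence_tsv(matrix: PresenceMatrix, path: PathLike) -> None:
    out = matrix.presence.astype(int)
    out.index.name = "gene_id"
    out.to_csv(Path(path), sep="\t")


def read_presence_tsv(path: PathLike, species_id: Optional[str] = None) -> PresenceMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col="gene_id")
    return PresenceMatrix(species_id=species_id or Path(path).stem, presence=df.astype(bool))


# ---------------------------------------------------------------------------
# Replicate map TSV
# ---------------------------------------------------------------------------

REPLICATE_MAP_COLUMNS = ["sample_id", "individual_id", "time_point", "lane"]


def write_replicate_map(replicate_map: pd.DataFrame, path: PathLike) -> None:
    replicate_map[REPLICATE_MAP_COLUMNS].to_csv(Path(path), sep="\t", index=False)


def read_replicate_map(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str, "individual_id": str})
    missing = [c for c in REPLICATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"replicate map missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Deletion blocks BED
# ---------------------------------------------------------------------------

def write_blocks_bed(
    blocks: Iterable[DeletionBlock], reference: ReferenceGeneSet, path: PathLike
) -> None:
    """Write blocks as BED: 0-based half-open span from the first to the
    last gene of the block; name = ``sample:blocksize:class``."""
    coords = reference.genes.set_index("gene_id")[["start", "end"]]
    with Path(path).open("w") as fh:
        for b in blocks:
            start = int(coords.loc[b.gene_ids[0], "start"]) - 1
            end = int(coords.loc[b.gene_ids[-1], "end"])
            name = f"{b.sample_id}:{b.n_genes}:{b.block_class}"
            fh.write(f"{b.contig_id}\t{start}\t{end}\t{name}\n")


def read_gene_category_map(path: PathLike) -> pd.Series:
    """Gene -> functional category map from a two-column TSV."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("gene-category map needs two columns (gene_id, category)")
    return df.set_index(df.columns[0])[df.columns[1]]
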