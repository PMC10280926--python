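"""File I/O: FASTA, coverage tables, tabular hit files, ortho matrices."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .covpart import GenomeBin
from .orthstats import OrthoMatrix
from .rbh import ProteinSeq
from .taxbin import BinAssignment, GeneTaxCall, ScaffoldRecord

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, wrap: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=wrap).write_file(records)


def read_proteins(path: str | Path) -> list[ProteinSeq]:
    return [ProteinSeq(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    """Columns: scaffold_id, length, coverage."""
    df = pd.read_csv(path, sep="\t")
    expected = {"scaffold_id", "length", "coverage"}
    if not expected <= set(df.columns):
        raise ValueError(f"coverage table must have columns {sorted(expected)}")
    return df


def write_coverage_tsv(scaffolds: list[ScaffoldRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "scaffold_id": [s.scaffold_id for s in scaffolds],
            "length": [s.length for s in scaffolds],
            "coverage": [s.coverage for s in scaffolds],
        }
    ).to_csv(path, sep="\t", index=False)


def scaffolds_from_tables(
    coverage: pd.DataFrame, gene_map: dict[str, str] | None = None
) -> list[ScaffoldRecord]:
    gene_map = gene_map or {}
    by_scaffold: dict[str, list[str]] = {}
    for gene, scaffold in gene_map.items():
        by_scaffold.setdefault(scaffold, []).append(gene)
    return [
        ScaffoldRecord(
            scaffold_id=str(row.scaffold_id),
            length=int(row.length),
            coverage=float(row.coverage),
            gene_ids=sorted(by_scaffold.get(str(row.scaffold_id), [])),
        )
        for row in coverage.itertuples()
    ]


def taxon_from_subject(sseqid: str) -> str:
    """Subject ids encode taxonomy as 'acc|<lineage>|nnn'."""
    parts = sseqid.split("|")
    if len(parts) < 2:
        raise ValueError(f"subject id does not encode a taxon: {sseqid!r}")
    return parts[1]


def read_hits_tabular(
    path: str | Path,
    gene_map: dict[str, str],
    evalue_cutoff: float = 1e-5,
) -> list[GeneTaxCall]:
    """Parse a 12-column tabular hit file into best-hit-per-gene tax calls.

    Hits above the e-value cutoff are dropped; the best retained hit per
    gene (highest bitscore, then smallest e-value, then subject id) wins.
    """
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    df = df[df["evalue"] <= evalue_cutoff]
    df = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
    ).drop_duplicates("qseqid", keep="first")
    calls = []
    unknown = []
    for row in df.itertuples():
        gene = str(row.qseqid)
        if gene not in gene_map:
            unknown.append(gene)
            continue
        calls.append(
            GeneTaxCall(
                gene_id=gene,
                scaffold_id=gene_map[gene],
                taxon=taxon_from_subject(str(row.sseqid)),
                evalue=float(row.evalue),
                bitscore=float(row.bitscore),
            )
        )
    if unknown:
        raise ValueError(
            "hits reference genes absent from the gene->scaffold map: "
            + ", ".join(sorted(unknown)[:10])
        )
    return calls


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene_id, scaffold_id."""
    df = pd.read_csv(path, sep="\t", names=["gene_id", "scaffold_id"], header=None)
    if df["gene_id"].iloc[0] == "gene_id":  # tolerate a header line
        df = df.iloc[1:]
    return dict(zip(df["gene_id"].astype(str), df["scaffold_id"].astype(str)))


def read_calls_tsv(path: str | Path) -> list[GeneTaxCall]:
    """Combined call table: gene_id, scaffold_id, taxon, evalue, bitscore."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneTaxCall(
            str(r.gene_id), str(r.scaffold_id), str(r.taxon),
            float(r.evalue), float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def write_calls_tsv(calls: list[GeneTaxCall], path: str | Path) -> None:
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(path, sep="\t", index=False)


def write_assignments_tsv(assignments: list[BinAssignment], path: str | Path) -> None:
    pd.DataFrame([a.__dict__ for a in assignments]).to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path: str | Path) -> list[BinAssignment]:
    df = pd.read_csv(path, sep="\t")
    return [
        BinAssignment(str(r.scaffold_id), str(r.bin), float(r.vote_fraction), int(r.n_votes))
        for r in df.itertuples()
    ]


def write_genome_bins_tsv(bins: list[GenomeBin], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": b.name,
                "n_scaffolds": b.n_scaffolds,
                "total_length": b.total_length,
                "mean_coverage": b.mean_coverage,
                "scaffold_ids": ",".join(b.scaffold_ids),
            }
            for b in bins
        ]
    ).to_csv(path, sep="\t", index=False)


def read_ortho_matrix(
    matrix_path: str | Path,
    genus_map_path: str | Path,
    lineage_map_path: str | Path | None = None,
    flags_path: str | Path | None = None,
    totals_path: str | Path | None = None,
) -> OrthoMatrix:
    """Long-format membership TSV (group_id, species, count) + map tables."""
    long = pd.read_csv(matrix_path, sep="\t")
    counts = (
        long.pivot_table(index="group_id", columns="species", values="count",
                         aggfunc="sum", fill_value=0)
        .astype(int)
    )
    counts.columns.name = None
    genus = pd.read_csv(genus_map_path, sep="\t")
    genus_map = dict(zip(genus["species"].astype(str), genus["genus"].astype(str)))
    kw: dict = {}
    if lineage_map_path:
        lin = pd.read_csv(lineage_map_path, sep="\t")
        kw["lineage_map"] = dict(zip(lin["species"].astype(str), lin["lineage"].astype(str)))
    if flags_path:
        flags = pd.read_csv(flags_path, sep="\t")
        kw["external_match"] = dict(
            zip(flags["group_id"].astype(str), flags["has_match_outside_lineage"].astype(bool))
        )
    if totals_path:
        tot = pd.read_csv(totals_path, sep="\t")
        kw["species_totals"] = dict(zip(tot["species"].astype(str), tot["total_genes"].astype(int)))
    return OrthoMatrix(counts=counts, genus_map=genus_map, **kw)


def write_ortho_matrix(matrix: OrthoMatrix, path: str | Path) -> None:
    long = (
        matrix.counts.stack().rename("count").reset_index()
        .rename(columns={"level_0": "group_id", "level_1": "species"})
    )
    long.columns = ["group_id", "species", "count"]
    long = long[long["count"] > 0]
    long.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
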