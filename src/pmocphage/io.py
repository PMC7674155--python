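"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython; tabular formats are TSV with 0-based half-open
coordinates. Every writer has a matching reader (round-trip identity is
tested).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneRecord, GenomeRecord
from .synthetic import SimulatedDepth


def write_genomes_fasta(genomes: list[GenomeRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=scaffold_id, description="")
        for genome in genomes
        for scaffold_id, seq in sorted(genome.sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_proteins_fasta(genes: list[GeneRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.protein), id=g.gene_id, description=g.product)
        for g in genes
        if g.protein
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gene_table(genomes: list[GenomeRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": genome.genome_id,
            "gene_id": g.gene_id,
            "scaffold_id": g.genome_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "product": g.product,
            "protein": g.protein,
        }
        for genome in genomes
        for g in sorted(genome.genes, key=lambda g: (g.genome_id, g.start))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> dict[str, list[GeneRecord]]:
    """Genes per genome_id from a gene-table TSV."""
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, list[GeneRecord]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(row.genome_id, []).append(
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.scaffold_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                product=row.product,
                protein=row.protein,
            )
        )
    return out


def write_depth(sim: SimulatedDepth, path: str | Path) -> None:
    """Long-format depth TSV: scaffold, pos, depth, identity_bin.

    Zero-depth (position, bin) pairs are omitted; positions are 0-based.
    """
    frames = []
    for ident, depth in zip(sim.identities, sim.depth_by_bin):
        pos = np.flatnonzero(depth)
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": sim.scaffold_id,
                    "pos": pos,
                    "depth": depth[pos],
                    "identity_bin": ident,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scaffold", "pos", "depth", "identity_bin"]
    )
    table.sort_values(["pos", "identity_bin"]).to_csv(path, sep="\t", index=False)


def read_depth(path: str | Path, length: int) -> SimulatedDepth:
    table = pd.read_csv(path, sep="\t")
    scaffold = str(table["scaffold"].iloc[0]) if len(table) else ""
    identities = tuple(sorted(set(table["identity_bin"])))
    depth = np.zeros((len(identities), length), dtype=np.int64)
    index = {ident: i for i, ident in enumerate(identities)}
    for row in table.itertuples(index=False):
        depth[index[row.identity_bin], int(row.pos)] = int(row.depth)
    return SimulatedDepth(scaffold, identities, depth)
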