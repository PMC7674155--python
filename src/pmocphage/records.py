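"""Core record types shared across the pipeline.

Coordinates are 0-based half-open throughout; strand is "+" or "-".
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneRecord:
    """A predicted protein-coding gene on a genome or scaffold."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = "hypothetical protein"
    protein: str = ""
    nucleotide: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A phage or bacterial genome (or scaffold set) with its genes.

    ``sequences`` maps scaffold id -> nucleotide sequence. Single-scaffold
    genomes (all curated phages here) use one entry keyed by ``genome_id``.
    """

    genome_id: str
    sequences: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    short_name: str = ""
    site: str = ""
    completeness: str = "complete"
    pmoc_taxonomy: str = ""
    kind: str = "phage"  # "phage" or "host"

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def n_orfs(self) -> int:
        return len(self.genes)

    @property
    def gc(self) -> float:
        """GC content in percent over all scaffolds."""
        total = self.length
        if total == 0:
            raise ValueError(f"genome {self.genome_id} has no sequence")
        gc = sum(s.count("G") + s.count("C") for s in self.sequences.values())
        return 100.0 * gc / total

    def scaffold_ids(self) -> list[str]:
        return sorted(self.sequences)

    def genes_on(self, scaffold_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.genome_id == scaffold_id]
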