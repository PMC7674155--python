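"""Metatranscriptome expression profiles and phage activity calls.

Per-gene expression for phage i in sample j is

    E_k = N_k / (L_k * S_ij)

with N_k the reads mapped to gene k, L_k the gene length in bp and S_ij
the total reads from the sample mapped to any gene of the phage. The
normalization makes sum_k E_k * L_k = 1 within a phage/sample, so ranks
compare within-phage allocation of transcription, not absolute levels.

A phage is called transcriptionally active in a sample when it attracts
both a minimum share (default 1%) and a minimum number (default 50) of
the sample's phage-assigned RNA reads; these thresholds are configurable
policy, chosen so that genomes recruiting only a few stray reads are
called inactive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACTIVITY_MIN_FRACTION = 0.01
ACTIVITY_MIN_READS = 50
TOP_N = 20

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ExpressionProfile:
    phage_id: str
    sample_id: str
    table: pd.DataFrame = field(repr=False)  # gene, start, N, L, E
    total_reads: int = 0

    @property
    def no_signal(self) -> bool:
        return self.total_reads == 0


def normalize_expression(
    counts: pd.DataFrame, phage_id: str = "", sample_id: str = ""
) -> ExpressionProfile:
    """Compute E_k = N_k / (L_k * S_ij) from a (gene, length, reads) table.

    ``counts`` needs columns gene, length, reads (optional start for tie
    ordering). All-zero counts yield a no-signal profile with empty E.
    """
    required = {"gene", "length", "reads"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if (counts["length"] <= 0).any():
        bad = counts.loc[counts["length"] <= 0, "gene"].tolist()
        raise ValueError(f"non-positive gene length for {bad}")
    if (counts["reads"] < 0).any():
        raise ValueError("negative read count")
    table = counts.copy()
    if "start" not in table.columns:
        table["start"] = np.arange(len(table))
    total = int(table["reads"].sum())
    table["E"] = (
        table["reads"] / (table["length"] * total) if total > 0 else np.nan
    )
    return ExpressionProfile(phage_id, sample_id, table, total)


def top_expressed(profile: ExpressionProfile, n: int = TOP_N) -> pd.DataFrame:
    """The n most highly expressed genes, ties broken by genomic position."""
    if profile.no_signal:
        raise ValueError(f"no RNA signal for phage {profile.phage_id}")
    ranked = profile.table.sort_values(
        ["E", "start"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(n).reset_index(drop=True)


@dataclass(frozen=True)
class ActivityCall:
    phage_id: str
    sample_id: str
    mapped_reads: int
    mapped_fraction: float
    active: bool


def activity_call(
    phage_read_totals: dict[str, int],
    sample_id: str = "",
    min_fraction: float = ACTIVITY_MIN_FRACTION,
    min_reads: int = ACTIVITY_MIN_READS,
) -> list[ActivityCall]:
    """Active/inactive call per phage from one sample's mapped-read totals."""
    if any(v < 0 for v in phage_read_totals.values()):
        raise ValueError("negative read total")
    total = sum(phage_read_totals.values())
    calls = []
    for phage_id in sorted(phage_read_totals):
        reads = phage_read_totals[phage_id]
        fraction = reads / total if total > 0 else 0.0
        calls.append(
            ActivityCall(
                phage_id=phage_id,
                sample_id=sample_id,
                mapped_reads=reads,
                mapped_fraction=fraction,
                active=fraction >= min_fraction and reads >= min_reads,
            )
        )
    return calls


def codon_usage(orf_sequences: list[str]) -> dict[str, int]:
    """In-frame codon counts over ORF nucleotide sequences (stops excluded)."""
    counts: dict[str, int] = {}
    for seq in orf_sequences:
        seq = seq.upper()
        if len(seq) % 3:
            raise ValueError("ORF length not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS or set(codon) - set("ACGT"):
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_trna_correspondence(
    orf_sequences: list[str], trna_anticodons: list[str]
) -> float | None:
    """Fraction of the genome's top-m codons decoded by its own tRNAs.

    m is the number of distinct codons decoded (reverse complement of the
    anticodon, exact Watson-Crick pairing); the score is |top-m codons
    intersected with decoded| / m. None when the genome encodes no tRNAs.
    """
    if not trna_anticodons:
        return None
    decoded = {
        anticodon.upper().translate(_COMPLEMENT)[::-1]
        for anticodon in trna_anticodons
    }
    m = len(decoded)
    usage = codon_usage(orf_sequences)
    ranked = sorted(usage, key=lambda c: (-usage[c], c))
    top = set(ranked[:m])
    return len(top & decoded) / m
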