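"""Protein pairwise alignment and percent identity.

Global (end-gap-free) alignment with BLOSUM62 scores, gap open 11 and
extend 1. Percent identity is identical columns divided by aligned
columns, where terminal gap overhangs are excluded but internal gap
columns count as non-identical. This is the identity used both to call
PmoC homologs on phage scaffolds and to rank candidate hosts.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class PairwiseResult:
    """Summary of one query-vs-reference protein alignment."""

    identity_pct: float  # identical / aligned columns, terminal gaps excluded
    n_matches: int
    n_aligned_columns: int
    ref_span: tuple[int, int]  # 0-based half-open reference interval covered
    query_span: tuple[int, int]
    ref_to_query: dict[int, int]  # aligned ref position -> query position

    def query_residue_at(self, query: str, ref_pos: int) -> str | None:
        """Query residue aligned to a (0-based) reference position, if any."""
        qpos = self.ref_to_query.get(ref_pos)
        return None if qpos is None else query[qpos]


def align_protein(query: str, reference: str) -> PairwiseResult:
    """Align ``query`` against ``reference`` and summarize identity/spans."""
    if not query or not reference:
        raise ValueError("cannot align empty sequence")
    alignment = _aligner().align(reference, query)[0]
    blocks_ref, blocks_query = alignment.aligned

    n_matches = 0
    aligned_cols = 0
    ref_to_query: dict[int, int] = {}
    prev_ref_end = prev_q_end = None
    for (rs, re_), (qs, qe) in zip(blocks_ref, blocks_query):
        if prev_ref_end is not None:
            # internal gap columns between consecutive matched blocks
            aligned_cols += (rs - prev_ref_end) + (qs - prev_q_end)
        aligned_cols += re_ - rs
        for offset in range(re_ - rs):
            rpos, qpos = rs + offset, qs + offset
            ref_to_query[rpos] = qpos
            if reference[rpos] == query[qpos]:
                n_matches += 1
        prev_ref_end, prev_q_end = re_, qe

    if aligned_cols == 0:
        return PairwiseResult(0.0, 0, 0, (0, 0), (0, 0), {})
    ref_span = (int(blocks_ref[0][0]), int(blocks_ref[-1][1]))
    query_span = (int(blocks_query[0][0]), int(blocks_query[-1][1]))
    return PairwiseResult(
        identity_pct=100.0 * n_matches / aligned_cols,
        n_matches=n_matches,
        n_aligned_columns=aligned_cols,
        ref_span=ref_span,
        query_span=query_span,
        ref_to_query=ref_to_query,
    )


def percent_identity(a: str, b: str) -> float:
    """Percent identity of ``a`` aligned against ``b``."""
    return align_protein(a, b).identity_pct
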