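"""Phage scaffold classification and the PmoC homolog screen.

A scaffold is called phage when its annotations contain at least one
phage-diagnostic keyword (capsid, terminase, portal, tail, ...) and no
bacterial single-copy marker (ribosomal protein) annotations — the manual
curation rule used to separate phage scaffolds from host material.

PmoC homologs are found by global protein alignment against a packaged
reference set; hits are reported at >=50% identity by default, checked for
the copper-binding triad (Asp156/His160/His173 in reference numbering),
and classified as full, one-terminus-only, or core-deleted. Fragmented
pmoC genes (split into two ORFs) are merged by concatenating the
fragments in reference order before downstream use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import PairwiseResult, align_protein
from .records import GeneRecord
from .references import CATALYTIC_RESIDUES, CATALYTIC_SITES, canonical_pmoc

PHAGE_KEYWORDS = (
    "capsid",
    "phage",
    "virus",
    "prophage",
    "terminase",
    "prohead",
    "tape measure",
    "tail",
    "head",
    "portal",
    "dna packaging",
)
HOST_MARKER_KEYWORDS = ("ribosomal protein",)

DEFAULT_REPORT_THRESHOLD = 50.0  # percent identity
FRAGMENT_MAX_SPAN_OVERLAP = 10  # residues
FRAGMENT_MAX_GENE_DISTANCE = 5_000  # bp
FULL_LENGTH_MIN_COVER = 0.7  # fraction of reference


def classify_phage_scaffold(genes: list[GeneRecord]) -> tuple[bool, float]:
    """Keyword-based phage call for one scaffold.

    Returns ``(is_phage, score)`` where score is the phage-keyword excess
    over host markers, floored at 0, per annotated gene.
    """
    if not genes:
        raise ValueError("cannot classify a scaffold with no genes")
    phage_hits = host_hits = 0
    for gene in genes:
        product = gene.product.lower()
        if any(k in product for k in HOST_MARKER_KEYWORDS):
            host_hits += 1
        elif any(k in product for k in PHAGE_KEYWORDS):
            phage_hits += 1
    score = max(phage_hits - host_hits, 0) / len(genes)
    return (phage_hits >= 1 and host_hits == 0), score


@dataclass
class PmoCHit:
    """A PmoC (or PmoA/PmoB) homolog found on a scaffold."""

    gene_id: str
    genome_id: str
    best_reference_id: str
    percent_identity: float
    reference_span: tuple[int, int]  # 0-based half-open on the reference
    query: str
    gene_start: int
    gene_end: int
    fragmented: bool = False
    partial: str = "full"  # full | N-only | C-only | core-deleted
    residues_ok: dict[int, bool] = field(default_factory=dict)
    member_genes: list[str] = field(default_factory=list)
    warning: str = ""


def residue_check(
    query: str,
    reference: str | None = None,
    alignment: PairwiseResult | None = None,
) -> dict[int, bool]:
    """Check the catalytic triad against the canonical reference numbering.

    A site is True iff the query column aligned to that reference position
    holds the required residue; sites falling in gaps or outside the
    aligned region are False (absent, not an error).
    """
    reference = reference or canonical_pmoc()
    if alignment is None:
        alignment = align_protein(query, reference)
    out: dict[int, bool] = {}
    for site, required in zip(CATALYTIC_SITES, CATALYTIC_RESIDUES):
        residue = alignment.query_residue_at(query, site - 1)
        out[site] = residue == required
    return out


def _third_coverage(aln: PairwiseResult, ref_len: int) -> tuple[float, float, float]:
    """Fraction of each reference third covered by aligned columns."""
    third = ref_len // 3
    bounds = [(0, third), (third, ref_len - third), (ref_len - third, ref_len)]
    covered = sorted(aln.ref_to_query)
    out = []
    for lo, hi in bounds:
        width = max(hi - lo, 1)
        n = sum(1 for p in covered if lo <= p < hi)
        out.append(n / width)
    return tuple(out)  # type: ignore[return-value]


def _classify_partial(aln: PairwiseResult, ref_len: int) -> str:
    n_cov, core_cov, c_cov = _third_coverage(aln, ref_len)
    total_cov = len(aln.ref_to_query) / ref_len
    if n_cov >= 0.5 and c_cov >= 0.5 and core_cov < 0.5:
        return "core-deleted"
    if total_cov >= FULL_LENGTH_MIN_COVER:
        return "full"
    return "C-only" if c_cov >= n_cov else "N-only"


def pmoc_search(
    proteins: list[GeneRecord],
    references: dict[str, str] | None = None,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> list[PmoCHit]:
    """Align every protein against every reference; report hits above threshold.

    The best reference (by identity) defines the hit; the catalytic-triad
    check always runs against the canonical numbering reference.
    """
    references = references if references is not None else {"PmoC_ref": canonical_pmoc()}
    if not references:
        raise ValueError("empty reference set")
    hits: list[PmoCHit] = []
    for gene in proteins:
        if not gene.protein:
            continue
        best_id, best_aln = None, None
        for ref_id in sorted(references):
            aln = align_protein(gene.protein, references[ref_id])
            if best_aln is None or aln.identity_pct > best_aln.identity_pct:
                best_id, best_aln = ref_id, aln
        assert best_aln is not None and best_id is not None
        if best_aln.identity_pct < report_threshold:
            continue
        ref_len = len(references[best_id])
        hits.append(
            PmoCHit(
                gene_id=gene.gene_id,
                genome_id=gene.genome_id,
                best_reference_id=best_id,
                percent_identity=best_aln.identity_pct,
                reference_span=best_aln.ref_span,
                query=gene.protein,
                gene_start=gene.start,
                gene_end=gene.end,
                partial=_classify_partial(best_aln, ref_len),
                residues_ok=residue_check(gene.protein, references[best_id], best_aln),
                member_genes=[gene.gene_id],
            )
        )
    return hits


def merge_pmoc_fragments(
    hits: list[PmoCHit], references: dict[str, str] | None = None
) -> list[PmoCHit]:
    """Merge split pmoC fragments on one scaffold into a single hit.

    Two hits sharing scaffold and reference merge when their reference
    spans are near-disjoint (overlap <= 10 residues) and the genes lie
    within 5 kb; the merged query is the concatenation in reference-span
    order and its identity/triad status is recomputed from a fresh
    alignment. More than two candidate fragments are still merged but the
    result carries a warning.
    """
    if not hits:
        return []
    references = references if references is not None else {"PmoC_ref": canonical_pmoc()}
    by_key: dict[tuple[str, str], list[PmoCHit]] = {}
    for h in hits:
        by_key.setdefault((h.genome_id, h.best_reference_id), []).append(h)

    merged: list[PmoCHit] = []
    for (_, ref_id), group in sorted(by_key.items()):
        group = sorted(group, key=lambda h: h.reference_span)
        if len(group) == 1:
            merged.append(group[0])
            continue
        spans_ok = all(
            group[i].reference_span[1] - group[i + 1].reference_span[0]
            <= FRAGMENT_MAX_SPAN_OVERLAP
            for i in range(len(group) - 1)
        )
        positions_ok = (
            max(h.gene_end for h in group) - min(h.gene_start for h in group)
            <= FRAGMENT_MAX_GENE_DISTANCE
        )
        if not (spans_ok and positions_ok):
            merged.extend(group)
            continue
        concat = "".join(h.query for h in group)
        ref = references[ref_id]
        aln = align_protein(concat, ref)
        merged.append(
            PmoCHit(
                gene_id="+".join(h.gene_id for h in group),
                genome_id=group[0].genome_id,
                best_reference_id=ref_id,
                percent_identity=aln.identity_pct,
                reference_span=(
                    group[0].reference_span[0],
                    group[-1].reference_span[1],
                ),
                query=concat,
                gene_start=min(h.gene_start for h in group),
                gene_end=max(h.gene_end for h in group),
                fragmented=True,
                partial=_classify_partial(aln, len(ref)),
                residues_ok=residue_check(concat, ref, aln),
                member_genes=[g for h in group for g in h.member_genes],
                warning="more than two pmoC fragments" if len(group) > 2 else "",
            )
        )
    return merged


def confirm_no_pmoab(
    genes: list[GeneRecord],
    references: dict[str, str],
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> bool:
    """True iff no gene hits a PmoA/PmoB reference at the report threshold."""
    return not pmoc_search(genes, references, report_threshold)


def screen_genome(
    genes: list[GeneRecord],
    pmoc_refs: dict[str, str] | None = None,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> list[PmoCHit]:
    """Search, then merge fragments: the standard per-genome pmoC screen."""
    hits = pmoc_search(genes, pmoc_refs, report_threshold)
    return merge_pmoc_fragments(hits, pmoc_refs)
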