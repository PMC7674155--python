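"""Phage-host linkage: PmoC similarity, co-occurrence, CRISPR spacers.

A phage is assigned to the coexisting methanotroph whose PmoC is most
similar to the phage's PmoC, provided that identity exceeds 90%; near-ties
(within 0.5 points) are reported as ambiguous. The link is corroborated by
Pearson correlation of log10 coverages across samples and, independently,
by CRISPR spacers from host scaffolds matching the phage genome over at
least 30 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import AbundanceSeries
from .screen import PmoCHit

HOST_ASSIGN_MIN_IDENTITY = 90.0  # percent
AMBIGUITY_MARGIN = 0.5  # identity points
SPACER_MIN_MATCH = 30  # bp
CRISPR_MIN_SPACER = 17  # bp
CRISPR_MAX_SPACER = 72  # bp
CRISPR_REPEAT_RANGE = (21, 48)  # bp, inclusive

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class HostPrediction:
    phage_id: str
    host_id: str | None
    pmoc_identity: float
    runner_up_identity: float
    ambiguous_with: list[str] = field(default_factory=list)
    cooccurrence_r: float | None = None
    co_detected_samples: int | None = None
    crispr_support: bool = False


@dataclass
class CrisprArray:
    scaffold_id: str
    repeat: str
    spacers: list[str]
    span: tuple[int, int]  # 0-based half-open locus span


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    phage_id: str
    match_length: int
    mismatches: int
    position: int  # 0-based start on the phage genome (forward strand)
    strand: str


def predict_host_by_pmoc(
    phage_hit: PmoCHit,
    candidate_hosts: dict[str, str],
    min_identity: float = HOST_ASSIGN_MIN_IDENTITY,
) -> HostPrediction:
    """Assign the host whose PmoC is most similar to the phage PmoC (>90%)."""
    from .align import percent_identity

    if not candidate_hosts:
        raise ValueError("no candidate hosts supplied")
    identities = {
        host_id: percent_identity(phage_hit.query, seq)
        for host_id, seq in candidate_hosts.items()
    }
    ranked = sorted(identities.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else 0.0
    if best <= min_identity:
        return HostPrediction(phage_hit.genome_id, None, best, runner_up)
    ambiguous = [h for h, ident in ranked[1:] if best - ident < AMBIGUITY_MARGIN]
    return HostPrediction(
        phage_id=phage_hit.genome_id,
        host_id=best_id,
        pmoc_identity=best,
        runner_up_identity=runner_up,
        ambiguous_with=ambiguous,
    )


def cooccurrence(
    phage_series: AbundanceSeries, host_series: AbundanceSeries
) -> tuple[float, int]:
    """Correlation of phage and host coverages across samples.

    Pearson r of log10(coverage + pseudocount) over samples where at least
    one of the two is detected; the pseudocount is 0.1x the smallest
    nonzero coverage in either series. Also counts samples where both
    detection rules pass. r is NaN with fewer than 3 usable samples or a
    constant series.
    """
    if phage_series.samples != host_series.samples:
        raise ValueError("series must share the same sample index")
    either = phage_series.detected | host_series.detected
    co_detected = int(np.sum(phage_series.detected & host_series.detected))
    x = phage_series.coverage[either]
    y = host_series.coverage[either]
    if x.size < 3:
        return float("nan"), co_detected
    nonzero = np.concatenate([x[x > 0], y[y > 0]])
    pseudo = 0.1 * nonzero.min() if nonzero.size else 1.0
    lx, ly = np.log10(x + pseudo), np.log10(y + pseudo)
    if np.ptp(lx) == 0 or np.ptp(ly) == 0:
        return float("nan"), co_detected
    r = float(np.corrcoef(lx, ly)[0, 1])
    return r, co_detected


def find_crispr_arrays(
    sequence: str,
    scaffold_id: str = "",
    min_spacer: int = CRISPR_MIN_SPACER,
    max_spacer: int = CRISPR_MAX_SPACER,
    repeat_range: tuple[int, int] = CRISPR_REPEAT_RANGE,
) -> list[CrisprArray]:
    """Find CRISPR-like loci: >=2 exact repeat units separated by spacers.

    A simplified exact-repeat scanner: a seed k-mer of the minimum repeat
    length recurring with spacer-sized gaps nucleates an array; the repeat
    unit is then extended maximally (left and right) while every
    occurrence agrees, up to the maximum repeat length. Arrays need >=2
    exact repeat units, spacers within [min_spacer, max_spacer], and
    adjacent spacers must differ (tandem repeats are not arrays).
    """
    if len(sequence) < 100:
        raise ValueError("sequence too short to scan for CRISPR loci")
    seq = sequence.upper()
    n = len(seq)
    k = repeat_range[0]
    max_rep = repeat_range[1]

    index: dict[str, list[int]] = {}
    for i in range(0, n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    masked = np.zeros(n, dtype=bool)
    arrays: list[CrisprArray] = []
    slack = max_rep - k  # unextended unit may leave repeat residue in the gap

    # collect every candidate chain, then commit the longest ones first so a
    # shifted shadow of a repeat cannot fragment the true array
    candidates: list[list[int]] = []
    for positions in index.values():
        if len(positions) < 2:
            continue
        for start in range(len(positions) - 1):
            chain = [positions[start]]
            for p in positions[start + 1 :]:
                gap = p - (chain[-1] + k)
                if min_spacer <= gap <= max_spacer + slack:
                    chain.append(p)
                elif gap > max_spacer + slack:
                    break
            if len(chain) >= 2:
                candidates.append(chain)
    candidates.sort(key=lambda c: (-len(c), c[0]))

    for chain in candidates:
        if any(masked[p] or masked[p + k - 1] for p in chain):
            continue
        # extend the unit while all occurrences agree; agreement stops at the
        # true repeat/spacer boundary for non-identical spacers, and spacers
        # that end up too short disqualify the array afterwards
        min_diff = min(b - a for a, b in zip(chain, chain[1:]))
        left, right = 0, k

        def can_grow(left: int, right: int) -> bool:
            return right - left < max_rep and right - left < min_diff - 1

        while (
            can_grow(left, right)
            and chain[-1] + right < n
            and len({seq[p + right] for p in chain}) == 1
        ):
            right += 1
        while (
            can_grow(left, right)
            and chain[0] + left > 0
            and len({seq[p + left - 1] for p in chain}) == 1
        ):
            left -= 1
        starts = [p + left for p in chain]
        rep_len = right - left
        unit = seq[starts[0] : starts[0] + rep_len]
        spacers = [
            seq[starts[j] + rep_len : starts[j + 1]]
            for j in range(len(starts) - 1)
        ]
        if not all(min_spacer <= len(s) <= max_spacer for s in spacers):
            continue
        if any(a == b for a, b in zip(spacers, spacers[1:])):
            continue
        # a spacer sharing a k-long stretch of the repeat unit means the
        # chain skipped a repeat occurrence (shadow chain) - not an array
        unit_kmers = {unit[i : i + k] for i in range(rep_len - k + 1)}
        if any(kmer in s for kmer in unit_kmers for s in spacers):
            continue
        span = (starts[0], starts[-1] + rep_len)
        arrays.append(CrisprArray(scaffold_id, unit, spacers, span))
        masked[span[0] : span[1]] = True
    arrays.sort(key=lambda a: a.span)
    return arrays


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _mismatch_counts(genome: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Mismatches of the probe at every window start (vectorized scan)."""
    m, n = probe.size, genome.size
    if n < m:
        return np.empty(0, dtype=int)
    counts = np.zeros(n - m + 1, dtype=np.int32)
    for k in range(m):
        counts += genome[k : n - m + k + 1] != probe[k]
    return counts


def spacer_targets(
    spacers: dict[str, str],
    phage_genomes: dict[str, str],
    max_mismatches: int = 0,
    min_match: int = SPACER_MIN_MATCH,
) -> list[SpacerMatch]:
    """Match spacers against phage genomes on both strands.

    A match is the full spacer aligned ungapped with at most
    ``max_mismatches``; spacers shorter than ``min_match`` bp can never be
    reported, mirroring the >=30 bp reporting rule.
    """
    if not spacers:
        raise ValueError("no spacers supplied")
    matches: list[SpacerMatch] = []
    encoded_genomes = {pid: _encode(s) for pid, s in phage_genomes.items()}
    for spacer_id in sorted(spacers):
        spacer = spacers[spacer_id]
        if len(spacer) < min_match:
            continue
        for strand, probe_seq in (("+", spacer), ("-", revcomp(spacer))):
            probe = _encode(probe_seq)
            for phage_id in sorted(encoded_genomes):
                counts = _mismatch_counts(encoded_genomes[phage_id], probe)
                for pos in np.flatnonzero(counts <= max_mismatches):
                    matches.append(
                        SpacerMatch(
                            spacer_id=spacer_id,
                            phage_id=phage_id,
                            match_length=len(spacer),
                            mismatches=int(counts[pos]),
                            position=int(pos),
                            strand=strand,
                        )
                    )
    return matches
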