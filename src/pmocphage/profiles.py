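"""Coverage, breadth, detection rules, marker abundance and growth index.

All statistics derive from per-base depth profiles. A profile carries the
read-identity filter it was accumulated under: depth contributed by reads
below the filter is discarded before any statistic is computed, matching
the convention that a read either maps at the required similarity or does
not count at all.

Detection rules (inclusive thresholds):

* phage present in a sample  - breadth >= 0.75 at read identity >= 95%
* host present in a sample   - every scaffold at breadth >= 0.75 at read
  identity >= 98%; genome coverage is the unweighted mean of per-scaffold
  coverages
* marker (rpS3) reported     - breadth >= 0.5; relative abundance is the
  marker coverage divided by the summed coverage of all reported markers

The growth index estimates the origin-to-terminus coverage gradient of a
replicating population: windowed log2 coverage is sorted, trimmed, and
regressed against rank fraction; the index is 2**slope, so a flat profile
gives ~1 and a population replicating with a 2:1 origin/terminus gradient
gives ~2. Genomes under 5x mean coverage are ineligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PHAGE_MIN_IDENTITY = 0.95
HOST_MIN_IDENTITY = 0.98
DETECTION_MIN_BREADTH = 0.75
MARKER_MIN_BREADTH = 0.5
GROWTH_MIN_COVERAGE = 5.0


@dataclass
class DepthProfile:
    """Per-base depth for one scaffold under a stated identity filter."""

    scaffold_id: str
    depth: np.ndarray  # int per-base depth, length == scaffold length
    identity_filter: float = 0.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D per-base array")
        if self.depth.size == 0:
            raise ValueError(f"zero-length scaffold {self.scaffold_id}")
        if np.any(self.depth < 0):
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class CoverageStat:
    coverage: float  # mean per-base depth (fold)
    breadth: float  # fraction of positions with depth >= 1


@dataclass(frozen=True)
class DetectionCall:
    entity_id: str
    detected: bool
    rule: str
    genome_coverage: float


@dataclass
class AbundanceSeries:
    """Per-sample coverage and detection flags for one entity."""

    entity_id: str
    samples: list[str]
    coverage: np.ndarray  # fold coverage per sample
    detected: np.ndarray  # boolean per sample (entity's detection rule)

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        if not (len(self.samples) == self.coverage.size == self.detected.size):
            raise ValueError("samples, coverage and detected must align")


@dataclass(frozen=True)
class GrowthIndex:
    genome_id: str
    index: float | None
    eligible: bool
    mean_coverage: float


def scaffold_coverage(profile: DepthProfile) -> CoverageStat:
    """Mean depth (total mapped bases / length) and covered fraction."""
    depth = profile.depth
    return CoverageStat(
        coverage=float(depth.sum()) / depth.size,
        breadth=float(np.count_nonzero(depth)) / depth.size,
    )


def detect_phage(
    stats: CoverageStat,
    identity_filter: float,
    entity_id: str = "",
    min_breadth: float = DETECTION_MIN_BREADTH,
) -> DetectionCall:
    """Phage occurrence call: breadth >= 0.75 under a >=95% identity filter."""
    if identity_filter < PHAGE_MIN_IDENTITY:
        raise ValueError(
            f"phage detection requires an identity filter >= {PHAGE_MIN_IDENTITY}, "
            f"got {identity_filter}"
        )
    return DetectionCall(
        entity_id=entity_id,
        detected=stats.breadth >= min_breadth,
        rule=f"phage: id>={identity_filter:g} & breadth>={min_breadth:g}",
        genome_coverage=stats.coverage,
    )


def detect_host(
    profiles: list[DepthProfile],
    entity_id: str = "",
    min_breadth: float = DETECTION_MIN_BREADTH,
) -> DetectionCall:
    """Host occurrence call: every scaffold at breadth >= 0.75 (>=98% identity).

    Genome coverage is the unweighted mean of per-scaffold coverages,
    reported whether or not the genome is called present.
    """
    if not profiles:
        raise ValueError("host detection needs at least one scaffold profile")
    for p in profiles:
        if p.identity_filter < HOST_MIN_IDENTITY:
            raise ValueError(
                f"host detection requires profiles filtered at >= {HOST_MIN_IDENTITY} "
                f"identity; scaffold {p.scaffold_id} was filtered at {p.identity_filter}"
            )
    stats = [scaffold_coverage(p) for p in profiles]
    return DetectionCall(
        entity_id=entity_id,
        detected=all(s.breadth >= min_breadth for s in stats),
        rule=f"host: id>={HOST_MIN_IDENTITY:g} & breadth>={min_breadth:g} on every scaffold",
        genome_coverage=float(np.mean([s.coverage for s in stats])),
    )


def dereplicate_markers(
    markers: dict[str, str], min_mutual_overlap: float = 0.8
) -> tuple[list[str], dict[str, str]]:
    """Collapse identical marker proteins (100% identity over >=0.8 mutual overlap).

    Two sequences collapse when one is a substring of the other and the
    shared region covers at least ``min_mutual_overlap`` of both lengths.
    The representative is the longest member (ties broken by id). Returns
    the representative ids and a member -> representative map.
    """
    if not markers:
        raise ValueError("no marker sequences to dereplicate")
    order = sorted(markers, key=lambda i: (-len(markers[i]), i))
    reps: list[str] = []
    assign: dict[str, str] = {}
    for mid in order:
        seq = markers[mid]
        home = None
        for rep in reps:
            rseq = markers[rep]
            if seq in rseq and len(seq) >= min_mutual_overlap * len(rseq):
                home = rep
                break
        if home is None:
            reps.append(mid)
            assign[mid] = mid
        else:
            assign[mid] = home
    return sorted(reps), assign


def rps3_relative_abundance(
    marker_stats: dict[str, CoverageStat], min_breadth: float = MARKER_MIN_BREADTH
) -> dict[str, float]:
    """Per-sample relative abundance from marker (rpS3) coverages.

    Markers with breadth below ``min_breadth`` are dropped from both the
    numerator and the denominator. The reported abundances sum to 1; an
    empty dict means no marker passed the breadth cutoff.
    """
    eligible = {
        mid: s.coverage for mid, s in marker_stats.items() if s.breadth >= min_breadth
    }
    total = sum(eligible.values())
    if total <= 0:
        return {}
    return {mid: cov / total for mid, cov in eligible.items()}


def growth_index(
    profile: DepthProfile,
    window: int = 5_000,
    trim: float = 0.05,
    min_coverage: float = GROWTH_MIN_COVERAGE,
    genome_id: str = "",
) -> GrowthIndex:
    """Origin-to-terminus coverage-gradient index for a replicating genome.

    Non-overlapping ``window``-bp mean coverages are sorted, the top and
    bottom ``trim`` fractions are discarded, and log2 coverage is regressed
    on rank fraction in [0, 1]; the index is 2**slope. A pseudocount of 0.5
    guards log2 of empty windows. The index is scale-invariant only up to
    the pseudocount, which is negligible at the >=5x coverages where the
    estimate is reported at all.
    """
    name = genome_id or profile.scaffold_id
    mean_cov = float(profile.depth.mean())
    if mean_cov < min_coverage:
        return GrowthIndex(name, None, False, mean_cov)
    n_windows = profile.length // window
    if n_windows < 2:
        raise ValueError(
            f"genome {name} shorter than two {window}-bp windows; "
            "use a smaller window"
        )
    used = n_windows * window
    means = np.sort(profile.depth[:used].reshape(n_windows, window).mean(axis=1))
    # sorted window values are matched to evenly spaced window-center
    # positions so the fitted slope is per unit of genome fraction; the
    # replication origin's location is unknown, hence the sort
    centers = (window / 2 + window * np.arange(n_windows)) / profile.length
    k = int(trim * n_windows)
    if n_windows - 2 * k >= 2:
        means = means[k : n_windows - k]
        centers = centers[k : n_windows - k]
    log2cov = np.log2(means + 0.5)
    slope = np.polyfit(centers, log2cov, 1)[0]
    return GrowthIndex(name, float(2.0**slope), True, mean_cov)
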