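"""Synthetic methanotroph/phage communities for end-to-end testing.

Generates the data structures the downstream analyses consume, with the
statistical features they assume:

* host (methanotroph) genomes carrying a pmoCAB operon, optionally a
  stand-alone pmoC, ribosomal-protein markers (incl. rpS3) and a planted
  CRISPR array whose first spacer targets one of the phages;
* phage genomes carrying phage-diagnostic structural genes and a pmoC
  copied from their true host, with elevated divergence in the N/C
  terminal thirds of the protein and optional fragmentation into two ORFs;
* "related" phages sharing the structural gene repertoire but lacking
  pmoC (the comparison genomes of the presence/absence analysis);
* coupled host-phage abundance series across samples;
* per-base depth profiles with a read-identity mix and an optional
  origin-to-terminus coverage gradient (replication signal);
* per-gene transcript counts with pmoC and structural genes boosted in
  late infection;
* SNP allele-count tables with a planted fraction of frequency-shifted
  sites.

Everything is driven by one integer seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import GeneRecord, GenomeRecord
from .references import (
    AMINO_ACIDS,
    CATALYTIC_SITES,
    canonical_pmoa,
    canonical_pmob,
    canonical_pmoc,
)

STRUCTURAL_PRODUCTS = (
    "major capsid protein",
    "portal protein",
    "terminase large subunit",
    "prohead protease",
    "tail sheath protein",
    "tail fibre protein",
    "scaffolding protein",
    "DNA packaging protein",
)
RIBOSOMAL_PRODUCTS = (
    "ribosomal protein S3",
    "ribosomal protein L2",
    "ribosomal protein S7",
)
PMOC_PRODUCT = "particulate methane monooxygenase subunit C"
PMOA_PRODUCT = "particulate methane monooxygenase subunit A"
PMOB_PRODUCT = "particulate methane monooxygenase subunit B"

# deterministic reverse-translation table: lexicographically first codon
_CODONS = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}


def reverse_translate(protein: str) -> str:
    return "".join(_CODONS[aa] for aa in protein) + "TAA"


@dataclass
class CommunityConfig:
    """Study conditions for one synthetic community.

    Genome sizes are scaled down (tens of kb) relative to real curated
    phage genomes so that whole communities simulate in seconds; every
    analysis operates per-base/per-gene and is size-agnostic.
    """

    n_hosts: int = 4
    n_phages: int = 5
    n_related_phages: int = 2  # structural-gene relatives without pmoC
    genome_length_range: tuple[int, int] = (30_000, 60_000)
    pmoc_terminal_divergence: float = 0.08
    pmoc_core_divergence: float = 0.01
    host_terminal_divergence: float = 0.15  # host PmoC vs the canonical ref
    host_core_divergence: float = 0.04
    fragmentation_prob: float = 0.0
    standalone_pmoc_prob: float = 0.5
    n_samples: int = 12
    coupling: float = 0.9
    depth_mean: float = 20.0
    read_identity_mix: tuple[tuple[float, float], ...] = (
        (0.99, 0.7),
        (0.96, 0.2),
        (0.90, 0.1),
    )
    growth_gradient: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "pmoc_terminal_divergence",
            "pmoc_core_divergence",
            "host_terminal_divergence",
            "host_core_divergence",
            "fragmentation_prob",
            "standalone_pmoc_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.genome_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"genome_length_range must be positive, got {lo, hi}")
        if not -1.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must be in [-1, 1], got {self.coupling}")
        if self.depth_mean < 0:
            raise ValueError(f"depth_mean must be >= 0, got {self.depth_mean}")
        if self.growth_gradient < 1.0:
            raise ValueError(
                f"growth_gradient must be >= 1, got {self.growth_gradient}"
            )
        weights = [w for _, w in self.read_identity_mix]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"read_identity_mix weights must sum to 1, got {weights}")
        for count_field in ("n_hosts", "n_phages", "n_samples"):
            if getattr(self, count_field) < 1:
                raise ValueError(f"{count_field} must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth planted in a community."""

    true_host_of: dict[str, str]
    true_abundances: pd.DataFrame  # samples x entities, rows sum to 1
    coverage: pd.DataFrame  # samples x entities, fold coverage
    true_growth_index: dict[str, float]
    planted_spacers: list[tuple[str, str, str]]  # (host, spacer, phage)
    pmoc_genes: dict[str, list[str]] = field(default_factory=dict)
    host_pmoc: dict[str, str] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _diverge(
    rng: np.random.Generator,
    protein: str,
    terminal_rate: float,
    core_rate: float,
    protect: tuple[int, ...] = (),
) -> str:
    """Substitute residues at different rates in terminal thirds vs core.

    Terminal thirds are len//3 residues at each end (integer division; any
    middle remainder belongs to the core). ``protect`` lists 1-based
    positions never touched (the catalytic triad).
    """
    n = len(protein)
    third = n // 3
    out = list(protein)
    protected = {p - 1 for p in protect}
    for i in range(n):
        if i in protected:
            continue
        rate = terminal_rate if (i < third or i >= n - third) else core_rate
        if rng.random() < rate:
            choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _layout_genome(
    rng: np.random.Generator,
    genome_id: str,
    length: int,
    planned: list[tuple[str, str, str | None]],
    locked_pairs: set[str] = frozenset(),
    reserve_start: int = 0,
) -> GenomeRecord:
    """Assemble a genome: random background plus laid-out genes.

    ``planned`` holds (gene tag, product, protein-or-None) entries; None
    means a random protein. Entries whose tag is in ``locked_pairs`` stay
    adjacent to the following entry (fragmented-gene pairs). Hypothetical
    genes fill the remaining space. The first ``reserve_start`` bp are kept
    gene-free (CRISPR planting space).
    """
    entries = list(planned)
    units: list[list[tuple[str, str, str | None]]] = []
    i = 0
    while i < len(entries):
        if entries[i][0] in locked_pairs and i + 1 < len(entries):
            units.append([entries[i], entries[i + 1]])
            i += 2
        else:
            units.append([entries[i]])
            i += 1
    rng.shuffle(units)

    background = rng.choice(list("ACGT"), size=length)
    genes: list[GeneRecord] = []
    pos = reserve_start + int(rng.integers(150, 400))
    serial = 0

    def place(tag: str, product: str, protein: str | None) -> bool:
        nonlocal pos, serial
        if protein is None:
            protein = _random_protein(rng, int(rng.integers(100, 300)))
        nt = reverse_translate(protein)
        if pos + len(nt) + 100 > length:
            return False
        serial += 1
        gid = f"{genome_id}_{serial:03d}_{tag}"
        genes.append(
            GeneRecord(
                gene_id=gid,
                genome_id=genome_id,
                start=pos,
                end=pos + len(nt),
                strand="+",
                product=product,
                protein=protein,
                nucleotide=nt,
            )
        )
        background[pos : pos + len(nt)] = list(nt)
        pos += len(nt) + int(rng.integers(60, 200))
        return True

    for unit in units:
        for tag, product, protein in unit:
            if not place(tag, product, protein):
                raise ValueError(
                    f"genome length {length} too short for the planned genes "
                    f"of {genome_id}"
                )
    while pos + 1_200 < length:
        place("hyp", "hypothetical protein", None)

    genes.sort(key=lambda g: g.start)
    return GenomeRecord(
        genome_id=genome_id,
        sequences={genome_id: "".join(background)},
        genes=genes,
    )


def simulate_community(
    config: CommunityConfig,
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate a full community and its planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.genome_length_range

    host_pmoc: dict[str, str] = {}
    genomes: list[GenomeRecord] = []
    pmoc_genes: dict[str, list[str]] = {}

    # --- hosts -----------------------------------------------------------
    host_ids = [f"host_{i + 1}" for i in range(config.n_hosts)]
    for hid in host_ids:
        pmoc = _diverge(
            rng,
            canonical_pmoc(),
            config.host_terminal_divergence,
            config.host_core_divergence,
            protect=CATALYTIC_SITES,
        )
        host_pmoc[hid] = pmoc
        planned: list[tuple[str, str, str | None]] = [
            ("rpS3", RIBOSOMAL_PRODUCTS[0], _random_protein(rng, 220)),
            ("rpL2", RIBOSOMAL_PRODUCTS[1], None),
            ("rpS7", RIBOSOMAL_PRODUCTS[2], None),
            ("pmoC", PMOC_PRODUCT, pmoc),
            ("pmoA", PMOA_PRODUCT, canonical_pmoa()),
            ("pmoB", PMOB_PRODUCT, canonical_pmob()),
        ]
        if rng.random() < config.standalone_pmoc_prob:
            planned.append(("pmoC2", PMOC_PRODUCT, pmoc))
        genome = _layout_genome(
            rng, hid, int(rng.integers(lo, hi + 1)), planned, reserve_start=700
        )
        genome.kind = "host"
        genomes.append(genome)
        pmoc_genes[hid] = [
            g.gene_id for g in genome.genes if g.product == PMOC_PRODUCT
        ]

    # --- pmoC-phages ------------------------------------------------------
    phage_ids = [f"phage_{i + 1}" for i in range(config.n_phages)]
    true_host_of: dict[str, str] = {}
    for pid in phage_ids:
        host = host_ids[int(rng.integers(config.n_hosts))]
        true_host_of[pid] = host
        pmoc = _diverge(
            rng,
            host_pmoc[host],
            config.pmoc_terminal_divergence,
            config.pmoc_core_divergence,
            protect=CATALYTIC_SITES,
        )
        planned = [
            (f"struct{i}", product, None)
            for i, product in enumerate(STRUCTURAL_PRODUCTS)
        ]
        locked: set[str] = set()
        if rng.random() < config.fragmentation_prob:
            cut = int(len(pmoc) * rng.uniform(0.4, 0.6))
            planned.append(("pmoCn", "hypothetical protein", pmoc[:cut]))
            planned.append(("pmoCc", "hypothetical protein", pmoc[cut:]))
            locked.add("pmoCn")
        else:
            planned.append(("pmoC", "hypothetical protein", pmoc))
        genome = _layout_genome(
            rng, pid, int(rng.integers(lo, hi + 1)), planned, locked_pairs=locked
        )
        genome.kind = "phage"
        genome.pmoc_taxonomy = "synthetic"
        genomes.append(genome)
        pmoc_genes[pid] = [
            g.gene_id
            for g in genome.genes
            if "pmoC" in g.gene_id.rsplit("_", 1)[-1]
        ]

    # --- related phages without pmoC -------------------------------------
    related_ids = [f"related_{i + 1}" for i in range(config.n_related_phages)]
    for rid in related_ids:
        planned = [
            (f"struct{i}", product, None)
            for i, product in enumerate(STRUCTURAL_PRODUCTS)
        ]
        genome = _layout_genome(rng, rid, int(rng.integers(lo, hi + 1)), planned)
        genome.kind = "phage"
        genomes.append(genome)

    by_id = {g.genome_id: g for g in genomes}

    # --- CRISPR spacers planted into host genomes -------------------------
    planted_spacers: list[tuple[str, str, str]] = []
    hosts_of: dict[str, list[str]] = {}
    for pid, hid in true_host_of.items():
        hosts_of.setdefault(hid, []).append(pid)
    for hid in host_ids:
        targets = hosts_of.get(hid, [])
        if not targets:
            continue
        repeat = "".join(rng.choice(list("ACGT"), size=28))
        spacers: list[str] = []
        for pid in targets:
            phage_seq = by_id[pid].sequences[pid]
            start = int(rng.integers(500, len(phage_seq) - 600))
            spacer = phage_seq[start : start + 32]
            spacers.append(spacer)
            planted_spacers.append((hid, spacer, pid))
        while len(spacers) < 3:
            spacers.append("".join(rng.choice(list("ACGT"), size=33)))
        locus = repeat + repeat.join(spacers) + repeat
        host_seq = by_id[hid].sequences[hid]
        insert_at = 50
        by_id[hid].sequences[hid] = (
            host_seq[:insert_at]
            + locus
            + host_seq[insert_at + len(locus) :]
        )

    # --- coupled abundance series -----------------------------------------
    samples = [f"S{j + 1:02d}" for j in range(config.n_samples)]
    entities = host_ids + phage_ids + related_ids
    log_abund = pd.DataFrame(index=samples, columns=entities, dtype=float)
    for hid in host_ids:
        log_abund[hid] = rng.normal(0.0, 0.5, size=config.n_samples)
    for pid in phage_ids:
        noise = rng.normal(0.0, 0.3, size=config.n_samples)
        log_abund[pid] = config.coupling * log_abund[true_host_of[pid]] + noise
    for rid in related_ids:
        log_abund[rid] = rng.normal(0.0, 0.5, size=config.n_samples)
    coverage = config.depth_mean * 10.0**log_abund
    rel = coverage.div(coverage.sum(axis=1), axis=0)

    truth = SyntheticTruth(
        true_host_of=true_host_of,
        true_abundances=rel,
        coverage=coverage,
        true_growth_index={hid: config.growth_gradient for hid in host_ids},
        planted_spacers=planted_spacers,
        pmoc_genes=pmoc_genes,
        host_pmoc=host_pmoc,
    )
    return genomes, truth


# --- depth ----------------------------------------------------------------


@dataclass
class SimulatedDepth:
    """Per-base depth split by read-identity bin (before filtering)."""

    scaffold_id: str
    identities: tuple[float, ...]
    depth_by_bin: np.ndarray  # shape (n_bins, length)

    def filtered(self, min_identity: float) -> "profiles.DepthProfile":
        from . import profiles

        keep = [i for i, ident in enumerate(self.identities) if ident >= min_identity]
        depth = (
            self.depth_by_bin[keep].sum(axis=0)
            if keep
            else np.zeros(self.depth_by_bin.shape[1], dtype=np.int64)
        )
        return profiles.DepthProfile(
            self.scaffold_id, depth.astype(np.int64), identity_filter=min_identity
        )


def simulate_depth(
    genome: GenomeRecord,
    abundance: float,
    gradient: float,
    config: CommunityConfig,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDepth:
    """Poisson per-base depth with an origin-to-terminus gradient.

    Expected depth declines log-linearly along the genome with
    origin/terminus ratio ``gradient`` and genome-wide mean ``abundance``;
    each base's depth is apportioned among the configured read-identity
    bins. ``gradient`` = 1 gives a flat expectation.
    """
    if abundance < 0:
        raise ValueError(f"abundance must be >= 0, got {abundance}")
    if gradient < 1.0:
        raise ValueError(f"gradient must be >= 1, got {gradient}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    length = genome.length
    x = np.arange(length) / max(length - 1, 1)
    shape = gradient**-x
    shape = shape * (abundance / shape.mean())
    identities = tuple(ident for ident, _ in config.read_identity_mix)
    weights = np.array([w for _, w in config.read_identity_mix])
    depth = np.vstack(
        [rng.poisson(shape * w) for w in weights]
    )
    scaffold_id = genome.scaffold_ids()[0]
    return SimulatedDepth(scaffold_id, identities, depth)


# --- transcriptome ---------------------------------------------------------

STAGES = ("inactive", "early", "late")
LATE_BOOST = 25.0
INACTIVE_MAX_READS = 10


def simulate_transcriptome(
    phage: GenomeRecord, stage: str, total_reads: int, seed: int
) -> pd.DataFrame:
    """Multinomial per-gene read counts for one phage in one sample.

    Rates are proportional to gene length; in "late" stage pmoC and
    structural genes get a 25x per-base boost (the late-replication
    co-expression signal); "inactive" caps the library at a few background
    reads. Returns a (gene, start, length, reads) table.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    rng = np.random.default_rng(seed)
    genes = sorted(phage.genes, key=lambda g: g.start)
    if not genes:
        raise ValueError(f"phage {phage.genome_id} has no genes")
    rates = np.array([float(g.length) for g in genes])
    if stage == "late":
        structural = {p.lower() for p in STRUCTURAL_PRODUCTS}
        for i, g in enumerate(genes):
            tag = g.gene_id.rsplit("_", 1)[-1]
            if g.product.lower() in structural or tag.startswith("pmoC"):
                rates[i] *= LATE_BOOST
    n = total_reads if stage != "inactive" else min(total_reads, INACTIVE_MAX_READS)
    counts = (
        rng.multinomial(n, rates / rates.sum())
        if n > 0
        else np.zeros(len(genes), dtype=int)
    )
    return pd.DataFrame(
        {
            "gene": [g.gene_id for g in genes],
            "start": [g.start for g in genes],
            "length": [g.length for g in genes],
            "reads": counts,
        }
    )


# --- SNP tables -------------------------------------------------------------


def simulate_snp_table(
    n_sites: int,
    group_depths: tuple[int, int] = (200, 200),
    shifted_fraction: float = 0.0,
    effect: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Allele-count table for two sample groups with planted shifts.

    A ``shifted_fraction`` of sites change true alternate-allele frequency
    by ``effect`` between groups; the rest are null. Returns the table
    (scaffold, pos, ref, alt, alt_a, depth_a, alt_b, depth_b) and the
    boolean planted-shift mask.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError(f"effect must be in [0, 1], got {effect}")
    if not 0.0 <= shifted_fraction <= 1.0:
        raise ValueError(f"shifted_fraction must be in [0, 1], got {shifted_fraction}")
    if min(group_depths) <= 0:
        raise ValueError(f"group depths must be positive, got {group_depths}")
    rng = np.random.default_rng(seed)
    if n_sites == 0:
        empty = pd.DataFrame(
            columns=[
                "scaffold", "pos", "ref", "alt", "alt_a", "depth_a", "alt_b", "depth_b",
            ]
        )
        return empty, np.zeros(0, dtype=bool)
    base = rng.uniform(0.05, 0.45, size=n_sites)
    shifted = rng.random(n_sites) < shifted_fraction
    freq_b = np.where(shifted, np.clip(base + effect, 0.0, 0.95), base)
    depth_a, depth_b = group_depths
    alt_a = rng.binomial(depth_a, base)
    alt_b = rng.binomial(depth_b, freq_b)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_sites)
    alt = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in ref]
    )
    table = pd.DataFrame(
        {
            "scaffold": "scaf_1",
            "pos": np.arange(n_sites) * 37 + 11,
            "ref": ref,
            "alt": alt,
            "alt_a": alt_a,
            "depth_a": depth_a,
            "alt_b": alt_b,
            "depth_b": depth_b,
        }
    )
    return table, shifted


# --- similarity edge fabrication -------------------------------------------


def true_families(
    genomes: list[GenomeRecord], truth: SyntheticTruth, phage_only: bool = True
) -> tuple[dict[str, str], dict[str, str]]:
    """Ground-truth family label and genome of every protein.

    Named products (structural, ribosomal, pMMO subunits) define shared
    families; phage pmoC genes (annotated as hypothetical) are resolved
    through the planted truth; remaining hypotheticals are singletons.
    """
    family_of: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    pmoc_gene_ids = {
        gid for gids in truth.pmoc_genes.values() for gid in gids
    }
    for genome in genomes:
        if phage_only and genome.kind != "phage":
            continue
        for gene in genome.genes:
            genome_of[gene.gene_id] = genome.genome_id
            if gene.gene_id in pmoc_gene_ids:
                family_of[gene.gene_id] = "true:pmoC"
            elif gene.product != "hypothetical protein":
                family_of[gene.gene_id] = f"true:{gene.product}"
            else:
                family_of[gene.gene_id] = f"single:{gene.gene_id}"
    return family_of, genome_of


def fabricate_protein_edges(
    family_of: dict[str, str], seed: int = 0
) -> list["families.SimilarityEdge"]:
    """Protein-level similarity edges consistent with the true families.

    Each multi-member family is split into two sequence subgroups; strong
    within-subgroup edges (the subfamily signal) are emitted, while the
    between-subgroup relationship is left to profile-level edges — the
    two-tier structure the clustering is designed to recover.
    """
    from .families import SimilarityEdge

    rng = np.random.default_rng(seed)
    members: dict[str, list[str]] = {}
    for protein, fam in family_of.items():
        members.setdefault(fam, []).append(protein)
    edges: list[SimilarityEdge] = []
    for fam in sorted(members):
        group = sorted(members[fam])
        if len(group) < 2:
            continue
        half = (len(group) + 1) // 2
        for sub in (group[:half], group[half:]):
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    edges.append(
                        SimilarityEdge(
                            a=sub[i],
                            b=sub[j],
                            evalue=float(10.0 ** -rng.uniform(10, 40)),
                            cover=float(rng.uniform(0.8, 1.0)),
                        )
                    )
    return edges


def fabricate_profile_edges(
    subfamily_of: dict[str, str], family_of: dict[str, str], seed: int = 0
) -> list["families.SimilarityEdge"]:
    """Subfamily-level (profile comparison) edges from the true families.

    Subfamilies whose members belong to the same true family are linked
    with high probability/coverage scores.
    """
    from .families import SimilarityEdge

    rng = np.random.default_rng(seed)
    fam_of_sub: dict[str, str] = {}
    for protein, sub in subfamily_of.items():
        fam_of_sub[sub] = family_of[protein]
    subs = sorted(fam_of_sub)
    edges: list[SimilarityEdge] = []
    for i in range(len(subs)):
        for j in range(i + 1, len(subs)):
            if fam_of_sub[subs[i]] == fam_of_sub[subs[j]]:
                edges.append(
                    SimilarityEdge(
                        a=subs[i],
                        b=subs[j],
                        evalue=0.0,
                        cover=float(rng.uniform(0.7, 1.0)),
                        probability=float(rng.uniform(0.96, 1.0)),
                    )
                )
    return edges
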