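# Methods

This note documents the models, rules and numerical choices behind
`pmocphage`, and what the synthetic-data validation does and does not
demonstrate.

## Coverage, breadth and occurrence rules

A depth profile is the per-base read depth of one scaffold accumulated
under a stated minimum read identity; depth from reads below the cutoff is
discarded before any statistic is computed. Coverage is mean depth
(total mapped bases / length); the two common phrasings — "bases mapped
divided by length" and "total length of mapped reads divided by length" —
are the same quantity for fully mapped reads and are treated as such.
Breadth is the fraction of positions with depth ≥ 1, the minimal reading
of "covered".

Occurrence rules use inclusive thresholds, as printed:

| entity | read identity | rule |
|---|---|---|
| phage  | ≥ 95% | breadth ≥ 0.75 |
| host   | ≥ 98% | breadth ≥ 0.75 on **every** scaffold |

Host genome coverage is the **unweighted** mean of per-scaffold coverages
("average sequencing coverage of all the scaffolds"); whether a
length-weighted mean was intended is not stated, so the literal unweighted
mean is used.

Community composition uses rpS3 as a single-copy marker. Marker proteins
are dereplicated cd-hit-style: 100% identity with mutual overlap ≥ 0.8 of
both lengths (implemented as a substring containment check — the only case
that arises at 100% identity); the representative is the longest member.
A marker's coverage is reported only when its breadth is ≥ 0.5, and
relative abundance is its coverage divided by the summed coverage of all
reported markers, so reported abundances sum to 1 per sample.

## Growth index

The replication signal of a growing bacterial population is the
origin-to-terminus read-depth gradient. The estimator: non-overlapping
5,000-bp window means, sorted (the origin's position is unknown), top and
bottom 5% of windows trimmed, and log₂ coverage regressed by OLS against
the windows' center positions expressed as genome fractions; the index is
2^slope, so a flat profile gives ≈ 1 and a 2:1 gradient gives ≈ 2. The
regressor is the window-center fraction, not the rank fraction in [0, 1]:
window centers span only (n−1)·w/L of the genome, and using rank fractions
would attenuate the slope by exactly that factor (≈ 0.8 at the simulated
sizes), biasing the index low. A pseudocount of 0.5 guards log₂ of empty
windows, which makes the index exactly scale-invariant only in the limit
of no empty windows — irrelevant above the ≥ 5× mean-coverage eligibility
floor, below which no index is reported. Validation is by parameter
recovery: a planted 2.0 gradient at 30× is recovered as ≈ 1.97–1.99.

## PmoC screen

Homology search is pairwise global alignment (Needleman–Wunsch via
Biopython's PairwiseAligner) with BLOSUM62, gap open 11 / extend 1, end
gaps scored. Percent identity is identical columns over aligned columns,
excluding terminal-gap overhangs but counting internal gaps as
mismatches. End gaps are deliberately *scored* (not free): with free end
gaps a random protein can align a tiny terminal block at 100% identity,
defeating any identity threshold. Fragments still localize to their
sub-region of the reference because match score dominates placement, and
the terminal-gap exclusion keeps their identity meaningful. Hits are
reported at ≥ 50% identity — a reporting default, chosen well below the
80–100% identities real hits show, so the observed ">86%" behaviour is a
property of hits rather than a filter.

The packaged references (PmoC, PmoA, PmoB) are deterministic synthetic
stand-ins, not database sequences; the canonical PmoC is constructed so the
copper-binding triad lands at Asp156/His160/His173, which defines the site
numbering used by the residue check. A site check is True iff the query
column aligned to that reference position holds the required residue;
sites falling in deletions are absent (False), not errors.

Partial-gene classification uses coverage of the reference thirds by
aligned columns: N and C thirds covered but the middle third < 50% →
core-deleted; total coverage ≥ 70% → full; otherwise N-only or C-only by
which terminus is covered. Two hits on one scaffold whose reference spans
overlap by ≤ 10 residues and whose genes lie within 5 kb merge into one
fragmented hit; the fragments are concatenated in reference order and
realigned, mirroring the practice of concatenating PmoC fragments before
comparison.

Phage scaffold classification is keyword-based (capsid, phage, virus,
prophage, terminase, prohead, tape measure, tail, head, portal, DNA
packaging) with ribosomal-protein annotations as host markers; a scaffold
is a phage iff it has ≥ 1 phage keyword and zero host markers, and the
score is (phage hits − host hits, floored at 0) / genes.

## Host linkage

Host assignment: the phage PmoC is aligned to every coexisting candidate
host PmoC; the best host is assigned iff identity > 90% (aligned-columns
identity, consistent with the screen); candidates within 0.5 identity
points of the best are reported as ambiguous. Co-occurrence is the Pearson
correlation of log₁₀(coverage + pseudocount) over samples where at least
one partner is detected, with pseudocount 0.1× the smallest nonzero
coverage; the correlation statistic is a package choice — the underlying
claim is qualitative co-occurrence. Fewer than three usable samples yield
an undefined correlation (the co-detection count is still reported).

CRISPR arrays are found by a simplified exact-repeat scanner rather than a
minced port: seed 21-mers (the minimum repeat length) recurring with
spacer-sized gaps nucleate chains; chains are committed longest-first, and
the repeat unit is extended maximally while all occurrences agree (21–48
bp). Arrays need ≥ 2 exact repeats, spacers of 17–72 bp, distinct adjacent
spacers, and no spacer may contain a 21-mer of the repeat (which would
mean the chain skipped a repeat occurrence). Longest-chain-first
commitment matters: a "shadow" of the repeat shifted by a shared flanking
base can otherwise fragment the true array. Spacer matching is an
exhaustive ungapped sliding-window comparison on both strands with a
configurable mismatch budget (default 0), reported only at ≥ 30 bp — the
E-value machinery of a BLAST search is replaced by this exact criterion.

## Protein families

Two tiers, as in profile-based family analysis: (1) a greedy set-cover
over the protein similarity graph (edges kept at e-value ≤ 0.001 and
coverage ≥ 0.5): repeatedly pick the unassigned protein covering the most
unassigned neighbours (ties by id), it plus its unassigned neighbours
form a subfamily; (2) Markov clustering of the subfamily graph whose edges
keep probability ≥ 0.95 and coverage ≥ 0.5 with weight = probability ×
coverage, inflation 2.0. MCL details not fixed by the source procedure are
documented defaults: self-loop weight = each node's maximum incident edge
weight (1 for isolated nodes), entries < 1e-8 pruned per iteration,
convergence when the matrix changes by < 1e-6 (cap 200 iterations,
non-convergence flagged), clusters read from attractor rows with
overlapping clusters merged. These defaults are validated by exact
agreement with an independently coded plain-Python MCL on random graphs.

All-vs-all protein search and HMM–HMM profile comparison are input
contracts (edge lists), not computations; the synthetic module fabricates
edge lists consistent with its planted families, splitting each true
family into two subgroups so that the protein tier only sees
within-subgroup edges and the profile tier must reunite them — the
structure the two-tier design exists to recover.

The presence/absence matrix keeps families found in ≥ 5 genomes; genome
clustering is complete linkage on Jaccard distances (a genome with no
retained families is at distance 1 from everything, by convention), with
deterministic genome-id ordering; group-specific families are those
present in every group member and absent from every non-member.

## Expression and activity

`E_k = N_k / (L_k · S_ij)` with S_ij the total reads from sample j mapped
to any gene of phage i; hence Σ_k E_k·L_k = 1 whenever S_ij > 0, which is
asserted as an invariant. S_ij = 0 yields a flagged no-signal profile
rather than a division error. Ranking is by E_k descending with ties
broken by genomic position (upstream first). Fragmented pmoC pieces are
ranked as separate genes — no merging before ranking, so differential
expression of the N and C fragments stays visible.

Activity is a configurable policy, not a claim from the source analyses
(which describe activity qualitatively): a phage is active in a sample
iff it receives ≥ 1% of the sample's phage-assigned RNA reads **and**
≥ 50 reads. Both knobs are exposed in the pipeline configuration.

Codon–tRNA correspondence: with m distinct codons decoded by the genome's
tRNAs (reverse-complement anticodon, exact pairing), the score is the
fraction of the genome's m most-used codons (stop codons excluded) that
are decoded; no tRNAs → score absent. A random anticodon set scores
≈ m/61 by chance, which the tests verify by permutation.

## Variant dynamics

Per site, the pooled two-proportion z-test:
z = (f_a − f_b) / √(p̂(1−p̂)(1/n_a + 1/n_b)) with p̂ the pooled alternate
frequency; two-sided p from the standard normal; degenerate pooled
frequencies (0 or 1) give z = 0, p = 1. "z-test" and "q" are not further
specified in the source; the pooled test and Benjamini–Hochberg are the
standard readings, and reads are pooled across each group's samples by
default (per-sample averaging can be done upstream). BH q-values follow
the step-up formula and are cross-checked against statsmodels. Calibration
is verified by simulation: type-I error within binomial noise of α under
the null, and power > 0.9 for a 0.5 frequency shift at 200× depth per
group at q < 0.05.

## Synthetic communities: what they emulate

The generator plants, from one seed, everything the analyses assume:
methanotroph genomes with a pmoCAB operon, optional stand-alone pmoC,
ribosomal markers and a CRISPR array whose spacers sample their phages'
genomes; pmoC-phages whose pmoC descends from their true host with
substitution rates of 0.08 in the terminal thirds and 0.01 in the core by
default (expected phage–host identity ≈ 94%, mirroring the > 90%
similarity of phage PmoC to coexisting hosts, while hosts diverge ~15%/4%
from the shared ancestral reference so wrong hosts sit near 75%);
optional fragmentation of the phage pmoC into two adjacent ORFs; related
phages sharing the structural-gene repertoire but lacking pmoC (the
comparison group for the presence/absence analysis); log-coupled
host–phage abundance series (phage log-abundance = coupling × host
log-abundance + noise — the simplest model consistent with co-occurrence;
no quantitative host–phage dynamic model is claimed by the source);
Poisson per-base depth with a log-linear origin-to-terminus gradient and
read-identity bins (depth is simulated directly, Lander–Waterman style,
rather than via read placement — alignment is out of scope); multinomial
transcriptomes with pmoC and structural genes boosted 25× per base in
late infection and a ≤ 10-read background in the inactive stage; and SNP
tables with a planted fraction of frequency-shifted sites.

Genome sizes default to 30–60 kb (15–25 kb in repeated-community test
settings) — scaled down from the real 159–527 kb genomes; every analysis
is per-base or per-gene and size-agnostic, so this changes runtime, not
behaviour. Sample count defaults to 12. Substitutions are uniform random
(no indels except explicit fragmentation), terminal thirds are defined by
integer division with the remainder assigned to the core, and the
catalytic triad is never mutated.

For tests asserting *exact* host recovery, the terminal divergence is set
to 0.05 ("separable setting"): at the default 0.08 the binomial tail puts
roughly one phage in a hundred below the 90% assignment threshold, which
violates the separability those tests presuppose rather than any failure
of the method.

What passing these tests does **not** show about real data: no read-level
error or mapping ambiguity (identity is an annotation on depth mass, not
an alignment outcome), no phylogenetic structure in sequence divergence,
no assembly artifacts or strain mixtures, fabricated (not computed)
similarity edge lists, and abundance dynamics far simpler than real
communities. The validation demonstrates that each analysis recovers the
structure it targets when that structure is present as described — not
that the structure is present in any particular environmental dataset.

## Pipeline and reproducibility

Stages (simulate → screen → profile → link-hosts → families → express →
snps) communicate through files in a run directory; a missing input names
its producing stage. Per-base depth is regenerated deterministically
inside the profile stage (seeded per genome × sample via CRC-derived
streams) instead of being written to disk. All thresholds live in a
single declarative configuration whose defaults are the published values;
identical configuration + seed reproduces identical output bytes, which
the tests assert file-by-file. Coordinates are 0-based half-open
internally; FASTA/TSV writers have matching readers and round-trip
identity is tested.
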