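"""Host prediction, co-occurrence, CRISPR arrays and spacer matching."""

import numpy as np
import pytest

from pmocphage.linkage import (
    cooccurrence,
    find_crispr_arrays,
    predict_host_by_pmoc,
    revcomp,
    spacer_targets,
)
from pmocphage.profiles import AbundanceSeries
from pmocphage.references import AMINO_ACIDS, canonical_pmoc
from pmocphage.screen import PmoCHit


def hit(query, phage_id="phageX"):
    return PmoCHit(
        gene_id="g",
        genome_id=phage_id,
        best_reference_id="PmoC_ref",
        percent_identity=100.0,
        reference_span=(0, len(query)),
        query=query,
        gene_start=0,
        gene_end=3 * len(query),
    )


def mutate(seq, k, rng):
    out = list(seq)
    for p in rng.choice(len(seq), size=k, replace=False):
        out[p] = rng.choice([a for a in AMINO_ACIDS if a != out[p]])
    return "".join(out)


class TestHostPrediction:
    def test_clear_winner_above_threshold(self, rng):
        ref = canonical_pmoc()
        pred = predict_host_by_pmoc(
            hit(mutate(ref, 10, rng)),  # ~96% to ref
            {"hostA": ref, "hostB": mutate(ref, 78, rng)},  # ~70%
        )
        assert pred.host_id == "hostA"
        assert pred.pmoc_identity > 90
        assert not pred.ambiguous_with

    def test_no_candidate_above_90(self, rng):
        ref = canonical_pmoc()
        pred = predict_host_by_pmoc(
            hit(mutate(ref, 40, rng)),  # ~85%
            {"hostA": ref},
        )
        assert pred.host_id is None

    def test_tie_reported_ambiguous(self):
        ref = canonical_pmoc()
        pred = predict_host_by_pmoc(hit(ref), {"hostA": ref, "hostB": ref})
        assert pred.host_id == "hostA"  # deterministic order
        assert pred.ambiguous_with == ["hostB"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            predict_host_by_pmoc(hit(canonical_pmoc()), {})

    def test_truth_recovery_on_community(self, community):
        from pmocphage.screen import screen_genome
        from pmocphage.synthetic import PMOC_PRODUCT

        _, genomes, truth = community
        host_pmoc = {
            g.genome_id: next(
                x.protein for x in g.genes if x.product == PMOC_PRODUCT
            )
            for g in genomes
            if g.kind == "host"
        }
        for phage_id, true_host in truth.true_host_of.items():
            genome = next(g for g in genomes if g.genome_id == phage_id)
            best = max(
                screen_genome(genome.genes), key=lambda h: h.percent_identity
            )
            pred = predict_host_by_pmoc(best, host_pmoc)
            assert pred.host_id == true_host


class TestCooccurrence:
    def series(self, cov, detected=None):
        cov = np.asarray(cov, dtype=float)
        detected = (
            cov > 0 if detected is None else np.asarray(detected, dtype=bool)
        )
        return AbundanceSeries(
            "e", [f"S{i}" for i in range(cov.size)], cov, detected
        )

    def test_identical_series_correlate_perfectly(self):
        x = self.series([1.0, 5.0, 20.0, 3.0, 8.0])
        r, co = cooccurrence(x, x)
        assert r == pytest.approx(1.0)
        assert co == 5

    def test_no_overlap_in_detection(self):
        host = self.series([2.0, 4.0, 8.0, 1.0, 2.0])
        phage = self.series(np.zeros(5))
        r, co = cooccurrence(phage, host)
        assert co == 0

    def test_matches_closed_form_pearson(self):
        cov_x = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 5.0])
        cov_y = np.array([2.0, 3.0, 9.0, 14.0, 30.0, 6.0])
        x, y = self.series(cov_x), self.series(cov_y)
        r, _ = cooccurrence(x, y)
        pseudo = 0.1 * 1.0
        lx, ly = np.log10(cov_x + pseudo), np.log10(cov_y + pseudo)
        num = ((lx - lx.mean()) * (ly - ly.mean())).sum()
        den = np.sqrt(((lx - lx.mean()) ** 2).sum() * ((ly - ly.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-9)

    def test_fewer_than_three_samples_undefined(self):
        x = self.series([1.0, 2.0, 0.0, 0.0], [True, True, False, False])
        r, co = cooccurrence(x, x)
        assert np.isnan(r)
        assert co == 2


class TestCrisprArrays:
    def random_seq(self, rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_constructed_array_recovered(self, rng):
        repeat = self.random_seq(rng, 28)
        spacers = [self.random_seq(rng, 33) for _ in range(3)]
        seq = (
            self.random_seq(rng, 400)
            + repeat
            + repeat.join(spacers)
            + repeat
            + self.random_seq(rng, 400)
        )
        arrays = find_crispr_arrays(seq, "test")
        assert len(arrays) == 1
        assert arrays[0].repeat == repeat
        assert arrays[0].spacers == spacers

    def test_short_spacers_rejected(self, rng):
        repeat = self.random_seq(rng, 28)
        spacers = [self.random_seq(rng, 16) for _ in range(3)]
        seq = (
            self.random_seq(rng, 300)
            + repeat
            + repeat.join(spacers)
            + repeat
            + self.random_seq(rng, 300)
        )
        assert find_crispr_arrays(seq, "test") == []

    def test_random_sequence_has_no_arrays(self, rng):
        assert find_crispr_arrays(self.random_seq(rng, 20_000), "r") == []

    def test_planted_community_arrays(self, community):
        _, genomes, truth = community
        hosts_with_phages = {h for h, _, _ in truth.planted_spacers}
        for host_id in hosts_with_phages:
            genome = next(g for g in genomes if g.genome_id == host_id)
            arrays = find_crispr_arrays(genome.sequences[host_id], host_id)
            assert arrays, host_id
            planted = [s for h, s, _ in truth.planted_spacers if h == host_id]
            extracted = [s for a in arrays for s in a.spacers]
            for spacer in planted:
                assert spacer in extracted


def brute_force_spacer_scan(spacer, genome, max_mm):
    out = []
    for probe, strand in ((spacer, "+"), (revcomp(spacer), "-")):
        for i in range(len(genome) - len(probe) + 1):
            mm = sum(a != b for a, b in zip(probe, genome[i : i + len(probe)]))
            if mm <= max_mm:
                out.append((i, strand, mm))
    return out


class TestSpacerTargets:
    def test_exact_32bp_match(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        spacer = genome[500:532]
        matches = spacer_targets({"s1": spacer}, {"p1": genome})
        assert [(m.position, m.match_length) for m in matches] == [(500, 32)]

    def test_29bp_exact_is_below_reporting_length(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        assert spacer_targets({"s1": genome[100:129]}, {"p1": genome}) == []

    def test_reverse_complement_hit_reports_strand(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        spacer = revcomp(genome[700:732])
        (m,) = spacer_targets({"s1": spacer}, {"p1": genome})
        assert m.strand == "-" and m.position == 700

    def test_mismatch_tolerance_matches_brute_force(self, rng):
        genome = "".join(rng.choice(list("ACGT"), size=3000))
        spacer = list(genome[1000:1032])
        spacer[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[spacer[10]]
        spacer = "".join(spacer)
        assert spacer_targets({"s": spacer}, {"p": genome}, max_mismatches=0) == []
        matches = spacer_targets({"s": spacer}, {"p": genome}, max_mismatches=1)
        expected = brute_force_spacer_scan(spacer, genome, 1)
        assert sorted((m.position, m.strand, m.mismatches) for m in matches) == sorted(
            expected
        )

    def test_exhaustive_equivalence_on_community_genome(self, community, rng):
        _, genomes, _ = community
        genome = next(g for g in genomes if g.kind == "phage")
        seq = genome.sequences[genome.genome_id][:40_000]
        spacer = seq[12_345 : 12_345 + 35]
        matches = spacer_targets({"s": spacer}, {"p": seq}, max_mismatches=1)
        expected = brute_force_spacer_scan(spacer, seq, 1)
        assert sorted((m.position, m.strand, m.mismatches) for m in matches) == sorted(
            expected
        )
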