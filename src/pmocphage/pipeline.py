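"""Stage-wise pipeline orchestration over a synthetic community.

Stages run in dependency order: simulate -> screen -> profile ->
link-hosts -> families -> express -> snps. Each stage reads the files
written by its producers and writes its own outputs under the run
directory, so any stage can be re-run from disk; a missing input names
the stage that produces it. Identical config + seed reproduces identical
output bytes.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import PipelineConfig
from .expression import activity_call, normalize_expression, top_expressed
from .families import (
    build_subfamilies,
    cluster_genomes,
    dendrogram_newick,
    family_graph,
    mcl_cluster,
    presence_matrix,
    specific_families,
)
from .linkage import (
    cooccurrence,
    find_crispr_arrays,
    predict_host_by_pmoc,
    spacer_targets,
)
from .profiles import (
    AbundanceSeries,
    detect_host,
    detect_phage,
    growth_index,
    rps3_relative_abundance,
    scaffold_coverage,
)
from .records import GenomeRecord
from .references import pmoab_references
from .screen import classify_phage_scaffold, confirm_no_pmoab, screen_genome
from .synthetic import (
    PMOC_PRODUCT,
    RIBOSOMAL_PRODUCTS,
    SyntheticTruth,
    fabricate_profile_edges,
    fabricate_protein_edges,
    simulate_community,
    simulate_depth,
    simulate_snp_table,
    simulate_transcriptome,
    true_families,
)
from .variants import frequency_change_test

STAGES = ("simulate", "screen", "profile", "link-hosts", "families",
          "express", "snps")


class Pipeline:
    """One pipeline run rooted at ``outdir``."""

    def __init__(self, config: PipelineConfig, outdir: str | Path):
        config.validate()
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # --- helpers ----------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, name: str, producer: str) -> Path:
        path = self._path(name)
        if not path.exists():
            raise FileNotFoundError(
                f"missing input {path.name}; run the '{producer}' stage first"
            )
        return path

    def _load_genomes(self) -> list[GenomeRecord]:
        self._require("genomes.fasta", "simulate")
        self._require("genes.tsv", "simulate")
        sequences = pio.read_fasta(self._path("genomes.fasta"))
        genes_by_genome = pio.read_gene_table(self._path("genes.tsv"))
        genomes = []
        for gid in sorted(sequences):
            genes = genes_by_genome.get(gid, [])
            is_host = any(
                g.product in RIBOSOMAL_PRODUCTS for g in genes
            )
            genomes.append(
                GenomeRecord(
                    genome_id=gid,
                    sequences={gid: sequences[gid]},
                    genes=genes,
                    kind="host" if is_host else "phage",
                )
            )
        return genomes

    def _coverage(self) -> pd.DataFrame:
        self._require("coverage.csv", "simulate")
        return pd.read_csv(self._path("coverage.csv"), index_col=0)

    def _depth_rng(self, genome_id: str, sample_idx: int) -> np.random.Generator:
        key = zlib.crc32(f"{genome_id}:{sample_idx}".encode()) % (2**31)
        return np.random.default_rng([self.config.seed % (2**31), key])

    def _simulated_depth(self, genome: GenomeRecord, sample_idx: int,
                         coverage: float):
        gradient = (
            self.config.community.growth_gradient
            if genome.kind == "host"
            else 1.0
        )
        return simulate_depth(
            genome,
            coverage,
            gradient,
            self.config.community,
            rng=self._depth_rng(genome.genome_id, sample_idx),
        )

    # --- stages -----------------------------------------------------------

    def simulate(self) -> tuple[list[GenomeRecord], SyntheticTruth]:
        genomes, truth = simulate_community(self.config.community)
        pio.write_genomes_fasta(genomes, self._path("genomes.fasta"))
        pio.write_gene_table(genomes, self._path("genes.tsv"))
        truth.coverage.round(8).to_csv(self._path("coverage.csv"))
        truth.true_abundances.round(10).to_csv(self._path("abundance_truth.csv"))
        pd.DataFrame(
            sorted(truth.true_host_of.items()), columns=["phage", "host"]
        ).to_csv(self._path("true_hosts.tsv"), sep="\t", index=False)
        pd.DataFrame(
            truth.planted_spacers, columns=["host", "spacer", "phage"]
        ).to_csv(self._path("true_spacers.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [(g, gid) for g, gids in sorted(truth.pmoc_genes.items())
             for gid in gids],
            columns=["genome", "gene_id"],
        ).to_csv(self._path("pmoc_genes.tsv"), sep="\t", index=False)
        return genomes, truth

    def screen(self) -> pd.DataFrame:
        genomes = self._load_genomes()
        rows = []
        for genome in genomes:
            is_phage, score = classify_phage_scaffold(genome.genes)
            hits = screen_genome(
                genome.genes, report_threshold=self.config.pmoc_report_threshold
            )
            no_pmoab = confirm_no_pmoab(
                genome.genes,
                pmoab_references(),
                self.config.pmoc_report_threshold,
            )
            best = max(hits, key=lambda h: h.percent_identity, default=None)
            rows.append(
                {
                    "genome": genome.genome_id,
                    "is_phage": is_phage,
                    "phage_score": round(score, 6),
                    "n_pmoc_hits": len(hits),
                    "pmoc_gene": best.gene_id if best else "",
                    "pmoc_identity": round(best.percent_identity, 4) if best else "",
                    "pmoc_fragmented": best.fragmented if best else "",
                    "pmoc_partial": best.partial if best else "",
                    "triad_ok": all(best.residues_ok.values()) if best else "",
                    "pmoc_query": best.query if best else "",
                    "no_pmoab_nearby": no_pmoab,
                    "is_pmoc_phage": bool(is_phage and hits and no_pmoab),
                }
            )
        table = pd.DataFrame(rows).sort_values("genome").reset_index(drop=True)
        table.to_csv(self._path("screen.tsv"), sep="\t", index=False)
        return table

    def profile(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        genomes = self._load_genomes()
        coverage = self._coverage()
        samples = list(coverage.index)
        detection_rows, growth_rows = [], []
        marker_abundances: dict[str, dict[str, float]] = {}
        for si, sample in enumerate(samples):
            marker_stats = {}
            for genome in genomes:
                cov = float(coverage.loc[sample, genome.genome_id])
                sim = self._simulated_depth(genome, si, cov)
                if genome.kind == "phage":
                    profile = sim.filtered(self.config.phage_min_identity)
                    call = detect_phage(
                        scaffold_coverage(profile),
                        self.config.phage_min_identity,
                        genome.genome_id,
                        self.config.min_breadth,
                    )
                else:
                    profile = sim.filtered(self.config.host_min_identity)
                    call = detect_host(
                        [profile], genome.genome_id, self.config.min_breadth
                    )
                    gi = growth_index(
                        profile,
                        min_coverage=self.config.growth_min_coverage,
                        genome_id=genome.genome_id,
                    )
                    growth_rows.append(
                        {
                            "sample": sample,
                            "genome": genome.genome_id,
                            "eligible": gi.eligible,
                            "mean_coverage": round(gi.mean_coverage, 4),
                            "growth_index": round(gi.index, 4) if gi.eligible else "",
                        }
                    )
                    for gene in genome.genes:
                        if gene.product == RIBOSOMAL_PRODUCTS[0]:  # rpS3
                            window = profile.depth[gene.start : gene.end]
                            marker_stats[genome.genome_id] = scaffold_coverage(
                                type(profile)(gene.gene_id, window,
                                              profile.identity_filter)
                            )
                detection_rows.append(
                    {
                        "sample": sample,
                        "genome": genome.genome_id,
                        "kind": genome.kind,
                        "detected": call.detected,
                        "rule": call.rule,
                        "coverage": round(call.genome_coverage, 4),
                    }
                )
            marker_abundances[sample] = rps3_relative_abundance(
                marker_stats, self.config.marker_min_breadth
            )
        detection = pd.DataFrame(detection_rows)
        growth = pd.DataFrame(growth_rows)
        abundance = pd.DataFrame(marker_abundances).T.sort_index()
        abundance.index.name = "sample"
        detection.to_csv(self._path("detection.tsv"), sep="\t", index=False)
        growth.to_csv(self._path("growth.tsv"), sep="\t", index=False)
        abundance.round(8).to_csv(self._path("marker_abundance.csv"))
        return detection, growth, abundance

    def link_hosts(self) -> pd.DataFrame:
        genomes = {g.genome_id: g for g in self._load_genomes()}
        screen_table = pd.read_csv(
            self._require("screen.tsv", "screen"), sep="\t", keep_default_na=False
        )
        detection = pd.read_csv(
            self._require("detection.tsv", "profile"), sep="\t"
        )
        coverage = self._coverage()
        samples = list(coverage.index)

        host_pmoc: dict[str, str] = {}
        for genome in genomes.values():
            if genome.kind == "host":
                for gene in genome.genes:
                    if gene.product == PMOC_PRODUCT:
                        host_pmoc[genome.genome_id] = gene.protein
                        break

        def series(entity: str) -> AbundanceSeries:
            sub = detection[detection["genome"] == entity].set_index("sample")
            return AbundanceSeries(
                entity,
                samples,
                coverage[entity].to_numpy(),
                sub.loc[samples, "detected"].to_numpy(),
            )

        # CRISPR sweep over all host scaffolds once
        spacers: dict[str, str] = {}
        for genome in genomes.values():
            if genome.kind != "host":
                continue
            for scaffold_id, seq in genome.sequences.items():
                for ai, array in enumerate(
                    find_crispr_arrays(seq, scaffold_id,
                                       self.config.crispr_min_spacer)
                ):
                    for k, spacer in enumerate(array.spacers):
                        spacers[f"{scaffold_id}_a{ai}_s{k}"] = spacer
        phage_seqs = {
            gid: g.sequences[gid]
            for gid, g in genomes.items()
            if g.kind == "phage"
        }
        matches = (
            spacer_targets(spacers, phage_seqs, min_match=self.config.spacer_min_match)
            if spacers
            else []
        )
        pd.DataFrame(
            [
                {
                    "spacer": m.spacer_id,
                    "phage": m.phage_id,
                    "length": m.match_length,
                    "mismatches": m.mismatches,
                    "strand": m.strand,
                    "position": m.position,
                }
                for m in matches
            ],
            columns=["spacer", "phage", "length", "mismatches", "strand", "position"],
        ).to_csv(self._path("spacer_matches.tsv"), sep="\t", index=False)
        crispr_supported = {
            m.phage_id: m.spacer_id.rsplit("_a", 1)[0] for m in matches
        }

        from .screen import PmoCHit

        rows = []
        for row in screen_table.itertuples(index=False):
            if not row.is_pmoc_phage:
                continue
            hit = PmoCHit(
                gene_id=row.pmoc_gene,
                genome_id=row.genome,
                best_reference_id="PmoC_ref",
                percent_identity=float(row.pmoc_identity),
                reference_span=(0, 0),
                query=row.pmoc_query,
                gene_start=0,
                gene_end=0,
            )
            pred = predict_host_by_pmoc(
                hit, host_pmoc, self.config.host_assign_min_identity
            )
            if pred.host_id is not None:
                r, co = cooccurrence(series(row.genome), series(pred.host_id))
                pred.cooccurrence_r = r
                pred.co_detected_samples = co
                pred.crispr_support = (
                    crispr_supported.get(row.genome) == pred.host_id
                )
            rows.append(
                {
                    "phage": row.genome,
                    "host": pred.host_id or "",
                    "pmoc_identity": round(pred.pmoc_identity, 4),
                    "runner_up_identity": round(pred.runner_up_identity, 4),
                    "ambiguous_with": ";".join(pred.ambiguous_with),
                    "cooccurrence_r": (
                        round(pred.cooccurrence_r, 6)
                        if pred.cooccurrence_r is not None
                        and not np.isnan(pred.cooccurrence_r)
                        else ""
                    ),
                    "co_detected_samples": pred.co_detected_samples,
                    "crispr_support": pred.crispr_support,
                }
            )
        predictions = pd.DataFrame(rows).sort_values("phage").reset_index(drop=True)
        predictions.to_csv(self._path("host_predictions.tsv"), sep="\t", index=False)
        return predictions

    def families(self) -> tuple[pd.DataFrame, list[str]]:
        genomes = self._load_genomes()
        pmoc_gene_table = pd.read_csv(
            self._require("pmoc_genes.tsv", "simulate"), sep="\t"
        )
        truth_stub = SyntheticTruth(
            true_host_of={},
            true_abundances=pd.DataFrame(),
            coverage=pd.DataFrame(),
            true_growth_index={},
            planted_spacers=[],
            pmoc_genes={
                g: group["gene_id"].tolist()
                for g, group in pmoc_gene_table.groupby("genome")
            },
        )
        family_of_true, genome_of = true_families(genomes, truth_stub)
        proteins = sorted(family_of_true)
        protein_edges = fabricate_protein_edges(family_of_true, self.config.seed)
        sub_of = build_subfamilies(proteins, protein_edges)
        profile_edges = fabricate_profile_edges(
            sub_of, family_of_true, self.config.seed
        )
        graph = family_graph(profile_edges, sorted(set(sub_of.values())))
        clusters, _ = mcl_cluster(graph, self.config.mcl_inflation)
        family_of = {}
        for cluster in clusters:
            fam = "fam_" + min(cluster)
            for sub in cluster:
                family_of[sub] = fam
        protein_family = {p: family_of[s] for p, s in sub_of.items()}
        pd.DataFrame(
            sorted(protein_family.items()), columns=["protein", "family"]
        ).to_csv(self._path("families.tsv"), sep="\t", index=False)

        matrix = presence_matrix(
            protein_family, genome_of, self.config.family_min_genomes
        )
        matrix.to_csv(self._path("presence.csv"))
        if len(matrix) >= 2:
            root = cluster_genomes(matrix)
            newick = dendrogram_newick(root, sorted(matrix.index))
            self._path("phage_clusters.nwk").write_text(newick + "\n")
        pmoc_group = set(truth_stub.pmoc_genes) & set(matrix.index)
        specific = (
            specific_families(matrix, pmoc_group) if pmoc_group else []
        )
        self._path("pmoc_specific_families.txt").write_text(
            "\n".join(specific) + ("\n" if specific else "")
        )
        return matrix, specific

    def express(self) -> pd.DataFrame:
        genomes = self._load_genomes()
        screen_table = pd.read_csv(
            self._require("screen.tsv", "screen"), sep="\t", keep_default_na=False
        )
        pmoc_phages = set(screen_table.loc[screen_table["is_pmoc_phage"], "genome"])
        phages = [g for g in genomes if g.kind == "phage"]
        totals: dict[str, int] = {}
        rows = []
        per_gene_frames = []
        for genome in sorted(phages, key=lambda g: g.genome_id):
            stage = "late" if genome.genome_id in pmoc_phages else "inactive"
            counts = simulate_transcriptome(
                genome,
                stage,
                self.config.transcriptome_reads,
                seed=(self.config.seed * 1009 + len(genome.genome_id)) % (2**31),
            )
            totals[genome.genome_id] = int(counts["reads"].sum())
            profile = normalize_expression(counts, genome.genome_id, "S01")
            if not profile.no_signal:
                top = top_expressed(profile)
                pmoc_ids = set(
                    screen_table.loc[
                        screen_table["genome"] == genome.genome_id, "pmoc_gene"
                    ]
                )
                pmoc_members = {
                    part for gid in pmoc_ids for part in str(gid).split("+")
                }
                rows.append(
                    {
                        "phage": genome.genome_id,
                        "stage": stage,
                        "total_reads": totals[genome.genome_id],
                        "pmoc_in_top20": bool(pmoc_members & set(top["gene"])),
                    }
                )
                table = profile.table.copy()
                table.insert(0, "phage", genome.genome_id)
                per_gene_frames.append(table)
            else:
                rows.append(
                    {
                        "phage": genome.genome_id,
                        "stage": stage,
                        "total_reads": 0,
                        "pmoc_in_top20": False,
                    }
                )
        calls = activity_call(
            totals,
            "S01",
            self.config.activity_min_fraction,
            self.config.activity_min_reads,
        )
        activity = pd.DataFrame(
            [
                {
                    "phage": c.phage_id,
                    "mapped_reads": c.mapped_reads,
                    "mapped_fraction": round(c.mapped_fraction, 6),
                    "active": c.active,
                }
                for c in calls
            ]
        ).merge(pd.DataFrame(rows), on="phage")
        activity.to_csv(self._path("activity.tsv"), sep="\t", index=False)
        if per_gene_frames:
            pd.concat(per_gene_frames, ignore_index=True).round(
                {"E": 10}
            ).to_csv(self._path("expression.tsv"), sep="\t", index=False)
        return activity

    def snps(self) -> pd.DataFrame:
        table, _ = simulate_snp_table(
            self.config.snp_sites,
            (self.config.snp_depth, self.config.snp_depth),
            self.config.snp_shifted_fraction,
            self.config.snp_effect,
            seed=self.config.seed,
        )
        results = frequency_change_test(table, self.config.q_cutoff)
        results.round({"freq_a": 6, "freq_b": 6, "z": 6, "p": 10, "q": 10}).to_csv(
            self._path("snps.tsv"), sep="\t", index=False
        )
        return results

    def run_all(self) -> dict:
        genomes, truth = self.simulate()
        screen_table = self.screen()
        detection, growth, abundance = self.profile()
        predictions = self.link_hosts()
        matrix, specific = self.families()
        activity = self.express()
        snps = self.snps()

        truth_hosts = truth.true_host_of
        correct = sum(
            1
            for row in predictions.itertuples(index=False)
            if truth_hosts.get(row.phage) == row.host
        )
        growth_vals = [
            float(v) for v in growth["growth_index"] if v != ""
        ]
        summary = {
            "config_seed": self.config.seed,
            "n_genomes": len(genomes),
            "n_pmoc_phages_detected": int(screen_table["is_pmoc_phage"].sum()),
            "host_prediction_accuracy": (
                round(correct / len(predictions), 6) if len(predictions) else None
            ),
            "crispr_supported_links": int(predictions["crispr_support"].sum())
            if len(predictions)
            else 0,
            "mean_growth_index": (
                round(float(np.mean(growth_vals)), 4) if growth_vals else None
            ),
            "n_families_retained": int(matrix.shape[1]),
            "pmoc_specific_families": specific,
            "n_active_phages": int(activity["active"].sum()),
            "n_significant_snps": int(snps["significant"].sum()),
            "thresholds": {
                "min_breadth": self.config.min_breadth,
                "phage_min_identity": self.config.phage_min_identity,
                "host_min_identity": self.config.host_min_identity,
                "marker_min_breadth": self.config.marker_min_breadth,
                "host_assign_min_identity": self.config.host_assign_min_identity,
                "spacer_min_match": self.config.spacer_min_match,
                "family_min_genomes": self.config.family_min_genomes,
                "mcl_inflation": self.config.mcl_inflation,
                "q_cutoff": self.config.q_cutoff,
                "growth_min_coverage": self.config.growth_min_coverage,
            },
        }
        self._path("summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        return summary
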