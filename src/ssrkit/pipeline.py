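"""End-to-end orchestration of the synthetic-data pipeline stages.

Stages (mine -> design -> vpcr -> diversity -> amova -> tree -> dapc)
run independently from files or end-to-end in one call; every output
file starts with a provenance line carrying the config hash and seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import amova as amova_mod
from . import dapc as dapc_mod
from . import design as design_mod
from . import diversity as div_mod
from . import io as io_mod
from . import mining, phylo, simulate, vpcr
from .config import PipelineConfig

__all__ = ["run_pipeline", "DEFAULT_PLANTED"]

DEFAULT_PLANTED = (
    simulate.PlantedLocus("AG", 12, 80, 80),
    simulate.PlantedLocus("CT", 13, 80, 80),
    simulate.PlantedLocus("TG", 14, 80, 80),
    simulate.PlantedLocus("CA", 12, 80, 80),
    simulate.PlantedLocus("AAG", 8, 80, 80),
    simulate.PlantedLocus("GAA", 9, 80, 80),
    simulate.PlantedLocus("ACGT", 7, 80, 80),
    simulate.PlantedLocus("AT", 11, 80, 80),
)


def _stamp(path: Path, config: PipelineConfig) -> None:
    text = path.read_text()
    path.write_text(f"# ssrkit config={config.digest()} seed={config.seed}\n" + text)


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ssrkit config={config.digest()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all stages on a seeded synthetic dataset; returns output paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- simulate + mine -------------------------------------------------
    spec = simulate.ReadSimSpec(
        n_reads=120,
        planted_loci=DEFAULT_PLANTED,
        short_read_fraction=0.1,
        seed=config.seed,
    )
    reads, truth = simulate.simulate_reads(spec)
    reads_path = outdir / "reads.fasta"
    io_mod.write_fasta(reads, reads_path)
    outputs["reads"] = reads_path
    _write_tsv(truth, outdir / "reads_truth.tsv", config)

    retained, n_rejected = mining.filter_reads(reads, config.min_read_length)
    catalog_rows = []
    loci_by_read: dict[str, list[mining.SSRLocus]] = {}
    for rid, seq in retained:
        motifs = mining.find_ssrs(
            seq, config.thresholds(), config.min_tract, config.strand_collapse
        )
        loci = mining.build_loci(
            motifs, rid, len(seq), config.max_interruption, config.min_flank
        )
        if loci:
            loci_by_read[rid] = loci
        for locus in loci:
            for m in locus.motifs:
                catalog_rows.append(
                    {
                        "read_id": rid,
                        "structure": locus.structure,
                        "motif": m.motif,
                        "canonical_class": m.canonical_class,
                        "repeat_count": m.repeat_count,
                        "start": m.start,
                        "end": m.end,
                        "left_flank": locus.left_flank,
                        "right_flank": locus.right_flank,
                        "primer_designable": locus.primer_designable,
                    }
                )
    catalog = pd.DataFrame(catalog_rows)
    _write_tsv(catalog, outdir / "ssr_catalog.tsv", config)
    all_loci = [l for ll in loci_by_read.values() for l in ll]
    summary = mining.summarize_catalog(all_loci)
    summary_df = pd.DataFrame(
        [
            {"category": "reads_total", "count": len(reads)},
            {"category": "reads_quality", "count": len(retained)},
            {"category": "reads_rejected_short", "count": n_rejected},
            {"category": "loci_total", "count": summary["total"]},
            {"category": "loci_perfect", "count": summary["perfect"]},
            {"category": "loci_compound", "count": summary["compound"]},
            {"category": "loci_di", "count": summary["di"]},
            {"category": "loci_tri", "count": summary["tri"]},
            {"category": "loci_tetra", "count": summary["tetra"]},
        ]
    )
    _write_tsv(summary_df, outdir / "ssr_summary.tsv", config)
    outputs["catalog"] = outdir / "ssr_catalog.tsv"

    # --- design ----------------------------------------------------------
    read_seqs = dict(reads)
    params = design_mod.PickerParams(
        product_range=(config.product_min, config.product_max),
        max_tm_diff=config.design_max_tm_diff,
        length_range=(config.primer_len_min, config.primer_len_max),
        salt_mM=config.salt_mM,
        primer_nM=config.primer_nM,
    )
    pairs: dict[str, design_mod.PrimerPair] = {}
    primer_rows = []
    idx = 1
    for rid, loci in loci_by_read.items():
        for locus in loci:
            if not locus.primer_designable:
                continue
            pair = design_mod.pick_primers(
                locus, read_seqs[rid], f"Mkr-{idx:02d}", params
            )
            if pair is None:
                continue
            pairs[rid] = pair
            primer_rows.append(
                {
                    "marker": pair.marker_name,
                    "read_id": rid,
                    "forward": pair.forward,
                    "reverse": pair.reverse,
                    "tm_forward": pair.tm_forward,
                    "tm_reverse": pair.tm_reverse,
                    "ta_opt": pair.ta_opt,
                    "expected_size": pair.expected_size,
                }
            )
            idx += 1
    _write_tsv(pd.DataFrame(primer_rows), outdir / "primers.tsv", config)
    outputs["primers"] = outdir / "primers.tsv"

    # --- virtual PCR validation -----------------------------------------
    designed = truth[truth["read_id"].isin(pairs)].reset_index(drop=True)
    deltas = [2, 0, -2, 3, 0, 1][: len(designed)]
    pols = {
        rid: simulate.LocusPolymorphism(delta=deltas[i % len(deltas)] if deltas else 0)
        for i, rid in enumerate(designed["read_id"])
    }
    genome_a, genome_b, expect = simulate.simulate_template_pair(
        designed, read_seqs, pols, primer_pairs=pairs, seed=config.seed
    )
    io_mod.write_fasta(genome_a, outdir / "template_a.fasta")
    io_mod.write_fasta(genome_b, outdir / "template_b.fasta")
    verdict_rows = []
    for rid, pair in pairs.items():
        evidence = []
        for gname, genome in (("A", genome_a), ("B", genome_b)):
            index = vpcr.index_template(genome, config.kmer)
            amps = vpcr.predict_amplicons(
                pair, index, config.max_product, config.ta_window
            )
            evidence.append(
                design_mod.TemplateEvidence(
                    template_id=gname,
                    amplicon_sizes=tuple(a.size for a in amps),
                    annealing_estimate=amps[0].annealing_estimate if len(amps) == 1 else None,
                    tm_forward=pair.tm_forward,
                    tm_reverse=pair.tm_reverse,
                )
            )
        verdict = design_mod.classify_validation(
            pair.marker_name,
            evidence,
            pair.expected_size,
            config.min_ta,
            config.validation_max_tm_diff,
        )
        verdict_rows.append(
            {
                "marker": pair.marker_name,
                "read_id": rid,
                "expected_size": pair.expected_size,
                "verdict": verdict.verdict,
                "size_deltas": ",".join(map(str, verdict.size_deltas)),
            }
        )
    _write_tsv(pd.DataFrame(verdict_rows), outdir / "vpcr_verdicts.tsv", config)
    outputs["vpcr"] = outdir / "vpcr_verdicts.tsv"

    # --- genotypes + diversity ------------------------------------------
    gspec = simulate.GenotypeSimSpec(
        n_populations=3,
        sizes=(20, 20, 20),
        n_loci=15,
        alleles_per_locus=5,
        differentiation=0.15,
        missing_rate=0.02,
        clone_pairs=2,
        seed=config.seed,
    )
    G, _ = simulate.simulate_genotypes(gspec)
    io_mod.write_genalex(G, outdir / "genotypes.csv")
    outputs["genotypes"] = outdir / "genotypes.csv"
    _stamp(outdir / "genotypes.csv", config)

    locus_stats = pd.DataFrame(
        [vars(d) for d in div_mod.locus_diversity(G)]
    )
    _write_tsv(locus_stats, outdir / "locus_diversity.tsv", config)
    pop_stats = div_mod.population_summary(G, config.rarefaction_g)
    _write_tsv(pop_stats, outdir / "population_diversity.tsv", config)
    outputs["diversity"] = outdir / "locus_diversity.tsv"

    # --- AMOVA -----------------------------------------------------------
    D = amova_mod.distance_matrix(G, config.amova_metric)
    res = amova_mod.amova_phipt(
        D, G.pops, n_perm=config.n_permutations, seed=config.seed
    )
    amova_df = pd.DataFrame(
        [
            {
                "source": "among_pops",
                "df": res.df_among,
                "SS": res.ss_among,
                "variance": res.va,
                "pct": res.pct_among,
                "PhiPT": res.phipt,
                "p_value": res.p_value,
            },
            {
                "source": "within_pops",
                "df": res.df_within,
                "SS": res.ss_within,
                "variance": res.vw,
                "pct": res.pct_within,
                "PhiPT": "",
                "p_value": "",
            },
        ]
    )
    _write_tsv(amova_df, outdir / "amova.tsv", config)
    phi, pval = amova_mod.pairwise_phipt(
        G, n_perm=config.n_permutations, seed=config.seed, metric=config.amova_metric
    )
    _write_tsv(phi.reset_index(names="population"), outdir / "pairwise_phipt.tsv", config)
    outputs["amova"] = outdir / "amova.tsv"

    # --- UPGMA tree ------------------------------------------------------
    pop_freqs = div_mod.allele_frequencies(G, by_population=True)
    labels, ND = phylo.nei_distance_matrix(pop_freqs, config.nei_variant)
    tree = phylo.upgma(labels, ND)
    newick_path = outdir / "populations.nwk"
    newick_path.write_text(phylo.to_newick(tree) + "\n")
    outputs["tree"] = newick_path

    # --- DAPC ------------------------------------------------------------
    X, _cols = dapc_mod.allele_count_coding(G)
    search = dapc_mod.find_clusters(
        X,
        k_range=range(config.k_min, min(config.k_max, G.n_individuals - 1) + 1),
        n_pc_prefilter=config.pc_prefilter,
        n_restarts=config.kmeans_restarts,
        seed=config.seed,
    )
    bic_df = pd.DataFrame(
        sorted(search.bic_curve.items()), columns=["K", "BIC"]
    )
    _write_tsv(bic_df, outdir / "bic_curve.tsv", config)
    n_pc = max(1, min(5, G.n_individuals - search.best_k - 1))
    fit = dapc_mod.dapc_fit(X, search.assignments, n_pc, seed=config.seed)
    member_df = pd.DataFrame(
        fit.membership, columns=[f"cluster{c}" for c in fit.classes]
    )
    member_df.insert(0, "individual", G.ids)
    member_df.insert(1, "assignment", fit.assignments)
    _write_tsv(member_df, outdir / "dapc_membership.tsv", config)
    outputs["dapc"] = outdir / "dapc_membership.tsv"

    return outputs
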