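"""End-to-end run of the full analysis on a synthetic species community.

``run_pipeline`` simulates the default eight-species scenario and pushes it
through every stage — copy-number profiling, monomer extraction, divergence
landscapes and summaries, the variant MST, long-read array detection with
flanker clustering, and transcription quantification — writing each report
as TSV/BED/FASTA under an output directory.  The analysis drivers under
``analysis/`` are thin wrappers over the same stage functions.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import divergence, expression, longread, monomers, mst, profiles, seqio, simulate
from .scenarios import DEFAULT_MONOMER, default_config, make_gene_panel
from .simulate import GenomeTruth, SimulationConfig

__all__ = ["run_pipeline", "PipelineResult", "simulate_community", "CommunityData"]


@dataclass
class CommunityData:
    """Simulated genomes, reads and truth for one species community."""

    config: SimulationConfig
    genomes: dict[str, str]
    truths: dict[str, GenomeTruth]
    short_reads: dict[str, list]  # species -> flat list of SequenceRecords
    long_reads: dict[str, list]
    long_read_truth: dict[str, dict]
    genes: list[tuple[str, str]]


@dataclass
class PipelineResult:
    outdir: str
    files: dict[str, str] = field(default_factory=dict)
    copy_numbers: dict[str, float] = field(default_factory=dict)
    pools: Optional[monomers.VariantPool] = None
    summary: Optional[divergence.DivergenceSummary] = None

    def path(self, key: str) -> str:
        return self.files[key]


def simulate_community(
    config: SimulationConfig,
    long_read_species: Sequence[str] = (),
    genes: Optional[list[tuple[str, str]]] = None,
) -> CommunityData:
    """Simulate genomes, short reads and (for chosen species) long reads."""
    genes = genes if genes is not None else make_gene_panel()
    pools = simulate.evolve_library(config)
    data = CommunityData(config, {}, {}, {}, {}, {}, genes)
    for sp in config.species:
        genome, truth = simulate.build_genome(pools[sp.name], config, sp.name, genes)
        data.genomes[sp.name] = genome
        data.truths[sp.name] = truth
        pairs = simulate.simulate_short_reads(genome, config, sp.name)
        data.short_reads[sp.name] = [r for p in pairs for r in p]
        if sp.name in long_read_species and config.long_read is not None:
            reads, rtruth = simulate.simulate_long_reads(
                genome, config, truth.intervals, sp.name
            )
            data.long_reads[sp.name] = reads
            data.long_read_truth[sp.name] = rtruth
    return data


def _write(result: PipelineResult, key: str, filename: str) -> str:
    path = os.path.join(result.outdir, filename)
    result.files[key] = path
    return path


def run_pipeline(
    outdir: str,
    seed: int,
    config: Optional[SimulationConfig] = None,
    long_read_species: Sequence[str] = ("dispersed_sp3", "dispersed_sp4"),
) -> PipelineResult:
    """Run every analysis stage on the default synthetic community."""
    os.makedirs(outdir, exist_ok=True)
    cfg = config or default_config(seed)
    result = PipelineResult(outdir)
    consensus = cfg.ancestral_monomer
    # 1-kb genes keep total carved content well under the 50-kb background
    data = simulate_community(cfg, long_read_species, genes=make_gene_panel(length=1000))
    genes = data.genes
    gene_ids = [g for g, _ in genes]

    # raw data + truth on disk
    for sp, genome in data.genomes.items():
        seqio.write_sequences(
            _write(result, f"genome:{sp}", f"{sp}.genome.fa"),
            [seqio.SequenceRecord(sp, genome)],
        )
        seqio.write_sequences(
            _write(result, f"reads:{sp}", f"{sp}.reads.fq"), data.short_reads[sp]
        )
        seqio.write_intervals(
            _write(result, f"truth:{sp}", f"{sp}.truth.bed"), data.truths[sp].intervals
        )

    # stage 1: coverage profiles and copy numbers
    refs = [("sat", profiles.build_concatemer(consensus))] + genes
    profile_rows = []
    scaled = {}
    for sp in data.genomes:
        mapped = profiles.map_reads(data.short_reads[sp], refs, mode="local")
        sat = mapped.profiles["sat"]
        copies = profiles.estimate_copy_number(mapped, "sat", gene_ids)
        result.copy_numbers[sp] = copies
        scaled[sp] = sat.scaled
        nonref = profiles.variant_fraction(sat, refs[0][1])
        profile_rows.append(
            {
                "species": sp,
                "total_reads": len(data.short_reads[sp]),
                "covered_fraction": sat.covered_fraction,
                "normalized_copies": copies,
                "true_copies": data.truths[sp].copy_number,
                "max_nonref_fraction": float(np.nanmax(nonref)) if sat.aligned_bases else np.nan,
            }
        )
    seqio.write_table(
        pd.DataFrame(profile_rows), _write(result, "profiles", "copy_number.tsv")
    )
    corr_rows = []
    species_list = list(data.genomes)
    for i, a in enumerate(species_list):
        for b in species_list[i + 1 :]:
            try:
                r = profiles.profile_correlation(scaled[a], scaled[b])
            except profiles.UndefinedCorrelationError:
                r = np.nan
            corr_rows.append({"species_a": a, "species_b": b, "pearson_r": r})
    seqio.write_table(
        pd.DataFrame(corr_rows), _write(result, "correlations", "profile_correlations.tsv")
    )

    # stage 2: monomer extraction, pools, composition
    pool = monomers.VariantPool()
    comp_rows = []
    for sp in data.genomes:
        raw = monomers.extract_monomers(data.short_reads[sp], consensus)
        counts = monomers.tally_and_filter(raw)
        pool.add_species(sp, counts)
        if counts:
            comp = monomers.consensus_and_composition(counts)
            comp_rows.append(
                {
                    "species": sp,
                    "n_variants": len(counts),
                    "n_monomers": sum(counts.values()),
                    "consensus": comp.consensus,
                    "at_fraction": comp.at_fraction,
                }
            )
    result.pools = pool
    pool_rows = [
        {"species": sp, "sequence": s, "count": c}
        for sp in pool.species()
        for s, c in sorted(pool.counts(sp).items())
    ]
    seqio.write_table(pd.DataFrame(pool_rows), _write(result, "pool", "variant_pool.tsv"))
    seqio.write_table(pd.DataFrame(comp_rows), _write(result, "composition", "composition.tsv"))

    # stage 3: landscapes and divergence summary
    land_rows = []
    for sp in pool.species():
        if not pool.counts(sp):
            continue
        hist = divergence.repeat_landscape(pool.counts(sp), consensus)
        for b, mass in sorted(hist.bin_bases.items()):
            land_rows.append({"species": sp, "divergence_bin_pct": b, "bases": mass})
    seqio.write_table(pd.DataFrame(land_rows), _write(result, "landscape", "landscape.tsv"))
    populated = [sp for sp in pool.species() if pool.counts(sp)]
    summary = divergence.divergence_summary(
        monomers.VariantPool({sp: pool.counts(sp) for sp in populated}),
        consensus=consensus,
    )
    result.summary = summary
    sum_rows = [
        {"species": sp, "intraspecific_kd_pct": k} for sp, k in summary.intraspecific.items()
    ]
    sum_rows.append({"species": "interspecific", "intraspecific_kd_pct": summary.interspecific})
    seqio.write_table(pd.DataFrame(sum_rows), _write(result, "divergence", "divergence.tsv"))

    # stage 4: MST + shared variants (nodes in the consensus frame so edge
    # lengths are columnwise mutational steps)
    merged = Counter()
    for sp in populated:
        merged.update(monomers.phase_align(pool.counts(sp), consensus))
    top = [s for s, _ in merged.most_common(60)]
    tree = mst.build_mst(
        mst.hamming_matrix(top), ids=top, abundances={s: merged[s] for s in top}
    )
    edge_rows = [{"u": u, "v": v, "distance": d} for u, v, d in tree.edges]
    seqio.write_table(pd.DataFrame(edge_rows), _write(result, "mst_edges", "mst_edges.tsv"))
    shared = mst.shared_variants(pool)
    shared_rows = [
        {
            "sequence": sv.sequence,
            "n_species": sv.n_species,
            "species": ",".join(sp for sp, _ in sv.species_counts),
        }
        for sv in shared
    ]
    seqio.write_table(pd.DataFrame(shared_rows), _write(result, "shared", "shared_variants.tsv"))

    # stage 5: long-read arrays, density, flankers
    array_records = []
    density_rows = []
    flankers = []
    for sp, reads in data.long_reads.items():
        intervals = []
        total = 0
        for read in reads:
            total += len(read)
            hits = longread.detect_arrays(read.sequence, consensus, read_id=read.id)
            intervals.extend(hits)
            for iv in hits:
                up, down = longread.extract_flankers(read.sequence, (iv.start, iv.end))
                flankers.extend([f for f in (up, down) if len(f) >= 100])
        density = longread.repeat_density(intervals, total) if intervals else None
        density_rows.append(
            {
                "species": sp,
                "mb_sequenced": total / 1e6,
                "kb_annotated": density.kb_annotated if density else 0.0,
                "density_kb_per_mb": density.density if density else 0.0,
            }
        )
        array_records.extend(
            seqio.IntervalRecord(
                iv.read_id, iv.start, iv.end, "sat", 1000 * (1 - iv.noise), iv.strand
            )
            for iv in intervals
        )
    seqio.write_intervals(_write(result, "arrays", "arrays.bed"), array_records)
    seqio.write_table(pd.DataFrame(density_rows), _write(result, "density", "density.tsv"))
    cluster_rows = []
    if flankers:
        for i, cl in enumerate(longread.cluster_flankers(flankers, keep_small=True)):
            cluster_rows.append(
                {"cluster": i, "size": cl.size, "representative_length": len(cl.representative)}
            )
    seqio.write_table(
        pd.DataFrame(cluster_rows, columns=["cluster", "size", "representative_length"]),
        _write(result, "flankers", "flanker_clusters.tsv"),
    )

    # stage 6: transcription (RNA from the satellite and endogenous genes)
    targets = {"sat": profiles.build_concatemer(consensus)}
    for gid, gseq in genes[:4]:
        targets[gid] = gseq[: len(targets["sat"])]
    rates = {t: 1.0 for t in targets}
    rates["sat"] = 2.0
    fpkm_frames = []
    for tissue, scale in (("muscle", 1.0), ("ovary", 0.25)):
        tissue_rates = dict(rates)
        tissue_rates["sat"] = rates["sat"] * scale
        rna = simulate.simulate_rna_reads(
            targets, tissue_rates, n_reads=8000, seed=seed, label=tissue
        )
        mapped = profiles.map_reads(rna, list(targets.items()), mode="global")
        table = expression.fpkm_table(
            mapped.counts(), {t: len(s) for t, s in targets.items()}, library_id=tissue
        )
        fpkm_frames.append(table)
    fpkm_all = pd.concat(fpkm_frames, ignore_index=True)
    seqio.write_table(fpkm_all, _write(result, "fpkm", "fpkm.tsv"))
    # qPCR demo: Ct values consistent with the simulated abundances
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9C9]))
    ct_rows = []
    for sample, dct in (("muscle", 2.0), ("ovary", 5.0)):
        for rep in range(3):
            ct_rows.append(
                {"sample": sample, "target": "sat", "replicate": rep,
                 "ct": 18.0 + dct + rng.normal(0, 0.05)}
            )
            ct_rows.append(
                {"sample": sample, "target": "hprt", "replicate": rep,
                 "ct": 18.0 + rng.normal(0, 0.05)}
            )
    ct = pd.DataFrame(ct_rows)
    rq = expression.qpcr_relative(ct, target="sat", reference="hprt", calibrator="ovary")
    seqio.write_table(rq, _write(result, "qpcr", "qpcr_rq.tsv"))
    return result
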