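#!/usr/bin/env python
"""Simulate the eight-species community and write raw data plus truth.

Genomes (50 kb), 2x101 read pairs and, for two species, noisy long reads go
under scratch/sim/; planted-array truth is BED6.  Everything downstream
(02-07) re-derives its inputs from the same seed, so this script exists to
let you eyeball the raw data."""

import argparse
import os

from satcons import seqio
from satcons.pipeline import simulate_community
from satcons.scenarios import default_config, make_gene_panel


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="scratch/sim")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)
    cfg = default_config(args.seed)
    data = simulate_community(
        cfg, long_read_species=("dispersed_sp3", "dispersed_sp4"),
        genes=make_gene_panel(length=1000),
    )
    for sp, genome in data.genomes.items():
        seqio.write_sequences(
            os.path.join(args.outdir, f"{sp}.genome.fa"), [seqio.SequenceRecord(sp, genome)]
        )
        seqio.write_sequences(
            os.path.join(args.outdir, f"{sp}.reads.fq"), data.short_reads[sp]
        )
        seqio.write_intervals(
            os.path.join(args.outdir, f"{sp}.truth.bed"), data.truths[sp].intervals
        )
        truth = data.truths[sp]
        print(
            f"{sp}: {len(truth.intervals)} arrays, {truth.copy_number} monomer copies, "
            f"{len(data.short_reads[sp])} reads"
        )
    for sp, reads in data.long_reads.items():
        seqio.write_sequences(os.path.join(args.outdir, f"{sp}.longreads.fa"), reads)
        print(f"{sp}: {len(reads)} long reads, {sum(len(r) for r in reads)/1e6:.2f} Mb")


if __name__ == "__main__":
    main()
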