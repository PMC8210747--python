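#!/usr/bin/env python
"""Recompute the published survey's summary rows from its printed columns.

The CharSat01-52 survey table (14 characiform species) ships with the
package; its Mean/SD/CV rows for genomic abundance and intraspecific K2P
divergence are recomputed here with column_summary and written to
results/survey_statistics.tsv."""

import argparse
import os

import pandas as pd

from satcons.divergence import column_summary
from satcons.survey import INTERSPECIFIC_KD_PCT, survey_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)  # unused; uniform CLI
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    os.makedirs(args.outdir, exist_ok=True)
    table = survey_table()
    rows = []
    for column in ("abundance_pct", "intraspecific_kd_pct", "at_pct"):
        stats = column_summary(table[column].dropna())
        rows.append(
            {"column": column, "n": stats.n, "mean": stats.mean, "sd": stats.sd, "cv": stats.cv}
        )
    out = pd.DataFrame(rows)
    out.to_csv(os.path.join(args.outdir, "survey_statistics.tsv"), sep="\t", index=False)
    print(out.to_string(index=False))
    total = int(table["n_monomers"].dropna().sum())
    print(f"\nmonomer total across species: {total}")
    print(f"published overall interspecific KD: {INTERSPECIFIC_KD_PCT}% — of the same "
          "order as the intraspecific mean, the survey's key observation "
          "(concerted evolution predicts intra << inter).")


if __name__ == "__main__":
    main()
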