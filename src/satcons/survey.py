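"""Published CharSat01-52 survey values across 14 characiform species.

Per-species figures from the published DNA-seq survey of the CharSat01-52
satellite (monomer counts after singleton filtering, consensus A+T content,
genomic abundance as percent of the library, and intraspecific Kimura
2-parameter divergence).  These printed values are inputs: the package
recomputes the survey's summary rows (mean, sample SD, CV, totals) from
them with :func:`satcons.divergence.column_summary`.

Missing entries (dash in the source table) are ``None``: no monomers could
be collected for *Hoplias malabaricus* (residual copies only) and the
satellite is absent from *Distichodus sexfasciatus*, the non-Characoidei
outgroup.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["survey_table", "INTERSPECIFIC_KD_PCT"]

# (species, n_monomers, monomer_size_bp, at_pct, abundance_pct, intraspecific_kd_pct)
_ROWS = [
    ("Characidium gomesi", 2145, 52, 71.5, 3.53e-3, 15.43),
    ("Hoplias malabaricus", None, 52, None, 3.03917e-5, 21.5),
    ("Hemiodus gracilis", 116, 52, 66.0, 0.000923, 16.1),
    ("Piaractus mesopotamicus", 6, 52, 67.4, 0.000124, 19.4),
    ("Myleus asterias", 12, 52, 66.2, 0.000155, 18.2),
    ("Pygocentrus nattereri", 63, 52, 65.5, 0.000182849, 18.6),
    ("Prochilodus lineatus", 90, 52, 59.3, 0.000287, 14.4),
    ("Leporinus friderici", 69, 52, 67.4, 0.000196, 14.5),
    ("Megaleporinus macrocephalus", 187, 52, 67.6, 0.000315, 13.5),
    ("Brycon orbignyanus", 63, 52, 64.6, 0.000191, 8.16),
    ("Astyanax mexicanus", 33, 52, 68.2, 0.000179, 13.2),
    ("Astyanax paranae", 65, 52, 67.7, 0.000137, 11.3),
    ("Moenkhausia sanctaefilomenae", 104, 52, 67.9, 0.00074, 9.48),
    ("Distichodus sexfasciatus", None, None, None, 0.0, 0.0),
]

#: Overall interspecific K2P divergence (%) reported by the survey.
INTERSPECIFIC_KD_PCT = 15.22


def survey_table() -> pd.DataFrame:
    """The survey as a DataFrame, one row per species, in published order."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "species",
            "n_monomers",
            "monomer_size_bp",
            "at_pct",
            "abundance_pct",
            "intraspecific_kd_pct",
        ],
    )
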