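"""Bundled instrument data for plasma n-3 fatty acids.

The package ships the published 26-row table of SNP-exposure associations
for four plasma n-3 fatty acids (ALA, DHA, DPA, EPA) from the CHARGE
consortium GWAS (n = 8,866, European ancestry), including the published
per-SNP variance explained (``ve_percent``) and F-statistic (``f_stat``)
columns.

The trait variances in :data:`EXPOSURE_VARIANCE` are not printed in the
source table; they were recovered by inverting

    VE(%) = 2 * beta^2 * eaf * (1 - eaf) / var * 100

row by row and taking the per-exposure median (the per-row values agree to
about four significant digits, so the inversion is well conditioned).
With these variances the full-precision VE recomputation reproduces every
published integer F value.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .summary_io import GwasTable, SnpAssociation, write_gwas_table

_DATA_FILE = "charge_n3pufa_instruments.tsv"

#: Exposure GWAS sample size.
EXPOSURE_SAMPLE_SIZE = 8866

#: Per-exposure trait variance back-solved from the published VE column.
EXPOSURE_VARIANCE = {
    "ALA": 0.0109517,
    "DHA": 0.9596795,
    "DPA": 0.0300015,
    "EPA": 0.1600637,
}

EXPOSURES = ("ALA", "DHA", "DPA", "EPA")


def load_instruments_frame() -> pd.DataFrame:
    """The bundled 26-row instrument table as a DataFrame."""
    with resources.files("mr2s.data").joinpath(_DATA_FILE).open("r") as handle:
        return pd.read_csv(handle, sep="\t")


def exposure_table(pufa: str) -> GwasTable:
    """Bundled instruments for one exposure as a validated GwasTable."""
    if pufa not in EXPOSURES:
        raise KeyError(f"unknown exposure {pufa!r}; choose from {EXPOSURES}")
    frame = load_instruments_frame()
    sub = frame[frame["pufa"] == pufa]
    records = [
        SnpAssociation(
            rsid=row.rsid,
            chromosome=str(row.chr),
            position=int(row.pos),
            effect_allele=row.ea,
            other_allele=row.nea,
            eaf=float(row.eaf),
            beta=float(row.beta),
            se=float(row.se),
            pvalue=float(row.pval),
        )
        for row in sub.itertuples(index=False)
    ]
    return GwasTable(
        trait_name=pufa,
        trait_type="continuous",
        sample_size=EXPOSURE_SAMPLE_SIZE,
        trait_variance=EXPOSURE_VARIANCE[pufa],
        records=records,
    )


def write_fixtures(outdir) -> list[Path]:
    """Write one canonical summary-statistic TSV per exposure.

    Returns the written paths; useful for exercising the CLI without any
    external downloads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for pufa in EXPOSURES:
        path = outdir / f"{pufa.lower()}_instruments.tsv"
        write_gwas_table(exposure_table(pufa), path)
        written.append(path)
    return written
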