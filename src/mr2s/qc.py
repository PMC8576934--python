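"""Instrument-strength quality control: variance explained and F-statistics.

For a SNP with per-allele effect ``beta`` and effect-allele frequency
``eaf`` on a trait with variance ``var``,

    VE(%) = 2 * beta^2 * eaf * (1 - eaf) / var * 100

and, with R^2 = VE/100, sample size ``n`` and ``k`` instruments,

    F = (R^2 * (n - 1 - k)) / ((1 - R^2) * k).

The conventional weak-instrument bound is F <= 10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .summary_io import GwasTable

logger = logging.getLogger(__name__)

#: Sample size of the exposure GWAS used when a table carries none.
DEFAULT_EXPOSURE_N = 8866

WEAK_F_BOUND = 10.0


def variance_explained(beta: float, eaf: float, trait_variance: float) -> float:
    """Percent of trait variance explained by one SNP.

    Accepts scalars or numpy arrays for ``beta`` and ``eaf``.
    """
    if not np.all(np.asarray(trait_variance) > 0):
        raise DomainError(f"trait_variance must be > 0, got {trait_variance}")
    eaf_arr = np.asarray(eaf, dtype=float)
    if not np.all((eaf_arr > 0) & (eaf_arr < 1)):
        raise DomainError(f"eaf must lie in (0,1), got {eaf}")
    ve = 2.0 * np.asarray(beta, dtype=float) ** 2 * eaf_arr * (1.0 - eaf_arr) / trait_variance * 100.0
    return float(ve) if np.isscalar(beta) or np.ndim(ve) == 0 else ve


def f_statistic(ve_percent: float, n: int, k: int = 1) -> float:
    """Instrument F-statistic from percent variance explained."""
    ve_arr = np.asarray(ve_percent, dtype=float)
    if not np.all((ve_arr >= 0) & (ve_arr < 100)):
        raise DomainError(f"ve_percent must lie in [0,100), got {ve_percent}")
    if not n > k + 1:
        raise DomainError(f"need n > k + 1, got n={n}, k={k}")
    r2 = ve_arr / 100.0
    f = r2 * (n - 1 - k) / ((1.0 - r2) * k)
    return float(f) if np.ndim(f) == 0 else f


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class QcRecord:
    rsid: str
    ve_percent: float
    f_stat: float
    n: int
    k: int

    @property
    def f_rounded(self) -> int:
        return round_half_away(self.f_stat)

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_F_BOUND


def qc_report(
    table: GwasTable,
    k_convention: str = "per_snp",
    n: int | None = None,
    ve_percent: Sequence[float] | None = None,
) -> tuple[list[QcRecord], dict]:
    """Per-SNP instrument-strength report plus a summary block.

    Parameters
    ----------
    table
        Exposure associations.  ``table.trait_variance`` is required unless
        precomputed ``ve_percent`` values are supplied.
    k_convention
        ``'per_snp'`` computes each F with k = 1 (the convention that
        reproduces published per-SNP F values); ``'per_set'`` uses
        k = number of instruments.
    n
        Exposure sample size; falls back to ``table.sample_size`` and then
        to :data:`DEFAULT_EXPOSURE_N` with a warning.
    ve_percent
        Optional externally supplied VE values, one per record, overriding
        the in-package computation.

    The summary (mean/min/max F) is computed over the per-SNP F values
    rounded half away from zero to integers, matching how such tables are
    customarily presented; unrounded VE summaries are included alongside.
    """
    if k_convention not in {"per_snp", "per_set"}:
        raise ConfigurationError(f"k_convention must be 'per_snp' or 'per_set', got {k_convention!r}")
    if n is None:
        n = table.sample_size
    if n is None:
        n = DEFAULT_EXPOSURE_N
        logger.warning("no sample size on table %r; defaulting to n=%d", table.trait_name, n)
    records = table.records
    if ve_percent is None:
        if table.trait_variance is None:
            raise ConfigurationError(
                f"table {table.trait_name!r} has no trait_variance; supply the exposure trait "
                "variance (from phenotype literature) or precomputed ve_percent values"
            )
        ve_values = [
            variance_explained(r.beta, r.eaf_or_nan, table.trait_variance) for r in records
        ]
    else:
        ve_values = [float(v) for v in ve_percent]
        if len(ve_values) != len(records):
            raise ConfigurationError(
                f"got {len(ve_values)} ve_percent values for {len(records)} records"
            )
    k = 1 if k_convention == "per_snp" else max(len(records), 1)
    out = [
        QcRecord(rsid=r.rsid, ve_percent=v, f_stat=f_statistic(v, n, k), n=n, k=k)
        for r, v in zip(records, ve_values)
    ]
    summary = summarize_qc(out)
    if summary["n_weak"]:
        logger.warning("%d instrument(s) have F <= %g", summary["n_weak"], WEAK_F_BOUND)
    return out, summary


def summarize_qc(records: Sequence[QcRecord]) -> dict:
    """Summary over rounded per-SNP F values and raw VE values."""
    if not records:
        return {
            "n": 0, "mean_f": math.nan, "min_f": math.nan, "max_f": math.nan,
            "mean_ve": math.nan, "min_ve": math.nan, "max_ve": math.nan, "n_weak": 0,
        }
    rounded = [r.f_rounded for r in records]
    ves = [r.ve_percent for r in records]
    return {
        "n": len(records),
        "mean_f": float(np.mean(rounded)),
        "min_f": int(min(rounded)),
        "max_f": int(max(rounded)),
        "mean_ve": float(np.mean(ves)),
        "min_ve": float(min(ves)),
        "max_ve": float(max(ves)),
        "n_weak": sum(r.weak for r in records),
    }


def write_qc_table(records: Sequence[QcRecord], path, summary: dict | None = None) -> None:
    """Write the QC report TSV (rsid, ve_percent, f_stat, weak_flag)."""
    frame = pd.DataFrame(
        [(r.rsid, r.ve_percent, r.f_stat, int(r.weak)) for r in records],
        columns=["rsid", "ve_percent", "f_stat", "weak_flag"],
    )
    with open(path, "w", encoding="utf-8") as handle:
        frame.to_csv(handle, sep="\t", index=False, float_format="%.6g")
        if summary is not None and summary["n"]:
            handle.write(
                "# summary\tmean_f=%.6g\tmin_f=%d\tmax_f=%d\tmean_ve=%.6g\tn_weak=%d\n"
                % (
                    summary["mean_f"],
                    summary["min_f"],
                    summary["max_f"],
                    summary["mean_ve"],
                    summary["n_weak"],
                )
            )
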