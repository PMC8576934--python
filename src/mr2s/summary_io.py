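"""Reading, validating and writing GWAS summary-statistic tables.

The on-disk dialect is tab-delimited UTF-8 text with a header line.
Canonical column names are ``rsid, chr, pos, ea, nea, eaf, beta, se, pval``;
a :data:`DEFAULT_COLUMN_MAP` mapping these onto themselves ships with the
package and custom mappings may be supplied per file.  Missing values use
the token ``NA``.  Numbers tolerate a unicode minus sign and optional
whitespace before the exponent (``9.61 E-44``), as found in published
tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: Canonical file columns mapped onto themselves.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "chr": "chr",
    "pos": "pos",
    "ea": "ea",
    "nea": "nea",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
}

#: Columns of the long-format analysis results table.
RESULT_COLUMNS: tuple[str, ...] = (
    "exposure",
    "outcome",
    "method",
    "n_snp",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "q_stat",
    "q_pval",
    "egger_intercept",
    "egger_intercept_se",
    "egger_intercept_pval",
    "presso_global_pval",
    "flags",
)

MISSING_TOKEN = "NA"


def parse_number(text: str | float | None) -> float:
    """Parse a numeric token from a summary-statistic file.

    Handles the unicode minus sign, internal whitespace (``9.61 E-44``,
    ``- 0.0404``) and the ``NA``/empty missing tokens (returned as NaN).
    """
    if text is None:
        return math.nan
    if isinstance(text, float):
        return text
    cleaned = str(text).strip()
    if cleaned == "" or cleaned.upper() in {"NA", "NAN"}:
        return math.nan
    cleaned = cleaned.replace("−", "-").replace("–", "-")
    cleaned = "".join(cleaned.split())
    try:
        return float(cleaned)
    except ValueError as exc:
        raise FormatError(f"cannot parse number from {text!r}") from exc


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele effect: trait units for continuous
    traits, log-odds for binary traits.
    """

    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float

    def violations(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.effect_allele not in VALID_BASES:
            problems.append(f"effect allele {self.effect_allele!r} is not a single A/C/G/T base")
        if self.other_allele not in VALID_BASES:
            problems.append(f"other allele {self.other_allele!r} is not a single A/C/G/T base")
        if (
            self.effect_allele in VALID_BASES
            and self.other_allele in VALID_BASES
            and self.effect_allele == self.other_allele
        ):
            problems.append("effect and other allele are identical")
        if self.eaf is not None and not math.isnan(self.eaf) and not 0.0 < self.eaf < 1.0:
            problems.append(f"eaf {self.eaf} outside (0,1)")
        if not (math.isfinite(self.se) and self.se > 0.0):
            problems.append(f"se {self.se} is not positive")
        if not math.isfinite(self.beta):
            problems.append(f"beta {self.beta} is not finite")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append(f"p-value {self.pvalue} outside (0,1]")
        return problems

    @property
    def eaf_or_nan(self) -> float:
        return math.nan if self.eaf is None else self.eaf


@dataclass(frozen=True)
class RejectedRow:
    """A row excluded on read, with the reason."""

    line: int
    rsid: str
    reason: str


@dataclass
class GwasTable:
    """A validated set of SNP associations for a single trait."""

    trait_name: str
    trait_type: str = "continuous"  # continuous | binary
    sample_size: int | None = None
    trait_variance: float | None = None
    records: list[SnpAssociation] = field(default_factory=list)
    rejections: list[RejectedRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in {"continuous", "binary"}:
            raise ValidationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}"
            )
        if self.sample_size is not None and self.sample_size < 2:
            raise ValidationError(f"sample_size must be >= 2, got {self.sample_size}")
        if self.trait_variance is not None and not self.trait_variance > 0:
            raise ValidationError(f"trait_variance must be > 0, got {self.trait_variance}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise ValidationError(f"duplicate rsid {rec.rsid!r} in table {self.trait_name!r}")
            seen.add(rec.rsid)
        self._index = {rec.rsid: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, rsid: str) -> SnpAssociation | None:
        return self._index.get(rsid)

    def with_records(self, records: Sequence[SnpAssociation]) -> "GwasTable":
        """Copy of this table carrying a different record set."""
        return GwasTable(
            trait_name=self.trait_name,
            trait_type=self.trait_type,
            sample_size=self.sample_size,
            trait_variance=self.trait_variance,
            records=list(records),
        )


def _row_to_association(row: Mapping[str, object], colmap: Mapping[str, str]) -> SnpAssociation:
    def cell(name: str) -> object:
        return row[colmap[name]]

    eaf = parse_number(cell("eaf")) if "eaf" in colmap else math.nan
    return SnpAssociation(
        rsid=str(cell("rsid")).strip(),
        chromosome=str(cell("chr")).strip() if "chr" in colmap else "",
        position=int(parse_number(cell("pos"))) if "pos" in colmap else 0,
        effect_allele=str(cell("ea")).strip().upper(),
        other_allele=str(cell("nea")).strip().upper(),
        eaf=None if math.isnan(eaf) else eaf,
        beta=parse_number(cell("beta")),
        se=parse_number(cell("se")),
        pvalue=parse_number(cell("pval")),
    )


def read_gwas_table(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait_name: str = "trait",
    trait_type: str = "continuous",
    sample_size: int | None = None,
    trait_variance: float | None = None,
) -> GwasTable:
    """Read a tab-delimited summary-statistic file into a :class:`GwasTable`.

    Parameters
    ----------
    path
        File to read; tab-delimited with a header line.
    column_map
        Mapping from canonical field names (``rsid``, ``chr``, ``pos``,
        ``ea``, ``nea``, ``eaf``, ``beta``, ``se``, ``pval``) to the file's
        column names.  Defaults to :data:`DEFAULT_COLUMN_MAP`.
    trait_name, trait_type, sample_size, trait_variance
        Trait metadata attached to the returned table.

    Rows violating :class:`SnpAssociation` invariants are excluded and
    recorded in ``table.rejections`` with a reason; a duplicate rsid among
    accepted rows raises :class:`~mr2s.exceptions.ValidationError`.
    """
    colmap = dict(column_map or DEFAULT_COLUMN_MAP)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"rsid", "ea", "nea", "beta", "se", "pval"}
    for canonical in required:
        if canonical not in colmap:
            raise FormatError(f"column map lacks required field {canonical!r}")
        if colmap[canonical] not in frame.columns:
            raise FormatError(
                f"mapped column {colmap[canonical]!r} (for {canonical!r}) missing from "
                f"header of {path}"
            )
    for optional in ("chr", "pos", "eaf"):
        if optional in colmap and colmap[optional] not in frame.columns:
            del colmap[optional]

    records: list[SnpAssociation] = []
    rejections: list[RejectedRow] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(frame.to_dict("records")):
        line = i + 2  # 1-based, after header
        try:
            assoc = _row_to_association(row, colmap)
        except (FormatError, ValueError) as exc:
            rsid = str(row.get(colmap["rsid"], "?"))
            rejections.append(RejectedRow(line, rsid, str(exc)))
            logger.warning("rejected line %d (%s): %s", line, rsid, exc)
            continue
        problems = assoc.violations()
        if problems:
            rejections.append(RejectedRow(line, assoc.rsid, "; ".join(problems)))
            logger.warning("rejected line %d (%s): %s", line, assoc.rsid, "; ".join(problems))
            continue
        if assoc.rsid in seen:
            raise ValidationError(
                f"duplicate rsid {assoc.rsid!r} at lines {seen[assoc.rsid]} and {line} of {path}"
            )
        seen[assoc.rsid] = line
        records.append(assoc)

    table = GwasTable(
        trait_name=trait_name,
        trait_type=trait_type,
        sample_size=sample_size,
        trait_variance=trait_variance,
        records=records,
    )
    table.rejections = rejections
    return table


def write_gwas_table(table: GwasTable, path, float_precision: int = 10) -> None:
    """Write a :class:`GwasTable` in the canonical tab-delimited dialect."""
    rows = [
        {
            "rsid": r.rsid,
            "chr": r.chromosome,
            "pos": r.position,
            "ea": r.effect_allele,
            "nea": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pval": r.pvalue,
        }
        for r in table.records
    ]
    frame = pd.DataFrame(rows, columns=list(DEFAULT_COLUMN_MAP))
    frame.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep=MISSING_TOKEN,
        float_format=f"%.{float_precision}g",
    )


def write_results_table(
    rows: Iterable[Mapping[str, object]],
    path,
    columns: Sequence[str] = RESULT_COLUMNS,
    float_precision: int = 6,
) -> None:
    """Write analysis result records as a tab-delimited table.

    Missing optional fields (``None``/NaN) are rendered as ``NA``.
    """
    frame = pd.DataFrame(list(rows))
    if frame.empty:
        frame = pd.DataFrame(columns=list(columns))
    else:
        for col in columns:
            if col not in frame.columns:
                frame[col] = None
        frame = frame[list(columns)]
    frame.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep=MISSING_TOKEN,
        float_format=f"%.{float_precision}g",
    )


def read_results_table(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False)
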