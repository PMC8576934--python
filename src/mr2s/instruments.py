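"""Instrument selection, LD pruning, allele harmonization and pleiotropy
screening for two-sample Mendelian randomization.

The stages form a funnel:

    significance filter -> LD prune -> exposure/outcome harmonization
    -> confounder screen

and each stage is a pure function from tables to tables so counts can be
logged and audited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import HarmonizationError, ValidationError
from .summary_io import GwasTable, SnpAssociation

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Harmonization actions.
KEPT = "kept"
ALLELE_FLIPPED = "allele_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_UNMATCHED = "dropped_unmatched"


class LdMatrix:
    """Symmetric pairwise LD (r-squared) lookup keyed by unordered rsid pair.

    Missing pairs are treated as r^2 = 0 with a warning by default
    (``missing='zero'``); ``missing='strict'`` raises instead.
    """

    def __init__(self, entries: Mapping | None = None, missing: str = "zero"):
        if missing not in {"zero", "strict"}:
            raise ValidationError(f"missing policy must be 'zero' or 'strict', got {missing!r}")
        self.missing = missing
        self.n_missing_lookups = 0
        self._entries: dict[frozenset, float] = {}
        if entries:
            for key, value in entries.items():
                pair = frozenset(key)
                self._set(pair, float(value))

    def _set(self, pair: frozenset, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"r2 {r2} outside [0,1] for pair {sorted(pair)}")
        if len(pair) == 1 and not math.isclose(r2, 1.0):
            raise ValidationError(f"self-pair r2 must be 1, got {r2} for {sorted(pair)}")
        self._entries[pair] = r2

    def add(self, rsid_a: str, rsid_b: str, r2: float) -> None:
        self._set(frozenset((rsid_a, rsid_b)), float(r2))

    def r2(self, rsid_a: str, rsid_b: str) -> float:
        if rsid_a == rsid_b:
            return 1.0
        pair = frozenset((rsid_a, rsid_b))
        if pair in self._entries:
            return self._entries[pair]
        if self.missing == "strict":
            raise ValidationError(f"no LD entry for pair ({rsid_a}, {rsid_b})")
        if self.n_missing_lookups == 0 and self._entries:
            logger.warning(
                "LD pair (%s, %s) missing; assuming r2 = 0 (further misses logged at debug)",
                rsid_a, rsid_b,
            )
        else:
            logger.debug("LD pair (%s, %s) missing; assuming r2 = 0", rsid_a, rsid_b)
        self.n_missing_lookups += 1
        return 0.0

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_file(cls, path, missing: str = "zero") -> "LdMatrix":
        """Read a three-column tab-delimited file: rsid_a, rsid_b, r2."""
        frame = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
        for col in ("rsid_a", "rsid_b", "r2"):
            if col not in frame.columns:
                raise ValidationError(f"LD file {path} lacks column {col!r}")
        matrix = cls(missing=missing)
        for row in frame.itertuples(index=False):
            matrix.add(row.rsid_a, row.rsid_b, float(row.r2))
        return matrix


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An instrument aligned across the exposure and outcome samples.

    ``gamma``/``se_gamma`` are the SNP-exposure effect and SE, and
    ``Gamma``/``se_Gamma`` the SNP-outcome effect and SE, all expressed per
    copy of the same effect allele.  Dropped records carry NaN effects.
    """

    rsid: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    eaf_exposure: float
    eaf_outcome: float
    action: str

    @property
    def usable(self) -> bool:
        return self.action in (KEPT, ALLELE_FLIPPED)


def select_by_significance(table: GwasTable, threshold: float = 5e-8) -> GwasTable:
    """Keep associations with p strictly below ``threshold`` (order kept)."""
    return table.with_records([r for r in table.records if r.pvalue < threshold])


def ld_prune(table: GwasTable, ld: LdMatrix | None = None, r2_threshold: float = 0.1) -> GwasTable:
    """Greedy LD pruning.

    SNPs are visited in ascending p-value (ties broken by rsid so the result
    is deterministic); a SNP is kept iff its r^2 with every already-kept SNP
    is at most ``r2_threshold``.  The kept set is returned in the original
    table order.
    """
    if ld is None:
        ld = LdMatrix()
    ordered = sorted(table.records, key=lambda r: (r.pvalue, r.rsid))
    kept: list[str] = []
    for rec in ordered:
        if all(ld.r2(rec.rsid, other) <= r2_threshold for other in kept):
            kept.append(rec.rsid)
    kept_set = set(kept)
    return table.with_records([r for r in table.records if r.rsid in kept_set])


def is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def _dropped(rec: SnpAssociation, outcome_eaf: float, action: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        rsid=rec.rsid,
        gamma=math.nan,
        se_gamma=math.nan,
        Gamma=math.nan,
        se_Gamma=math.nan,
        eaf_exposure=rec.eaf_or_nan,
        eaf_outcome=outcome_eaf,
        action=action,
    )


def harmonize_pair(
    exposure: GwasTable,
    outcome: GwasTable,
    palindromic_eaf_window: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Rules, applied per exposure SNP found in the outcome table:

    * same allele orientation (directly or on the complementary strand):
      keep the outcome effect as-is;
    * swapped effect/other alleles: negate the outcome beta and reflect its
      EAF (``action='allele_flipped'``);
    * palindromic pair (A/T or C/G): strand is ambiguous, so orient by
      allele frequency — usable only when both EAFs are present, both are
      farther than ``palindromic_eaf_window`` from 0.5, and the frequencies
      agree under the chosen orientation; otherwise the SNP is dropped
      (``action='dropped_palindromic'``);
    * exposure SNP absent from the outcome: ``action='dropped_unmatched'``.

    An allele pair that cannot be reconciled even after strand complement
    raises :class:`~mr2s.exceptions.HarmonizationError`.
    """
    out: list[HarmonizedInstrument] = []
    for rec in exposure.records:
        other = outcome.get(rec.rsid)
        if other is None:
            out.append(_dropped(rec, math.nan, DROPPED_UNMATCHED))
            continue
        ea_x, oa_x = rec.effect_allele, rec.other_allele
        ea_y, oa_y = other.effect_allele, other.other_allele
        eaf_y = other.eaf_or_nan

        if is_palindromic(ea_x, oa_x) != is_palindromic(ea_y, oa_y):
            raise HarmonizationError(
                f"{rec.rsid}: alleles {ea_x}/{oa_x} vs {ea_y}/{oa_y} are incompatible"
            )

        if is_palindromic(ea_x, oa_x):
            inst = _harmonize_palindromic(rec, other, palindromic_eaf_window)
            out.append(inst)
            continue

        comp_pair = (COMPLEMENT[ea_y], COMPLEMENT[oa_y])
        if (ea_y, oa_y) == (ea_x, oa_x) or comp_pair == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x) or comp_pair == (oa_x, ea_x):
            flip = True
        else:
            raise HarmonizationError(
                f"{rec.rsid}: alleles {ea_x}/{oa_x} vs {ea_y}/{oa_y} are incompatible"
            )
        out.append(
            HarmonizedInstrument(
                rsid=rec.rsid,
                gamma=rec.beta,
                se_gamma=rec.se,
                Gamma=-other.beta if flip else other.beta,
                se_Gamma=other.se,
                eaf_exposure=rec.eaf_or_nan,
                eaf_outcome=1.0 - eaf_y if flip else eaf_y,
                action=ALLELE_FLIPPED if flip else KEPT,
            )
        )
    return out


def _harmonize_palindromic(
    rec: SnpAssociation, other: SnpAssociation, window: float
) -> HarmonizedInstrument:
    eaf_x = rec.eaf_or_nan
    eaf_y = other.eaf_or_nan
    if math.isnan(eaf_x) or math.isnan(eaf_y):
        return _dropped(rec, eaf_y, DROPPED_PALINDROMIC)
    if abs(eaf_x - 0.5) <= window or abs(eaf_y - 0.5) <= window:
        return _dropped(rec, eaf_y, DROPPED_PALINDROMIC)

    # Align allele labels first (for a palindromic SNP the outcome's effect
    # allele is either the exposure's effect allele or its other allele, up
    # to strand complement, which leaves the label set unchanged).
    if other.effect_allele in (rec.effect_allele, COMPLEMENT[rec.effect_allele]):
        beta_y, freq_y = other.beta, eaf_y
        label_flip = False
    else:
        beta_y, freq_y = -other.beta, 1.0 - eaf_y
        label_flip = True

    # Frequencies on the same side of 0.5 -> orientation consistent; on
    # opposite sides -> the outcome is reported for the complementary
    # strand's allele, so flip.
    if (eaf_x - 0.5) * (freq_y - 0.5) > 0:
        flip = False
    else:
        beta_y, freq_y = -beta_y, 1.0 - freq_y
        flip = True
    return HarmonizedInstrument(
        rsid=rec.rsid,
        gamma=rec.beta,
        se_gamma=rec.se,
        Gamma=beta_y,
        se_Gamma=other.se,
        eaf_exposure=eaf_x,
        eaf_outcome=freq_y,
        action=ALLELE_FLIPPED if (flip ^ label_flip) else KEPT,
    )


@dataclass(frozen=True)
class Exclusion:
    """One instrument excluded by the confounder screen."""

    rsid: str
    trait: str
    pvalue: float
    threshold: float


def screen_pleiotropy(
    instruments: Sequence[HarmonizedInstrument],
    confounder_tables: Iterable[GwasTable] = (),
    threshold: float = 5e-8,
) -> tuple[list[HarmonizedInstrument], list[Exclusion]]:
    """Drop instruments genome-wide associated with any confounder trait.

    Returns the kept instruments and a report with one row per excluded
    (rsid, trait) hit; an instrument hitting several traits appears once
    per trait but is excluded once.  Kept + excluded partition the input.
    """
    tables = list(confounder_tables)
    kept: list[HarmonizedInstrument] = []
    report: list[Exclusion] = []
    for inst in instruments:
        hits = [
            Exclusion(inst.rsid, t.trait_name, rec.pvalue, threshold)
            for t in tables
            if (rec := t.get(inst.rsid)) is not None and rec.pvalue < threshold
        ]
        if hits:
            report.extend(hits)
        else:
            kept.append(inst)
    return kept, report


def write_exclusion_report(report: Sequence[Exclusion], path) -> None:
    frame = pd.DataFrame(
        [(e.rsid, e.trait, e.pvalue, e.threshold) for e in report],
        columns=["rsid", "trait", "pvalue", "threshold"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
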