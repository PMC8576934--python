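"""End-to-end orchestration for exposure-outcome pairs.

``run_pair`` drives the funnel (significance filter, LD pruning,
harmonization, confounder screen, QC, estimators), applies method gating
(weighted median, Egger and PRESSO need at least 3 instruments; IVW always
runs and reduces to the Wald ratio at J = 1), rescales estimates to the
configured exposure unit, and applies the headline decision rule: a
significant Egger intercept switches the primary estimate from IVW to
MR-PRESSO.  ``run_grid`` maps this over a grid of pairs, isolating
failures, and emits long- and wide-format result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import estimators as est
from .exceptions import CorrectionError, ValidationError
from .instruments import (
    Exclusion,
    HarmonizedInstrument,
    LdMatrix,
    harmonize_pair,
    ld_prune,
    screen_pleiotropy,
    select_by_significance,
    write_exclusion_report,
)
from .qc import QcRecord, qc_report, write_qc_table
from .summary_io import RESULT_COLUMNS, GwasTable, write_results_table

logger = logging.getLogger(__name__)

PRIMARY_IVW = "ivw"
PRIMARY_PRESSO = "presso"


@dataclass
class AnalysisConfig:
    """Tuning knobs for a full pair analysis.

    ``unit_scale`` multiplies causal estimates, SEs and CI bounds (e.g.
    0.05 for effects per 0.05-unit increase in the exposure); ``alpha`` is
    the two-sided decision level.
    """

    significance_threshold: float = 5e-8
    r2_threshold: float = 0.1
    confounder_threshold: float = 5e-8
    palindromic_eaf_window: float = 0.08
    ivw_model: str = "auto"
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    unit_scale: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.significance_threshold <= 1.0:
            raise ValidationError("significance_threshold must lie in [0,1]")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValidationError("r2_threshold must lie in [0,1]")
        if not 0.0 <= self.confounder_threshold <= 1.0:
            raise ValidationError("confounder_threshold must lie in [0,1]")
        if not 0.0 <= self.palindromic_eaf_window < 0.5:
            raise ValidationError("palindromic_eaf_window must lie in [0,0.5)")
        if not self.unit_scale > 0:
            raise ValidationError("unit_scale must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0,1)")
        if self.ivw_model not in {"fixed", "random", "auto"}:
            raise ValidationError("ivw_model must be fixed|random|auto")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in mapping.items()})

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_mapping(data)


@dataclass(frozen=True)
class ResultsRow:
    """One (exposure, outcome, method) line of the results grid."""

    exposure: str
    outcome: str
    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    q_stat: float | None
    q_pval: float | None
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    presso_global_pval: float | None
    pleiotropy_flag: bool | None
    primary_method: str
    flags: str = ""

    def to_dict(self) -> dict:
        out = {c: getattr(self, c) for c in RESULT_COLUMNS}
        out["pleiotropy_flag"] = self.pleiotropy_flag
        out["primary_method"] = self.primary_method
        return out


@dataclass
class PairResult:
    """Everything produced for one exposure-outcome pair."""

    exposure: str
    outcome: str
    rows: list[ResultsRow]
    stage_counts: dict[str, int]
    exclusions: list[Exclusion] = field(default_factory=list)
    qc_records: list[QcRecord] = field(default_factory=list)
    qc_summary: dict = field(default_factory=dict)
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    primary_method: str = PRIMARY_IVW
    notes: list[str] = field(default_factory=list)


def pair_seed(base_seed: int, exposure: str, outcome: str) -> int:
    """Stable per-pair seed independent of grid iteration order."""
    digest = hashlib.sha256(f"{base_seed}|{exposure}|{outcome}".encode()).digest()
    return int.from_bytes(digest[:8], "big")


def decide_primary(rows: Sequence[ResultsRow], alpha: float = 0.05) -> str:
    """Headline-method rule.

    When the Egger intercept is significant at ``alpha`` the MR-PRESSO
    estimate prevails (outlier-corrected when outliers were found);
    otherwise IVW is the primary method.  With fewer than 3 instruments no
    Egger row exists and IVW is primary by default.
    """
    egger_rows = [r for r in rows if r.method == est.EGGER]
    if not egger_rows:
        return PRIMARY_IVW
    intercept_p = egger_rows[0].egger_intercept_pval
    if intercept_p is not None and intercept_p < alpha:
        return PRIMARY_PRESSO
    return PRIMARY_IVW


def _row_from_estimate(
    exposure: str,
    outcome: str,
    estimate: est.MrEstimate,
    presso_global_pval: float | None = None,
    flags: str = "",
) -> ResultsRow:
    return ResultsRow(
        exposure=exposure,
        outcome=outcome,
        method=estimate.method,
        n_snp=estimate.n_snps,
        beta=estimate.beta,
        se=estimate.se,
        ci_low=estimate.ci_low,
        ci_high=estimate.ci_high,
        pval=estimate.pvalue,
        q_stat=estimate.q_stat,
        q_pval=estimate.q_pvalue,
        egger_intercept=estimate.intercept,
        egger_intercept_se=estimate.intercept_se,
        egger_intercept_pval=estimate.intercept_pvalue,
        presso_global_pval=presso_global_pval,
        pleiotropy_flag=None,
        primary_method=PRIMARY_IVW,
        flags=flags,
    )


def run_pair(
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LdMatrix | None = None,
    confounders: Iterable[GwasTable] = (),
    config: AnalysisConfig | None = None,
) -> PairResult:
    """Run the full analysis for one exposure-outcome pair.

    Returns a :class:`PairResult`; an empty instrument set after screening
    yields an empty row list with an explanatory note rather than an error.
    """
    cfg = config or AnalysisConfig()
    counts: dict[str, int] = {"input": len(exposure)}
    notes: list[str] = []

    selected = select_by_significance(exposure, cfg.significance_threshold)
    counts["selected"] = len(selected)
    pruned = ld_prune(selected, ld, cfg.r2_threshold)
    counts["pruned"] = len(pruned)
    harmonized = harmonize_pair(pruned, outcome, cfg.palindromic_eaf_window)
    usable = [h for h in harmonized if h.usable]
    counts["harmonized"] = len(usable)
    kept, exclusions = screen_pleiotropy(usable, confounders, cfg.confounder_threshold)
    counts["screened"] = len(kept)
    logger.info(
        "%s vs %s: input=%d selected=%d pruned=%d harmonized=%d screened=%d",
        exposure.trait_name, outcome.trait_name, counts["input"], counts["selected"],
        counts["pruned"], counts["harmonized"], counts["screened"],
    )

    result = PairResult(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        rows=[],
        stage_counts=counts,
        exclusions=exclusions,
        instruments=kept,
        notes=notes,
    )
    if not kept:
        notes.append("no instruments remain after screening; nothing to estimate")
        logger.warning("%s vs %s: %s", exposure.trait_name, outcome.trait_name, notes[-1])
        return result

    kept_rsids = {h.rsid for h in kept}
    if exposure.trait_variance is not None:
        qc_table = pruned.with_records([r for r in pruned.records if r.rsid in kept_rsids])
        result.qc_records, result.qc_summary = qc_report(qc_table)
    else:
        notes.append("trait_variance not set; instrument-strength QC skipped")

    seed = pair_seed(cfg.seed, exposure.trait_name, outcome.trait_name)
    J = len(kept)
    rows: list[ResultsRow] = []

    estimate = est.ivw(kept, model=cfg.ivw_model).scaled(cfg.unit_scale)
    rows.append(_row_from_estimate(exposure.trait_name, outcome.trait_name, estimate))

    if J >= 3:
        wm = est.weighted_median(kept, n_boot=cfg.n_boot, seed=seed).scaled(cfg.unit_scale)
        rows.append(_row_from_estimate(exposure.trait_name, outcome.trait_name, wm))
        egger = est.mr_egger(kept).scaled(cfg.unit_scale)
        rows.append(_row_from_estimate(exposure.trait_name, outcome.trait_name, egger))
        try:
            presso = est.mr_presso(
                kept,
                n_sim=cfg.n_sim,
                signif_threshold=cfg.alpha,
                seed=seed + 1,
                ivw_model=cfg.ivw_model,
            )
        except CorrectionError as exc:
            notes.append(f"MR-PRESSO correction failed: {exc}")
        else:
            chosen = presso.corrected_estimate or presso.raw_estimate
            flags = ""
            if presso.outlier_rsids:
                flags = "outliers:" + ",".join(presso.outlier_rsids)
            rows.append(
                _row_from_estimate(
                    exposure.trait_name,
                    outcome.trait_name,
                    chosen.scaled(cfg.unit_scale),
                    presso_global_pval=presso.global_pvalue,
                    flags=flags,
                )
            )
    else:
        notes.append(
            f"{J} instrument(s): weighted median, MR-Egger and MR-PRESSO require a minimum "
            "of 3 IVs and were not run"
        )

    primary = decide_primary(rows, cfg.alpha)
    egger_p = next(
        (r.egger_intercept_pval for r in rows if r.method == est.EGGER), None
    )
    flag = (egger_p is not None and egger_p < cfg.alpha) if J >= 3 else None
    result.rows = [
        dataclasses.replace(row, pleiotropy_flag=flag, primary_method=primary) for row in rows
    ]
    result.primary_method = primary
    return result


@dataclass
class GridResult:
    pairs: list[PairResult]
    errors: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def rows(self) -> list[ResultsRow]:
        return [row for pair in self.pairs for row in pair.rows]

    def long_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.rows])

    def matrix_frame(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wide method-by-pair matrix of causal estimates.

        Cells hold the estimate formatted to 4 significant digits with a
        trailing ``*`` marking two-sided p < ``alpha``.
        """
        cells: dict[str, dict[str, str]] = {}
        for row in self.rows:
            col = f"{row.exposure}|{row.outcome}"
            star = "*" if row.pval < alpha else ""
            cells.setdefault(row.method, {})[col] = f"{row.beta:.4g}{star}"
        frame = pd.DataFrame(cells).T.sort_index()
        frame.index.name = "method"
        return frame


def run_grid(
    exposures: Sequence[GwasTable],
    outcomes: Sequence[GwasTable],
    ld: LdMatrix | None = None,
    confounders: Iterable[GwasTable] = (),
    config: AnalysisConfig | None = None,
    unit_scales: Mapping[str, float] | None = None,
) -> GridResult:
    """Run every exposure-outcome pair independently.

    ``unit_scales`` optionally overrides ``config.unit_scale`` per exposure
    name.  A failing pair is recorded in ``errors`` and does not abort the
    others.
    """
    cfg = config or AnalysisConfig()
    confounders = list(confounders)
    result = GridResult(pairs=[])
    for exposure in exposures:
        pair_cfg = cfg
        if unit_scales and exposure.trait_name in unit_scales:
            pair_cfg = AnalysisConfig(
                **{**cfg.__dict__, "unit_scale": unit_scales[exposure.trait_name]}
            )
        for outcome in outcomes:
            try:
                result.pairs.append(run_pair(exposure, outcome, ld, confounders, pair_cfg))
            except Exception as exc:  # noqa: BLE001 - grid isolation by contract
                logger.error(
                    "pair %s vs %s failed: %s", exposure.trait_name, outcome.trait_name, exc
                )
                result.errors[(exposure.trait_name, outcome.trait_name)] = str(exc)
    return result


def write_grid(result: GridResult, outdir, alpha: float = 0.05) -> None:
    """Write results.tsv, matrix.tsv, qc.tsv and exclusions.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_results_table(
        [r.to_dict() for r in result.rows],
        outdir / "results.tsv",
        columns=list(RESULT_COLUMNS) + ["pleiotropy_flag", "primary_method"],
    )
    result.matrix_frame(alpha).to_csv(outdir / "matrix.tsv", sep="\t")
    qc_rows = [rec for pair in result.pairs for rec in pair.qc_records]
    write_qc_table(qc_rows, outdir / "qc.tsv")
    write_exclusion_report(
        [e for pair in result.pairs for e in pair.exclusions], outdir / "exclusions.tsv"
    )
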