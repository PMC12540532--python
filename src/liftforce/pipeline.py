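"""End-to-end workflow: simulate (or ingest) -> extract -> trim -> analyze.

``run_pipeline`` ties the modules together and produces the three report
tables the validation question needs:

* a per-trial measures table (nine force/timing measures plus the
  perceptual %-score),
* the 2 x 2 repeated-measures ANOVA and switch-contrast report, one row
  per measure x effect,
* the handle-vs-platform agreement report — ICC(3,1) for the PLFR<->PPFR,
  LF1st<->PF1st and LPD1<->LPD2 pairs, split by the four transition
  conditions (heavy-after-heavy, heavy-after-light, light-after-light,
  light-after-heavy).

Every absent or trimmed value is logged with its reason and collected in an
exclusions table; a trial failing extraction never aborts the cohort.  The
whole run is deterministic given the global seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .design import DISCARD, HEAVY, LIGHT, NO_SWITCH, SWITCH
from .exceptions import (
    InsufficientDataError,
    LiftForceError,
    UndefinedStatisticError,
)
from .io import read_session, write_measures
from .measures import (
    HANDLE_PLATFORM_PAIRS,
    MEASURE_NAMES,
    ExtractionConfig,
    condition_means,
    extract_measures,
    percent_scores,
    trim_outliers,
)
from .simulate import TrialRecord, simulate_cohort
from .stats import PairedAgreement, TwoWayRepeatedAnova

logger = logging.getLogger("liftforce")

#: Analysis variables: perceptual score first, then the nine force measures.
ANALYSIS_VARIABLES = ("pct_score",) + tuple(MEASURE_NAMES)

#: Transition-condition names, as (cube, switch) cells.
CONDITION_CELLS = {
    "heavy_after_heavy": (HEAVY, NO_SWITCH),
    "heavy_after_light": (HEAVY, SWITCH),
    "light_after_light": (LIGHT, NO_SWITCH),
    "light_after_heavy": (LIGHT, SWITCH),
}


@dataclass
class PipelineResult:
    """All tables produced by one run."""

    measures: pd.DataFrame
    cell_means: pd.DataFrame
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    icc: pd.DataFrame
    exclusions: pd.DataFrame
    summary_text: str


def extract_cohort(
    records: list[TrialRecord], config: ExtractionConfig = ExtractionConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract the measures table from a list of trials.

    Returns the per-trial table and an exclusions table with one row per
    absent measure (participant, trial, measure, reason).
    """
    rows = []
    exclusions = []
    for rec in records:
        try:
            tm = extract_measures(rec, config)
        except LiftForceError as exc:
            logger.warning(
                "extraction failed for %s trial %d: %s",
                rec.participant_id,
                rec.trial_index,
                exc,
            )
            tm = None
        row = {
            "participant_id": rec.participant_id,
            "trial_index": rec.trial_index,
            "cube": rec.condition.cube,
            "switch": rec.condition.switch,
            "magnitude_estimate": rec.magnitude_estimate,
        }
        if tm is None:
            row.update(dict.fromkeys(MEASURE_NAMES, np.nan))
            absent = dict.fromkeys(MEASURE_NAMES, "trace extraction failed")
        else:
            row.update(
                {k: (np.nan if v is None else v) for k, v in tm.as_dict().items()}
            )
            absent = tm.absent
        rows.append(row)
        for measure, reason in absent.items():
            logger.debug(
                "%s trial %d: %s absent: %s",
                rec.participant_id,
                rec.trial_index,
                measure,
                reason,
            )
            exclusions.append(
                {
                    "participant_id": rec.participant_id,
                    "trial_index": rec.trial_index,
                    "measure": measure,
                    "stage": "extraction",
                    "reason": reason,
                }
            )
    measures = pd.DataFrame(rows)
    exclusion_cols = ["participant_id", "trial_index", "measure", "stage", "reason"]
    return measures, pd.DataFrame(exclusions, columns=exclusion_cols)


def add_percent_scores(
    measures: pd.DataFrame, literal_sign: bool = False
) -> pd.DataFrame:
    """Attach per-participant %-scores computed over the analyzable trials."""
    out = measures.copy()
    out["pct_score"] = np.nan
    for participant, group in out.groupby("participant_id", sort=False):
        analyzable = group["switch"] != DISCARD
        idx = group.index[analyzable]
        scores = percent_scores(
            group.loc[idx, "magnitude_estimate"].to_numpy(), literal_sign
        )
        out.loc[idx, "pct_score"] = scores
    return out


def trim_measures(
    measures: pd.DataFrame, k: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the +/- k SD trimming rule per participant x measure x cube.

    Switch levels are pooled within each cube so trace-level artifacts are
    removed without erasing switch effects.  Trimmed entries become NaN in
    the returned copy; the second frame logs each exclusion.
    """
    out = measures.copy()
    exclusions = []
    analyzable = out["switch"] != DISCARD
    for variable in ANALYSIS_VARIABLES:
        if variable not in out.columns:
            continue
        for (participant, cube), group in out[analyzable].groupby(
            ["participant_id", "cube"], sort=False
        ):
            values = group[variable]
            present = values.notna()
            if present.sum() < 2:
                continue
            mask = trim_outliers(values[present].to_numpy(), k=k)
            dropped_idx = values[present].index[~mask]
            for idx in dropped_idx:
                logger.debug(
                    "%s trial %d: %s = %.4g trimmed (> %.0f SD within %s)",
                    participant,
                    out.loc[idx, "trial_index"],
                    variable,
                    out.loc[idx, variable],
                    k,
                    cube,
                )
                exclusions.append(
                    {
                        "participant_id": participant,
                        "trial_index": out.loc[idx, "trial_index"],
                        "measure": variable,
                        "stage": "trimming",
                        "reason": f"beyond {k:g} SD of the participant's {cube} trials",
                    }
                )
            out.loc[dropped_idx, variable] = np.nan
    exclusion_cols = ["participant_id", "trial_index", "measure", "stage", "reason"]
    return out, pd.DataFrame(exclusions, columns=exclusion_cols)


def anova_report(
    cell_means: pd.DataFrame, run: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One 2 x 2 RM-ANOVA (with switch contrasts) per analysis variable."""
    anova_rows = []
    contrast_rows = []
    for variable in ANALYSIS_VARIABLES:
        sub = cell_means[cell_means["measure"] == variable]
        if sub.empty:
            continue
        note = ""
        try:
            model = TwoWayRepeatedAnova.from_dataframe(sub)
            result = model.fit(
                d_variant=run.d_variant, correction_family_size=run.bonferroni_family
            )
        except (InsufficientDataError, LiftForceError) as exc:
            note = str(exc)
            logger.info("ANOVA for %s not computed: %s", variable, note)
            anova_rows.append(
                {
                    "measure": variable,
                    "effect": "",
                    "n": int(sub["participant_id"].nunique()),
                    "F": np.nan,
                    "df_num": np.nan,
                    "df_den": np.nan,
                    "p": np.nan,
                    "partial_eta_sq": np.nan,
                    "note": note,
                }
            )
            continue
        if model.n_dropped:
            note = f"{model.n_dropped} participant(s) dropped (incomplete cells)"
            logger.info("ANOVA for %s: %s", variable, note)
        for eff in result.effects.values():
            anova_rows.append(
                {
                    "measure": variable,
                    "effect": eff.name,
                    "n": result.n,
                    "F": eff.F,
                    "df_num": eff.df_num,
                    "df_den": eff.df_den,
                    "p": eff.p,
                    "partial_eta_sq": eff.partial_eta_sq,
                    "note": "degenerate (zero error variance)"
                    if eff.degenerate
                    else note,
                }
            )
        for c in result.contrasts:
            contrast_rows.append(
                {
                    "measure": variable,
                    "cube": c.cube,
                    "n": result.n,
                    "mean_difference": c.mean_difference,
                    "t": c.t,
                    "df": c.df,
                    "p_bonferroni": c.p_bonferroni,
                    "cohens_d": c.cohens_d,
                    "d_variant": c.d_variant,
                    "note": "degenerate (zero-variance differences)"
                    if c.degenerate
                    else note,
                }
            )
    anova_cols = [
        "measure", "effect", "n", "F", "df_num", "df_den", "p",
        "partial_eta_sq", "note",
    ]
    contrast_cols = [
        "measure", "cube", "n", "mean_difference", "t", "df", "p_bonferroni",
        "cohens_d", "d_variant", "note",
    ]
    return (
        pd.DataFrame(anova_rows, columns=anova_cols),
        pd.DataFrame(contrast_rows, columns=contrast_cols),
    )


def icc_report(cell_means: pd.DataFrame, run: RunConfig) -> pd.DataFrame:
    """Handle-vs-platform ICC(3,1) per measure pair and transition condition."""
    wide = cell_means.pivot_table(
        index=["participant_id", "cube", "switch"],
        columns="measure",
        values="value",
        aggfunc="mean",
    ).reset_index()
    rows = []
    for handle_m, platform_m in HANDLE_PLATFORM_PAIRS:
        for condition, (cube, switch) in CONDITION_CELLS.items():
            sub = wide[(wide["cube"] == cube) & (wide["switch"] == switch)]
            pair = sub[[handle_m, platform_m]].to_numpy(dtype=float)
            complete = int(np.isfinite(pair).all(axis=1).sum())
            row = {
                "comparison": f"{handle_m}_vs_{platform_m}",
                "condition": condition,
                "n": complete,
                "icc": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "band": "",
                "note": "",
            }
            try:
                res = PairedAgreement(pair).fit(
                    form=run.icc_form, boundary=run.icc_boundary
                )
                row.update(
                    icc=res.estimate, ci_low=res.ci_low, ci_high=res.ci_high,
                    band=res.band,
                )
            except (InsufficientDataError, UndefinedStatisticError) as exc:
                row["note"] = str(exc)
                logger.info(
                    "ICC %s / %s not computed: %s", handle_m, condition, exc
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _summary_text(
    anova: pd.DataFrame, contrasts: pd.DataFrame, icc: pd.DataFrame
) -> str:
    lines = ["Lifting-force analysis summary", "=" * 30, ""]
    lines.append("2 x 2 repeated-measures ANOVAs (cube x switch)")
    for variable in ANALYSIS_VARIABLES:
        sub = anova[anova["measure"] == variable]
        if sub.empty:
            continue
        lines.append(f"  {variable}:")
        for _, row in sub.iterrows():
            if row["note"] and not row["effect"]:
                lines.append(f"    not analyzed: {row['note']}")
                continue
            if np.isnan(row["F"]):
                lines.append(f"    {row['effect']}: {row['note']}")
                continue
            lines.append(
                f"    {row['effect']}: F({row['df_num']:.0f}, {row['df_den']:.0f}) "
                f"= {row['F']:.2f}, p = {row['p']:.4g}, "
                f"partial eta^2 = {row['partial_eta_sq']:.2f}"
            )
        for _, row in contrasts[contrasts["measure"] == variable].iterrows():
            if np.isnan(row["t"]):
                lines.append(f"    {row['cube']} switch contrast: {row['note']}")
                continue
            lines.append(
                f"    {row['cube']} switch vs no-switch: mean diff = "
                f"{row['mean_difference']:.3f}, t({row['df']:.0f}) = {row['t']:.2f}, "
                f"p = {row['p_bonferroni']:.4g}, d = {row['cohens_d']:.2f}"
            )
    lines.append("")
    lines.append("Handle vs platform agreement, ICC(3,1)")
    for _, row in icc.iterrows():
        if row["note"]:
            lines.append(
                f"  {row['comparison']} {row['condition']}: {row['note']}"
            )
        else:
            lines.append(
                f"  {row['comparison']} {row['condition']}: "
                f"ICC = {row['icc']:.2f} [{row['ci_low']:.2f}, "
                f"{row['ci_high']:.2f}] ({row['band']})"
            )
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: RunConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Run the full workflow and optionally write all report files.

    When ``config.input_manifest`` is set the cohort is read from disk;
    otherwise it is simulated under ``config.seed``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.input_manifest:
        records = read_session(config.input_manifest)
        logger.info("ingested %d trials from %s", len(records), config.input_manifest)
    else:
        records = simulate_cohort(config.simulation_config())
        logger.info(
            "simulated %d trials (%d participants)",
            len(records),
            config.n_participants,
        )
    measures, absences = extract_cohort(records, config.extraction_config())
    measures = add_percent_scores(measures, config.literal_percent_sign)
    trimmed, trim_log = trim_measures(measures, k=config.trim_k)
    exclusions = pd.concat([absences, trim_log], ignore_index=True)
    logger.info(
        "%d absent values at extraction, %d values trimmed",
        len(absences),
        len(trim_log),
    )
    cells = condition_means(
        trimmed, measure_columns=list(ANALYSIS_VARIABLES), strict=False
    )
    anova, contrasts = anova_report(cells, config)
    icc = icc_report(cells, config)
    summary = _summary_text(anova, contrasts, icc)
    result = PipelineResult(
        measures=trimmed,
        cell_means=cells,
        anova=anova,
        contrasts=contrasts,
        icc=icc,
        exclusions=exclusions,
        summary_text=summary,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_measures(out_dir / "measures.csv", trimmed)
        cells.to_csv(out_dir / "cell_means.csv", index=False, na_rep="")
        anova.to_csv(out_dir / "anova.csv", index=False, na_rep="")
        contrasts.to_csv(out_dir / "contrasts.csv", index=False, na_rep="")
        icc.to_csv(out_dir / "icc.csv", index=False, na_rep="")
        exclusions.to_csv(out_dir / "exclusions.csv", index=False, na_rep="")
        (out_dir / "summary.txt").write_text(summary)
        logger.info("reports written to %s", out_dir)
    return result
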