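"""Inferential layer: ICC(3,1) agreement and 2 x 2 repeated-measures ANOVA.

Two model classes drive the analysis, in the statsmodels idiom of a model
object built from data whose ``fit()`` returns a results object:

* :class:`PairedAgreement` — concurrent validity of two fixed measurement
  methods applied to the same subjects.  ``fit()`` computes the two-way
  mixed-effects, single-measure, *consistency* intraclass correlation
  ICC(3,1) with exact-F 95% confidence limits and the conventional
  poor / moderate / good / excellent interpretation bands (<.50, .50-.75,
  .75-.90, >.90).  Absolute agreement ICC(A,1) is available for sensitivity
  analysis.
* :class:`TwoWayRepeatedAnova` — a 2 (cube) x 2 (switch) within-subject
  ANOVA.  With two-level factors each effect is an orthogonal
  within-subject contrast, so F = t^2 and sphericity holds trivially; the
  results carry F, (1, n-1) degrees of freedom, p, partial eta squared, and
  the two switch-vs-no-switch post-hoc contrasts with Bonferroni-corrected
  p-values and Cohen's d.

The functional entry points ``icc_3_1``, ``interpret_icc``,
``rm_anova_2x2``, ``switch_contrasts`` and ``cohens_d`` wrap the same code.
All sums of squares are computed here directly; no third-party ANOVA
routine stands behind these estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .design import HEAVY, LIGHT, NO_SWITCH, SWITCH
from .exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    MissingCellError,
    UndefinedStatisticError,
)

#: Fixed axis orders for 2 x 2 cell arrays: cells[:, cube, switch].
CUBE_LEVELS = (LIGHT, HEAVY)
SWITCH_LEVELS = (NO_SWITCH, SWITCH)

ICC_BANDS = ("poor", "moderate", "good", "excellent")
_ICC_EDGES = (0.50, 0.75, 0.90)


def interpret_icc(estimate: float, boundary: str = "lower") -> str:
    """Bin an ICC estimate into poor / moderate / good / excellent.

    The conventional ranges overlap at .50, .75 and .90; by default a
    boundary value falls in the lower-named band (``.75 -> moderate``).
    ``boundary="upper"`` assigns it to the upper band instead.
    """
    if not np.isfinite(estimate):
        raise InvalidArgumentError(f"ICC estimate must be finite, got {estimate}")
    if boundary not in ("lower", "upper"):
        raise InvalidArgumentError(f"boundary must be 'lower' or 'upper', got {boundary}")
    for band, edge in zip(ICC_BANDS, _ICC_EDGES):
        if (estimate <= edge) if boundary == "lower" else (estimate < edge):
            return band
    return ICC_BANDS[-1]


@dataclass(frozen=True)
class IccResult:
    """ICC point estimate, 95% confidence limits and interpretation band."""

    estimate: float
    ci_low: float
    ci_high: float
    band: str
    n: int
    k: int
    form: str
    ci_level: float
    ms_rows: float
    ms_cols: float
    ms_error: float

    def summary(self) -> str:
        pct = int(round(self.ci_level * 100))
        return (
            "Intraclass correlation, two-way mixed, single measure "
            f"({self.form})\n"
            f"  n = {self.n} subjects, k = {self.k} methods\n"
            f"  ICC = {self.estimate:.3f}, {pct}% CI "
            f"[{self.ci_low:.3f}, {self.ci_high:.3f}]  ->  {self.band} agreement"
        )


class PairedAgreement:
    """Agreement between fixed measurement methods rated on the same subjects.

    Parameters
    ----------
    ratings
        An ``(n, k)`` table (array or DataFrame), one row per subject and
        one column per method; rows containing any non-finite value are
        dropped before fitting.  The standard use here is ``k = 2``
        (handle vs platform).
    """

    def __init__(self, ratings) -> None:
        x = np.asarray(
            ratings.values if isinstance(ratings, pd.DataFrame) else ratings,
            dtype=float,
        )
        if x.ndim != 2 or x.shape[1] < 2:
            raise InvalidArgumentError(
                f"ratings must be a 2-D (n, k>=2) table, got shape {x.shape}"
            )
        self.ratings = x[np.isfinite(x).all(axis=1)]
        self.n_dropped = x.shape[0] - self.ratings.shape[0]

    def fit(
        self,
        form: str = "consistency",
        ci_level: float = 0.95,
        boundary: str = "lower",
    ) -> IccResult:
        x = self.ratings
        n, k = x.shape
        if n < 5:
            raise InsufficientDataError(
                f"need at least 5 complete subject pairs for an ICC, got {n}"
            )
        if form not in ("consistency", "absolute"):
            raise InvalidArgumentError(
                f"form must be 'consistency' or 'absolute', got {form!r}"
            )
        grand = x.mean()
        row_means = x.mean(axis=1)
        col_means = x.mean(axis=0)
        ss_total = float(((x - grand) ** 2).sum())
        if ss_total <= 0:
            raise UndefinedStatisticError("zero total variance: ICC undefined")
        ss_rows = k * float(((row_means - grand) ** 2).sum())
        ss_cols = n * float(((col_means - grand) ** 2).sum())
        ss_err = ss_total - ss_rows - ss_cols
        msr = ss_rows / (n - 1)
        msc = ss_cols / (k - 1)
        mse = ss_err / ((n - 1) * (k - 1))

        q = 1.0 - (1.0 - ci_level) / 2.0
        if form == "consistency":
            estimate = (msr - mse) / (msr + (k - 1) * mse)
            if mse <= 0:
                lo = hi = 1.0
            else:
                df1, df2 = n - 1, (n - 1) * (k - 1)
                fobs = msr / mse
                fl = fobs / scipy.stats.f.ppf(q, df1, df2)
                fu = fobs * scipy.stats.f.ppf(q, df2, df1)
                lo = (fl - 1.0) / (fl + k - 1.0)
                hi = (fu - 1.0) / (fu + k - 1.0)
        else:
            denom = msr + (k - 1) * mse + k * (msc - mse) / n
            estimate = (msr - mse) / denom
            if mse <= 0 and msc <= 0:
                lo = hi = 1.0
            else:
                # Satterthwaite-approximated F limits (standard exact-F form
                # for the single-measure absolute-agreement ICC).
                r = estimate
                a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
                b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r < 1 else np.inf
                if np.isinf(a) or np.isinf(b):
                    lo = hi = 1.0
                else:
                    nu = (a * msc + b * mse) ** 2 / (
                        (a * msc) ** 2 / (k - 1)
                        + (b * mse) ** 2 / ((n - 1) * (k - 1))
                    )
                    f1 = scipy.stats.f.ppf(q, n - 1, nu)
                    f2 = scipy.stats.f.ppf(q, nu, n - 1)
                    lo = (
                        n
                        * (msr - f1 * mse)
                        / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
                    )
                    hi = (
                        n
                        * (f2 * msr - mse)
                        / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
                    )
        return IccResult(
            estimate=float(estimate),
            ci_low=float(min(lo, estimate)),
            ci_high=float(max(hi, estimate)),
            band=interpret_icc(float(estimate), boundary),
            n=n,
            k=k,
            form=form,
            ci_level=ci_level,
            ms_rows=msr,
            ms_cols=msc,
            ms_error=mse,
        )


def icc_3_1(
    ratings, ci_level: float = 0.95, form: str = "consistency", boundary: str = "lower"
) -> IccResult:
    """ICC(3,1) of an (n, 2) table of paired measurements (see PairedAgreement)."""
    return PairedAgreement(ratings).fit(form=form, ci_level=ci_level, boundary=boundary)


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with the standardizer variant it used."""

    value: float
    variant: str
    degenerate: bool = False


def cohens_d(a, b=None, variant: str = "dz") -> EffectSize:
    """Cohen's d for paired data.

    ``dz`` standardizes the mean difference by the SD of the differences;
    ``dav`` by the average of the two condition SDs (requires both columns).
    A zero standardizer yields a degenerate flag, not an exception.
    """
    if variant not in ("dz", "dav"):
        raise InvalidArgumentError(f"variant must be 'dz' or 'dav', got {variant!r}")
    a = np.asarray(a, dtype=float)
    if b is None:
        if variant == "dav":
            raise InvalidArgumentError("dav requires both paired columns")
        diffs = a
    else:
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise InvalidArgumentError("paired columns must have equal length")
        diffs = a - b
    if diffs.size < 2:
        raise InvalidArgumentError("need at least 2 paired observations")
    mean = diffs.mean()
    if variant == "dz":
        sd = diffs.std(ddof=1)
    else:
        sd = (a.std(ddof=1) + b.std(ddof=1)) / 2.0
    if sd == 0:
        return EffectSize(value=float("nan"), variant=variant, degenerate=True)
    return EffectSize(value=float(mean / sd), variant=variant)


@dataclass(frozen=True)
class EffectResult:
    """One within-subject effect: F, df, p and partial eta squared."""

    name: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    degenerate: bool = False


@dataclass(frozen=True)
class ContrastResult:
    """A switch vs no-switch paired contrast within one cube level."""

    cube: str
    mean_difference: float
    t: float
    df: int
    p_uncorrected: float
    p_bonferroni: float
    cohens_d: float
    d_variant: str
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    """2 x 2 within-subject effects plus the two switch contrasts."""

    effects: dict[str, EffectResult]
    contrasts: tuple[ContrastResult, ...]
    n: int

    def summary(self) -> str:
        lines = [f"2 x 2 repeated-measures ANOVA, n = {self.n} participants"]
        for eff in self.effects.values():
            if eff.degenerate:
                lines.append(f"  {eff.name}: degenerate (zero error variance)")
            else:
                lines.append(
                    f"  {eff.name}: F({eff.df_num}, {eff.df_den}) = {eff.F:.2f}, "
                    f"p = {eff.p:.4g}, partial eta^2 = {eff.partial_eta_sq:.3f}"
                )
        lines.append("  Switch vs no-switch contrasts (Bonferroni-corrected):")
        for c in self.contrasts:
            if c.degenerate:
                lines.append(f"    {c.cube}: degenerate (zero-variance differences)")
            else:
                lines.append(
                    f"    {c.cube}: mean diff = {c.mean_difference:.3f}, "
                    f"t({c.df}) = {c.t:.2f}, p = {c.p_bonferroni:.4g}, "
                    f"d({c.d_variant}) = {c.cohens_d:.2f}"
                )
        return "\n".join(lines)


def _as_cells(data) -> np.ndarray:
    """Coerce input to an (n, 2, 2) cell array ordered by CUBE/SWITCH_LEVELS."""
    if isinstance(data, pd.DataFrame):
        return _cells_from_frame(data)
    x = np.asarray(data, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise InvalidArgumentError(
            f"cell data must have shape (n, 2, 2), got {x.shape}"
        )
    return x


def _cells_from_frame(
    df: pd.DataFrame, value: str = "value", subject: str = "participant_id"
) -> np.ndarray:
    required = {subject, "cube", "switch", value}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"cell table lacks columns: {sorted(missing)}")
    pivot = df.pivot_table(
        index=subject, columns=["cube", "switch"], values=value, aggfunc="mean"
    )
    cells = np.full((pivot.shape[0], 2, 2), np.nan)
    for i, cube in enumerate(CUBE_LEVELS):
        for j, sw in enumerate(SWITCH_LEVELS):
            if (cube, sw) not in pivot.columns:
                raise MissingCellError(f"cell ({cube}, {sw}) missing from the table")
            cells[:, i, j] = pivot[(cube, sw)].to_numpy()
    return cells


_DEGENERATE_TOL = 1e-12


class TwoWayRepeatedAnova:
    """2 (cube) x 2 (switch) fully within-subject ANOVA.

    Parameters
    ----------
    data
        Either an ``(n, 2, 2)`` array of per-participant cell means, axes
        ordered ``[participant, cube(light, heavy), switch(no_switch,
        switch)]``, or a tidy DataFrame accepted by :meth:`from_dataframe`.
        Participants with any missing (NaN) cell are dropped; at least 3
        complete participants are required at fit time.
    """

    def __init__(self, data) -> None:
        cells = _as_cells(data)
        complete = np.isfinite(cells).all(axis=(1, 2))
        self.cells = cells[complete]
        self.n_dropped = int((~complete).sum())

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value: str = "value", subject: str = "participant_id"
    ) -> "TwoWayRepeatedAnova":
        """Build from a tidy frame with participant_id/cube/switch/value columns."""
        return cls(_cells_from_frame(df, value=value, subject=subject))

    def fit(
        self, d_variant: str = "dz", correction_family_size: int = 2
    ) -> AnovaResult:
        y = self.cells
        n = y.shape[0]
        if n < 3:
            raise InsufficientDataError(
                f"need at least 3 complete participants, got {n}"
            )
        grand = y.mean()
        subj = y.mean(axis=(1, 2))
        cube_m = y.mean(axis=(0, 2))
        sw_m = y.mean(axis=(0, 1))
        cell_m = y.mean(axis=0)
        subj_cube = y.mean(axis=2)
        subj_sw = y.mean(axis=1)

        ss_subj = 4.0 * float(((subj - grand) ** 2).sum())
        ss_cube = 2.0 * n * float(((cube_m - grand) ** 2).sum())
        ss_sw = 2.0 * n * float(((sw_m - grand) ** 2).sum())
        ss_inter = n * float(
            ((cell_m - cube_m[:, None] - sw_m[None, :] + grand) ** 2).sum()
        )
        ss_cube_err = 2.0 * float(
            ((subj_cube - subj[:, None] - cube_m[None, :] + grand) ** 2).sum()
        )
        ss_sw_err = 2.0 * float(
            ((subj_sw - subj[:, None] - sw_m[None, :] + grand) ** 2).sum()
        )
        ss_total = float(((y - grand) ** 2).sum())
        ss_inter_err = (
            ss_total - ss_subj - ss_cube - ss_sw - ss_inter - ss_cube_err - ss_sw_err
        )
        ss_inter_err = max(ss_inter_err, 0.0)

        scale = max(1.0, ss_total)
        effects: dict[str, EffectResult] = {}
        for name, ss_eff, ss_err in (
            ("cube", ss_cube, ss_cube_err),
            ("switch", ss_sw, ss_sw_err),
            ("interaction", ss_inter, ss_inter_err),
        ):
            if ss_err <= _DEGENERATE_TOL * scale:
                effects[name] = EffectResult(
                    name=name,
                    F=float("nan"),
                    df_num=1,
                    df_den=n - 1,
                    p=float("nan"),
                    partial_eta_sq=float("nan"),
                    ss_effect=ss_eff,
                    ss_error=ss_err,
                    degenerate=True,
                )
                continue
            F = (ss_eff / 1.0) / (ss_err / (n - 1))
            effects[name] = EffectResult(
                name=name,
                F=float(F),
                df_num=1,
                df_den=n - 1,
                p=float(scipy.stats.f.sf(F, 1, n - 1)),
                partial_eta_sq=float(ss_eff / (ss_eff + ss_err)),
                ss_effect=ss_eff,
                ss_error=ss_err,
            )
        contrasts = switch_contrasts(
            y, correction_family_size=correction_family_size, d_variant=d_variant
        )
        return AnovaResult(effects=effects, contrasts=tuple(contrasts), n=n)


def rm_anova_2x2(
    cell_means, d_variant: str = "dz", correction_family_size: int = 2
) -> AnovaResult:
    """Fit the 2 x 2 within-subject ANOVA (see TwoWayRepeatedAnova)."""
    return TwoWayRepeatedAnova(cell_means).fit(
        d_variant=d_variant, correction_family_size=correction_family_size
    )


def switch_contrasts(
    cell_means, correction_family_size: int = 2, d_variant: str = "dz"
) -> list[ContrastResult]:
    """Paired switch-vs-no-switch t-tests within each cube level.

    p-values are multiplied by ``correction_family_size`` (Bonferroni) and
    capped at 1.  Zero-variance differences yield a degenerate record.
    """
    y = _as_cells(cell_means)
    y = y[np.isfinite(y).all(axis=(1, 2))]
    n = y.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need at least 2 complete participants, got {n}")
    results = []
    for i, cube in enumerate(CUBE_LEVELS):
        sw = y[:, i, SWITCH_LEVELS.index(SWITCH)]
        nosw = y[:, i, SWITCH_LEVELS.index(NO_SWITCH)]
        diffs = sw - nosw
        mean = float(diffs.mean())
        sd = float(diffs.std(ddof=1))
        if sd <= _DEGENERATE_TOL * max(1.0, float(np.abs(diffs).max(initial=0.0))):
            # No variance in the differences: a zero shift is trivially
            # non-significant (p = 1); a constant nonzero shift has an
            # unbounded t.  Both are flagged rather than reported as finite.
            results.append(
                ContrastResult(
                    cube=cube,
                    mean_difference=mean,
                    t=0.0 if mean == 0 else float("inf") * np.sign(mean),
                    df=n - 1,
                    p_uncorrected=1.0 if mean == 0 else float("nan"),
                    p_bonferroni=1.0 if mean == 0 else float("nan"),
                    cohens_d=float("nan"),
                    d_variant=d_variant,
                    degenerate=True,
                )
            )
            continue
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 1))
        d = cohens_d(sw, nosw, variant=d_variant)
        results.append(
            ContrastResult(
                cube=cube,
                mean_difference=mean,
                t=float(t),
                df=n - 1,
                p_uncorrected=p,
                p_bonferroni=min(1.0, p * correction_family_size),
                cohens_d=d.value,
                d_variant=d_variant,
                degenerate=d.degenerate,
            )
        )
    return results
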