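"""Participant- and cohort-level 24-h time-use outputs.

A participant's imputed minute-of-day profile is condensed into a daily
composition (sleep, sedentary and LIPA in h/day, MVPA in min/day — the four
components close to 24 h), overall acceleration in mg/day, hour-of-day and
six-hour-quadrant profiles, and weekday/weekend variants.  Cohort-level
operations reproduce the study-accounting arithmetic (ordered exclusion
cascade, recruitment/compliance rates, waking-time shares) and the
statistical analysis: covariate-adjusted marginal means by g-computation
over the observed covariate distribution, a linear trend test on group
medians, and the per-decade decline in overall acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .synth import BEHAVIOURS
from .wear import MinuteProfile

#: ordered exclusion stages mirroring the participant flow chart
CASCADE_STAGES = (
    ("unreadable file", "unreadable"),
    ("uncalibratable", "uncalibratable"),
    ("incomplete questionnaire", "incomplete_questionnaire"),
    ("insufficient wear-time", "insufficient_weartime"),
    ("implausible acceleration", "implausible_acceleration"),
)

QUADRANT_LABELS = ("00:00-05:59", "06:00-11:59", "12:00-17:59", "18:00-23:59")


@dataclass
class ParticipantSummary:
    overall_accel: float          # mg/day
    sleep_h: float
    sedentary_h: float
    lipa_h: float
    mvpa_min: float
    hour_profile: pd.DataFrame    # 24 rows: accel_mg + 4 behaviour fractions
    quadrant_profile: pd.DataFrame
    weekday: dict | None = None   # same five scalars, worn weekdays only
    weekend: dict | None = None

    @property
    def closure_error_h(self) -> float:
        """|sleep + sedentary + LIPA + MVPA/60 - 24| in hours."""
        total = self.sleep_h + self.sedentary_h + self.lipa_h + self.mvpa_min / 60.0
        return abs(total - 24.0)


@dataclass
class ExclusionCascade:
    stages: list[tuple[str, int, int]]   # (name, entering, removed)

    @property
    def final(self) -> int:
        if not self.stages:
            return 0
        name, entering, removed = self.stages[-1]
        return entering - removed

    def entering(self, stage_name: str) -> int:
        for name, entering, _ in self.stages:
            if name == stage_name:
                return entering
        raise KeyError(stage_name)

    def after(self, stage_name: str) -> int:
        for name, entering, removed in self.stages:
            if name == stage_name:
                return entering - removed
        raise KeyError(stage_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages,
                            columns=["stage", "entering", "removed"])


@dataclass
class GroupComparison:
    group: str
    outcome: str
    table: pd.DataFrame           # per group: n, marginal mean, SE
    covariates: tuple
    log_transformed: bool
    model_summary: str = ""


def _compose(profile: MinuteProfile):
    if not profile.complete or np.isnan(profile.fractions).any():
        raise ValueError("profile is incomplete; impute before summarising")
    minutes = profile.fractions.sum(axis=0)          # minutes/day per behaviour
    return dict(zip(BEHAVIOURS, minutes))


def summarize_participant(profile: MinuteProfile,
                          epochs=None, mask=None,
                          labels: np.ndarray | None = None) -> ParticipantSummary:
    """Condense an imputed minute profile into the daily time-use summary.

    Behaviour hours are sums of per-minute fractions / 60; overall
    acceleration is the unweighted mean slot ENMO.  When the underlying
    worn epochs and labels are supplied, weekday (Mon-Fri) and weekend
    scalars are computed from worn days only, without imputation.
    """
    comp = _compose(profile)
    slots = np.arange(1440)
    hours = slots // 60
    hp = pd.DataFrame({
        "accel_mg": [profile.enmo[hours == h].mean() for h in range(24)],
    }, index=pd.Index(range(24), name="hour"))
    for k, b in enumerate(BEHAVIOURS):
        hp[f"f_{b}"] = [profile.fractions[hours == h, k].mean()
                        for h in range(24)]
    quad = slots // 360
    qp = pd.DataFrame({
        "accel_mg": [profile.enmo[quad == q].mean() for q in range(4)],
    }, index=pd.Index(QUADRANT_LABELS, name="quadrant"))
    for k, b in enumerate(BEHAVIOURS):
        qp[f"f_{b}"] = [profile.fractions[quad == q, k].mean()
                        for q in range(4)]

    weekday = weekend = None
    if epochs is not None and mask is not None and labels is not None:
        stamps = pd.to_datetime(np.asarray(epochs.epoch_start), unit="s", utc=True)
        is_weekend = stamps.dayofweek >= 5
        labels = np.asarray(labels, dtype=object)
        worn = mask.worn & np.isin(labels, BEHAVIOURS)
        out = {}
        for name, sel in (("weekday", worn & ~is_weekend),
                          ("weekend", worn & is_weekend)):
            if sel.sum() == 0:
                out[name] = None
                continue
            frac = {b: float(np.mean(labels[sel] == b)) for b in BEHAVIOURS}
            out[name] = {
                "overall_accel": float(np.nanmean(epochs.enmo_mean[sel])),
                "sleep_h": 24.0 * frac["sleep"],
                "sedentary_h": 24.0 * frac["sedentary"],
                "lipa_h": 24.0 * frac["LIPA"],
                "mvpa_min": 24.0 * 60.0 * frac["MVPA"],
            }
        weekday, weekend = out["weekday"], out["weekend"]

    return ParticipantSummary(
        overall_accel=float(profile.enmo.mean()),
        sleep_h=comp["sleep"] / 60.0,
        sedentary_h=comp["sedentary"] / 60.0,
        lipa_h=comp["LIPA"] / 60.0,
        mvpa_min=comp["MVPA"],
        hour_profile=hp, quadrant_profile=qp,
        weekday=weekday, weekend=weekend)


def waking_shares(sleep_h: float, sedentary_h: float, lipa_h: float,
                  mvpa_min: float) -> dict[str, int]:
    """Percent of waking time per waking behaviour, integer-rounded.

    Waking time is 24 h minus sleep; shares are displayed the way the
    field reports them (nearest whole percent).
    """
    waking = 24.0 - sleep_h
    if waking <= 0:
        raise ValueError("waking-time shares undefined: sleep fills the day")
    def pct(x):
        return int(Decimal(100.0 * x / waking).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP))
    return {"sedentary": pct(sedentary_h), "LIPA": pct(lipa_h),
            "MVPA": pct(mvpa_min / 60.0)}


def cascade(manifest: pd.DataFrame,
            stages=CASCADE_STAGES) -> ExclusionCascade:
    """Ordered exclusion-cascade accounting from per-participant flags.

    Each participant is removed at the first failing stage, in the fixed
    order unreadable file -> uncalibratable -> incomplete questionnaire ->
    insufficient wear-time -> implausible acceleration.
    """
    if len(manifest) == 0:
        return ExclusionCascade(stages=[])
    missing = [flag for _, flag in stages if flag not in manifest.columns]
    if missing:
        raise KeyError(f"manifest lacks exclusion flags: {missing}")
    remaining = np.ones(len(manifest), dtype=bool)
    out = []
    for name, flag in stages:
        entering = int(remaining.sum())
        removed_mask = remaining & manifest[flag].to_numpy(dtype=bool)
        removed = int(removed_mask.sum())
        out.append((name, entering, removed))
        remaining &= ~removed_mask
    return ExclusionCascade(stages=out)


def rate(numerator: int, denominator: int) -> float:
    """Percentage at 1 decimal, half-up — study-accounting display rule."""
    if denominator == 0:
        raise ZeroDivisionError("rate undefined for zero denominator")
    return float(Decimal(100.0 * numerator / denominator).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


_LOG_OFFSET = 1.0   # MVPA is log(x+1)-transformed: zero-MVPA participants exist


def marginal_means(data: pd.DataFrame, outcome: str, group: str,
                   covariates: tuple = ("age", "sex", "region"),
                   log_transform: bool = False) -> GroupComparison:
    """Covariate-adjusted marginal means per group (g-computation).

    Fits ``outcome ~ C(group) + covariates`` by OLS; the marginal mean of
    group g averages the model prediction with every participant's
    covariates held at their observed values and group set to g.  The SE
    propagates the coefficient covariance through the averaged design row.
    Log-transformed outcomes (MVPA) are fitted as log(x+1) and
    back-transformed as exp(m)-1 for display.
    """
    data = data.copy()
    groups = pd.unique(data[group])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for marginal means")
    ycol = outcome
    if log_transform:
        ycol = f"__log_{outcome}"
        data[ycol] = np.log(data[outcome] + _LOG_OFFSET)
    terms = [f"C({group})"]
    for c in covariates:
        terms.append(c if pd.api.types.is_numeric_dtype(data[c]) else f"C({c})")
    formula = f"{ycol} ~ " + " + ".join(terms)
    try:
        model = smf.ols(formula, data=data).fit()
    except Exception as err:  # pragma: no cover - statsmodels raises variously
        raise ValueError(f"model fit failed (collinearity?): {err}") from err
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        bad = [n for n, v in zip(model.model.exog_names,
                                 np.isnan(model.bse) | (model.bse == 0)) if v]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")

    design_info = model.model.data.design_info
    V = model.cov_params().to_numpy()
    rows = []
    for g in groups:
        counter = data.copy()
        counter[group] = g
        (X,) = build_design_matrices([design_info], counter)
        w = np.asarray(X).mean(axis=0)
        m = float(w @ model.params.to_numpy())
        se = float(np.sqrt(w @ V @ w))
        if log_transform:
            # delta method for the back-transformed display scale
            m_disp = float(np.exp(m) - _LOG_OFFSET)
            se_disp = float(np.exp(m) * se)
        else:
            m_disp, se_disp = m, se
        rows.append({group: g, "n": int((data[group] == g).sum()),
                     "marginal_mean": m_disp, "se": se_disp})
    table = pd.DataFrame(rows).set_index(group)
    return GroupComparison(group=group, outcome=outcome, table=table,
                           covariates=tuple(covariates),
                           log_transformed=log_transform,
                           model_summary=str(model.summary()))


def trend_test(data: pd.DataFrame, outcome: str, group: str,
               group_medians: dict,
               covariates: tuple = ("age", "sex", "region"),
               log_transform: bool = False) -> dict:
    """Linear trend across ordered groups.

    Refits the adjustment model replacing the group indicators by each
    group's median as a continuous covariate, and reports the slope test.
    """
    if len(group_medians) < 3:
        raise ValueError("trend test needs at least 3 ordered groups")
    data = data.copy()
    data["__median"] = data[group].map(group_medians).astype(float)
    if data["__median"].isna().any():
        raise KeyError("group_medians does not cover all groups")
    ycol = outcome
    if log_transform:
        ycol = f"__log_{outcome}"
        data[ycol] = np.log(data[outcome] + _LOG_OFFSET)
    terms = ["__median"]
    for c in covariates:
        terms.append(c if pd.api.types.is_numeric_dtype(data[c]) else f"C({c})")
    model = smf.ols(f"{ycol} ~ " + " + ".join(terms), data=data).fit()
    return {"slope": float(model.params["__median"]),
            "t": float(model.tvalues["__median"]),
            "p": float(model.pvalues["__median"])}


def decade_decline(group_midpoints: np.ndarray, group_means: np.ndarray,
                   cohort_mean: float | None = None) -> tuple[float, float]:
    """Decline in overall acceleration per additional decade of age.

    Least-squares slope of group mean acceleration over group age midpoints,
    scaled to 10 years; the relative decline is ``100 * |slope| /
    cohort_mean`` displayed at 1 decimal.
    """
    x = np.asarray(group_midpoints, dtype=float)
    y = np.asarray(group_means, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 age groups")
    slope_per_year = np.polyfit(x, y, 1)[0]
    per_decade = slope_per_year * 10.0
    if cohort_mean is None:
        cohort_mean = float(y.mean())
    if cohort_mean == 0:
        pct = 0.0
    else:
        pct = float(Decimal(100.0 * abs(per_decade) / cohort_mean).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP))
    return float(per_decade), pct
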