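"""Statistical evaluation pipeline for two-arm pre/post affect data.

Implements the analysis applied to the evaluation study: Shapiro-Wilk and
Levene assumption checks (advisory — the ANOVA proceeds regardless),
mixed-design (split-plot) ANOVAs with Mauchly sphericity testing and
Greenhouse-Geisser correction, Bonferroni-adjusted Welch post hocs per time
point, paired t tests, two standardized-mean-change variants of Cohen's d,
partial eta squared, and a two-step inverse-variance meta-analysis across
studies.

Two d variants coexist deliberately.  ``change_sd`` (d_z) divides the mean
change by the change-score SD; ``pooled_prepost`` (sometimes d_av) divides by
sqrt((sd_pre^2 + sd_post^2)/2).  Published per-study values in this protocol
family match the pooled variant even when labelled d_z, so the variant is
recorded with every effect size and summary-table reproduction defaults to
``pooled_prepost``.

The meta-analytic combination weights each study by the inverse of its
change-score variance (without a sample-size factor) and averages absolute
effects; both readings are what the published combined values imply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    n: int | None = None
    n1: int | None = None
    n2: int | None = None
    kind: str = "paired"


@dataclass(frozen=True)
class AnovaEffect:
    """One effect of a split-plot ANOVA.

    ``gg_epsilon`` / ``p_gg`` / ``sphericity_p`` are populated only for
    within-subject effects with at least three levels; with two levels the
    correction is vacuous (epsilon = 1)."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta2: float
    gg_epsilon: float | None = None
    p_gg: float | None = None
    sphericity_p: float | None = None


@dataclass(frozen=True)
class EffectSize:
    d: float
    variant: str  # change_sd | pooled_prepost
    n: int | None = None
    se: float | None = None


@dataclass(frozen=True)
class MetaInput:
    label: str
    d: float
    change_sd: float
    n: int | None = None


@dataclass(frozen=True)
class MetaResult:
    combined_d: float
    weights: dict
    contributions: dict


# ---------------------------------------------------------------------------
# assumption checks


def check_assumptions(*samples) -> dict:
    """Shapiro-Wilk normality per sample and a Levene test across samples.

    Advisory only.  Requires n >= 3 and non-constant values in each sample.
    """
    clean = [np.asarray(s, dtype=float) for s in samples]
    for s in clean:
        if len(s) < 3:
            raise ValueError("assumption checks need n >= 3 per sample")
        if np.ptp(s) == 0:
            raise ValueError("constant sample is degenerate for a normality test")
    shapiro = [sps.shapiro(s) for s in clean]
    out = {"shapiro": [{"W": float(r.statistic), "p": float(r.pvalue)} for r in shapiro]}
    if len(clean) >= 2:
        lev = sps.levene(*clean, center="median")
        out["levene"] = {"W": float(lev.statistic), "p": float(lev.pvalue)}
    return out


# ---------------------------------------------------------------------------
# t tests


def paired_t(pre, post) -> TTestResult:
    """Two-tailed paired t test on equal-length vectors."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-d vectors")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    change = post - pre
    sd = change.std(ddof=1)
    if sd == 0:
        raise ValueError("zero change variance")
    t = change.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), n=n, kind="paired")


def paired_t_from_summary(change_mean: float, change_sd: float, n: int) -> TTestResult:
    """Paired t from change-score summary statistics."""
    if change_sd <= 0 or n < 2:
        raise ValueError("need change_sd > 0 and n >= 2")
    t = change_mean / (change_sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p), n=n, kind="paired")


def welch_t(x, y) -> TTestResult:
    """Welch two-sample t test (unequal variances, Welch-Satterthwaite df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t needs n >= 2 per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / (vx ** 2 / (len(x) ** 2 * (len(x) - 1))
                     + vy ** 2 / (len(y) ** 2 * (len(y) - 1)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p),
                       n1=len(x), n2=len(y), kind="welch")


def bonferroni(pvals) -> list[float]:
    """Bonferroni adjustment: p * m, capped at 1."""
    pvals = list(pvals)
    if any(not 0.0 <= p <= 1.0 for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pvals)
    return [min(1.0, p * m) for p in pvals]


# ---------------------------------------------------------------------------
# effect sizes


def _dz_se(d: float, n: int | None) -> float | None:
    if n is None or n < 2:
        return None
    return math.sqrt(1.0 / n + d ** 2 / (2.0 * n))


def cohen_d_change(change_mean: float, change_sd: float,
                   n: int | None = None) -> EffectSize:
    """Standardized mean change using the change-score SD (d_z)."""
    if change_sd <= 0:
        raise ValueError("change_sd must be positive")
    d = change_mean / change_sd
    return EffectSize(d=float(d), variant="change_sd", n=n, se=_dz_se(d, n))


def cohen_d_pooled_prepost(m1: float, sd1: float, m2: float, sd2: float,
                           n: int | None = None) -> EffectSize:
    """Standardized mean change using the root mean of pre and post
    variances: (m2 - m1) / sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("pre/post SDs must be positive")
    d = (m2 - m1) / math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    return EffectSize(d=float(d), variant="pooled_prepost", n=n, se=_dz_se(d, n))


def partial_eta2(F: float, df1: float, df2: float) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2), identical to SS_eff/(SS_eff+SS_err)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# split-plot ANOVA


def _complete_cases(table: pd.DataFrame, dv: str, within: str, between: str,
                    subject: str) -> tuple[pd.DataFrame, list]:
    times = sorted(table[within].unique())
    counts = table.groupby(subject)[within].agg(lambda s: (len(s), len(set(s))))
    bad = []
    for subj, (n_rows, n_levels) in counts.items():
        if n_rows != len(times) or n_levels != len(times):
            bad.append(subj)
    if bad:
        table = table[~table[subject].isin(bad)]
    return table, sorted(bad)


def mixed_anova(table: pd.DataFrame, dv: str = "value", within: str = "time",
                between: str = "group", subject: str = "participant"
                ) -> list[AnovaEffect]:
    """Split-plot ANOVA: between-subject factor ``group``, within-subject
    factor ``time``.

    Participants without every time level are removed (listwise deletion);
    duplicated cells are rejected.  With >= 3 within levels a Mauchly test is
    run and Greenhouse-Geisser-corrected dfs/p reported alongside the
    uncorrected ones.  With a single group only the time effect is computed.
    """
    table = table[[subject, between, within, dv]].dropna()
    dup = table.duplicated([subject, within])
    if dup.any():
        raise ValueError("one row per participant x time required")
    table, excluded = _complete_cases(table, dv, within, between, subject)
    groups = sorted(table[between].unique())
    if any((table[table[between] == g][subject].nunique() < 2) for g in groups):
        raise ValueError("every group needs at least 2 complete participants")
    k = table[within].nunique()
    if k < 2:
        raise ValueError("within factor needs at least 2 levels")

    if len(groups) == 1:
        res = pg.rm_anova(data=table, dv=dv, within=within, subject=subject,
                          correction=(k >= 3), detailed=False)
        row = res.iloc[0]
        eps = float(row["eps"]) if "eps" in res.columns and k >= 3 else None
        p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in res.columns else None
        sph_p = float(row["p_spher"]) if "p_spher" in res.columns else None
        return [AnovaEffect(effect="time", F=float(row["F"]),
                            df1=float(row["ddof1"]), df2=float(row["ddof2"]),
                            p=float(row["p_unc"]),
                            partial_eta2=partial_eta2(float(row["F"]),
                                                      float(row["ddof1"]),
                                                      float(row["ddof2"])),
                            gg_epsilon=eps, p_gg=p_gg, sphericity_p=sph_p)]

    res = pg.mixed_anova(data=table, dv=dv, within=within, subject=subject,
                         between=between, correction=(k >= 3))
    effects = []
    name_map = {"group": between, "time": within, "interaction": "Interaction"}
    for label, source in name_map.items():
        row = res[res["Source"] == source].iloc[0]
        # floating-point cancellation in the SS decomposition can yield a
        # negligibly negative F for a null effect
        F = max(float(row["F"]), 0.0)
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        within_effect = label in ("time", "interaction")
        eps = p_gg = sph_p = None
        if within_effect and k >= 3:
            time_row = res[res["Source"] == within].iloc[0]
            if "eps" in res.columns and np.isfinite(time_row.get("eps", np.nan)):
                eps = float(time_row["eps"])
            if "p_GG_corr" in res.columns and np.isfinite(row.get("p_GG_corr", np.nan)):
                p_gg = float(row["p_GG_corr"])
            if "p_spher" in res.columns and np.isfinite(time_row.get("p_spher", np.nan)):
                sph_p = float(time_row["p_spher"])
        elif within_effect:
            eps = 1.0
        effects.append(AnovaEffect(
            effect=label, F=F, df1=df1, df2=df2, p=float(row["p_unc"]),
            partial_eta2=partial_eta2(F, df1, df2),
            gg_epsilon=eps, p_gg=p_gg, sphericity_p=sph_p))
    return effects


# ---------------------------------------------------------------------------
# meta-analysis


def meta_combine(inputs) -> MetaResult:
    """Inverse-variance-weighted combination of standardized mean changes.

    Weights are w_i = 1 / change_sd_i^2 and the combined effect is the
    weighted mean of |d_i|; the combined value therefore lies between the
    smallest and largest |d_i| and is invariant to study ordering.
    """
    inputs = list(inputs)
    if not inputs:
        raise ValueError("meta_combine needs at least one study")
    weights = {}
    contributions = {}
    total_w = 0.0
    total = 0.0
    for s in inputs:
        if s.change_sd <= 0:
            raise ValueError(f"study {s.label!r} has non-positive change SD")
        w = 1.0 / s.change_sd ** 2
        weights[s.label] = w
        contributions[s.label] = w * abs(s.d)
        total_w += w
        total += w * abs(s.d)
    return MetaResult(combined_d=total / total_w, weights=weights,
                      contributions=contributions)


# ---------------------------------------------------------------------------
# orchestration


def _effect_to_dict(e: AnovaEffect) -> dict:
    return {k: getattr(e, k) for k in ("effect", "F", "df1", "df2", "p",
                                       "partial_eta2", "gg_epsilon", "p_gg",
                                       "sphericity_p")}


def evaluate_study(table: pd.DataFrame, measures=None, alpha: float = 0.05) -> dict:
    """Full per-measure evaluation of a long questionnaire table.

    For every measure: assumption checks on the group x time cells, a
    split-plot ANOVA, Bonferroni-adjusted Welch group comparisons at each
    time point (the Bonferroni family is the per-measure set of time points),
    and both standardized-change variants per group.  Participants lacking a
    time level for a measure are excluded listwise and reported.
    """
    required = {"participant", "group", "time", "measure", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    if measures is None:
        measures = sorted(table["measure"].unique())
    groups = sorted(table["group"].unique())
    report: dict = {"alpha": alpha, "measures": {}, "exclusions": {},
                    "n_participants": int(table["participant"].nunique())}
    for measure in measures:
        sub = table[table["measure"] == measure]
        if sub.empty:
            continue
        sub, excluded = _complete_cases(sub, "value", "time", "group", "participant")
        report["exclusions"][measure] = excluded
        times = sorted(sub["time"].unique(),
                       key=lambda t: {"baseline": 0, "intermediate": 1, "post": 2}
                       .get(t, 99))
        entry: dict = {}
        # assumptions (advisory)
        try:
            cells = [sub[(sub["group"] == g) & (sub["time"] == t)]["value"].values
                     for g in groups for t in times]
            entry["assumptions"] = check_assumptions(*cells)
        except ValueError as err:
            entry["assumptions"] = {"error": str(err)}
        entry["anova"] = [_effect_to_dict(e) for e in
                          mixed_anova(sub, dv="value")]
        if len(groups) == 2:
            raw = []
            for t in times:
                x = sub[(sub["group"] == groups[0]) & (sub["time"] == t)]["value"].values
                y = sub[(sub["group"] == groups[1]) & (sub["time"] == t)]["value"].values
                raw.append((t, welch_t(x, y)))
            adj = bonferroni([r.p for _, r in raw])
            entry["posthoc"] = [
                {"time": t, "t": r.t, "df": r.df, "p": r.p, "p_bonf": pb,
                 "n1": r.n1, "n2": r.n2, "groups": groups}
                for (t, r), pb in zip(raw, adj)]
        entry["effect_sizes"] = {}
        for g in groups:
            wide = sub[sub["group"] == g].pivot(index="participant",
                                               columns="time", values="value")
            if "baseline" not in wide.columns or "post" not in wide.columns:
                continue
            pre, post = wide["baseline"].values, wide["post"].values
            change = post - pre
            es = {"n": int(len(pre)),
                  "change_mean": float(change.mean()),
                  "change_sd": float(change.std(ddof=1))}
            if es["change_sd"] > 0:
                tt = paired_t(pre, post)
                es["paired_t"] = {"t": tt.t, "df": tt.df, "p": tt.p}
                es["d_change_sd"] = cohen_d_change(es["change_mean"],
                                                   es["change_sd"], len(pre)).d
            if pre.std(ddof=1) > 0 and post.std(ddof=1) > 0:
                es["d_pooled_prepost"] = cohen_d_pooled_prepost(
                    float(pre.mean()), float(pre.std(ddof=1)),
                    float(post.mean()), float(post.std(ddof=1)), len(pre)).d
            entry["effect_sizes"][g] = es
        report["measures"][measure] = entry
    return report
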