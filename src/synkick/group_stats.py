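"""The 2 x 2 (group x time) repeated-measures testing scheme.

Each measure is screened per cell with Shapiro-Wilk; normally distributed
measures go to a mixed-design ANOVA (session within subject, group between
subjects), followed -- only when the interaction is significant -- by four
Bonferroni-corrected simple-effect contrasts (between groups at each
session, between sessions within each group).  Non-normal measures fall
back to within-group pre/post Wilcoxon signed-rank tests with Holm
correction and the standard effect size r = |Z| / sqrt(n).  A Friedman
omnibus is reported as not-applicable for this design: with only two
within-subject conditions and group varying between subjects there is no
valid >=3-condition within-subject block to rank.

Outliers are flagged per cell with the 1.5 x IQR rule; the default is
report-only, because silent removal harms reproducibility (a removal mode
exists behind config).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .emg_io import GROUPS, SESSIONS

__all__ = [
    "StatTestResult",
    "validate_measure_table",
    "normality_screen",
    "rm_anova_2x2",
    "simple_effects",
    "friedman_wilcoxon",
    "holm_adjust",
    "flag_outliers",
    "analyze_measure",
]


@dataclass(frozen=True)
class StatTestResult:
    """One test outcome in the 2x2 scheme."""

    measure: str
    effect: str
    statistic: float
    p: float
    adjusted_p: float
    correction: str  # bonferroni | holm | none
    family: str  # rm-anova | t-test | wilcoxon | friedman | shapiro
    effect_size_r: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        for name, v in (("p", self.p), ("adjusted_p", self.adjusted_p)):
            if np.isfinite(v) and not 0 <= v <= 1:
                raise ValueError(f"{name} out of [0, 1]: {v}")
        if (
            np.isfinite(self.p)
            and np.isfinite(self.adjusted_p)
            and self.adjusted_p < self.p - 1e-12
        ):
            raise ValueError("adjusted p cannot be below raw p")


def validate_measure_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy measure table's structural invariants.

    One measure at a time: every subject in exactly one group with both
    sessions present, all values finite.
    """
    required = {"subject", "group", "session", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"measure table needs columns {sorted(required)}")
    if df["measure"].nunique() > 1 if "measure" in df.columns else False:
        raise ValueError("one measure at a time")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite measure values")
    groups_per_subject = df.groupby("subject")["group"].nunique()
    if (groups_per_subject > 1).any():
        bad = groups_per_subject[groups_per_subject > 1].index.tolist()
        raise ValueError(f"subject(s) in more than one group: {bad}")
    sessions = df.groupby("subject")["session"].apply(set)
    incomplete = sessions[sessions != set(SESSIONS)].index.tolist()
    if incomplete:
        raise ValueError(f"subject(s) missing a session: {incomplete}")
    return df


def _cells(df: pd.DataFrame):
    for g in GROUPS:
        for s in SESSIONS:
            vals = df[(df["group"] == g) & (df["session"] == s)]["value"]
            yield g, s, vals.to_numpy(dtype=float)


def normality_screen(
    df: pd.DataFrame, alpha: float = 0.05, measure: str = "measure"
) -> tuple[list[StatTestResult], str]:
    """Shapiro-Wilk per group x session cell; any rejection routes the
    measure down the nonparametric path."""
    results = []
    route = "parametric"
    for g, s, vals in _cells(df):
        if len(vals) < 3:
            raise ValueError(f"cell ({g}, {s}) has fewer than 3 values")
        if np.ptp(vals) == 0:
            raise ValueError(f"cell ({g}, {s}) is constant; Shapiro-Wilk undefined")
        stat, p = sst.shapiro(vals)
        results.append(
            StatTestResult(
                measure=measure,
                effect=f"normality[{g},{s}]",
                statistic=float(stat),
                p=float(p),
                adjusted_p=float(p),
                correction="none",
                family="shapiro",
            )
        )
        if p < alpha:
            route = "nonparametric"
    return results, route


def rm_anova_2x2(df: pd.DataFrame, measure: str = "measure") -> list[StatTestResult]:
    """Mixed-design ANOVA: session within subject, group between subjects.

    Returns F and p for the time (session) main effect, the group main
    effect, and the time x group interaction.
    """
    import pingouin as pg

    validate_measure_table(df)
    aov = pg.mixed_anova(
        data=df, dv="value", within="session", subject="subject", between="group"
    )
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    label = {"group": "group", "session": "time", "Interaction": "interaction"}
    out = []
    for _, row in aov.iterrows():
        out.append(
            StatTestResult(
                measure=measure,
                effect=label.get(row["Source"], row["Source"]),
                statistic=float(row["F"]),
                p=float(row[p_col]),
                adjusted_p=float(row[p_col]),
                correction="none",
                family="rm-anova",
            )
        )
    return out


def simple_effects(
    df: pd.DataFrame,
    measure: str = "measure",
    interaction_p: float | None = None,
    alpha: float = 0.05,
    force: bool = False,
) -> list[StatTestResult]:
    """Four Bonferroni-corrected simple-effect contrasts.

    Between groups at each session (independent t) and between sessions
    within each group (paired t); family size fixed at 4.  Refuses to run
    without a significant interaction unless ``force``.
    """
    if not force:
        if interaction_p is None:
            raise ValueError(
                "simple_effects needs the interaction p (or force=True)"
            )
        if interaction_p >= alpha:
            raise ValueError(
                f"interaction p={interaction_p:.3g} is not significant at "
                f"alpha={alpha}; simple effects not warranted (force=True to "
                f"override)"
            )
    validate_measure_table(df)
    wide = df.pivot_table(
        index=["subject", "group"], columns="session", values="value"
    ).reset_index()
    family = 4
    out = []
    for session in SESSIONS:
        a = wide[wide["group"] == GROUPS[0]][session].to_numpy()
        b = wide[wide["group"] == GROUPS[1]][session].to_numpy()
        t, p = sst.ttest_ind(a, b)
        out.append(
            StatTestResult(
                measure=measure,
                effect=f"group@{session}",
                statistic=float(t),
                p=float(p),
                adjusted_p=float(min(1.0, family * p)),
                correction="bonferroni",
                family="t-test",
            )
        )
    for group in GROUPS:
        sub = wide[wide["group"] == group]
        t, p = sst.ttest_rel(sub["post"].to_numpy(), sub["pre"].to_numpy())
        out.append(
            StatTestResult(
                measure=measure,
                effect=f"time@{group}",
                statistic=float(t),
                p=float(p),
                adjusted_p=float(min(1.0, family * p)),
                correction="bonferroni",
                family="t-test",
            )
        )
    return out


def holm_adjust(ps: list[float]) -> list[float]:
    """Holm step-down adjustment, monotone and never below the raw p."""
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * ps[idx])
        running = max(running, val)
        adj[idx] = running
    return adj.tolist()


def friedman_wilcoxon(
    df: pd.DataFrame, measure: str = "measure"
) -> list[StatTestResult]:
    """Nonparametric fallback for the 2x2 design.

    Within-group pre/post Wilcoxon signed-rank tests, Holm-corrected over
    the within-group family, with effect size r = |Z| / sqrt(n) where n
    counts non-tied pairs.  The Friedman omnibus is recorded as not
    applicable (two within-subject conditions, group between subjects).
    """
    validate_measure_table(df)
    wide = df.pivot_table(
        index=["subject", "group"], columns="session", values="value"
    ).reset_index()
    out = [
        StatTestResult(
            measure=measure,
            effect="omnibus",
            statistic=float("nan"),
            p=float("nan"),
            adjusted_p=float("nan"),
            correction="none",
            family="friedman",
            note=(
                "not applicable: Friedman needs >=3 within-subject conditions; "
                "this design has 2 sessions with group between subjects"
            ),
        )
    ]
    raw = []
    for group in GROUPS:
        sub = wide[wide["group"] == group]
        diff = sub["post"].to_numpy() - sub["pre"].to_numpy()
        n_nonzero = int(np.count_nonzero(diff))
        if n_nonzero == 0:
            raw.append((group, 0.0, 1.0, 0.0, "degenerate: all pairs tied"))
            continue
        note = ""
        if n_nonzero < 5:
            note = f"only {n_nonzero} non-tied pairs; exact test unreliable"
        res = sst.wilcoxon(
            sub["post"].to_numpy(), sub["pre"].to_numpy(), method="approx"
        )
        z = float(res.zstatistic)
        r = abs(z) / np.sqrt(n_nonzero)
        raw.append((group, float(res.statistic), float(res.pvalue), r, note))
    adj = holm_adjust([p for _, _, p, _, _ in raw])
    for (group, stat, p, r, note), ap in zip(raw, adj):
        out.append(
            StatTestResult(
                measure=measure,
                effect=f"time@{group}",
                statistic=stat,
                p=p,
                adjusted_p=ap,
                correction="holm",
                family="wilcoxon",
                effect_size_r=r,
                note=note,
            )
        )
    return out


def flag_outliers(df: pd.DataFrame, k: float = 1.5) -> pd.DataFrame:
    """Per-cell 1.5 x IQR flags (report-only by default upstream)."""
    flags = np.zeros(len(df), dtype=bool)
    for g in GROUPS:
        for s in SESSIONS:
            mask = (df["group"] == g) & (df["session"] == s)
            vals = df.loc[mask, "value"]
            if vals.empty:
                continue
            q1, q3 = vals.quantile([0.25, 0.75])
            iqr = q3 - q1
            flags |= (mask & ((df["value"] < q1 - k * iqr) | (df["value"] > q3 + k * iqr))).to_numpy()
    out = df.copy()
    out["outlier"] = flags
    return out


def analyze_measure(
    df: pd.DataFrame,
    measure: str = "measure",
    alpha: float = 0.05,
    outlier_mode: str = "report",
) -> list[StatTestResult]:
    """Full scheme for one measure: screen, route, test, follow up."""
    df = validate_measure_table(df)
    flagged = flag_outliers(df)
    if outlier_mode == "remove":
        removed = flagged[flagged["outlier"]]["subject"].unique().tolist()
        df = flagged[~flagged["subject"].isin(removed)].drop(columns="outlier")
        df = validate_measure_table(df)
    results, route = normality_screen(df, alpha=alpha, measure=measure)
    if route == "parametric":
        aov = rm_anova_2x2(df, measure=measure)
        results.extend(aov)
        inter = next(r for r in aov if r.effect == "interaction")
        if inter.p < alpha:
            results.extend(
                simple_effects(df, measure=measure, interaction_p=inter.p, alpha=alpha)
            )
    else:
        results.extend(friedman_wilcoxon(df, measure=measure))
    return results
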