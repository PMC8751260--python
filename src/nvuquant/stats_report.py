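"""Group statistics for the microvascular measurements.

Per-disector values are averaged to one value per subject (the subject mean
over its sampled optical disectors is the unit of analysis), then summarized
as mean +- SEM per group. Plaque load uses one-way ANOVA with Tukey HSD
post-hoc tests; the coverage, capillary and pericyte measurements use
two-way factorial ANOVA with Sidak-adjusted pairwise comparisons
(p_adj = 1 - (1 - p)^m) within each comparison family. Significance at
alpha = 0.05 throughout. Unbalanced layouts use type-II sums of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "summarize_groups",
    "one_way_anova_tukey",
    "two_way_anova_sidak",
    "sidak_adjust",
]

ALPHA = 0.05


@dataclass
class AnovaResult:
    design: str  # "one-way" | "two-way"
    table: pd.DataFrame  # effect, F, df1, df2, p
    posthoc: pd.DataFrame  # pairwise comparisons with adjusted p
    alpha: float = ALPHA
    notes: list[str] = field(default_factory=list)


def summarize_groups(
    table: pd.DataFrame,
    value: str = "value",
    by: list[str] | str = "group",
) -> pd.DataFrame:
    """Per-group mean +- SEM (sd/sqrt(n), ddof=1) and n.

    Groups of size 1 get a missing SEM (with a warning), not an error.
    """
    by = [by] if isinstance(by, str) else list(by)
    rows = []
    singletons = []
    for key, sub in table.groupby(by, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = sub[value].to_numpy(dtype=float)
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        if n == 1:
            singletons.append(key)
        rows.append(dict(zip(by, key)) | {
            "mean": float(vals.mean()), "sem": sem, "n": n,
        })
    if singletons:
        warnings.warn(
            f"group(s) {singletons} have a single subject; SEM undefined",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _oneway_decomposition(groups: list[np.ndarray]) -> tuple[float, int, int]:
    """Classical between/within ANOVA decomposition -> (F, df1, df2)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(m * (g.mean() - grand) ** 2 for m, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, df1, df2
        raise ValueError("zero within-group variance everywhere: F undefined")
    return (ss_between / df1) / (ss_within / df2), df1, df2


def one_way_anova_tukey(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    *,
    alpha: float = ALPHA,
    posthoc: bool = True,
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""
    names, groups = [], []
    for key, sub in table.groupby(group, sort=True, observed=True):
        names.append(key)
        groups.append(sub[value].to_numpy(dtype=float))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    f, df1, df2 = _oneway_decomposition(groups)
    p = float(sps.f.sf(f, df1, df2))
    tab = pd.DataFrame(
        [{"effect": group, "F": f, "df1": df1, "df2": df2, "p": p}]
    )
    ph = pd.DataFrame(
        columns=["group1", "group2", "meandiff", "p_adj", "reject"]
    )
    notes = []
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(
            table[value].to_numpy(dtype=float),
            table[group].astype(str).to_numpy(),
            alpha=alpha,
        )
        ph = pd.DataFrame(
            res.summary().data[1:], columns=[c for c in res.summary().data[0]]
        ).rename(columns={"p-adj": "p_adj"})[
            ["group1", "group2", "meandiff", "p_adj", "reject"]
        ]
    if min(len(g) for g in groups) <= 3:
        notes.append("small groups (n <= 3): ANOVA computable but under-powered")
    return AnovaResult("one-way", tab, ph, alpha=alpha, notes=notes)


def sidak_adjust(p: float | np.ndarray, m: int) -> np.ndarray | float:
    """Sidak multiplicity adjustment: p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.clip(1.0 - (1.0 - np.asarray(p, dtype=float)) ** m, 0.0, 1.0)


def two_way_anova_sidak(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "exposure",
    factor_b: str = "group_time",
    *,
    alpha: float = ALPHA,
    family: str = "within_b",
) -> AnovaResult:
    """Two-way factorial ANOVA (type-II SS) with Sidak pairwise comparisons.

    ``family`` chooses the post-hoc comparison family: ``"within_b"``
    compares levels of factor A within each level of B (the Sidak m is the
    number of such comparisons), ``"within_a"`` the converse. Each pairwise t
    uses cell means with the pooled residual MSE from the full model.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[value, factor_a, factor_b]].copy()
    df.columns = ["y", "A", "B"]
    cells = df.groupby(["A", "B"], observed=True).size()
    levels_a = sorted(df["A"].astype(str).unique())
    levels_b = sorted(df["B"].astype(str).unique())
    for a in levels_a:
        for b in levels_b:
            n_cell = int(cells.get((a, b), 0))
            if n_cell == 0:
                raise ValueError(f"empty cell: {factor_a}={a}, {factor_b}={b}")
            if n_cell < 2:
                raise ValueError(
                    f"cell {factor_a}={a}, {factor_b}={b} has n < 2"
                )
    model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    an = sm.stats.anova_lm(model, typ=2)
    rename = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": "interaction"}
    rows = []
    df_resid = float(an.loc["Residual", "df"])
    for key, lab in rename.items():
        rows.append(
            {
                "effect": lab,
                "F": float(an.loc[key, "F"]),
                "df1": int(an.loc[key, "df"]),
                "df2": int(df_resid),
                "p": float(an.loc[key, "PR(>F)"]),
            }
        )
    tab = pd.DataFrame(rows)

    mse = float(an.loc["Residual", "sum_sq"] / df_resid)
    if family == "within_b":
        outer, inner, o_col, i_col = levels_b, levels_a, "B", "A"
    elif family == "within_a":
        outer, inner, o_col, i_col = levels_a, levels_b, "A", "B"
    else:
        raise ValueError("family must be 'within_a' or 'within_b'")
    comps = []
    for o in outer:
        sub = df[df[o_col].astype(str) == o]
        for i in range(len(inner)):
            for j in range(i + 1, len(inner)):
                g1 = sub[sub[i_col].astype(str) == inner[i]]["y"].to_numpy()
                g2 = sub[sub[i_col].astype(str) == inner[j]]["y"].to_numpy()
                diff = float(g1.mean() - g2.mean())
                se = float(np.sqrt(mse * (1 / len(g1) + 1 / len(g2))))
                t = diff / se if se > 0 else np.inf
                p_raw = 2.0 * float(sps.t.sf(abs(t), df_resid))
                comps.append(
                    {
                        "stratum": o,
                        "group1": inner[i],
                        "group2": inner[j],
                        "meandiff": diff,
                        "t": t,
                        "p_raw": p_raw,
                    }
                )
    ph = pd.DataFrame(comps)
    if len(ph):
        m = len(ph)
        ph["p_adj"] = sidak_adjust(ph["p_raw"].to_numpy(), m)
        ph["reject"] = ph["p_adj"] < alpha
    else:
        ph = pd.DataFrame(
            columns=["stratum", "group1", "group2", "meandiff", "t", "p_raw",
                     "p_adj", "reject"]
        )
    notes = []
    if int(cells.min()) <= 3:
        notes.append("small cells (n <= 3): ANOVA computable but under-powered")
    return AnovaResult("two-way", tab, ph, alpha=alpha, notes=notes)
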