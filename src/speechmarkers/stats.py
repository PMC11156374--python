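"""Group-level inferential statistics.

The group contrasts follow a fixed recipe: each ratio family (word
class, grammatical person) enters a 2x2 mixed ANOVA with group
(patients vs. controls) as the between-subject factor and tag ratio as
the within-subject factor, followed by Tukey HSD post hocs on the four
design cells; the lexical properties are compared with one-tailed
pooled-variance t tests; demographics use Yates-corrected chi-squared
(sex) and Dunnett's many-to-one test (age, education, cognition);
feature-cognition associations use Pearson or Spearman correlations.
p-values are corrected with the Benjamini-Hochberg false discovery rate
within each analysis family.

The mixed ANOVA is a direct split-plot sums-of-squares decomposition
(Type II under unbalanced groups), written out explicitly because it is
evaluated inside Monte-Carlo calibration loops where per-call overhead
matters. Effect size is partial eta squared, SS_effect /
(SS_effect + SS_error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple[float, float]
    p_raw: float
    p_fdr: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    tails: Literal["one", "two"] = "two"

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "tails": self.tails,
        }


def _as_wide(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Pivot long records (participant_id, group, level, value) to an
    (N, 2) array plus per-subject group labels; errors name incomplete
    participants."""
    required = {"participant_id", "group", "level", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"long records missing columns: {sorted(missing)}")
    levels = list(pd.unique(records["level"]))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 within-subject levels, got {levels}")
    piv = records.pivot_table(
        index=["participant_id", "group"], columns="level", values="value", observed=True
    )
    bad = piv.index[piv.isna().any(axis=1)].get_level_values(0).tolist()
    if bad:
        raise ValueError(f"participants missing a within-subject level: {bad}")
    groups_order = list(pd.unique(records["group"]))
    if len(groups_order) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups_order}")
    y = piv[levels].to_numpy(dtype=float)
    g = piv.index.get_level_values("group").to_numpy()
    return y, g, levels, groups_order


@dataclass
class MixedAnovaTable:
    """The three effects of the 2x2 split-plot design plus error terms.

    ``mse_pooled`` is the average of the between- and within-subject
    error mean squares — the single-MSE convention used for the Tukey
    post hocs on the four design cells (error df = N - 2).
    """

    results: dict[str, StatResult]
    mse_between: float
    mse_within: float
    df_error: int

    def __getitem__(self, key: str) -> StatResult:
        return self.results[key]

    def __iter__(self):
        return iter(self.results)

    @property
    def mse_pooled(self) -> float:
        return (self.mse_between + self.mse_within) / 2


def mixed_anova_2x2(records: pd.DataFrame) -> MixedAnovaTable:
    """2x2 mixed (split-plot) ANOVA on long-format ratio records.

    Returns StatResults for the between-subject "group" effect, the
    within-subject "within" effect, and their "interaction", each with
    F, (1, N-2) degrees of freedom and partial eta squared.
    """
    y, g, _levels, groups_order = _as_wide(records)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=1)
    mask = g == groups_order[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    g_means = np.array([y[mask].mean(), y[~mask].mean()])
    ss_betw = float(2 * n1 * (g_means[0] - grand) ** 2 + 2 * n2 * (g_means[1] - grand) ** 2)

    level_means = y.mean(axis=0)
    ss_with = float(n * ((level_means - grand) ** 2).sum())
    rm_error = float(((y - level_means[None, :] - subj_means[:, None] + grand) ** 2).sum())

    cell1 = y[mask].mean(axis=0)
    cell2 = y[~mask].mean(axis=0)
    ss_resall = float(((y[mask] - cell1[None, :]) ** 2).sum() + ((y[~mask] - cell2[None, :]) ** 2).sum())

    ss_inter = ss_total - (ss_resall + ss_with + ss_betw)
    ss_reswith = rm_error - ss_inter
    ss_resbetw = ss_total - (ss_with + ss_betw + ss_reswith + ss_inter)

    df_err = n - 2

    def result(name: str, ss_eff: float, ss_err: float) -> StatResult:
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / df_err
        if ms_err <= 0:
            # degenerate error term: e.g. complementary within-levels
            # (first+third person ratios sum to 1) make every subject
            # mean identical, so the between-subject effect is 0/0
            warnings.warn(
                f"degenerate error term for {name!r} (zero error SS); "
                "effect undefined, reported as F=0, p=1",
                stacklevel=3,
            )
            return StatResult(
                name=name, statistic=0.0, df=(1, df_err), p_raw=1.0,
                effect_size=0.0, effect_size_name="np2",
            )
        F = ms_eff / ms_err
        return StatResult(
            name=name,
            statistic=float(F),
            df=(1, df_err),
            p_raw=float(sps.f.sf(F, 1, df_err)),
            effect_size=float(ss_eff / (ss_eff + ss_err)),
            effect_size_name="np2",
        )

    return MixedAnovaTable(
        results={
            "group": result("group", ss_betw, ss_resbetw),
            "within": result("within", ss_with, ss_reswith),
            "interaction": result("interaction", ss_inter, ss_reswith),
        },
        mse_between=ss_resbetw / df_err,
        mse_within=ss_reswith / df_err,
        df_error=df_err,
    )


def tukey_hsd(records: pd.DataFrame, mse: float, df_error: int) -> list[StatResult]:
    """Tukey HSD over the four cells of the 2x2 design.

    The studentized-range statistic uses the pooled mean squared error
    convention with the supplied error df (Tukey-Kramer correction for
    unequal cell sizes); Cohen's d is the mean difference over sqrt(MSE).
    """
    if mse <= 0:
        raise ValueError("MSE must be positive")
    y, g, levels, groups_order = _as_wide(records)
    mask = g == groups_order[0]
    cells: dict[str, tuple[float, int]] = {}
    for gi, m in ((groups_order[0], mask), (groups_order[1], ~mask)):
        for si, level in enumerate(levels):
            cells[f"{gi}:{level}"] = (float(y[m, si].mean()), int(m.sum()))
    names = list(cells)
    out: list[StatResult] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            (m1, n1), (m2, n2) = cells[names[i]], cells[names[j]]
            diff = m1 - m2
            se = np.sqrt(mse / 2 * (1 / n1 + 1 / n2))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, len(names), df_error))
            out.append(
                StatResult(
                    name=f"{names[i]} vs {names[j]}",
                    statistic=float(q),
                    df=(len(names), df_error),
                    p_raw=min(1.0, p),
                    effect_size=float(diff / np.sqrt(mse)),
                    effect_size_name="cohen_d",
                )
            )
    return out


def one_tailed_t(
    x: Sequence[float],
    y: Sequence[float],
    direction: Literal["greater", "less"] = "greater",
) -> StatResult:
    """One-tailed pooled-variance independent-samples t test (x vs y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per sample")
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=True, alternative=direction)
    d = float((x.mean() - y.mean()) / np.sqrt(sp2))
    return StatResult(
        name=f"t ({direction})",
        statistic=float(res.statistic),
        df=(n1 + n2 - 2, 0),
        p_raw=float(res.pvalue),
        effect_size=d,
        effect_size_name="cohen_d",
        tails="one",
    )


def fdr_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def outlier_screen(values: Sequence[float], threshold: float = 3.0) -> np.ndarray:
    """Flag values strictly farther than ``threshold`` sample SDs from the mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need n >= 3 for outlier screening")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero SD: no outliers can be flagged", stacklevel=2)
        return np.zeros(len(v), dtype=bool)
    return np.abs(v - v.mean()) > threshold * sd


@dataclass
class DunnettResult:
    contrast: str
    statistic: float
    p_value: float
    df: int
    msw: float


def dunnett_t(
    control: tuple[float, float, int],
    treatments: dict[str, tuple[float, float, int]],
    *,
    n_mc: int = 100_000,
    seed: int | None = 12345,
) -> list[DunnettResult]:
    """Dunnett's many-to-one comparisons from summary statistics.

    Inputs are (mean, sd, n) per group. The within-group variance is
    pooled over ALL groups (control included); each contrast statistic
    is |mean_t - mean_c| / sqrt(MSW (1/n_t + 1/n_c)). Two-sided p-values
    come from the equicorrelated multivariate-t max-|T| null, estimated
    by seeded Monte Carlo.
    """
    groups = [control, *treatments.values()]
    if any(n < 2 for _, _, n in groups):
        raise ValueError("every group needs n >= 2")
    df = sum(n - 1 for _, _, n in groups)
    msw = sum((n - 1) * sd**2 for _, sd, n in groups) / df
    m0, _, n0 = control

    rng = np.random.default_rng(seed)
    s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    z0 = rng.normal(0, np.sqrt(1 / n0), size=n_mc)
    t_draws = np.empty((len(treatments), n_mc))
    for k, (_, _, n_t) in enumerate(treatments.values()):
        z_t = rng.normal(0, np.sqrt(1 / n_t), size=n_mc)
        t_draws[k] = (z_t - z0) / (s * np.sqrt(1 / n_t + 1 / n0))
    max_abs = np.abs(t_draws).max(axis=0)

    out: list[DunnettResult] = []
    for name, (m_t, _, n_t) in treatments.items():
        stat = abs(m_t - m0) / np.sqrt(msw * (1 / n_t + 1 / n0))
        p = float((max_abs >= stat).mean())
        out.append(DunnettResult(contrast=name, statistic=float(stat), p_value=p, df=df, msw=msw))
    return out


def chi2_2x2(table: Sequence[Sequence[int]], yates: bool = True) -> StatResult:
    """Pearson chi-squared on a 2x2 count table, optionally Yates-corrected."""
    tab = np.asarray(table)
    if tab.shape != (2, 2) or np.any(tab < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(tab, correction=yates)
    return StatResult(
        name="chi2" + (" (Yates)" if yates else ""),
        statistic=float(res.statistic),
        df=(1, 0),
        p_raw=float(res.pvalue),
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> StatResult | None:
    """Correlation with pairwise deletion of missing values.

    Returns None (with a warning) for constant input or fewer than 3
    complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("correlation undefined (constant input or < 3 pairs)", stacklevel=2)
        return None
    fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    r, p = fn(x, y)
    return StatResult(
        name=method,
        statistic=float(r),
        df=(len(x) - 2, 0),
        p_raw=float(p),
        effect_size=float(r),
        effect_size_name="r",
    )


def correlation_grid(
    df: pd.DataFrame,
    feature_cols: Sequence[str],
    score_cols: Sequence[str],
    method: Literal["pearson", "spearman"] = "spearman",
) -> pd.DataFrame:
    """All feature x score correlations with one FDR family over the grid."""
    rows = []
    for feat in feature_cols:
        for score in score_cols:
            if score not in df.columns:
                continue
            res = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = correlate(df[feat], df[score], method=method)
            rows.append(
                {
                    "feature": feat,
                    "score": score,
                    "r": res.statistic if res else np.nan,
                    "p_raw": res.p_raw if res else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    valid = out["p_raw"].notna()
    out["p_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "p_fdr"] = fdr_bh(out.loc[valid, "p_raw"].to_numpy())
    return out


def apply_fdr(results: Iterable[StatResult]) -> list[StatResult]:
    """Fill p_fdr across one family of StatResults (in place, returned)."""
    results = list(results)
    if results:
        adj = fdr_bh([r.p_raw for r in results])
        for r, a in zip(results, adj):
            r.p_fdr = float(a)
    return results


def wide_to_long(
    df: pd.DataFrame,
    value_cols: tuple[str, str],
    *,
    id_col: str = "participant_id",
    group_col: str = "group",
) -> pd.DataFrame:
    """Melt a features table into the (participant, group, level, value)
    long format the mixed ANOVA consumes."""
    long = df.melt(
        id_vars=[id_col, group_col],
        value_vars=list(value_cols),
        var_name="level",
        value_name="value",
    )
    return long.rename(columns={id_col: "participant_id", group_col: "group"})
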