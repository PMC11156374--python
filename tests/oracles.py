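"""Independent reference computations used as test oracles.

These deliberately avoid the package's own code paths: the split-plot
ANOVA is rebuilt from definitional cell/subject means with plain Python
loops (balanced designs, where every sum of squares has a direct
formula), and the Benjamini-Hochberg adjustment is an exhaustive
step-up enumeration straight from its definition.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import f as f_dist


def bruteforce_mixed_anova(y_g1: np.ndarray, y_g2: np.ndarray) -> dict:
    """Balanced 2x2 split-plot ANOVA from definitional sums of squares.

    ``y_g1``/``y_g2``: (n, 2) arrays, one row per subject, columns = the
    two within-subject levels; both groups must have the same n. Every
    SS is computed directly from cell/subject/level means (no
    subtraction shortcuts).
    """
    n = y_g1.shape[0]
    assert y_g2.shape == (n, 2)
    k = 2  # within levels
    N = 2 * n  # subjects
    data = {1: y_g1, 2: y_g2}

    grand = (y_g1.sum() + y_g2.sum()) / (N * k)
    group_mean = {g: data[g].mean() for g in (1, 2)}
    level_mean = {s: (y_g1[:, s].sum() + y_g2[:, s].sum()) / N for s in (0, 1)}
    cell_mean = {(g, s): data[g][:, s].mean() for g in (1, 2) for s in (0, 1)}
    subj_mean = {(g, i): data[g][i].mean() for g in (1, 2) for i in range(n)}

    ss_group = sum(n * k * (group_mean[g] - grand) ** 2 for g in (1, 2))
    ss_level = sum(N * (level_mean[s] - grand) ** 2 for s in (0, 1))
    ss_inter = sum(
        n * (cell_mean[(g, s)] - group_mean[g] - level_mean[s] + grand) ** 2
        for g in (1, 2)
        for s in (0, 1)
    )
    ss_subj = sum(
        k * (subj_mean[(g, i)] - group_mean[g]) ** 2 for g in (1, 2) for i in range(n)
    )
    ss_resid = sum(
        (data[g][i, s] - cell_mean[(g, s)] - subj_mean[(g, i)] + group_mean[g]) ** 2
        for g in (1, 2)
        for i in range(n)
        for s in (0, 1)
    )

    df_err = N - 2
    out = {}
    for name, ss_eff, ss_err in (
        ("group", ss_group, ss_subj),
        ("within", ss_level, ss_resid),
        ("interaction", ss_inter, ss_resid),
    ):
        F = (ss_eff / 1.0) / (ss_err / df_err)
        out[name] = {
            "F": F,
            "p": float(f_dist.sf(F, 1, df_err)),
            "np2": ss_eff / (ss_eff + ss_err),
        }
    out["ss_total_check"] = ss_group + ss_level + ss_inter + ss_subj + ss_resid
    return out


def bruteforce_fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition: the adjusted value
    of the i-th order statistic is min over j >= i of (m/j) p_(j),
    capped at 1, mapped back to the original order."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(pos, m)]
        adjusted[idx] = min(candidates)
    return adjusted


def binormal_auc(d: float) -> float:
    """Theoretical AUC for two unit-variance Gaussians separated by d."""
    from scipy.stats import norm

    return float(norm.cdf(d / np.sqrt(2)))
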