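"""Mixed-design ANOVAs, post-hoc contrasts and clinical correlations.

The mixed ANOVA handles one between-subjects factor (Group) crossed with
any number of fully-crossed within-subject factors on a balanced
within-design (every subject contributes one value per within-cell;
between-group sizes may differ). Sums of squares are Type III, computed
via the univariate approach: each within-effect is projected onto an
orthonormal contrast basis and tested with a one-way between-groups
analysis of the per-subject contrast scores, which reproduces the classic
mixed-model F tests (e.g. F(1, 48) for a 2-group, 2-level-within effect
with 50 subjects). No sphericity correction is applied by default;
Greenhouse-Geisser is available via a flag. Post-hoc contrasts follow the
Fisher-LSD convention (uncorrected pairwise t tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "mixed_anova",
    "posthoc_pairwise",
    "severity_correlation",
    "sensitivity_rerun",
    "clinical_table",
    "clinical_descriptives",
]


@dataclass(frozen=True)
class AnovaResult:
    """One effect row: F statistic, degrees of freedom, P, partial eta^2."""

    effect: str
    F: float
    df_num: float
    df_den: float
    P: float
    eta_p2: float


def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """(n_levels, n_levels-1) orthonormal columns orthogonal to ones."""
    return helmert(n_levels).T


def _gg_epsilon(z: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast scores (subjects x q)."""
    s = np.cov(z, rowvar=False)
    s = np.atleast_2d(s)
    q = s.shape[0]
    return float(np.trace(s) ** 2 / (q * np.sum(s * s)))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: list[str],
    subject: str,
    sphericity_correction: bool = False,
) -> pd.DataFrame:
    """Type-III mixed-design ANOVA table.

    ``data`` is long-format. Subjects with missing within-cells are
    dropped with a log entry. Returns a DataFrame with one row per main
    effect and interaction (columns ``effect, F, df_num, df_den, P,
    eta_p2``).
    """
    within = list(within)
    levels = {w: list(pd.unique(data[w])) for w in within}
    cells = list(product(*levels.values())) if within else [()]
    wide = data.pivot_table(
        index=[subject, between], columns=within or None, values=dv, aggfunc="mean"
    )
    if within:
        wide = wide.reindex(
            columns=pd.MultiIndex.from_tuples(cells, names=within)
            if len(within) > 1
            else [c[0] for c in cells]
        )
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        dropped = wide.index[incomplete].get_level_values(0).tolist()
        logger.warning("dropping subjects with missing cells: %s", dropped)
        wide = wide[~incomplete]
    groups = wide.index.get_level_values(between).to_numpy()
    group_names = list(pd.unique(groups))
    g = len(group_names)
    n_g = np.array([(groups == name).sum() for name in group_names], dtype=float)
    n_total = int(n_g.sum())
    if g < 2 or (n_g < 2).any():
        raise ValueError("need >= 2 subjects in each of >= 2 groups")
    y = wide.to_numpy(dtype=float)

    def one_way(z: np.ndarray) -> tuple[float, float, float]:
        """(SS_intercept_III, SS_group_III, SS_error) for columns of z."""
        ss_int = ss_grp = ss_err = 0.0
        for col in np.atleast_2d(z.T):
            m_g = np.array([col[groups == name].mean() for name in group_names])
            m_unw = m_g.mean()
            ss_int += m_unw**2 * g**2 / np.sum(1.0 / n_g)
            grand = col.mean()
            ss_grp += float(np.sum(n_g * (m_g - grand) ** 2))
            ss_err += float(
                sum(np.sum((col[groups == name] - m_g[i]) ** 2)
                    for i, name in enumerate(group_names))
            )
        return ss_int, ss_grp, ss_err

    rows: list[AnovaResult] = []

    def add(effect: str, ss: float, df1: float, ss_err: float, df2: float, eps: float = 1.0):
        df1_c, df2_c = df1 * eps, df2 * eps
        if ss_err <= 0:
            f = 0.0 if ss <= 0 else np.inf
        else:
            f = (ss / df1_c) / (ss_err / df2_c)
        p = float(sps.f.sf(f, df1_c, df2_c)) if np.isfinite(f) else 0.0
        eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        rows.append(AnovaResult(effect, float(f), df1_c, df2_c, p, float(eta)))

    # between-subjects effect on the per-subject means
    n_cells = y.shape[1]
    z0 = y.mean(axis=1) * np.sqrt(n_cells)
    _, ss_grp, ss_err0 = one_way(z0[:, None])
    add(between, ss_grp, g - 1, ss_err0, n_total - g)

    # within effects and their interactions with the between factor
    contr = {w: _orthonormal_contrasts(len(levels[w])) for w in within}
    ones = {w: np.full((len(levels[w]), 1), 1.0 / np.sqrt(len(levels[w]))) for w in within}
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            m = np.ones((1, 1))
            for w in within:
                m = np.kron(m, contr[w] if w in combo else ones[w])
            z = y @ m
            q = z.shape[1]
            eps = _gg_epsilon(z) if (sphericity_correction and q > 1) else 1.0
            ss_int, ss_grp, ss_err = one_way(z)
            name = " * ".join(combo)
            add(name, ss_int, q, ss_err, q * (n_total - g), eps)
            add(f"{between} * {name}", ss_grp, q * (g - 1), ss_err, q * (n_total - g), eps)

    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs["n_subjects"] = n_total
    out.attrs["groups"] = {name: int(k) for name, k in zip(group_names, n_g)}
    return out


def posthoc_pairwise(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: list[str],
    subject: str,
) -> pd.DataFrame:
    """Fisher-LSD style cell-wise pairwise comparisons.

    Cells are the within-factor level combinations. Between-group
    contrasts at each cell use independent-samples t tests; within-cell
    contrasts inside each group use paired t tests. P values are
    uncorrected, as is conventional for this post-hoc family.
    """
    within = list(within)
    wide = data.pivot_table(
        index=[subject, between], columns=within or None, values=dv, aggfunc="mean"
    )
    groups = wide.index.get_level_values(between)
    rows = []
    cols = list(wide.columns)
    # between-group, per within-cell
    for col in cols:
        for ga, gb in combinations(pd.unique(groups), 2):
            a = wide.loc[groups == ga, col].dropna()
            b = wide.loc[groups == gb, col].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = sps.ttest_ind(a, b)
            rows.append(
                {
                    "contrast": f"{ga} vs {gb} @ {col}",
                    "type": "between",
                    "mean_a": a.mean(), "mean_b": b.mean(),
                    "diff": a.mean() - b.mean(),
                    "t": float(t), "df": len(a) + len(b) - 2, "P": float(p),
                }
            )
    # within-group, per cell pair
    for gname in pd.unique(groups):
        sub = wide.loc[groups == gname]
        for ca, cb in combinations(cols, 2):
            paired = sub[[ca, cb]].dropna()
            if len(paired) < 2:
                continue
            a, b = paired[ca], paired[cb]
            if np.allclose(a, b):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(a, b)
            rows.append(
                {
                    "contrast": f"{gname}: {ca} vs {cb}",
                    "type": "within",
                    "mean_a": a.mean(), "mean_b": b.mean(),
                    "diff": a.mean() - b.mean(),
                    "t": float(t), "df": len(a) - 1, "P": float(p),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    df: int
    P: float
    method: str
    flagged: bool = False


def severity_correlation(
    scores, severity, method: str = "spearman"
) -> CorrelationResult:
    """Correlation between learning scores and a clinical severity scale."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(severity, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("need at least 4 matched subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: correlation undefined")
        return CorrelationResult(float("nan"), len(x) - 2, float("nan"), method, True)
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return CorrelationResult(float(r), len(x) - 2, float(p), method)


def sensitivity_rerun(
    data: pd.DataFrame,
    subjects: pd.DataFrame,
    analyses: dict[str, dict],
    subject_col: str = "subject",
    alpha: float = 0.05,
    trend: float = 0.10,
) -> dict:
    """Medication-free rerun of every ANOVA.

    Medicated patients and their matched controls (from the cohort's
    ``matched_to`` map) are excluded and each analysis in ``analyses``
    (name -> mixed_anova keyword arguments) is re-executed. Significance
    classes: significant (P < alpha), trend (P < trend) and ns.
    """
    medicated = subjects.loc[subjects["medicated"].astype(bool), subject_col]
    matched = subjects.set_index(subject_col).loc[medicated, "matched_to"]
    excluded = set(medicated) | set(matched)
    reduced = data[~data[subject_col].isin(excluded)]
    remaining = subjects[~subjects[subject_col].isin(excluded)]
    if (remaining.groupby("group").size() < 3).any():
        raise ValueError("fewer than 3 subjects per group after exclusion")

    def classify(p: float) -> str:
        return "significant" if p < alpha else ("trend" if p < trend else "ns")

    full_res, red_res, changes = {}, {}, []
    for name, kwargs in analyses.items():
        full_res[name] = mixed_anova(data, subject=subject_col, **kwargs)
        red_res[name] = mixed_anova(reduced, subject=subject_col, **kwargs)
        merged = full_res[name].merge(
            red_res[name], on="effect", suffixes=("_full", "_reduced")
        )
        for _, row in merged.iterrows():
            c_full, c_red = classify(row["P_full"]), classify(row["P_reduced"])
            if c_full != c_red:
                changes.append(
                    {
                        "analysis": name, "effect": row["effect"],
                        "P_full": row["P_full"], "P_reduced": row["P_reduced"],
                        "class_full": c_full, "class_reduced": c_red,
                    }
                )
    return {
        "full": full_res,
        "reduced": red_res,
        "n_excluded": len(excluded),
        "changed": pd.DataFrame(changes),
    }


def clinical_table() -> pd.DataFrame:
    """Packaged clinical-characteristics fixture of the 25 patients.

    Columns: patient, age, sex (1 = male, 2 = female), disease duration
    (years), diagnostic confidence index (DCI), YGTSS total, YGTSS tics,
    Rush video score (missing for 5 patients), comorbidities, medication.
    """
    with resources.files("asrtnet.data").joinpath("clinical_gts.csv").open() as f:
        # keep "N/A" medication entries (medicated, drug unspecified) as text
        return pd.read_csv(f, keep_default_na=False, na_values=[""])


def clinical_descriptives(clinical: pd.DataFrame | None = None) -> pd.Series:
    """Column means of the clinical table over available (non-missing) values."""
    if clinical is None:
        clinical = clinical_table()
    numeric = clinical.drop(columns=["patient"], errors="ignore").select_dtypes("number")
    means = numeric.mean()
    if means.isna().any():
        raise ValueError("empty clinical column: mean undefined")
    return means
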