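"""Cohort statistics: normality, group tests, adjusted correlations, ROC.

Implements the analysis layer applied to the measured SNc/LC volumes:
Shapiro-Wilk normality per group, two-tailed Welch's t (from raw samples or
from printed mean ± SE summaries), ANCOVA for the group effect with
covariates, Pearson correlations with age partialled out, and ROC/AUC with
Hanley–McNeil (or DeLong) standard errors, including a combined SNc+LC
marker built by logistic regression. Results are reported as mean ±
standard error with α = 0.05, and no multiple-testing correction is applied
by default (every test performed is logged in the report instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DegenerateDataError

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "ROCResult",
    "shapiro_wilk",
    "welch_t",
    "welch_t_from_summary",
    "ancova_group_effect",
    "partial_correlation",
    "roc_auc",
    "combine_markers",
    "SUBJECT_COLUMNS",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "disease_duration",
    "updrs3",
    "ledd",
    "moca",
    "nmsq",
    "rbdsq",
    "snc_volume",
    "lc_volume",
]


@dataclass
class GroupComparison:
    """A two-group test result (t or F statistic)."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    group_means: dict[str, float]
    group_ses: dict[str, float]
    test_name: str
    covariate_p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class CorrelationResult:
    """Pearson correlation with covariates partialled out."""

    r: float
    p_value: float
    n: int
    covariates: list[str]

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


@dataclass
class ROCResult:
    """Empirical ROC curve with AUC, SE and normal-approximation 95% CI."""

    auc: float
    se: float
    ci95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    p_value: float
    se_method: str
    n_positive: int
    n_negative: int
    orientation: str


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one sample (n ≥ 3).

    A constant sample leaves W undefined and raises
    :class:`DegenerateDataError`.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got n = {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: Shapiro-Wilk W is undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def welch_t_from_summary(
    mean_a: float,
    se_a: float,
    n_a: int,
    mean_b: float,
    se_b: float,
    n_b: int,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-tailed Welch's t-test from group summaries (mean, SE, n).

    t = (m_a − m_b) / √(se_a² + se_b²) with the Welch–Satterthwaite degrees
    of freedom. Lets printed tables (mean ± SE) be re-tested directly.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = se_a**2, se_b**2
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        statistic=float(t),
        df=float(df),
        p_value=float(p),
        group_means={labels[0]: float(mean_a), labels[1]: float(mean_b)},
        group_ses={labels[0]: float(se_a), labels[1]: float(se_b)},
        test_name="welch_t",
    )


def welch_t(
    sample_a, sample_b, labels: tuple[str, str] = ("a", "b")
) -> GroupComparison:
    """Two-tailed Welch's t-test from raw samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return GroupComparison(
                statistic=0.0,
                df=float(a.size + b.size - 2),
                p_value=1.0,
                group_means={labels[0]: float(a.mean()), labels[1]: float(b.mean())},
                group_ses={labels[0]: 0.0, labels[1]: 0.0},
                test_name="welch_t",
            )
        raise DegenerateDataError("zero variance in both groups with unequal means")
    se_a = a.std(ddof=1) / np.sqrt(a.size)
    se_b = b.std(ddof=1) / np.sqrt(b.size)
    return welch_t_from_summary(
        a.mean(), se_a, a.size, b.mean(), se_b, b.size, labels=labels
    )


def ancova_group_effect(
    records: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    group_column: str = "group",
) -> GroupComparison:
    """ANCOVA: linear model ``outcome ~ group + covariates`` by least squares.

    Reports the partial F for the group term on (1, n − p − 1) degrees of
    freedom (for a two-level group this equals the squared coefficient t),
    together with per-covariate p-values. Raises on a rank-deficient design
    (e.g. a covariate duplicating the group indicator).
    """
    covariates = list(covariates or [])
    data = records.dropna(subset=[outcome, group_column] + covariates)
    levels = sorted(data[group_column].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    n = len(data)
    p = 1 + len(covariates)
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} subjects, got {n}")

    indicator = (data[group_column] == levels[1]).astype(float).to_numpy()
    X = np.column_stack(
        [indicator] + [data[c].to_numpy(dtype=float) for c in covariates]
    )
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient ANCOVA design matrix")
    y = data[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()

    t_group = fit.tvalues[1]
    f_stat = float(t_group**2)
    df_resid = float(fit.df_resid)
    p_group = float(fit.pvalues[1])
    cov_p = {c: float(fit.pvalues[2 + i]) for i, c in enumerate(covariates)}

    means, ses = {}, {}
    for level in levels:
        vals = data.loc[data[group_column] == level, outcome].to_numpy(dtype=float)
        means[str(level)] = float(vals.mean())
        ses[str(level)] = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return GroupComparison(
        statistic=f_stat,
        df=(1.0, df_resid),
        p_value=p_group,
        group_means=means,
        group_ses=ses,
        test_name="ancova_F",
        covariate_p_values=cov_p,
    )


def partial_correlation(x, y, covariate, covariate_name: str = "age") -> CorrelationResult:
    """Pearson r between x and y after regressing out one covariate.

    Both variables are residualized on the covariate (with intercept) by
    least squares; p comes from t = r·√((n−3)/(1−r²)) on n−3 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"partial correlation needs n >= 4, got {n}")
    if not (y.size == n and z.size == n):
        raise ValueError("x, y, covariate must have equal length")
    design = np.column_stack([np.ones(n), z])

    def residualize(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx, ry = residualize(x), residualize(y)
    if np.allclose(rx, 0, atol=1e-12) or np.allclose(ry, 0, atol=1e-12):
        raise DegenerateDataError(
            "zero residual variance after removing the covariate"
        )
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, p_value=p, n=n, covariates=[covariate_name])


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via placement values."""
    m, n = scores_pos.size, scores_neg.size

    def placements(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # fraction of b that each element of a beats (ties count half)
        less = np.searchsorted(np.sort(b), a, side="left")
        leq = np.searchsorted(np.sort(b), a, side="right")
        return (less + 0.5 * (leq - less)) / b.size

    v10 = placements(scores_pos, scores_neg)
    v01 = 1.0 - placements(scores_neg, scores_pos)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(np.sqrt(s10 / m + s01 / n))


def roc_auc(
    scores,
    labels,
    positive_label="pd",
    positive_direction: str = "lower",
    se_method: str = "hanley-mcneil",
) -> ROCResult:
    """Empirical ROC curve and AUC for a scalar diagnostic marker.

    With ``positive_direction='lower'`` (the default for volumes: lower
    volume indicates disease) the score sign is flipped internally, so an
    informative marker yields AUC > 0.5 regardless of its direction; the
    orientation used is recorded on the result. SE is Hanley–McNeil by
    default, with DeLong as an option; the 95% CI is AUC ± 1.96·SE truncated
    to [0, 1], and p tests AUC = 0.5 against the null SE.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_pos = labels == positive_label
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    if positive_direction not in ("lower", "higher"):
        raise ValueError("positive_direction must be 'lower' or 'higher'")
    oriented = -scores if positive_direction == "lower" else scores

    fpr, tpr, _ = _sk_roc_curve(is_pos.astype(int), oriented)
    auc = float(np.trapezoid(tpr, fpr))
    if se_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, n_pos, n_neg)
    elif se_method == "delong":
        se = _delong_se(oriented[is_pos], oriented[~is_pos])
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    ci = (max(auc - 1.96 * se, 0.0), min(auc + 1.96 * se, 1.0))
    se_null = _hanley_mcneil_se(0.5, n_pos, n_neg)
    p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se_null)) if se_null > 0 else 1.0
    return ROCResult(
        auc=auc,
        se=se,
        ci95=ci,
        fpr=fpr,
        tpr=tpr,
        p_value=p,
        se_method=se_method,
        n_positive=n_pos,
        n_negative=n_neg,
        orientation=positive_direction,
    )


def combine_markers(
    records: pd.DataFrame,
    markers: list[str] = ("snc_volume", "lc_volume"),
    group_column: str = "group",
    positive_label="pd",
    se_method: str = "hanley-mcneil",
) -> tuple[np.ndarray, ROCResult]:
    """Combine markers by logistic regression; ROC on the fitted probability.

    Fits group ~ markers by maximum likelihood; zero-variance markers are
    dropped (they carry no information and would make the design collinear
    with the intercept). Under perfect separation the ML fit diverges — a
    warning is issued and an L2-penalized fit is used instead; the resulting
    score ranking (hence the ROC) is well defined either way.
    """
    markers = [m for m in markers]
    data = records.dropna(subset=list(markers) + [group_column])
    y = (data[group_column] == positive_label).astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("combine_markers needs both classes present")
    informative = [m for m in markers if np.ptp(data[m].to_numpy(dtype=float)) > 0]
    if not informative:
        raise DegenerateDataError("all markers are constant")
    X = data[informative].to_numpy(dtype=float)
    # standardize for optimizer conditioning; invariant for the fitted probs
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = sm.add_constant((X - mu) / sd, has_constant="add")

    probs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xs).fit(disp=0, maxiter=200)
            # on standardized predictors, coefficients this large mean the
            # likelihood is diverging (separation), not a real ML optimum
            if np.isfinite(fit.params).all() and np.abs(fit.params).max() < 30:
                probs = fit.predict(Xs)
        except Exception:
            probs = None
    if probs is None:
        warnings.warn(
            "perfect or near-perfect separation; using an L2-penalized "
            "logistic fit for the combined score",
            stacklevel=2,
        )
        fit = sm.Logit(y, Xs).fit_regularized(
            disp=0, alpha=1.0, L1_wt=0.0, maxiter=500
        )
        probs = fit.predict(Xs)

    roc = roc_auc(
        probs,
        data[group_column].to_numpy(),
        positive_label=positive_label,
        positive_direction="higher",
        se_method=se_method,
    )
    return np.asarray(probs), roc


# ---------------------------------------------------------------------------
# Cohort report

_STRUCTURES = {"snc_volume": "SNc", "lc_volume": "LC"}
# correlations examined in the patient group, each with age partialled out
_PD_CORRELATIONS = {
    "snc_volume": ["updrs3", "ledd", "moca", "disease_duration", "lc_volume"],
    "lc_volume": ["updrs3", "moca", "disease_duration"],
}


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "test": c.test_name,
        "statistic": c.statistic,
        "df": list(c.df) if isinstance(c.df, tuple) else c.df,
        "p_value": c.p_value,
        "group_means": c.group_means,
        "group_ses": c.group_ses,
        "covariate_p_values": c.covariate_p_values,
    }


def _roc_dict(r: ROCResult) -> dict:
    return {
        "auc": r.auc,
        "se": r.se,
        "ci95": list(r.ci95),
        "p_value": r.p_value,
        "se_method": r.se_method,
        "n_positive": r.n_positive,
        "n_negative": r.n_negative,
        "orientation": r.orientation,
        "curve": {"fpr": r.fpr.tolist(), "tpr": r.tpr.tolist()},
    }


def cohort_report(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    roc_se_method: str = "hanley-mcneil",
    positive_label: str = "pd",
) -> dict:
    """Full statistics report on a merged subject table.

    ``records`` needs group, age and the measured volumes; clinical columns
    are used where present. Sections: per-group Shapiro-Wilk normality,
    Welch group comparison and ANCOVA per structure, age-adjusted Pearson
    correlations in the patient group, and ROC/AUC for each volume plus the
    logistic combined marker. With a single group, the group-level sections
    are skipped with an explicit notice. Every test performed is listed; no
    multiple-comparison correction is applied.
    """
    covariates = list(covariates if covariates is not None else ["age", "education"])
    report: dict = {
        "alpha": alpha,
        "n_by_group": records["group"].value_counts().to_dict(),
        "tests_performed": [],
        "notices": [],
    }
    groups = sorted(records["group"].unique())

    normality: dict = {}
    for outcome, label in _STRUCTURES.items():
        if outcome not in records:
            continue
        normality[label] = {}
        for g in groups:
            vals = records.loc[records["group"] == g, outcome].dropna()
            try:
                w, p = shapiro_wilk(vals)
                normality[label][g] = {"W": w, "p_value": p, "n": int(vals.size)}
            except (ValueError, DegenerateDataError) as exc:
                normality[label][g] = {"degenerate": str(exc), "n": int(vals.size)}
            report["tests_performed"].append(f"shapiro_wilk:{label}:{g}")
    report["normality"] = normality

    two_groups = len(groups) == 2 and {positive_label} < set(groups)
    if not two_groups:
        report["notices"].append(
            "group comparisons skipped: need exactly one control and one "
            f"'{positive_label}' group, found {groups}"
        )
        return report

    control_label = next(g for g in groups if g != positive_label)
    comparisons: dict = {}
    for outcome, label in _STRUCTURES.items():
        if outcome not in records:
            continue
        a = records.loc[records["group"] == control_label, outcome].dropna()
        b = records.loc[records["group"] == positive_label, outcome].dropna()
        block: dict = {}
        try:
            block["welch"] = _comparison_dict(
                welch_t(a, b, labels=(control_label, positive_label))
            )
            report["tests_performed"].append(f"welch_t:{label}")
        except (ValueError, DegenerateDataError) as exc:
            block["welch"] = {"error": str(exc)}
        usable_cov = [
            c for c in covariates if c in records and records[c].notna().all()
        ]
        try:
            block["ancova"] = _comparison_dict(
                ancova_group_effect(records, outcome, usable_cov)
            )
            block["ancova"]["covariates"] = usable_cov
            report["tests_performed"].append(f"ancova:{label}")
        except (ValueError, np.linalg.LinAlgError) as exc:
            block["ancova"] = {"error": str(exc), "covariates": usable_cov}
        comparisons[label] = block
    report["group_comparisons"] = comparisons

    correlations: dict = {}
    pd_rows = records[records["group"] == positive_label]
    for outcome, partners in _PD_CORRELATIONS.items():
        if outcome not in records:
            continue
        label = _STRUCTURES[outcome]
        correlations[label] = {}
        for partner in partners:
            if partner not in pd_rows:
                continue
            sub = pd_rows.dropna(subset=[outcome, partner, "age"])
            if len(sub) < 4:
                correlations[label][partner] = {"error": "n < 4"}
                continue
            try:
                res = partial_correlation(
                    sub[outcome], sub[partner], sub["age"]
                )
                correlations[label][partner] = {
                    "r": res.r,
                    "p_value": res.p_value,
                    "n": res.n,
                    "covariates": res.covariates,
                }
                report["tests_performed"].append(
                    f"partial_correlation:{label}:{partner}"
                )
            except DegenerateDataError as exc:
                correlations[label][partner] = {"error": str(exc)}
    report["correlations_pd_group"] = correlations

    roc_block: dict = {}
    for outcome, label in _STRUCTURES.items():
        if outcome not in records:
            continue
        sub = records.dropna(subset=[outcome])
        roc_block[label] = _roc_dict(
            roc_auc(
                sub[outcome],
                sub["group"],
                positive_label=positive_label,
                positive_direction="lower",
                se_method=roc_se_method,
            )
        )
        report["tests_performed"].append(f"roc_auc:{label}")
    both = [o for o in _STRUCTURES if o in records]
    if len(both) == 2:
        try:
            _, combined = combine_markers(
                records,
                markers=both,
                positive_label=positive_label,
                se_method=roc_se_method,
            )
            roc_block["combined"] = _roc_dict(combined)
            report["tests_performed"].append("roc_auc:combined")
        except DegenerateDataError as exc:
            roc_block["combined"] = {"error": str(exc)}
    report["roc"] = roc_block
    return report


def report_markdown(report: dict) -> str:
    """Render a cohort report dict as a short Markdown document."""
    lines = ["# Cohort statistics report", ""]
    lines.append(f"Groups: {report.get('n_by_group', {})}; α = {report.get('alpha')}")
    for notice in report.get("notices", []):
        lines.append(f"> {notice}")
    if "normality" in report:
        lines += ["", "## Normality (Shapiro-Wilk)", ""]
        for label, by_group in report["normality"].items():
            for g, res in by_group.items():
                if "W" in res:
                    lines.append(
                        f"- {label} / {g}: W = {res['W']:.3f}, "
                        f"p = {res['p_value']:.3g} (n = {res['n']})"
                    )
                else:
                    lines.append(f"- {label} / {g}: {res.get('degenerate')}")
    if "group_comparisons" in report:
        lines += ["", "## Group comparisons", ""]
        for label, block in report["group_comparisons"].items():
            w = block.get("welch", {})
            if "statistic" in w:
                means = ", ".join(
                    f"{g}: {m:.1f} ± {w['group_ses'][g]:.1f}"
                    for g, m in w["group_means"].items()
                )
                lines.append(
                    f"- {label} Welch t = {w['statistic']:.3f}, "
                    f"df = {w['df']:.1f}, p = {w['p_value']:.4g} ({means})"
                )
            a = block.get("ancova", {})
            if "statistic" in a:
                lines.append(
                    f"- {label} ANCOVA (covariates {a.get('covariates')}): "
                    f"F = {a['statistic']:.3f}, p = {a['p_value']:.4g}"
                )
    if "correlations_pd_group" in report:
        lines += ["", "## Age-adjusted correlations (patient group)", ""]
        for label, partners in report["correlations_pd_group"].items():
            for partner, res in partners.items():
                if "r" in res:
                    lines.append(
                        f"- {label} ~ {partner}: r = {res['r']:.3f}, "
                        f"p = {res['p_value']:.3g} (n = {res['n']})"
                    )
    if "roc" in report:
        lines += ["", "## ROC analysis", ""]
        for label, res in report["roc"].items():
            lines.append(
                f"- {label}: AUC = {res['auc']:.3f} "
                f"(SE {res['se']:.3f}, 95% CI {res['ci95'][0]:.3f}–"
                f"{res['ci95'][1]:.3f}, p = {res['p_value']:.3g})"
            )
    lines.append("")
    return "\n".join(lines)
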