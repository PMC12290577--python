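"""Group statistics on ROI summary tables.

Paired within-subject comparisons (paired t or Wilcoxon signed-rank chosen
by a Shapiro-Wilk normality check on the differences) and covariate-adjusted
between-group differences by ordinary least squares (metric ~ group + age +
sex [+ lesion volume for disease-course contrasts]).  Two-sided p-values;
no multiple-testing correction enters any decision, but a Benjamini-Hochberg
adjusted column is emitted alongside for reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .roi import METRICS

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: tuple[int, ...]
    test: str


def _hodges_lehmann_ci(diffs: np.ndarray, level: float = 0.95):
    """Hodges-Lehmann pseudo-median and distribution-free CI from Walsh averages."""
    n = diffs.size
    ii, jj = np.triu_indices(n)
    walsh = np.sort((diffs[ii] + diffs[jj]) / 2.0)
    est = float(np.median(walsh))
    z = sps.norm.ppf(0.5 + level / 2.0)
    m = n * (n + 1) / 2.0
    k = int(np.floor(m / 2.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)))
    k = max(k, 0)
    if k >= walsh.size // 2:
        return est, float(walsh[0]), float(walsh[-1])
    return est, float(walsh[k]), float(walsh[-(k + 1)])


def paired_compare(values_a, values_b, normality: str = "auto") -> ComparisonResult:
    """Two-sided paired comparison of per-subject metric pairs.

    ``normality``: "t" forces the paired t-test, "wilcoxon" the signed-rank
    test, "auto" picks by Shapiro-Wilk on the paired differences at 0.05.
    Pairs with a missing member are dropped; fewer than 3 complete pairs is
    an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    d = a - b
    if normality not in ("auto", "t", "wilcoxon"):
        raise ValueError("normality must be one of auto|t|wilcoxon")
    if np.all(d == d[0]):
        # zero-variance differences: degenerate t branch
        est = float(d[0])
        p = 1.0 if est == 0.0 else 0.0
        return ComparisonResult("paired", est, est, est, p, (n,), "paired_t")
    use_t = normality == "t"
    if normality == "auto":
        use_t = sps.shapiro(d).pvalue >= 0.05
    if use_t:
        res = sps.ttest_rel(a, b)
        est = float(np.mean(d))
        se = float(np.std(d, ddof=1) / np.sqrt(n))
        tcrit = sps.t.ppf(0.975, n - 1)
        return ComparisonResult(
            "paired", est, est - tcrit * se, est + tcrit * se,
            float(res.pvalue), (n,), "paired_t",
        )
    res = sps.wilcoxon(a, b, zero_method="wilcox", mode="auto")
    est, lo, hi = _hodges_lehmann_ci(d)
    return ComparisonResult("paired", est, lo, hi, float(res.pvalue), (n,), "wilcoxon")


def adjusted_group_difference(
    table: pd.DataFrame,
    metric: str,
    group_col: str,
    levels: tuple[str, str],
    covariates: tuple[str, ...] = ("age", "sex"),
) -> ComparisonResult:
    """OLS-adjusted difference in ``metric`` between two group levels.

    Fits metric ~ 1 + I(group == levels[1]) + covariates on the rows
    belonging to the two levels and reports the group coefficient
    (levels[1] minus levels[0]) with its 95 % CI and two-sided p-value.
    Categorical covariates (e.g. sex) are indicator-coded; constant
    covariate columns are dropped with a logged warning.
    """
    sub = table[table[group_col].isin(levels)].copy()
    sub = sub.dropna(subset=[metric])
    n_by = tuple(int((sub[group_col] == g).sum()) for g in levels)
    if min(n_by) < 3:
        raise ValueError(
            f"need >= 3 subjects per level for {metric} {levels}, got {n_by}"
        )
    y = sub[metric].astype(float).to_numpy()
    cols = {"group": (sub[group_col] == levels[1]).astype(float).to_numpy()}
    for cov in covariates:
        v = sub[cov]
        if v.dtype == object or str(v.dtype) == "category" or v.dtype == bool:
            ref = sorted(v.astype(str).unique())[0]
            col = (v.astype(str) != ref).astype(float).to_numpy()
            log.debug("covariate %s indicator-coded with reference level %r", cov, ref)
        else:
            col = v.astype(float).to_numpy()
        if np.all(col == col[0]):
            log.warning("covariate %r is constant in this contrast; dropped", cov)
            continue
        cols[cov] = col
    X = pd.DataFrame(cols, index=sub.index)
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if corr.size else ("?", "?")
        raise ValueError(
            f"rank-deficient design for {metric}: collinear columns {worst}"
        )
    fit = sm.OLS(y, Xc).fit()
    ci = fit.conf_int().loc["group"]
    return ComparisonResult(
        contrast=f"{levels[1]}_vs_{levels[0]}",
        estimate=float(fit.params["group"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["group"]),
        n=n_by[::-1],
        test="ols_adjusted",
    )


def _row(contrast, metric, res: ComparisonResult | None, note: str = ""):
    if res is None:
        return dict(
            contrast=contrast, metric=metric, estimate=np.nan, ci_low=np.nan,
            ci_high=np.nan, p=np.nan, n="", test="missing", note=note,
        )
    return dict(
        contrast=contrast, metric=metric, estimate=res.estimate, ci_low=res.ci_low,
        ci_high=res.ci_high, p=res.p_value, n="/".join(str(v) for v in res.n),
        test=res.test, note=note,
    )


def run_comparison_suite(cohort: pd.DataFrame) -> pd.DataFrame:
    """All between- and within-group contrasts on a tidy cohort table.

    ``cohort`` has one row per subject x ROI with columns: subject, group
    (MS|SC), disease_course, age, sex, t2_lesion_volume_ml, bbb_leakage
    (bool), roi, and the metric columns.  Emits one row per contrast x
    metric; contrasts that cannot be computed (insufficient n) appear as
    missing rows rather than being dropped.
    """
    rows: list[dict] = []
    if cohort.empty:
        return pd.DataFrame(
            columns=["contrast", "metric", "estimate", "ci_low", "ci_high",
                     "p", "p_bh", "n", "test", "note"]
        )

    def pivot(roi):
        return cohort[cohort["roi"] == roi].set_index("subject")

    ms_les = pivot("ms_t2flair")
    unspec = pivot("unspecific_t2flair")
    t1_les = pivot("ms_t1")
    subj = cohort.drop_duplicates("subject").set_index("subject")

    has_ms = "MS" in set(cohort["group"])
    has_sc = "SC" in set(cohort["group"])

    for metric in METRICS:
        # MS T2-FLAIR lesions (MS) vs unspecific lesions (SC), adjusted
        if has_ms and has_sc:
            tab = pd.concat(
                [
                    ms_les[ms_les["group"] == "MS"],
                    unspec[unspec["group"] == "SC"],
                ]
            ).reset_index()
            try:
                res = adjusted_group_difference(
                    tab, metric, "group", ("SC", "MS"), ("age", "sex")
                )
            except ValueError as e:
                res, note = None, str(e)
            else:
                note = ""
            rows.append(_row("ms_t2flair_MS_vs_unspecific_SC", metric, res, note))

        # within-MS: MS T2-FLAIR vs unspecific lesions, paired
        if has_ms:
            both = ms_les.join(
                unspec[[metric]], how="inner", lsuffix="", rsuffix="_unspec"
            )
            both = both[both["group"] == "MS"]
            try:
                res = paired_compare(both[metric], both[f"{metric}_unspec"])
            except ValueError as e:
                res, note = None, str(e)
            else:
                note = ""
            rows.append(_row("ms_t2flair_vs_unspecific_withinMS_paired", metric, res, note))

            # T1 lesions vs T2-FLAIR lesions within leakage subjects, paired
            both = t1_les.join(ms_les[[metric]], how="inner", lsuffix="", rsuffix="_t2")
            try:
                res = paired_compare(both[metric], both[f"{metric}_t2"])
            except ValueError as e:
                res, note = None, str(e)
            else:
                note = ""
            rows.append(_row("ms_t1_vs_ms_t2flair_paired", metric, res, note))

            # T2-FLAIR lesions stratified by BBB-leakage status, adjusted
            strat = ms_les[ms_les["group"] == "MS"].reset_index().copy()
            strat["leak"] = np.where(strat["bbb_leakage"].astype(bool), "w", "wo")
            try:
                res = adjusted_group_difference(
                    strat, metric, "leak", ("wo", "w"), ("age", "sex")
                )
            except ValueError as e:
                res, note = None, str(e)
            else:
                note = ""
            rows.append(_row("ms_t2flair_leakage_w_vs_wo", metric, res, note))

            # disease-course contrasts, additionally adjusted for lesion volume
            course = ms_les[ms_les["group"] == "MS"].reset_index()
            for a, b in (("CIS", "RRMS"), ("CIS", "PPMS")):
                tab = course[course["disease_course"].isin((a, b))]
                try:
                    res = adjusted_group_difference(
                        tab, metric, "disease_course", (a, b),
                        ("age", "sex", "t2_lesion_volume_ml"),
                    )
                except ValueError as e:
                    res, note = None, str(e)
                else:
                    note = ""
                rows.append(_row(f"{b}_vs_{a}_ms_t2flair", metric, res, note))

    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_bh"] = np.nan
    if mask.any():
        out.loc[mask, "p_bh"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out
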