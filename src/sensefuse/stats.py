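"""Evaluation statistics for the cross-study experiment.

Implements per-subject MAE summaries, paired-delta significance testing
(standard and cluster-adjusted one-sided Wilcoxon signed-rank), rank-based
effect sizes, Benjamini-Hochberg step-up correction, severity
classification metrics, two-sample distribution comparisons, and the
clustered regression (population-averaged and random-intercept) relating
the change in Proxy-A distance to the change in MAE.

Conventions: zero differences are dropped before ranking, ties receive
midranks, and the large-sample signed-rank test uses the tie-corrected
normal approximation.  The cluster-adjusted variant follows the
Rosner-Glynn-Lee construction: per-cluster signed-rank sums with an
empirical (cluster-robust) variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "AssociationResult",
    "ConfusionMetrics",
    "per_subject_mae",
    "mae_table",
    "signed_rank_test",
    "rank_biserial",
    "cramers_v",
    "bh_adjust",
    "sensitivity_table",
    "severity_metrics",
    "severity_table",
    "pad_mae_association",
    "compare_distributions",
    "build_delta_rows",
]

HP_COLUMNS = ["learning_rate", "n_trees", "depth", "smote", "k"]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    alternative: str
    effect_size: float | None = None
    effect_name: str = ""
    n: int = 0
    degenerate: bool = False
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")


@dataclass(frozen=True)
class AssociationResult:
    gee: pd.DataFrame
    lmm: pd.DataFrame
    n_rows: int
    n_clusters: int


# ---------------------------------------------------------------------------
# MAE summaries


def per_subject_mae(predictions: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-subject MAE and the unweighted (macro) average across subjects."""
    err = (predictions["y_true"] - predictions["y_pred"]).abs()
    by_subject = err.groupby(predictions["subject"]).mean()
    return by_subject, float(by_subject.mean())


def mae_table(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per (item, study, mode, hyperparams, subject) MAE rows."""
    df = predictions.copy()
    df["abs_err"] = (df["y_true"] - df["y_pred"]).abs()
    keys = ["item", "study", "mode"] + HP_COLUMNS + ["subject"]
    out = (
        df.groupby(keys, dropna=False)["abs_err"].mean().rename("mae").reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# nonparametric tests and effect sizes


def _signed_midranks(deltas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(deltas, dtype=float)
    nz = d != 0
    d = d[nz]
    ranks = sps.rankdata(np.abs(d)) if len(d) else np.array([])
    return d, ranks


def signed_rank_test(
    deltas,
    alternative: str = "greater",
    clustered: bool = False,
    clusters=None,
) -> TestResult:
    """Wilcoxon signed-rank test, optionally cluster-adjusted.

    Unclustered: scipy's implementation (exact null distribution for small
    zero- and tie-free samples, otherwise the tie-corrected normal
    approximation).  Clustered: per-cluster signed-rank sums S_i computed
    from ranks over all non-zero differences; T = sum S_i is referred to a
    normal with cluster-robust variance sum S_i^2.  Reports the matched
    pairs rank-biserial correlation as effect size.
    """
    d = np.asarray(deltas, dtype=float)
    if clustered and clusters is None:
        raise ValueError("clustered test requires cluster ids")
    nz = d != 0
    if not nz.any():
        return TestResult(
            name="signed-rank (clustered)" if clustered else "signed-rank",
            statistic=0.0, p_value=1.0, alternative=alternative,
            effect_size=0.0, effect_name="matched-pairs RBC", n=0,
            degenerate=True,
        )
    rbc = rank_biserial(d, paired=True)

    if not clustered:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative=alternative)
        return TestResult(
            name="signed-rank", statistic=float(res.statistic),
            p_value=float(res.pvalue), alternative=alternative,
            effect_size=rbc, effect_name="matched-pairs RBC",
            n=int(nz.sum()),
        )

    cl = np.asarray(clusters)[nz]
    dd = d[nz]
    ranks = sps.rankdata(np.abs(dd))
    signed = np.sign(dd) * ranks
    s_by_cluster = pd.Series(signed).groupby(pd.Series(cl)).sum().to_numpy()
    T = float(s_by_cluster.sum())
    var = float(np.sum(s_by_cluster**2))
    if var == 0:
        return TestResult(
            name="signed-rank (clustered)", statistic=T, p_value=1.0,
            alternative=alternative, effect_size=rbc,
            effect_name="matched-pairs RBC", n=len(dd), degenerate=True,
        )
    z = T / np.sqrt(var)
    if alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        p = float(sps.norm.cdf(z))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(
        name="signed-rank (clustered)", statistic=T, p_value=p,
        alternative=alternative, effect_size=rbc,
        effect_name="matched-pairs RBC", n=len(dd),
        extras={"z": float(z), "n_clusters": int(len(s_by_cluster))},
    )


def rank_biserial(values_a, values_b=None, paired: bool = True) -> float:
    """Rank-biserial correlation in [-1, 1].

    Paired (matched pairs): proportion of summed favorable minus
    unfavorable ranks of the differences.  Unpaired: 2U/(n1*n2) - 1 from
    the Mann-Whitney U of the first sample.
    """
    if paired:
        d = np.asarray(values_a, dtype=float)
        if values_b is not None:
            b = np.asarray(values_b, dtype=float)
            if len(b) != len(d):
                raise ValueError("paired samples must have equal length")
            d = d - b
        if d.size == 0:
            raise ValueError("empty input")
        dd, ranks = _signed_midranks(d)
        total = ranks.sum()
        if total == 0:
            return 0.0
        r_pos = ranks[dd > 0].sum()
        r_neg = ranks[dd < 0].sum()
        return float((r_pos - r_neg) / total)
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    u = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
    return float(2.0 * u / (len(a) * len(b)) - 1.0)


def cramers_v(table) -> float:
    """Cramer's V = sqrt(chi2 / (n * (min(r,c) - 1)))."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2 = sps.chi2_contingency(t, correction=False).statistic
    n = t.sum()
    return float(np.sqrt(chi2 / (n * (min(t.shape) - 1))))


def bh_adjust(p_values, fdr: float = 0.25) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at the given FDR."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0,1]")
    return multipletests(p, alpha=fdr, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# sensitivity analysis


_COMPARISONS = {
    "BC": ("baseline_combined", "combined"),
    "BS": ("baseline_single", "single"),
    "SC": ("single", "combined"),
    "CS": ("combined", "single"),
}
_INTERSECTIONS = {"BC∩SC": ("BC", "SC"), "BS∩CS": ("BS", "CS")}


def sensitivity_table(
    mae_tbl: pd.DataFrame, alpha: float = 0.05, fdr: float = 0.25
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count hyperparameter settings with significant paired MAE deltas.

    For each (item, held-out study) block and each hyperparameter setting,
    tests Delta-MAE_ij = MAE_i - MAE_j > 0 across validation subjects with
    the cluster-adjusted one-sided signed-rank test (clusters = subjects),
    for comparisons baseline-vs-combined (BC), baseline-vs-single (BS),
    single-vs-combined (SC) and combined-vs-single (CS), plus joint
    significance of (BC and SC) and (BS and CS).  Returns a summary of
    counts/percentages with and without BH correction, and the per-setting
    p-value detail table.
    """
    baseline_maes = {}
    for mode in ("baseline_single", "baseline_combined"):
        sub = mae_tbl[mae_tbl["mode"] == mode]
        if len(sub):
            baseline_maes[mode] = sub.set_index(["item", "study", "subject"])["mae"]

    core = mae_tbl[mae_tbl["mode"].isin(["single", "combined"])]
    detail_rows = []
    for (item, study), block in core.groupby(["item", "study"]):
        wide = block.pivot_table(
            index=HP_COLUMNS + ["subject"], columns="mode", values="mae"
        ).reset_index()
        for hp_vals, grp in wide.groupby(HP_COLUMNS):
            subj = grp["subject"]
            maes = {
                "single": grp.get("single"),
                "combined": grp.get("combined"),
            }
            for mode, key in (
                ("baseline_single", "baseline_single"),
                ("baseline_combined", "baseline_combined"),
            ):
                if key in baseline_maes:
                    maes[mode] = (
                        pd.MultiIndex.from_arrays(
                            [np.repeat(item, len(subj)),
                             np.repeat(study, len(subj)), subj]
                        ).map(baseline_maes[key]).to_numpy()
                    )
            row = dict(zip(HP_COLUMNS, hp_vals))
            row.update({"item": item, "study": study, "n_subjects": len(grp)})
            for comp, (i_mode, j_mode) in _COMPARISONS.items():
                mi, mj = maes.get(i_mode), maes.get(j_mode)
                if mi is None or mj is None:
                    row[f"p_{comp}"] = np.nan
                    continue
                deltas = np.asarray(mi, dtype=float) - np.asarray(mj, dtype=float)
                ok = ~np.isnan(deltas)
                res = signed_rank_test(
                    deltas[ok], alternative="greater", clustered=True,
                    clusters=subj.to_numpy()[ok],
                )
                row[f"p_{comp}"] = res.p_value
            detail_rows.append(row)

    detail = pd.DataFrame(detail_rows)
    summary_rows = []
    for (item, study), block in detail.groupby(["item", "study"]):
        n = len(block)
        row = {"item": item, "study": study, "n_settings": n}
        sig = {}
        sig_bh = {}
        for comp in _COMPARISONS:
            p = block[f"p_{comp}"].to_numpy(dtype=float)
            valid = ~np.isnan(p)
            s = np.zeros(n, dtype=bool)
            s[valid] = p[valid] < alpha
            sb = np.zeros(n, dtype=bool)
            if valid.any():
                sb[valid] = bh_adjust(p[valid], fdr=fdr)
            sig[comp], sig_bh[comp] = s, sb
        for name, (c1, c2) in _INTERSECTIONS.items():
            sig[name] = sig[c1] & sig[c2]
            sig_bh[name] = sig_bh[c1] & sig_bh[c2]
        for comp in list(_COMPARISONS) + list(_INTERSECTIONS):
            row[f"n_{comp}"] = int(sig[comp].sum())
            row[f"pct_{comp}"] = int(round(100.0 * sig[comp].sum() / n))
            row[f"n_{comp}_bh"] = int(sig_bh[comp].sum())
            row[f"pct_{comp}_bh"] = int(round(100.0 * sig_bh[comp].sum() / n))
        summary_rows.append(row)
    return pd.DataFrame(summary_rows), detail


# ---------------------------------------------------------------------------
# severity classification


def severity_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    severe_low: bool,
    threshold: float = 1.5,
) -> ConfusionMetrics:
    """Binarize regression output and score severe-symptom detection.

    True severe = the two most severe outcome categories (values <= 1 when
    low scores are severe, >= 2 otherwise).  Predicted severe = prediction
    in the severe half of the scale relative to ``threshold``.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if severe_low:
        true_sev = yt <= 1.0 + 1e-9
        pred_sev = yp <= threshold
    else:
        true_sev = yt >= 2.0 - 1e-9
        pred_sev = yp >= threshold
    tp = int(np.sum(true_sev & pred_sev))
    fp = int(np.sum(~true_sev & pred_sev))
    tn = int(np.sum(~true_sev & ~pred_sev))
    fn = int(np.sum(true_sev & ~pred_sev))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def severity_table(
    predictions: pd.DataFrame, severe_low: bool, per_subject: bool = False
) -> pd.DataFrame:
    """Per-hyperparameter severity metrics (pooled, or macro per subject)."""
    keys = ["item", "study", "mode"] + HP_COLUMNS
    rows = []
    for key_vals, grp in predictions.groupby(keys, dropna=False):
        row = dict(zip(keys, key_vals))
        if per_subject:
            per = []
            for _, sub in grp.groupby("subject"):
                m = severity_metrics(sub["y_true"], sub["y_pred"], severe_low)
                per.append((m.sensitivity, m.specificity, m.ppv))
            arr = np.asarray(per, dtype=float)
            with np.errstate(invalid="ignore"):
                sens, spec, ppv = np.nanmean(arr, axis=0)
            row.update(
                {"sensitivity": sens, "specificity": spec, "ppv": ppv,
                 "tp": np.nan, "fp": np.nan, "tn": np.nan, "fn": np.nan}
            )
        else:
            m = severity_metrics(grp["y_true"], grp["y_pred"], severe_low)
            row.update(
                {"sensitivity": m.sensitivity, "specificity": m.specificity,
                 "ppv": m.ppv, "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn}
            )
        row["mae"] = float((grp["y_true"] - grp["y_pred"]).abs().mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# delta rows and the PAD->MAE association


def build_delta_rows(
    mae_tbl: pd.DataFrame, pad_tbl: pd.DataFrame
) -> pd.DataFrame:
    """Per (subject, hyperparams) paired deltas of MAE and PAD.

    Delta-MAE = MAE_single - MAE_combined; Delta-PAD = PAD_single -
    PAD_combined, joined on (item, subject, k).
    """
    core = mae_tbl[mae_tbl["mode"].isin(["single", "combined"])]
    wide = core.pivot_table(
        index=["item", "study", "subject"] + HP_COLUMNS, columns="mode",
        values="mae",
    ).reset_index()
    wide["dmae"] = wide["single"] - wide["combined"]
    wide = wide.rename(columns={"single": "mae_single", "combined": "mae_combined"})

    padw = pad_tbl.pivot_table(
        index=["item", "subject", "k"], columns="mode", values="pad"
    ).reset_index()
    padw["dpad"] = padw["single"] - padw["combined"]
    padw = padw.rename(columns={"single": "pad_single", "combined": "pad_combined"})

    out = wide.merge(padw, on=["item", "subject", "k"], how="left")
    base = mae_tbl[mae_tbl["mode"].isin(["baseline_single", "baseline_combined"])]
    if len(base):
        bw = base.pivot_table(
            index=["item", "study", "subject"], columns="mode", values="mae"
        ).reset_index().rename(
            columns={
                "baseline_single": "mae_baseline_single",
                "baseline_combined": "mae_baseline_combined",
            }
        )
        out = out.merge(bw, on=["item", "study", "subject"], how="left")
    return out


def _tidy_params(result, terms) -> pd.DataFrame:
    ci = result.conf_int()
    return pd.DataFrame(
        {
            "term": terms,
            "beta": np.asarray(result.params, dtype=float),
            "ci_low": np.asarray(ci)[:, 0].astype(float),
            "ci_high": np.asarray(ci)[:, 1].astype(float),
            "p_value": np.asarray(result.pvalues, dtype=float),
        }
    )


def pad_mae_association(delta_rows: pd.DataFrame) -> AssociationResult:
    """Association between Delta-PAD and Delta-MAE within subjects.

    Fits (a) a population-averaged clustered linear regression with an
    exchangeable working correlation and (b) a random-intercept linear
    mixed model, both clustered on subject, on the identical row set.
    Covariates: Delta-PAD, an outcome-item indicator and personalization
    neighbor-count indicators (each included only when it varies), plus an
    intercept.
    """
    df = delta_rows.dropna(subset=["dmae", "dpad"]).copy()
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 clusters (subjects)")
    terms = ["dpad"]
    if "item" in df and df["item"].nunique() > 1:
        terms.append("C(item)")
    if "k" in df and df["k"].nunique() > 1:
        order = [v for v in ["5", "10", "50", "100", "500", "all"]
                 if v in set(df["k"].astype(str))]
        df["k"] = pd.Categorical(df["k"].astype(str), categories=order)
        terms.append("C(k)")
    formula = "dmae ~ " + " + ".join(terms)

    gee = smf.gee(
        formula, groups="subject", data=df,
        cov_struct=sm.cov_struct.Exchangeable(),
    ).fit()
    lmm = smf.mixedlm(formula, data=df, groups=df["subject"]).fit(reml=True)

    gee_tbl = _tidy_params(gee, list(gee.params.index))
    lmm_tbl = _tidy_params(lmm, list(lmm.params.index))
    # drop the random-effect variance row from the LMM coefficient table
    lmm_tbl = lmm_tbl[~lmm_tbl["term"].str.contains("Group Var")].reset_index(
        drop=True
    )
    return AssociationResult(
        gee=gee_tbl, lmm=lmm_tbl, n_rows=len(df),
        n_clusters=int(df["subject"].nunique()),
    )


# ---------------------------------------------------------------------------
# distribution comparisons


def compare_distributions(sample_a, sample_b, kind: str = "continuous") -> TestResult:
    """Two-sample comparison mirroring the cross-study feature contrasts.

    Continuous: omnibus normality per sample, two-sided Mann-Whitney U with
    the unpaired rank-biserial correlation.  Categorical: chi-square test
    of independence with Cramer's V.
    """
    a = np.asarray(sample_a)
    b = np.asarray(sample_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if kind == "continuous":
        a = a.astype(float)
        b = b.astype(float)
        norm_a = float(sps.normaltest(a).pvalue) if len(a) >= 8 else np.nan
        norm_b = float(sps.normaltest(b).pvalue) if len(b) >= 8 else np.nan
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult(
            name="mann-whitney", statistic=float(res.statistic),
            p_value=float(res.pvalue), alternative="two-sided",
            effect_size=rank_biserial(a, b, paired=False),
            effect_name="unpaired RBC", n=len(a) + len(b),
            extras={"normality_p_a": norm_a, "normality_p_b": norm_b},
        )
    if kind == "categorical":
        cats = sorted(set(a.tolist()) | set(b.tolist()))
        if len(cats) < 2:
            raise ValueError("need at least two categories")
        ta = pd.Series(a).value_counts().reindex(cats, fill_value=0)
        tb = pd.Series(b).value_counts().reindex(cats, fill_value=0)
        table = np.vstack([ta.to_numpy(), tb.to_numpy()])
        table = table[:, table.sum(axis=0) > 0]
        res = sps.chi2_contingency(table, correction=False)
        return TestResult(
            name="chi-square", statistic=float(res.statistic),
            p_value=float(res.pvalue), alternative="two-sided",
            effect_size=cramers_v(table), effect_name="Cramer's V",
            n=int(table.sum()),
        )
    raise ValueError(f"unknown kind {kind!r}")
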