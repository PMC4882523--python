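"""Genotype-phenotype association for candidate variants.

Allele-frequency chi-squared contrasts between groups, ordinary least
squares of a haematological trait on genotype (unordered factor) plus sex
(covariate), least-squares (adjusted) means at balanced sex weighting,
Fisher's LSD pairwise post-hoc tests, and Welch two-sample group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

TRAITS = ["RBC", "HGB", "HCT", "MCV", "MCH", "MCHC"]


@dataclass
class ChisqResult:
    chi2: float
    p: float
    df: int
    defined: bool


def allele_chisq(counts_g1, counts_g2) -> ChisqResult:
    """Pearson chi-squared (no continuity correction) on the 2x2 allele-count
    table [[ref1, alt1], [ref2, alt2]]; 1 df.

    A zero allele column (an allele absent from both groups) leaves the
    statistic undefined (flagged), not an exception.
    """
    table = np.array([counts_g1, counts_g2], dtype=float)
    if (table < 0).any():
        raise ValidationError("allele counts must be nonnegative")
    if (table.sum(axis=1) == 0).any():
        raise ValidationError("both groups must have nonzero allele totals")
    if (table.sum(axis=0) == 0).any():
        return ChisqResult(chi2=float("nan"), p=float("nan"), df=1, defined=False)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChisqResult(chi2=float(chi2), p=float(p), df=int(df), defined=True)


@dataclass
class GlmResult:
    """OLS fit of trait ~ genotype (+ sex): adjusted means and the genotype
    F-test against the covariate-only model."""

    trait: str
    adjusted_means: dict
    f_stat: float
    p_value: float
    df_num: int
    df_resid: int
    n_obs: int
    genotype_levels: list
    _params: np.ndarray = None
    _cov: np.ndarray = None
    _mean_rows: dict = None
    sigma2: float = None


def _design_rows(genotype_levels, sex_levels, include_sex):
    """Treatment-coded design rows averaged over sex (balanced weights)."""
    k = len(genotype_levels)
    rows = {}
    for gi, g in enumerate(genotype_levels):
        acc = []
        for sex in (sex_levels if include_sex else [None]):
            row = np.zeros(1 + (k - 1) + (len(sex_levels) - 1 if include_sex else 0))
            row[0] = 1.0
            if gi > 0:
                row[gi] = 1.0
            if include_sex and sex != sex_levels[0]:
                row[k + sex_levels[1:].index(sex)] = 1.0
            acc.append(row)
        rows[g] = np.mean(acc, axis=0)
    return rows


def glm_association(ph: pd.DataFrame, calls: pd.DataFrame, trait: str,
                    include_sex: bool = True) -> GlmResult:
    """Least-squares association of *trait* with a genotype factor, adjusting
    for sex.

    *ph* carries columns sample, sex and the traits; *calls* carries sample
    and genotype (class labels such as CC/CT/TT).  Missing trait values are
    dropped listwise.  The overall genotype test compares the full model with
    the sex-only (or intercept-only) model.
    """
    import statsmodels.api as sm

    if trait not in ph.columns:
        raise ValidationError(f"trait {trait!r} not in phenotype table")
    merged = ph.merge(calls[["sample", "genotype"]], on="sample", how="inner")
    merged = merged.dropna(subset=[trait])
    levels = sorted(merged["genotype"].unique())
    if len(levels) < 2:
        raise ValidationError("need >= 2 genotype classes")
    counts = merged["genotype"].value_counts()
    small = [g for g in levels if counts[g] < 2]
    if small:
        raise ValidationError(f"genotype classes with <2 samples: {small}")
    sex_levels = sorted(merged["sex"].unique()) if include_sex else []

    y = merged[trait].to_numpy(dtype=float)
    k = len(levels)
    n = len(merged)
    cols = [np.ones(n)]
    for g in levels[1:]:
        cols.append((merged["genotype"] == g).to_numpy(dtype=float))
    if include_sex:
        for s in sex_levels[1:]:
            cols.append((merged["sex"] == s).to_numpy(dtype=float))
    x_full = np.column_stack(cols)
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValidationError(
            "singular design: genotype factor is confounded with sex "
            f"(levels {levels} x {sex_levels})"
        )

    full = sm.OLS(y, x_full).fit()
    x_red = np.column_stack(
        [np.ones(n)] + ([c for c in cols[k:]] if include_sex else [])
    )
    reduced = sm.OLS(y, x_red).fit()
    f_stat, p_value, df_num = full.compare_f_test(reduced)

    mean_rows = _design_rows(levels, sex_levels, include_sex)
    params = full.params
    cov = full.cov_params()
    adjusted = {g: float(mean_rows[g] @ params) for g in levels}
    return GlmResult(
        trait=trait,
        adjusted_means=adjusted,
        f_stat=float(f_stat),
        p_value=float(p_value),
        df_num=int(df_num),
        df_resid=int(full.df_resid),
        n_obs=n,
        genotype_levels=levels,
        _params=np.asarray(params),
        _cov=np.asarray(cov),
        _mean_rows=mean_rows,
        sigma2=float(full.mse_resid),
    )


def lsd_posthoc(res: GlmResult) -> pd.DataFrame:
    """Fisher's LSD: unadjusted pairwise t-tests on adjusted means using the
    model residual variance and df."""
    levels = res.genotype_levels
    if len(levels) < 2:
        raise ValidationError("need >= 2 genotype classes")
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            gi, gj = levels[i], levels[j]
            contrast = res._mean_rows[gi] - res._mean_rows[gj]
            diff = float(contrast @ res._params)
            se = float(np.sqrt(contrast @ res._cov @ contrast))
            t = diff / se
            p = 2.0 * stats.t.sf(abs(t), res.df_resid)
            rows.append({"group1": gi, "group2": gj, "diff": diff, "se": se,
                         "t": t, "p": p})
    return pd.DataFrame(rows)


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0  # degenerate: identical constants
        return float("inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def group_trait_compare(ph_high: pd.DataFrame, ph_low: pd.DataFrame,
                        trait: str) -> dict:
    """Welch two-sample comparison of one trait between groups, overall and
    stratified by sex."""
    out = {}
    for label, (a, b) in {
        "overall": (ph_high, ph_low),
        **{
            f"sex={s}": (ph_high[ph_high["sex"] == s], ph_low[ph_low["sex"] == s])
            for s in sorted(set(ph_high["sex"]) & set(ph_low["sex"]))
        },
    }.items():
        x = a[trait].dropna().to_numpy(dtype=float)
        y = b[trait].dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            out[label] = {"n_high": len(x), "n_low": len(y), "mean_high": float("nan"),
                          "mean_low": float("nan"), "t": float("nan"), "p": float("nan")}
            continue
        t, p = _welch(x, y)
        out[label] = {
            "n_high": len(x), "n_low": len(y),
            "mean_high": float(x.mean()), "mean_low": float(y.mean()),
            "t": t, "p": p,
        }
    return out


def dosage_to_calls(g, vid: str) -> pd.DataFrame:
    """Genotype class labels (e.g. AA/AG/GG) for one variant from dosages."""
    from .genotype_io import MISSING

    j = g.vids.index(vid)
    v = g.variants[j]
    label = {0: v.ref + v.ref, 1: v.ref + v.alt, 2: v.alt + v.alt}
    rows = []
    for i, s in enumerate(g.samples):
        d = int(g.dosage[i, j])
        if d == MISSING:
            continue
        rows.append({"sample": s, "variant": vid, "genotype": label[d]})
    return pd.DataFrame(rows)
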