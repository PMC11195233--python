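"""Group x sex x region statistics for the chirp response variables.

The modeling layer mirrors a region-level repeated-measures design: nodes
within a region act as replicates of the subject x region response.  The
fit is a documented two-stage procedure — stage 1 collapses node replicates
to subject x region means, stage 2 fits a linear mixed model with a subject
random intercept (Group, Sex, Region fixed effects with interactions) and
reports Wald F tests per term.  Post-hoc cell contrasts per region use
pooled-SD t tests with Benjamini-Hochberg correction at 5% within a
response family and Cohen's d effect sizes.  Clinical associations use
Spearman rank correlations with BH at 10%; SA-ratio group comparisons use
two-sample rank-sum tests with rank-biserial effect sizes and Holm
correction.

ITPC responses are variance-stabilised before fitting by the signed cube
root of the log: ``t(x) = sign(ln x) * |ln x|^(1/3)`` for ``x`` in (0, 1];
corrected ITPC (which may be negative) is re-mapped to the raw domain by an
additive offset before the transform when requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .features import region_means

DEFAULT_CELL_PAIRS: tuple[tuple[tuple[str, str], tuple[str, str]], ...] = (
    (("FXS", "M"), ("TDC", "M")),
    (("FXS", "F"), ("TDC", "F")),
    (("FXS", "M"), ("FXS", "F")),
    (("FXS", "M"), ("TDC", "F")),
    (("FXS", "F"), ("TDC", "M")),
    (("TDC", "M"), ("TDC", "F")),
)


# ----------------------------------------------------------------------
# transforms and adjustments
# ----------------------------------------------------------------------

def itpc_transform(x, offset: float = 0.0):
    """Signed cube root of ln(x + offset); strictly increasing on (0, 1].

    ``offset`` re-maps trial-count-corrected ITPC (which can be negative)
    back to the raw domain — pass the analysis' ``r_critical``.
    """
    x = np.asarray(x, dtype=float) + offset
    if np.any(x <= 0):
        raise ValueError("itpc_transform requires x + offset > 0 "
                         "(pass offset=r_critical for corrected ITPC)")
    logs = np.log(x)
    return np.sign(logs) * np.abs(logs) ** (1.0 / 3.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="holm")[1]


def cohens_d(a, b) -> float:
    """Cohen's d from two cells with pooled SD."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


# ----------------------------------------------------------------------
# region-level model
# ----------------------------------------------------------------------

@dataclass
class RegionModelFit:
    response: str
    anova: pd.DataFrame                 # term, F, df_num, df_den, p
    cell_means: pd.DataFrame            # subject x region means (stage 1)
    metadata: dict = field(default_factory=dict)


def _check_replication(meta: pd.DataFrame) -> None:
    cell_sizes = meta.groupby(["group", "sex"])["subject_id"].nunique()
    if (cell_sizes < 2).any():
        raise ValueError(
            "insufficient replication: every group x sex cell needs >= 2 "
            f"subjects (got {cell_sizes.to_dict()})"
        )


def fit_region_model(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    response: str,
    transform: str = "none",
    transform_offset: float = 0.0,
) -> RegionModelFit:
    """Two-stage mixed model for one response variable.

    Stage 1 averages node replicates to subject x region means (so the fit
    is invariant to verbatim replicate duplication); stage 2 fits
    ``response ~ Group * Sex * Region`` with a subject random intercept
    (statsmodels MixedLM) and reports Wald F statistics per fixed term.
    The denominator degrees of freedom use the residual large-sample
    approximation, recorded in ``metadata`` — not the Pinheiro-Bates
    containment method.
    """
    means = region_means(features[["subject_id", "node", "region", response]])
    data = means.merge(metadata[["subject_id", "group", "sex"]], on="subject_id")
    _check_replication(data)
    y = data[response].to_numpy(dtype=float)
    if transform == "itpc_transform":
        y = itpc_transform(y, offset=transform_offset)
    elif transform == "third_log":
        y = np.log(data[response].to_numpy(float) + transform_offset) / 3.0
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    data = data.assign(_y=y)

    formula = "_y ~ C(group) * C(sex) * C(region)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, groups="subject_id", data=data)
        fit = model.fit(reml=True, method="lbfgs")

    terms = ("C(group)", "C(sex)", "C(region)",
             "C(group):C(sex)", "C(group):C(region)", "C(sex):C(region)",
             "C(group):C(sex):C(region)")
    exog_names = np.array(model.exog_names)
    n_obs = len(data)
    n_subj = data["subject_id"].nunique()
    df_den = n_obs - len(exog_names) - (n_subj - 1)
    fe = np.asarray(fit.fe_params)
    k_fe = fe.size
    cov_fe = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    rows = []
    for term in terms:
        cols = [i for i, name in enumerate(exog_names)
                if _term_of(name) == term]
        if not cols:
            continue
        beta = fe[cols]
        sub_cov = cov_fe[np.ix_(cols, cols)]
        wald = float(beta @ np.linalg.solve(sub_cov, beta))
        f_stat = wald / len(cols)
        p = float(sps.f.sf(f_stat, len(cols), df_den))
        rows.append({"term": term, "F": f_stat, "df_num": len(cols),
                     "df_den": df_den, "p": p})
    anova = pd.DataFrame(rows)
    return RegionModelFit(
        response=response,
        anova=anova,
        cell_means=data,
        metadata={
            "model": "two-stage: node means + MixedLM subject random intercept",
            "ddf_method": "residual approximation (not Pinheiro-Bates)",
            "transform": transform,
            "transform_offset": transform_offset,
        },
    )


def _term_of(exog_name: str) -> str:
    """Map a patsy column name to its model term."""
    parts = exog_name.split(":")
    factors = []
    for part in parts:
        factors.append(part.split("[")[0])
    return ":".join(factors)


# ----------------------------------------------------------------------
# post-hoc contrasts
# ----------------------------------------------------------------------

def posthoc_contrasts(
    fit: RegionModelFit,
    cell_pairs=((("FXS", "M"), ("TDC", "M")), (("FXS", "F"), ("TDC", "F"))),
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-region cell contrasts with BH adjustment and Cohen's d.

    Contrasts compare subject x region means between group/sex cells within
    each region (pooled-SD t test).  The BH family is all regions x cell
    pairs of this response.
    """
    data = fit.cell_means
    rows = []
    for region in sorted(data["region"].unique()):
        sub = data[data["region"] == region]
        for (g1, s1), (g2, s2) in cell_pairs:
            a = sub.loc[(sub["group"] == g1) & (sub["sex"] == s1), "_y"].to_numpy()
            b = sub.loc[(sub["group"] == g2) & (sub["sex"] == s2), "_y"].to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            t, p = sps.ttest_ind(a, b)
            rows.append({
                "response": fit.response, "region": region,
                "cell_1": f"{g1}-{s1}", "cell_2": f"{g2}-{s2}",
                "t": float(t), "df": a.size + b.size - 2,
                "p_raw": float(p), "cohens_d": cohens_d(a, b),
            })
    if not rows:
        raise ValueError("empty contrast family")
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"])
    out["significant"] = out["p_adj"] <= fdr
    return out


# ----------------------------------------------------------------------
# clinical correlations
# ----------------------------------------------------------------------

def spearman_fdr(
    feature_values: pd.DataFrame,
    clinical: pd.DataFrame,
    family: tuple[tuple[str, str], ...],
    fdr: float = 0.10,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman rank correlations with BH adjustment across the family.

    ``family`` lists ``(clinical_score, feature_column)`` pairs; both frames
    must carry ``subject_id``.  Pairs with fewer than ``min_n`` complete
    observations are skipped with a warning.
    """
    merged = feature_values.merge(clinical, on="subject_id", suffixes=("", "_clin"))
    rows = []
    for score, feature in family:
        sub = merged[[score, feature]].dropna()
        if len(sub) < min_n:
            warnings.warn(f"skipping {score} ~ {feature}: n={len(sub)} < {min_n}")
            continue
        rho, p = sps.spearmanr(sub[score], sub[feature])
        rows.append({"clinical": score, "feature": feature, "n": len(sub),
                     "rho": float(rho), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p_raw"])
        out["significant"] = out["p_adj"] <= fdr
    return out


# ----------------------------------------------------------------------
# SA-ratio group comparisons
# ----------------------------------------------------------------------

def compare_sa_groups(
    sa_summary: pd.DataFrame,
    metadata: pd.DataFrame,
    cell_pairs=DEFAULT_CELL_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based SA-ratio comparisons between group x sex cells per side.

    Uses a two-sample rank-sum (Mann-Whitney) test — the groups are
    independent samples — with the rank-biserial correlation as effect size
    and Holm adjustment across the sides x cell-pairs family.  The run
    metadata notes the departure from the original protocol's "signed
    ranks" label.
    """
    data = sa_summary.merge(metadata[["subject_id", "group", "sex"]],
                            on="subject_id")
    rows = []
    for side in sorted(data["side"].unique()):
        sub = data[data["side"] == side]
        for (g1, s1), (g2, s2) in cell_pairs:
            a = sub.loc[(sub["group"] == g1) & (sub["sex"] == s1),
                        "sa_ratio"].to_numpy()
            b = sub.loc[(sub["group"] == g2) & (sub["sex"] == s2),
                        "sa_ratio"].to_numpy()
            if a.size < 3 or b.size < 3:
                continue
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                raise ValueError("degenerate all-tied samples")
            method = ("exact" if max(a.size, b.size) <= 25
                      and np.unique(np.concatenate([a, b])).size == a.size + b.size
                      else "asymptotic")
            u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
            rank_biserial = 1.0 - 2.0 * u / (a.size * b.size)
            rows.append({
                "side": side, "cell_1": f"{g1}-{s1}", "cell_2": f"{g2}-{s2}",
                "W": float(u), "effect_size": float(-rank_biserial),
                "p_raw": float(p),
            })
    if not rows:
        raise ValueError("no comparable cells (need >= 3 subjects per cell)")
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_adjust(out["p_raw"])
    out["significant"] = out["p_adj"] <= alpha
    out.attrs["test"] = ("two-sample rank-sum (independent groups); the "
                         "source protocol's 'signed-ranks' label is a "
                         "misnomer for a between-group comparison")
    return out
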