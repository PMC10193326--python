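"""Per-cell-type treatment-effect testing on cohort score tables.

Cohorts carry one row per patient (arm ∈ {placebo, low_dose, high_dose}, age
in years, gender ∈ {F, M}) and one column per deconvolution signature.  For a
chosen contrast (one dose arm vs placebo, or both doses combined vs placebo)
each signature is tested with two ordinary least-squares models:

* covariate model — score ~ treated + age + gender, reporting the treated
  coefficient, its p-value, and the model's overall F-test p-value;
* simple model — score ~ treated only.

P-values are adjusted across signatures separately per contrast and per
p-value type (BH by default).  A signature is called significant when BOTH
the adjusted treated-coefficient p and the adjusted overall F-test p fall
strictly below 0.1 — the dual rule that requires the treatment signal to
survive age and gender adjustment.

Signatures that are almost entirely zero convey no information (the score
method never detected the cell type) and are removed up front by
:func:`zero_filter` before any model is fitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .validation import adjust

__all__ = ["CONTRASTS", "zero_filter", "fit_cell_type", "analyze"]

CONTRASTS = ("low_vs_placebo", "high_vs_placebo", "combined_vs_placebo")

_TREATED_ARMS = {
    "low_vs_placebo": ("low_dose",),
    "high_vs_placebo": ("high_dose",),
    "combined_vs_placebo": ("low_dose", "high_dose"),
}

METADATA_COLUMNS = ("arm", "age", "gender")

SIGNIFICANCE_THRESHOLD = 0.1


def signature_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in METADATA_COLUMNS]


def zero_filter(scores: pd.DataFrame, threshold: float = 0.99, axis: str = "columns"):
    """Drop signatures whose zero fraction exceeds ``threshold``.

    ``axis='columns'`` treats columns as signatures (cohort layout);
    ``axis='index'`` treats rows as signatures (score-matrix layout).  The
    comparison is strict, so a zero fraction exactly at the threshold is
    retained.  Returns ``(retained, dropped_names)``.
    """
    if axis not in ("columns", "index"):
        raise ValueError("axis must be 'columns' or 'index'")
    along = 0 if axis == "columns" else 1
    zero_frac = (scores == 0).mean(axis=along)
    dropped = list(zero_frac.index[zero_frac > threshold])
    retained = scores.drop(columns=dropped) if axis == "columns" else scores.drop(index=dropped)
    return retained, dropped


def _treated_indicator(cohort: pd.DataFrame, contrast: str) -> tuple[pd.DataFrame, pd.Series]:
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    treated_arms = _TREATED_ARMS[contrast]
    keep = cohort["arm"].isin(("placebo", *treated_arms))
    sub = cohort[keep]
    for arm in ("placebo", *treated_arms):
        if not (sub["arm"] == arm).any():
            raise ValueError(f"contrast {contrast}: arm {arm!r} has no samples")
    return sub, sub["arm"].isin(treated_arms).astype(float)


def fit_cell_type(cohort: pd.DataFrame, signature_id: str, contrast: str) -> dict:
    """Unadjusted model outputs for one signature under one contrast.

    Returns the treated coefficient and p-value from the age/gender-adjusted
    model, that model's overall F-test p-value, the treated p-value from the
    treatment-only model, and the sample size.  A constant score cannot be
    modelled and is flagged (all p NaN) so callers can exclude it from the
    adjustment family.
    """
    sub, treated = _treated_indicator(cohort, contrast)
    y = sub[signature_id].astype(float)
    out = {"signature_id": signature_id, "contrast": contrast, "n": int(len(sub)),
           "beta_treatment": np.nan, "p_treatment": np.nan, "p_ftest": np.nan,
           "p_simple": np.nan, "note": ""}
    if y.nunique() <= 1:
        out["note"] = "constant score; excluded from adjustment family"
        return out
    X = pd.DataFrame({
        "treated": treated,
        "age": sub["age"].astype(float),
        "gender_M": (sub["gender"] == "M").astype(float),  # F is the reference level
    })
    if len(sub) <= X.shape[1] + 1:
        raise ValueError(
            f"{signature_id}/{contrast}: {len(sub)} samples cannot support "
            f"{X.shape[1] + 1} parameters"
        )
    full = sm.OLS(y, sm.add_constant(X)).fit()
    simple = sm.OLS(y, sm.add_constant(X[["treated"]])).fit()
    out.update(
        beta_treatment=float(full.params["treated"]),
        p_treatment=float(full.pvalues["treated"]),
        p_ftest=float(full.f_pvalue),
        p_simple=float(simple.pvalues["treated"]),
    )
    return out


def analyze(
    cohort: pd.DataFrame,
    contrasts=CONTRASTS,
    adjust_method: str = "bh",
    zero_threshold: float = 0.99,
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> tuple[pd.DataFrame, list[str]]:
    """Full treatment-effect stage across signatures and contrasts.

    Applies :func:`zero_filter`, fits every (signature, contrast) pair, then
    adjusts p-values within each (contrast, p-type) family across the
    post-filter signatures.  ``significant`` is the dual rule: adjusted
    treated-coefficient p < threshold AND adjusted overall F-test p <
    threshold (strict).  Returns the results frame and the dropped signature
    names.
    """
    sig_cols = signature_columns(cohort)
    filtered, dropped = zero_filter(cohort[sig_cols], threshold=zero_threshold, axis="columns")
    rows = [fit_cell_type(cohort, sig, contrast)
            for contrast in contrasts for sig in filtered.columns]
    results = pd.DataFrame(rows)
    for p_col in ("p_treatment", "p_ftest", "p_simple"):
        adj = np.full(len(results), np.nan)
        for contrast in contrasts:
            fam = (results["contrast"] == contrast) & results[p_col].notna()
            if fam.any():
                adj[fam.to_numpy()] = adjust(results.loc[fam, p_col], method=adjust_method)
        results[p_col + "_adj"] = adj
    results["significant"] = (
        (results["p_treatment_adj"] < threshold) & (results["p_ftest_adj"] < threshold)
    ).fillna(False)
    return results, dropped
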