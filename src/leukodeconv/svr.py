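"""Signature-regression deconvolution of bulk expression by linear ν-SVR.

The model treats a bulk sample as a linear mixture m = f · B of reference
cell-type profiles: m is the gene-expression vector of the mixture, B the
signature matrix (genes × cell types) and f the vector of cell-type fractions
to be estimated.  Following the CIBERSORT algorithm, m and B are z-scored,
a linear ν-support-vector regression of m* on the columns of B* is fitted for
each ν in a small grid, and the ν whose reconstruction has the lowest RMSE
against m* wins.  The winning primal coefficients are clipped at zero and
renormalised to the unit simplex, so every reported fraction vector is
non-negative and sums to one.

ν-SVR with a linear kernel on fixed input is deterministic; no seed is used
here.  Because standardisation removes scale, fractions are invariant to
positive rescaling of the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

from .io import ScoreMatrix

__all__ = ["DeconvolutionFit", "standardize", "fit_sample", "deconvolve", "DEFAULT_NU_GRID"]

DEFAULT_NU_GRID: tuple[float, ...] = (0.25, 0.5, 0.75)


class DeconvolutionError(RuntimeError):
    """All ν values failed for a sample; carries per-ν diagnostics."""


@dataclass
class DeconvolutionFit:
    """Per-sample deconvolution result.

    ``fractions`` lie on the unit simplex (non-negative, summing to 1 within
    1e-9).  ``rmse`` and ``pearson_r`` measure how well the winning ν's raw
    coefficients reconstruct the standardized mixture.
    """

    sample_id: str
    fractions: pd.Series
    chosen_nu: float
    rmse: float
    pearson_r: float


def standardize(m: pd.Series, B: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Z-score mixture and signature matrix over their shared genes.

    B* is centred and scaled by the mean and standard deviation of the whole
    matrix (global standardisation, preserving between-column structure); m*
    is z-scored over the shared genes.  Both are shift- and scale-invariant in
    their respective inputs.
    """
    shared = B.index.intersection(m.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} genes shared between mixture and signature matrix")
    m = m.loc[shared].astype(float)
    B = B.loc[shared].astype(float)
    m_sd = m.std(ddof=1)
    if m_sd == 0:
        raise ValueError("mixture has zero variance over the shared genes")
    b_vals = B.to_numpy()
    b_sd = b_vals.std(ddof=1)
    if b_sd == 0:
        raise ValueError("signature matrix is constant over the shared genes")
    m_star = (m - m.mean()) / m_sd
    B_star = (B - b_vals.mean()) / b_sd
    return m_star, B_star


def fit_sample(
    m: pd.Series,
    B: pd.DataFrame,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    C: float = 1.0,
    sample_id: str = "sample",
) -> DeconvolutionFit:
    """Estimate one sample's cell-type fractions by linear ν-SVR.

    For each ν the regression of m* on the columns of B* yields a primal
    coefficient per cell type.  Model selection uses the RMSE between
    B*·w (raw coefficients) and m*; the winner's coefficients are clipped at
    zero and renormalised to sum to one.
    """
    m_star, B_star = standardize(m, B)
    X = B_star.to_numpy()
    y = m_star.to_numpy()

    best = None
    failures: dict[float, str] = {}
    for nu in nu_grid:
        try:
            model = NuSVR(kernel="linear", nu=nu, C=C)
            model.fit(X, y)
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            failures[nu] = str(exc)
            continue
        w = model.coef_.ravel()
        recon = X @ w
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        if best is None or rmse < best[1]:
            r = float(stats.pearsonr(recon, y)[0]) if np.ptp(recon) > 0 else float("nan")
            best = (nu, rmse, r, w)
    if best is None:
        raise DeconvolutionError(f"SVR failed for all nu on sample {sample_id!r}: {failures}")

    nu, rmse, r, w = best
    f = np.clip(w, 0.0, None)
    total = f.sum()
    if total == 0:
        raise DeconvolutionError(
            f"all coefficients non-positive for sample {sample_id!r} (nu={nu}); "
            "mixture is anti-correlated with every signature"
        )
    f = f / total
    fractions = pd.Series(f, index=B.columns, name=sample_id)
    return DeconvolutionFit(sample_id=sample_id, fractions=fractions, chosen_nu=nu, rmse=rmse, pearson_r=r)


def deconvolve(
    mix: pd.DataFrame,
    B: pd.DataFrame,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    C: float = 1.0,
    prefix: str | None = None,
) -> tuple[ScoreMatrix, pd.DataFrame]:
    """Deconvolve every sample of a mixture matrix against a signature matrix.

    Returns a ``ScoreMatrix`` (cell types × samples, method ``svr``) and a QC
    frame with one row per sample (``chosen_nu``, ``rmse``, ``pearson_r``,
    ``error``).  Per-sample failures are recorded in the QC frame rather than
    aborting the run; results are independent of sample order.
    """
    fits: dict[str, pd.Series] = {}
    qc_rows = []
    for sample in mix.columns:
        try:
            fit = fit_sample(mix[sample], B, nu_grid=nu_grid, C=C, sample_id=str(sample))
        except (DeconvolutionError, ValueError) as exc:
            qc_rows.append({"sample_id": sample, "chosen_nu": np.nan, "rmse": np.nan,
                            "pearson_r": np.nan, "error": str(exc)})
            continue
        fits[sample] = fit.fractions
        qc_rows.append({"sample_id": sample, "chosen_nu": fit.chosen_nu, "rmse": fit.rmse,
                        "pearson_r": fit.pearson_r, "error": ""})
    data = pd.DataFrame(fits, index=B.columns).reindex(columns=[s for s in mix.columns if s in fits])
    if prefix:
        data.index = [f"{prefix}.{c}" for c in data.index]
    qc = pd.DataFrame(qc_rows).set_index("sample_id")
    return ScoreMatrix(data, method="svr"), qc
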