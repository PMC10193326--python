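"""Concordance of deconvolution scores with flow cytometry.

For every mapped (signature, flow phenotype) pair the two per-sample vectors
are joined by sample id and compared with Spearman's rank correlation
(tie-corrected average ranks, two-sided p by the large-sample t approximation,
or exact permutation for very small n).  P-values are adjusted across the
tested pairs (Benjamini–Hochberg FDR by default; Bonferroni for small
confirmatory panels) and each pair is assessed on the published scheme:

* r > 0.5 and FDR ≤ 0.1 → strong correlation
* 0.3 < r ≤ 0.5 and FDR ≤ 0.1 → moderate correlation
* 0 < r ≤ 0.3 and FDR ≤ 0.1 → weak (but significant) correlation
* FDR > 0.1, or r ≤ 0 → no (or negative) correlation

Boundary values resolve downwards (r = 0.5 → moderate, r = 0.3 → weak), and a
negative r is never called a correlation however small its FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ScoreMatrix

__all__ = [
    "CATEGORIES",
    "spearman_pair",
    "adjust",
    "classify_correlation",
    "validate",
    "ValidationSummary",
]

CATEGORIES = ("strong", "moderate", "weak", "none")

#: exact permutation p-values become affordable at or below this n
EXACT_N_MAX = 9


def spearman_pair(scores, flow, exact: bool | None = None) -> tuple[float, float]:
    """Spearman correlation and two-sided p for two aligned sample vectors.

    ``exact=True`` (default for n ≤ 9) enumerates all permutations of one
    vector for the p-value; otherwise the t-distribution approximation on
    tie-corrected ranks is used.  A constant vector has no defined rank
    correlation and yields ``(nan, nan)``.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(flow, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 matched samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if exact is None:
        exact = n <= EXACT_N_MAX
    r, p = stats.spearmanr(x, y)
    if exact and n <= EXACT_N_MAX:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        observed = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= observed - 1e-12:
                count += 1
        p = count / total
    return float(r), float(p)


def adjust(pvalues, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: BH step-up FDR or Bonferroni, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method=key)[1]
    return out


def classify_correlation(r: float, fdr: float) -> str:
    """Assess one (r, FDR) pair on the published four-level scheme."""
    if not np.isfinite(r) or not np.isfinite(fdr):
        return "none"
    if r <= 0 or fdr > 0.1:
        return "none"
    if r > 0.5:
        return "strong"
    if r > 0.3:
        return "moderate"
    return "weak"


@dataclass
class ValidationSummary:
    """Per-category counts over the tested pairs."""

    counts: dict = field(default_factory=dict)
    total: int = 0
    untested: int = 0

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            self.counts.setdefault(cat, 0)
        assert sum(self.counts.values()) == self.total, "category counts must sum to total"


def validate(
    scores: ScoreMatrix | pd.DataFrame,
    flow: pd.DataFrame,
    mapping: pd.DataFrame,
    method: str = "bh",
    min_samples: int = 4,
    exact: bool | None = False,
) -> tuple[pd.DataFrame, ValidationSummary]:
    """Correlate every mapped signature with its flow phenotype and classify.

    ``mapping`` has columns (signature_id, flow_phenotype).  Samples are
    joined by id across the two inputs; unmatched samples are dropped and
    counted per pair.  Pairs that cannot be tested (missing signature or
    phenotype, too few samples, constant vector) are retained in the output
    with a reason rather than silently dropped, and excluded from the
    adjustment family.  Returns the per-pair results frame with columns
    (signature_id, flow_phenotype, n, r, p, adjusted, category, note) and a
    :class:`ValidationSummary`.
    """
    score_df = scores.data if isinstance(scores, ScoreMatrix) else scores
    shared_samples = score_df.columns.intersection(flow.index)

    rows = []
    for sig_id, phenotype in mapping[["signature_id", "flow_phenotype"]].itertuples(index=False):
        row = {"signature_id": sig_id, "flow_phenotype": phenotype, "n": 0,
               "r": np.nan, "p": np.nan, "note": ""}
        if sig_id not in score_df.index:
            row["note"] = "signature not in score matrix"
        elif phenotype not in flow.columns:
            row["note"] = "phenotype not in flow panel"
        else:
            x = score_df.loc[sig_id, shared_samples].astype(float)
            y = flow.loc[shared_samples, phenotype].astype(float)
            keep = x.notna() & y.notna()
            row["n"] = int(keep.sum())
            if row["n"] < min_samples:
                row["note"] = f"only {row['n']} matched samples"
            else:
                r, p = spearman_pair(x[keep], y[keep], exact=exact)
                if np.isnan(r):
                    row["note"] = "constant vector; correlation undefined"
                else:
                    row["r"], row["p"] = r, p
        rows.append(row)

    results = pd.DataFrame(rows)
    tested = results["p"].notna()
    results["adjusted"] = np.nan
    results.loc[tested, "adjusted"] = adjust(results.loc[tested, "p"], method=method)
    results["category"] = [
        classify_correlation(r, q) if ok else "untested"
        for r, q, ok in zip(results["r"], results["adjusted"], tested)
    ]

    counts = {cat: int((results["category"] == cat).sum()) for cat in CATEGORIES}
    summary = ValidationSummary(counts=counts, total=int(tested.sum()),
                                untested=int((~tested).sum()))
    return results, summary
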