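"""Static HTML concordance report: the offline stand-in for an interactive
score-vs-flow browser.  One summary table plus a scatter plot per mapped
pair, embedded as base64 PNGs so the file is self-contained."""

from __future__ import annotations

import base64
import html
import io as _io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .io import ScoreMatrix  # noqa: E402
from .validation import ValidationSummary  # noqa: E402

__all__ = ["write_validation_report"]


def _scatter_png(x, y, title: str) -> str:
    fig, ax = plt.subplots(figsize=(3.2, 3.0), dpi=90)
    ax.scatter(x, y, s=12, alpha=0.7, edgecolors="none")
    ax.set_xlabel("deconvolution score")
    ax.set_ylabel("flow (% parent)")
    ax.set_title(title, fontsize=8)
    fig.tight_layout()
    buf = _io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def write_validation_report(
    results: pd.DataFrame,
    summary: ValidationSummary,
    path: str | Path,
    scores: ScoreMatrix | pd.DataFrame | None = None,
    flow: pd.DataFrame | None = None,
) -> Path:
    """Write the per-pair results (and optional scatters) as standalone HTML."""
    path = Path(path)
    parts = ["<html><head><meta charset='utf-8'><title>Concordance report</title>",
             "<style>body{font-family:sans-serif} table{border-collapse:collapse}",
             "td,th{border:1px solid #999;padding:3px 8px;font-size:13px}</style></head><body>",
             "<h1>Deconvolution vs flow cytometry</h1>",
             f"<p>Tested pairs: {summary.total}; untested: {summary.untested}. Counts: "
             + ", ".join(f"{k}={v}" for k, v in summary.counts.items()) + "</p>",
             results.to_html(index=False, float_format=lambda v: f"{v:.4g}")]
    if scores is not None and flow is not None:
        score_df = scores.data if isinstance(scores, ScoreMatrix) else scores
        shared = score_df.columns.intersection(flow.index)
        parts.append("<h2>Per-pair scatter plots</h2>")
        for row in results.itertuples(index=False):
            if row.signature_id in score_df.index and row.flow_phenotype in flow.columns:
                png = _scatter_png(
                    score_df.loc[row.signature_id, shared],
                    flow.loc[shared, row.flow_phenotype],
                    f"{row.signature_id} vs {row.flow_phenotype} ({row.category})",
                )
                parts.append(f"<img alt='{html.escape(str(row.signature_id))}' "
                             f"src='data:image/png;base64,{png}'/>")
    parts.append("</body></html>")
    path.write_text("\n".join(parts))
    return path
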