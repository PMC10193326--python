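"""Tabular and gene-set I/O for the deconvolution pipeline.

All matrices travel as :class:`pandas.DataFrame` objects with labelled axes:

* expression — genes (rows) × samples (columns), linear-scale, non-negative;
* flow panels — samples (rows) × cell phenotypes (columns), percent of parent
  population in [0, 100];
* score matrices — signatures (rows) × samples (columns), wrapped in
  :class:`ScoreMatrix` to carry the producing method ("svr" or "ssgsea").

Readers are strict: duplicate labels, missing values, out-of-range entries and
non-numeric cells fail with located errors rather than being imputed.  Writers
prepend a ``#``-comment header recording the package version and parameters;
readers skip such comments, so write→read round-trips are lossless at the
printed precision (10 significant digits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "SchemaError",
    "ParseError",
    "RangeError",
    "ScoreMatrix",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_flow",
    "write_flow",
    "read_scores",
    "write_scores",
]

#: linear-scale microarray intensities comfortably exceed this; log2 data do not
LOG_SCALE_MAX = 50.0

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """The file's layout violates the expected schema."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries row/column coordinates."""


class RangeError(ValueError):
    """A value falls outside the domain permitted for its matrix type."""


@dataclass
class ScoreMatrix:
    """Cell-type/signature scores per sample, tagged with the producing method.

    ``data`` holds signatures (rows) × samples (columns).  For ``method='svr'``
    every column lies on the unit simplex (fractions, summing to one); for
    ``method='ssgsea'`` entries are non-negative enrichment scores.
    """

    data: pd.DataFrame
    method: str = "svr"

    _VALID_METHODS = ("svr", "ssgsea")

    def __post_init__(self) -> None:
        if self.method not in self._VALID_METHODS:
            raise ValueError(f"method must be one of {self._VALID_METHODS}, got {self.method!r}")

    def validate(self, atol: float = 1e-9) -> "ScoreMatrix":
        """Check the method-specific invariants, returning self for chaining."""
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise RangeError("score matrix contains non-finite values")
        if (vals < -atol).any():
            raise RangeError("score matrix contains negative values")
        if self.method == "svr":
            sums = vals.sum(axis=0)
            bad = np.abs(sums - 1.0) > atol
            if bad.any():
                sample = self.data.columns[int(np.argmax(bad))]
                raise RangeError(
                    f"svr fractions must sum to 1 per sample; sample {sample!r} sums to "
                    f"{sums[np.argmax(bad)]:.12g}"
                )
        return self

    @property
    def signature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _header_comment(params: dict | None = None) -> str:
    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in params.items())
    return f"# leukodeconv v{__version__}{extra}\n"


def _read_labelled_table(path: str | Path, what: str) -> pd.DataFrame:
    """Read a table whose first column is the row label, strictly numeric body."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str, index_col=0)
    if raw.columns.size == 0:
        raise SchemaError(f"{what} file {path} has no data columns")
    # a header row that parses entirely as numbers is almost certainly data
    def _is_num(s: str) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    if all(_is_num(c) for c in raw.columns):
        raise SchemaError(f"{what} file {path} appears to lack a header row of sample ids")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise SchemaError(f"duplicate column id {dup!r} in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric or missing value {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} in {path}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = raw.index.name
    return numeric


def _collapse_duplicates(df: pd.DataFrame, rule: str) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    if rule == "mean":
        return df.groupby(level=0, sort=False).mean()
    if rule == "first":
        return df[~df.index.duplicated(keep="first")]
    if rule == "max-mean":
        # keep, per gene, the row with the highest mean across samples
        order = df.mean(axis=1).to_numpy()
        keep = (
            pd.Series(order, index=np.arange(len(df)))
            .groupby(df.index.to_numpy(), sort=False)
            .idxmax()
            .to_numpy()
        )
        return df.iloc[np.sort(keep)]
    raise ValueError(f"unknown collapse rule {rule!r}; expected max-mean, mean or first")


def read_expression(
    path: str | Path,
    collapse_rule: str = "max-mean",
    anti_log: bool = True,
) -> pd.DataFrame:
    """Read a genes × samples expression matrix from TSV/CSV.

    Duplicate gene symbols (common on microarrays, one row per probe set) are
    collapsed by ``collapse_rule``: ``"max-mean"`` keeps the probe with the
    highest mean intensity, ``"mean"`` averages, ``"first"`` keeps the first
    occurrence.  If the global maximum is below ``LOG_SCALE_MAX`` the data are
    assumed log2-scaled; a warning is emitted and, when ``anti_log`` is true,
    values are transformed back to the linear scale as ``2**x``.  Genes are
    returned in sorted (canonical) order so reading is row-order independent.
    """
    df = _read_labelled_table(path, "expression")
    df = _collapse_duplicates(df, collapse_rule)
    if float(df.to_numpy().max(initial=0.0)) < LOG_SCALE_MAX:
        warnings.warn(
            f"expression maximum {df.to_numpy().max():.4g} < {LOG_SCALE_MAX:g}: data appear "
            "log-scaled" + ("; applying 2**x" if anti_log else ""),
            UserWarning,
            stacklevel=2,
        )
        if anti_log:
            df = np.power(2.0, df)
    if (df.to_numpy() < 0).any():
        raise RangeError(f"expression matrix {path} contains negative linear-scale values")
    return df.sort_index()


def write_expression(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep=_sep_for(path), float_format=_FLOAT_FMT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into ``{set_name: [genes...]}`` preserving order.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate set
    names and empty sets are rejected.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
                raise SchemaError(f"gene set {fields[0]!r} (line {lineno}) has no genes")
            name = fields[0]
            if name in sets:
                raise SchemaError(f"duplicate gene-set name {name!r} (line {lineno})")
            genes = [g.strip() for g in fields[2:] if g.strip()]
            sets[name] = list(dict.fromkeys(genes))
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_flow(path: str | Path) -> pd.DataFrame:
    """Read a samples × phenotypes flow-cytometry panel (percent of parent)."""
    df = _read_labelled_table(Path(path), "flow panel")
    vals = df.to_numpy()
    if (vals < 0).any() or (vals > 100).any():
        r, c = np.argwhere((vals < 0) | (vals > 100))[0]
        raise RangeError(
            f"flow percentage {vals[r, c]:g} out of [0, 100] at sample {df.index[r]!r}, "
            f"phenotype {df.columns[c]!r}"
        )
    return df


def write_flow(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep=_sep_for(path), float_format=_FLOAT_FMT)


def read_scores(path: str | Path) -> ScoreMatrix:
    """Read a signatures × samples score matrix written by :func:`write_scores`."""
    path = Path(path)
    method = "svr"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if tok.startswith("method="):
                method = tok.split("=", 1)[1]
    df = _read_labelled_table(path, "score matrix")
    return ScoreMatrix(df, method=method)


def write_scores(scores: ScoreMatrix, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    meta = {"method": scores.method}
    if params:
        meta.update(params)
    with open(path, "w") as fh:
        fh.write(_header_comment(meta))
        scores.data.to_csv(fh, sep=_sep_for(path), float_format=_FLOAT_FMT)
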