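"""Reference assets: cell-type inventories, the non-blood exclusion list, the
deconvolution↔flow mapping tables, and signature-matrix validation.

The xCell-style taxonomy covers 64 cell types; removing the 20 published
non-blood types (chondrocytes, fibroblasts, keratinocytes, ...) leaves the 44
cell types scored in whole blood.  The CIBERSORT-style inventory covers the 22
LM22 leukocyte subtypes.  Signature ids follow the ``method.Cell.type`` dot
convention (e.g. ``cibersort.Neutrophils``, ``xcell.CD4.Tcm``) so published
concordance tables can be used directly.

The LM22 signature matrix itself is a published third-party asset and is not
bundled; use :func:`leukodeconv.simulate.make_signature_matrix` for hermetic
tests, or load a locally downloaded copy with
:func:`leukodeconv.io.read_expression`-style TSV via :func:`read_signature_matrix`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import SchemaError

__all__ = [
    "xcell_cell_types",
    "cibersort_cell_types",
    "blood_exclusion_list",
    "apply_exclusion",
    "load_mapping",
    "load_correlation_table",
    "read_signature_matrix",
    "validate_signature_matrix",
    "signature_set_from_gmt",
]

_MAPPING_KEYS = ("gse93777_cibersort", "gse93777_xcell", "clarity")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("leukodeconv").joinpath("data", name)))


def xcell_cell_types() -> pd.DataFrame:
    """The 64-type taxonomy with one signature id per cell type."""
    return pd.read_csv(_data_path("xcell_cell_types.tsv"), sep="\t")


def cibersort_cell_types() -> pd.DataFrame:
    """The 22 LM22 leukocyte subtypes with their signature ids."""
    return pd.read_csv(_data_path("cibersort_cell_types.tsv"), sep="\t")


def blood_exclusion_list() -> list[str]:
    """The 20 non-blood cell types excluded before whole-blood scoring."""
    text = _data_path("xcell_blood_exclusion.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def apply_exclusion(
    signatures: Mapping[str, list] | Iterable[str],
    exclusion: Iterable[str],
    strict: bool = True,
):
    """Remove excluded cell types from a signature collection.

    ``signatures`` may be a mapping ``cell_type -> [gene sets]`` (filtered by
    key) or a plain iterable of cell-type names.  In strict mode an exclusion
    name absent from the collection raises :class:`SchemaError`; in lenient
    mode it only warns, which makes the operation idempotent.
    """
    exclusion = list(exclusion)
    if isinstance(signatures, Mapping):
        names = list(signatures.keys())
    else:
        names = list(signatures)
    missing = [e for e in exclusion if e not in names]
    if missing:
        if strict:
            raise SchemaError(f"exclusion names not present in collection: {missing}")
        warnings.warn(f"exclusion names not present (ignored): {missing}", UserWarning, stacklevel=2)
    drop = set(exclusion)
    if isinstance(signatures, Mapping):
        return {k: v for k, v in signatures.items() if k not in drop}
    return [n for n in names if n not in drop]


def load_mapping(which: str) -> pd.DataFrame:
    """Load a deconvolution↔flow mapping as a two-column frame.

    ``gse93777_cibersort`` (14 pairs) and ``gse93777_xcell`` (25 pairs) are the
    published pairings used for the array-cohort validation; ``clarity`` (26
    pairs: 9 CIBERSORT-style + 17 xCell-style against 9 flow phenotypes) is a
    documented reconstruction from published counts and examples.
    """
    if which not in _MAPPING_KEYS:
        raise ValueError(f"unknown mapping {which!r}; expected one of {_MAPPING_KEYS}")
    if which == "clarity":
        df = pd.read_csv(_data_path("mapping_clarity_reconstructed.tsv"), sep="\t", comment="#")
    else:
        df = load_correlation_table(which)[["signature_id", "flow_phenotype"]]
    df = df.reset_index(drop=True)
    if df.duplicated().any():
        raise SchemaError(f"mapping {which} contains duplicate pairs")
    expected = {"gse93777_cibersort": 14, "gse93777_xcell": 25, "clarity": 26}[which]
    if len(df) != expected:
        raise SchemaError(f"mapping {which} has {len(df)} pairs, expected {expected}")
    return df


def load_correlation_table(which: str) -> pd.DataFrame:
    """Published per-pair concordance statistics (r, p, FDR, assessment)."""
    fname = {
        "gse93777_cibersort": "gse93777_cibersort_correlations.tsv",
        "gse93777_xcell": "gse93777_xcell_correlations.tsv",
    }.get(which)
    if fname is None:
        raise ValueError(f"unknown correlation table {which!r}")
    df = pd.read_csv(_data_path(fname), sep="\t", dtype={"p_value": str})
    df["spearman_r"] = df["spearman_r"].astype(float)
    df["fdr"] = df["fdr"].astype(float)
    return df


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes × cell-types signature matrix (LM22 layout TSV/CSV)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    B = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    B = B.apply(pd.to_numeric)
    B.index = B.index.astype(str)
    validate_signature_matrix(B)
    return B


def validate_signature_matrix(B: pd.DataFrame) -> dict:
    """Sanity-check a signature matrix; returns a report dict.

    Fails on duplicate gene symbols or fewer than two cell types; flags (but
    does not fail on) constant columns, which make a cell type unidentifiable.
    """
    if B.index.duplicated().any():
        dup = B.index[B.index.duplicated()][0]
        raise SchemaError(f"signature matrix has duplicate gene {dup!r}")
    if B.shape[1] < 2:
        raise SchemaError("signature matrix needs at least 2 cell types")
    vals = B.to_numpy(dtype=float)
    if (vals < 0).any():
        raise SchemaError("signature matrix contains negative reference expression")
    constant = [c for c, v in zip(B.columns, vals.T) if np.ptp(v) == 0]
    return {
        "n_genes": int(B.shape[0]),
        "n_cell_types": int(B.shape[1]),
        "condition_number": float(np.linalg.cond(vals)),
        "constant_columns": constant,
    }


def signature_set_from_gmt(gmt: Mapping[str, list[str]], sep: str = "%") -> dict[str, list[set[str]]]:
    """Group GMT gene sets by cell type.

    Gene-set collections for cell-type scoring conventionally name sets
    ``CellType%source%k``; everything before the first ``sep`` is the cell
    type, and a cell type may contribute several sets (one per source
    compendium).
    """
    grouped: dict[str, list[set[str]]] = {}
    for name, genes in gmt.items():
        cell_type = name.split(sep, 1)[0]
        grouped.setdefault(cell_type, []).append(set(genes))
    empty = [ct for ct, sets in grouped.items() if not any(sets)]
    if empty:
        raise SchemaError(f"cell types with empty signature lists: {empty}")
    return grouped
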