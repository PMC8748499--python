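"""Signature exposure assignment by constrained quadratic programming.

A signature matrix holds K signatures as rows over the 96 context classes,
each row a probability distribution.  Exposures for a tumor are the
non-negative combination of signatures closest (least squares) to its count
vector; normalized exposures are the per-tumor proportions.  The QP is
solved as non-negative least squares per tumor; the sum-to-one constraint is
imposed by normalizing afterwards.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import context_classes_96

__all__ = [
    "read_signature_matrix",
    "write_signature_matrix",
    "validate_signature_matrix",
    "fit_exposures",
    "positivity",
    "read_exposure_table",
]

logger = logging.getLogger(__name__)


def validate_signature_matrix(signatures: pd.DataFrame) -> pd.DataFrame:
    """Check a K x 96 signature matrix: rows sum to 1, entries non-negative."""
    if signatures.shape[1] != 96:
        raise ValueError(f"signature matrix must have 96 columns, got {signatures.shape[1]}")
    if (signatures.values < 0).any():
        raise ValueError("signature matrix has negative entries")
    sums = signatures.sum(axis=1).values
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("signature rows must sum to 1 within 1e-8")
    return signatures


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a signature TSV (classes x signatures, class labels in column 1).

    Returns signatures as rows (K x 96) in the package's COSMIC class order.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    labels = context_classes_96()
    missing = set(labels) - set(table.index)
    if missing:
        raise ValueError(f"signature file missing {len(missing)} context classes")
    signatures = table.loc[labels].T
    signatures.index.name = "signature"
    return validate_signature_matrix(signatures)


def write_signature_matrix(signatures: pd.DataFrame, path: str | Path) -> None:
    """Write signatures as the classes x signatures TSV layout."""
    validate_signature_matrix(signatures)
    signatures.T.rename_axis("class").to_csv(path, sep="\t")


def fit_exposures(
    catalog: pd.DataFrame,
    signatures: pd.DataFrame,
    normalize: bool = True,
    irls_iterations: int = 2,
) -> pd.DataFrame:
    """Assign signature exposures per tumor by non-negative least squares.

    For each tumor count vector c the exposures e minimize the
    variance-weighted ||c - e S||_2 subject to e >= 0, then (by default)
    are normalized to proportions.  Counts are multinomial, so after an
    initial unweighted solve the classes are reweighted by 1/sqrt(fitted)
    (Poisson variance) and the non-negative quadratic program is re-solved
    ``irls_iterations`` times; set it to 0 for the plain unweighted fit.
    Tumors with zero mutations get all-zero rows.

    The catalog's columns and the signature matrix's columns must agree
    (same 96-class ordering and context mode).
    """
    if list(catalog.columns) != list(signatures.columns):
        raise ValueError("catalog and signature matrix disagree on context-class ordering")
    cat_mode = catalog.attrs.get("context_mode")
    sig_mode = signatures.attrs.get("context_mode")
    if cat_mode and sig_mode and cat_mode != sig_mode:
        raise ValueError(f"context mode mismatch: catalog {cat_mode!r} vs signatures {sig_mode!r}")
    S = signatures.values.astype(float)  # K x 96
    if np.linalg.matrix_rank(S) < S.shape[0]:
        logger.warning("fit_exposures: rank-deficient signature matrix; solution may be non-unique")
    counts = catalog.values.astype(float)
    exposures = np.zeros((counts.shape[0], S.shape[0]))
    ST = S.T  # 96 x K
    for i, c in enumerate(counts):
        if c.sum() == 0:
            continue
        e, _ = nnls(ST, c)
        for _ in range(irls_iterations):
            fitted = ST @ e
            w = 1.0 / np.sqrt(np.maximum(fitted, 0.5))
            e, _ = nnls(ST * w[:, None], c * w)
        exposures[i] = e
    if normalize:
        totals = exposures.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            exposures = np.where(totals > 0, exposures / np.where(totals == 0, 1, totals), 0.0)
    result = pd.DataFrame(exposures, index=catalog.index, columns=signatures.index)
    result.attrs["normalized"] = normalize
    return result


def positivity(exposures: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Flag tumors positive for a signature: normalized exposure strictly above 5%."""
    if not exposures.attrs.get("normalized", True):
        raise ValueError("positivity is defined on normalized exposures")
    return exposures > threshold


def read_exposure_table(path: str | Path) -> pd.DataFrame:
    """Import an externally computed exposure table (tumors x signatures TSV).

    Rows are renormalized to proportions so external assigners (absolute
    attributed counts or proportions alike) plug into the association test.
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table.values < 0).any():
        raise ValueError("exposure table has negative entries")
    totals = table.sum(axis=1)
    table = table.div(totals.where(totals > 0, 1.0), axis=0)
    table.index.name = "tumor_id"
    table.attrs["normalized"] = True
    return table
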