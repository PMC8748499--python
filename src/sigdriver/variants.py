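"""Somatic variant tables, tumor metadata and the panel-of-normals artifact filter.

A variant table is a :class:`pandas.DataFrame` with columns
``tumor_id, chrom, pos, ref, alt`` holding single-nucleotide substitutions
only.  Coordinates are 1-based inclusive throughout the package (the MAF/VCF
convention); any BED interaction converts at the boundary.  Tumor metadata
(`entity`, `sex`, and the filtered mutational load ``total_load``) live in a
profile table keyed by ``tumor_id``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_COLUMNS",
    "read_variant_table",
    "write_variant_table",
    "validate_variants",
    "read_panel_of_normals",
    "filter_panel_artifacts",
    "compute_tumor_loads",
]

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["tumor_id", "chrom", "pos", "ref", "alt"]
_BASES = frozenset("ACGT")


class VariantFormatError(ValueError):
    """Raised when a variant file cannot be parsed under the named dialect."""


def validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Check variant-table invariants and return the (unmodified) frame.

    Invariants: required columns present; ref/alt single bases in ACGT with
    ref != alt; (tumor_id, chrom, pos, alt) unique.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise VariantFormatError(f"variant table missing columns: {missing}")
    if len(variants) == 0:
        return variants
    bad_base = ~(variants["ref"].isin(_BASES) & variants["alt"].isin(_BASES))
    if bad_base.any():
        raise VariantFormatError(
            f"{int(bad_base.sum())} records are not single-base A/C/G/T substitutions"
        )
    if (variants["ref"] == variants["alt"]).any():
        raise VariantFormatError("records with ref == alt present")
    dup = variants.duplicated(subset=["tumor_id", "chrom", "pos", "alt"])
    if dup.any():
        raise VariantFormatError(f"{int(dup.sum())} duplicate (tumor, chrom, pos, alt) records")
    return variants


def _read_maf_like(path: Path, tumor_col: str | None) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise VariantFormatError(f"cannot parse {path} as TSV: {exc}") from exc
    cols = {c.lower(): c for c in table.columns}
    # accept the package's own minimal dialect or common MAF headers
    aliases = {
        "tumor_id": ["tumor_id", "tumor_sample_barcode", "sample", "sample_id"],
        "chrom": ["chrom", "chromosome", "chr"],
        "pos": ["pos", "start_position", "position", "start"],
        "ref": ["ref", "reference_allele"],
        "alt": ["alt", "tumor_seq_allele2", "alternate_allele"],
    }
    if tumor_col is not None:
        aliases["tumor_id"] = [tumor_col.lower()]
    renames = {}
    for target, names in aliases.items():
        found = next((cols[n] for n in names if n in cols), None)
        if found is None:
            kind = "schema" if target == "tumor_id" else "format"
            raise VariantFormatError(
                f"{kind} error: no column for '{target}' in {path} (looked for {names})"
            )
        renames[found] = target
    table = table.rename(columns=renames)[VARIANT_COLUMNS]
    return table


def read_variant_table(
    path: str | Path,
    format: str = "maf-like-tsv",
    tumor_col: str | None = None,
    tumor_id: str | None = None,
) -> pd.DataFrame:
    """Read somatic SNVs from a MAF-like TSV or a VCF.

    Only A/C/G/T -> A/C/G/T single-base substitutions are retained; indels
    and MNVs are dropped with a logged count, and multi-allelic VCF rows are
    split into one record per alternate allele.

    Parameters
    ----------
    path : file path
    format : {"maf-like-tsv", "vcf"}
    tumor_col : optional explicit tumor-identifier column (TSV only)
    tumor_id : tumor identifier for single-sample VCFs lacking sample columns
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "maf-like-tsv":
        table = _read_maf_like(path, tumor_col)
        table = table.dropna(subset=VARIANT_COLUMNS)
        n_raw = len(table)
        snv = table["ref"].isin(_BASES) & table["alt"].isin(_BASES)
        table = table[snv].copy()
        dropped = n_raw - len(table)
    elif format == "vcf":
        table, dropped = _read_vcf(path, tumor_id)
    else:
        raise ValueError(f"unknown format: {format!r}")
    if dropped:
        logger.info("read_variant_table: dropped %d non-SNV records from %s", dropped, path)
    table["pos"] = table["pos"].astype(np.int64)
    table = table.reset_index(drop=True)
    return validate_variants(table)


def _read_vcf(path: Path, tumor_id: str | None) -> tuple[pd.DataFrame, int]:
    import pysam

    records = []
    dropped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise VariantFormatError(f"cannot parse {path} as VCF: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples and tumor_id is None:
        raise VariantFormatError(
            f"schema error: {path} has no sample columns; pass tumor_id explicitly"
        )
    with vcf:
        for rec in vcf:
            ref = rec.ref
            for alt in rec.alts or ():
                if ref in _BASES and alt in _BASES and ref != alt:
                    if samples:
                        for sample in samples:
                            gt = rec.samples[sample].get("GT", (None,))
                            if any(a not in (None, 0) for a in gt):
                                records.append((sample, rec.chrom, rec.pos, ref, alt))
                    else:
                        records.append((tumor_id, rec.chrom, rec.pos, ref, alt))
                else:
                    dropped += 1
    table = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return table, dropped


def write_variant_table(variants: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as the minimal 5-column TSV dialect."""
    validate_variants(variants)
    variants.to_csv(path, sep="\t", index=False, columns=VARIANT_COLUMNS)


def read_panel_of_normals(path: str | Path) -> pd.DataFrame:
    """Read a panel of normals as TSV with columns chrom, pos, alt, fraction."""
    panel = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "alt": str})
    required = {"chrom", "pos", "alt", "fraction"}
    if not required.issubset(panel.columns):
        raise VariantFormatError(f"panel of normals needs columns {sorted(required)}")
    if ((panel["fraction"] < 0) | (panel["fraction"] > 1)).any():
        raise ValueError("panel fractions must lie in [0, 1]")
    return panel


def filter_panel_artifacts(
    variants: pd.DataFrame, panel: pd.DataFrame, max_fraction: float = 0.01
) -> pd.DataFrame:
    """Drop variants seen in more than ``max_fraction`` of panel-of-normals samples.

    Recurrent technical artifacts show up in many unrelated control genomes;
    any (chrom, pos, alt) whose panel fraction is strictly above the threshold
    (default 1%) is removed.  Variants absent from the panel are kept
    (fraction 0).  The operation is idempotent.
    """
    if not 0 < max_fraction <= 1:
        raise ValueError("max_fraction must lie in (0, 1]")
    if len(variants) == 0 or len(panel) == 0:
        return variants.copy()
    flagged = panel.loc[panel["fraction"] > max_fraction, ["chrom", "pos", "alt"]]
    if len(flagged) == 0:
        return variants.copy()
    key = pd.MultiIndex.from_frame(variants[["chrom", "pos", "alt"]])
    bad = pd.MultiIndex.from_frame(flagged)
    keep = ~key.isin(bad)
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_panel_artifacts: removed %d panel-recurrent records", removed)
    return variants[keep].reset_index(drop=True)


def compute_tumor_loads(
    variants: pd.DataFrame,
    tumors: pd.DataFrame | list[str],
) -> pd.DataFrame:
    """Attach per-tumor mutational loads V_t (filtered sSNV counts) to profiles.

    ``tumors`` is either a list of tumor ids or a profile frame with columns
    ``tumor_id, entity, sex``; tumors with no records get total_load 0.  A
    record whose tumor_id is absent from the metadata is a consistency error.
    """
    if isinstance(tumors, pd.DataFrame):
        profiles = tumors.copy()
        if "tumor_id" not in profiles.columns:
            raise ValueError("profile frame needs a tumor_id column")
    else:
        profiles = pd.DataFrame({"tumor_id": list(tumors)})
    known = set(profiles["tumor_id"])
    unknown = set(variants["tumor_id"]) - known
    if unknown:
        raise ValueError(f"variant records for tumors absent from metadata: {sorted(unknown)[:5]}")
    counts = variants.groupby("tumor_id").size()
    profiles["total_load"] = profiles["tumor_id"].map(counts).fillna(0).astype(np.int64)
    if "entity" not in profiles.columns:
        profiles["entity"] = "unspecified"
    if "sex" not in profiles.columns:
        profiles["sex"] = "unknown"
    return profiles
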