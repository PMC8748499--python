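"""Substitution context classes: trinucleotide and NxSxN penta-reduced catalogs.

Single-base substitutions are classified on the pyrimidine strand into 96
classes (6 substitution types x 4 five-prime x 4 three-prime flanks) in the
conventional COSMIC lexicographic order.  Two context modes are supported:

``trinucleotide``
    flanks are the immediate neighbours (-1/+1) of the mutated base.
``nxsxn``
    flanks are the bases two positions away (-2/+2); the immediate
    neighbours are marginalised out.  This collapses the full
    penta-nucleotide space (1536 = 6x4x4x4x4 classes) onto 96 classes while
    widening the motif footprint.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTITUTIONS",
    "BASES",
    "context_classes_96",
    "penta_classes_1536",
    "class_index",
    "classify_context",
    "reduce_penta_to_nxsxn",
    "build_catalog",
]

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}


def context_classes_96() -> list[str]:
    """The 96 class labels "X[R>A]Y" in COSMIC order (substitution, 5', 3')."""
    return [f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES]


def penta_classes_1536() -> list[str]:
    """The 1536 full penta-nucleotide labels "VW[R>A]XY".

    Order is (substitution, -2, -1, +1, +2), each flank cycling A,C,G,T;
    the -2/+2 bases are the ones an NxSxN reduction retains.
    """
    return [
        f"{m2}{m1}[{sub}]{p1}{p2}"
        for sub in SUBSTITUTIONS
        for m2 in BASES
        for m1 in BASES
        for p1 in BASES
        for p2 in BASES
    ]


def class_index(five: str, sub: str, three: str) -> int:
    """Index of a 96-class label from its parts."""
    return _SUB_INDEX[sub] * 16 + _BASE_INDEX[five] * 4 + _BASE_INDEX[three]


def _fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch genome sequence [start0, end0) 0-based from several accessor types."""
    if isinstance(genome, dict):
        seq = genome[chrom][start0:end0]
    elif hasattr(genome, "fetch"):  # pysam.FastaFile
        seq = genome.fetch(chrom, start0, end0)
    else:  # pyfaidx.Fasta or similar subscriptable accessor
        seq = genome[chrom][start0:end0]
    return str(seq).upper()


class ReferenceMismatchError(ValueError):
    """Genome base at the variant position does not match the stated ref allele."""


class UnclassifiableContextError(ValueError):
    """Flanking context contains N or falls off the chromosome end."""


def classify_context(genome, chrom: str, pos: int, ref: str, alt: str, mode: str) -> int:
    """Classify one substitution into its 96-class index.

    ``pos`` is 1-based; the genome base there must equal ``ref`` on the plus
    strand.  Purine-reference substitutions are reverse-complemented to the
    pyrimidine strand first.  In ``nxsxn`` mode the -2/+2 bases are the
    flanks; in ``trinucleotide`` mode the -1/+1 bases.
    """
    if mode not in ("trinucleotide", "nxsxn"):
        raise ValueError(f"unknown context mode: {mode!r}")
    offset = 1 if mode == "trinucleotide" else 2
    window = _fetch(genome, chrom, pos - 1 - offset, pos + offset)
    if len(window) != 2 * offset + 1:
        raise UnclassifiableContextError(f"{chrom}:{pos} too close to a contig end")
    genome_ref = window[offset]
    if genome_ref != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} reference is {genome_ref!r}, variant says {ref!r}"
        )
    five, three = window[0], window[-1]
    if ref in ("A", "G"):  # purine reference: flip the scene to the pyrimidine strand
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    if "N" in (five, three) or alt == "N":
        raise UnclassifiableContextError(f"{chrom}:{pos} has N in the used flank positions")
    return class_index(five, f"{ref}>{alt}", three)


def reduce_penta_to_nxsxn(penta: np.ndarray) -> np.ndarray:
    """Collapse 1536 penta-context counts onto the 96 NxSxN classes.

    Each NxSxN class is the sum over the 16 combinations of the omitted
    -1/+1 bases; totals are conserved.
    """
    penta = np.asarray(penta)
    if penta.shape[-1] != 1536:
        raise ValueError(f"expected 1536 penta classes, got {penta.shape[-1]}")
    # layout (sub, -2, -1, +1, +2) -> marginalise axes -1 and +1
    shaped = penta.reshape(penta.shape[:-1] + (6, 4, 4, 4, 4))
    reduced = shaped.sum(axis=(-3, -2))  # marginalise the -1 and +1 flanks
    return reduced.reshape(penta.shape[:-1] + (96,))


def build_catalog(
    variants: pd.DataFrame,
    genome,
    mode: str = "trinucleotide",
    tumors: list[str] | None = None,
) -> pd.DataFrame:
    """Build a tumors x 96 mutation catalog from a variant table.

    Rows sum to each tumor's count of classifiable variants; variants with N
    in the used flanks or at contig ends are excluded with a logged count.
    Reference-mismatch errors propagate.
    """
    labels = context_classes_96()
    if tumors is None:
        tumors = sorted(variants["tumor_id"].unique())
    counts = np.zeros((len(tumors), 96), dtype=np.int64)
    row = {t: i for i, t in enumerate(tumors)}
    skipped = 0
    for tumor_id, chrom, pos, ref, alt in variants[
        ["tumor_id", "chrom", "pos", "ref", "alt"]
    ].itertuples(index=False):
        try:
            k = classify_context(genome, chrom, int(pos), ref, alt, mode)
        except UnclassifiableContextError:
            skipped += 1
            continue
        counts[row[tumor_id], k] += 1
    if skipped:
        logger.info("build_catalog: excluded %d unclassifiable variants", skipped)
    catalog = pd.DataFrame(counts, index=pd.Index(tumors, name="tumor_id"), columns=labels)
    catalog.attrs["context_mode"] = mode
    return catalog
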