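"""Knowledge-based hotspot annotation, enrichment tests and driver calls.

Hotspot top sites are annotated against 18-state ChromHMM segmentations
(enhancer/TSS status by a majority-style ratio over epigenomes), a gene
model (coding status and nearest gene), and known-driver gene lists.
Signature-level evidence combines a permutation test of element overlap
over the mappable genome with hypergeometric enrichment of known drivers,
BH-corrected across the signature set.  A signature whose hotspots show
both enrichments plus more than three Cancer Gene Census overlaps is
driver-associated; its significant hotspots become putative drivers when
they meet at least one regulatory/coding/expression/recurrence criterion.

All interval inputs are BED-convention 0-based half-open and are converted
to the package's 1-based coordinates at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CHROMHMM_18_STATES",
    "ENHANCER_STATES",
    "TSS_STATES",
    "ENHANCER_BACKGROUND_STATES",
    "TSS_BACKGROUND_STATES",
    "DriverCall",
    "annotate_chromhmm",
    "annotate_coding",
    "permutation_enrichment",
    "hypergeometric_enrichment",
    "bh_adjust",
    "classify_driver_associated_signature",
    "classify_putative_driver",
]

logger = logging.getLogger(__name__)

# Roadmap 18-state ChromHMM mnemonics, state numbers 1-18
CHROMHMM_18_STATES = {
    1: "TssA", 2: "TssFlnk", 3: "TssFlnkU", 4: "TssFlnkD", 5: "Tx", 6: "TxWk",
    7: "EnhG1", 8: "EnhG2", 9: "EnhA1", 10: "EnhA2", 11: "EnhWk", 12: "ZNF/Rpts",
    13: "Het", 14: "TssBiv", 15: "EnhBiv", 16: "ReprPC", 17: "ReprPCWk", 18: "Quies",
}
_STATE_NUM = {v: k for k, v in CHROMHMM_18_STATES.items()}

ENHANCER_STATES = frozenset({"EnhG1", "EnhG2", "EnhA1", "EnhA2"})
TSS_STATES = frozenset({"TssA", "TssFlnk"})
# background sets by state number, kept exactly as published (their overlap
# with foreground-adjacent states is deliberate, and they are configurable)
ENHANCER_BACKGROUND_STATES = frozenset(
    CHROMHMM_18_STATES[i] for i in (*range(1, 7), 12, 13, 14)
)
TSS_BACKGROUND_STATES = frozenset(CHROMHMM_18_STATES[i] for i in range(5, 16))


def _states_at(track: pd.DataFrame, chrom: str, pos: int) -> pd.Series:
    """State per epigenome at a 1-based position (epigenomes w/o coverage absent)."""
    sub = track[
        (track["chrom"] == chrom) & (track["start"] < pos) & (track["end"] >= pos)
    ]
    return sub.set_index("epigenome")["state"]


def annotate_chromhmm(
    track: pd.DataFrame,
    chrom: str,
    pos: int,
    enhancer_states: frozenset[str] = ENHANCER_STATES,
    enhancer_background: frozenset[str] = ENHANCER_BACKGROUND_STATES,
    tss_states: frozenset[str] = TSS_STATES,
    tss_background: frozenset[str] = TSS_BACKGROUND_STATES,
) -> tuple[bool, bool]:
    """Enhancer/TSS flags for a site from chromatin states across epigenomes.

    ``track`` columns: epigenome, chrom, start, end (0-based half-open),
    state.  The site is an enhancer when the count of epigenomes in an
    enhancer state exceeds half the count in background states (ratio
    > 1:2); the TSS rule is analogous.  Foreground with an empty background
    counts as a hit (the ratio is unbounded); a site outside every track
    yields (False, False).
    """
    if track["epigenome"].nunique() == 0:
        raise ValueError("at least one epigenome required")
    states = _states_at(track, chrom, pos)
    if states.empty:
        logger.info("annotate_chromhmm: %s:%d outside all epigenome tracks", chrom, pos)
        return False, False
    flags = []
    for fore, back in ((enhancer_states, enhancer_background), (tss_states, tss_background)):
        e = int(states.isin(fore).sum())
        b = int(states.isin(back).sum())
        flags.append(e / b > 0.5 if b > 0 else e > 0)
    return flags[0], flags[1]


def annotate_coding(
    genes: pd.DataFrame, chrom: str, pos: int
) -> tuple[bool, str | None]:
    """Coding flag and nearest gene for a site.

    ``genes`` columns: gene, chrom, start, end (0-based half-open) and
    ``feature`` in {"gene", "CDS"}.  Coding means inside any CDS interval;
    the nearest gene minimizes genomic distance to its gene span, ties
    broken to the alphabetically first name (logged).
    """
    if len(genes) == 0:
        return False, None
    here = genes[genes["chrom"] == chrom]
    cds = here[(here["feature"] == "CDS") & (here["start"] < pos) & (here["end"] >= pos)]
    coding = len(cds) > 0
    spans = here[here["feature"] == "gene"]
    if len(spans) == 0:
        return coding, None
    start1 = spans["start"].values + 1
    end1 = spans["end"].values
    dist = np.where(pos < start1, start1 - pos, np.where(pos > end1, pos - end1, 0))
    best = dist.min()
    candidates = sorted(spans["gene"].values[dist == best])
    if len(candidates) > 1:
        logger.info("annotate_coding: equidistant genes %s at %s:%d; taking %s",
                    candidates, chrom, pos, candidates[0])
    return coding, candidates[0]


def _mappable_intervals(mappability: pd.DataFrame, min_mappability: float) -> pd.DataFrame:
    keep = mappability[mappability["score"] >= min_mappability]
    return keep[["chrom", "start", "end"]].sort_values(["chrom", "start"]).reset_index(drop=True)


def permutation_enrichment(
    sites: pd.DataFrame,
    elements: pd.DataFrame,
    mappability: pd.DataFrame,
    n_perm: int = 100_000,
    min_mappability: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided permutation p for element overlap of hotspot sites.

    Each round redraws ``len(sites)`` positions uniformly over the mappable
    genome (mappability track rows with score below ``min_mappability``
    removed) and counts how many fall inside the element intervals;
    p = (1 + #{rounds with overlap >= observed}) / (n_perm + 1).

    ``sites``: columns chrom, pos (1-based).  ``elements`` and
    ``mappability``: chrom, start, end (0-based half-open), the latter with
    a ``score`` column.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mappable = _mappable_intervals(mappability, min_mappability)
    if len(mappable) == 0 or (mappable["end"] - mappable["start"]).sum() == 0:
        raise ValueError("no mappable territory after filtering")
    lengths = (mappable["end"] - mappable["start"]).values
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    def in_elements(chroms: np.ndarray, pos1: np.ndarray) -> np.ndarray:
        hit = np.zeros(len(pos1), dtype=bool)
        for chrom, sub in elements.groupby("chrom"):
            mask = chroms == chrom
            if not mask.any():
                continue
            starts = sub["start"].values
            ends = sub["end"].values
            p = pos1[mask]
            inside = np.zeros(mask.sum(), dtype=bool)
            for s, e in zip(starts, ends):
                inside |= (p > s) & (p <= e)
            hit[mask] = inside
        return hit

    obs_chroms = sites["chrom"].values.astype(object)
    observed = int(in_elements(obs_chroms, sites["pos"].values).sum())
    n_sites = len(sites)
    # map uniform draws over the concatenated mappable space back to genome
    draws = rng.integers(0, total, size=(n_perm, n_sites))
    flat = draws.ravel()
    idx = np.searchsorted(offsets, flat, side="right") - 1
    pos1 = mappable["start"].values[idx] + (flat - offsets[idx]) + 1
    chroms = mappable["chrom"].values[idx].astype(object)
    hits = in_elements(chroms, pos1).reshape(n_perm, n_sites).sum(axis=1)
    p = (1 + int((hits >= observed).sum())) / (n_perm + 1)
    return float(p)


def hypergeometric_enrichment(
    hit_genes: set[str], target_genes: set[str], background_size: int = 21_000
) -> float:
    """Upper-tail hypergeometric P(X >= overlap) on a coding-gene universe.

    N = background_size (default 21,000 coding genes), K = |targets|,
    n = |hits|; returns P(X >= observed overlap).
    """
    hits = set(hit_genes)
    targets = set(target_genes)
    overlap = len(hits & targets)
    n, K = len(hits), len(targets)
    if overlap > min(n, K):
        raise AssertionError("overlap cannot exceed either set size")
    if K > background_size or n > background_size:
        raise ValueError("sets larger than the background universe")
    return float(hypergeom.sf(overlap - 1, background_size, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (monotone, order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_driver_associated_signature(
    q_driver: float,
    q_elements: float,
    cgc_overlap: int,
    alpha: float = 0.05,
) -> bool:
    """Driver-associated signature rule.

    True iff the known-driver enrichment and the coding/regulatory
    permutation enrichment are both significant (q < alpha) and more than
    three hotspot events overlap Cancer Gene Census genes.
    """
    return (q_driver < alpha) and (q_elements < alpha) and (cgc_overlap > 3)


@dataclass
class DriverCall:
    hotspot_id: str
    signature_driver_associated: bool
    putative_driver: bool
    criteria: frozenset[str] = field(default_factory=frozenset)


def classify_putative_driver(
    hotspot_id: str,
    enhancer: bool,
    tss: bool,
    coding: bool,
    signature_driver_associated: bool,
    top_recurrence: int,
    expression_effect: bool | None = None,
    min_recurrence: int = 10,
) -> DriverCall:
    """Putative-driver rule for a significant hotspot.

    A hotspot of a driver-associated signature is a putative driver when it
    meets at least one criterion: located in a regulatory element
    (enhancer/TSS), located in a coding region, affects expression
    (externally supplied evidence; absent means unmet), or is highly
    recurrent (top site carried by >= ``min_recurrence`` tumors).  Hotspots
    of other signatures are susceptible targets, never putative drivers.
    """
    criteria = set()
    if enhancer or tss:
        criteria.add("regulatory")
    if coding:
        criteria.add("coding")
    if expression_effect:
        criteria.add("expression")
    if top_recurrence >= min_recurrence:
        criteria.add("recurrence")
    putative = signature_driver_associated and bool(criteria)
    return DriverCall(
        hotspot_id=hotspot_id,
        signature_driver_associated=signature_driver_associated,
        putative_driver=putative,
        criteria=frozenset(criteria if putative else criteria),
    )
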