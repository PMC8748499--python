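"""Genomic window scan and weighted-load hotspot pruning.

The genome is scanned in half-overlapping 2 kb windows (1 kb step); windows
with fewer than 6 somatic variants are discarded.  Within a candidate
window, variants are binned into 30 bp sub-windows at 15 bp steps, each
tumor's contribution is down-weighted by its mutational load
(w_t = 1/log2(V_t)), and a sub-window i with weighted load L_i is a hotspot
when it simultaneously satisfies

    L_i >= max(L) / 2
    L_i >  3 * mean(L)
    L_i >= mean(L) + 3 * sd(L)      (sample sd, n-1 denominator)

Member sites of selected sub-windows form a hotspot region; per-site
recurrence R counts the tumors sharing the position and alternate allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HotspotRegion",
    "tumor_weight",
    "restrict_entities",
    "genome_scan_windows",
    "bin_variants",
    "weighted_load",
    "select_hotspot_windows",
    "prune_region",
    "hotspots_to_bed",
]

logger = logging.getLogger(__name__)

SUBWINDOW_WIDTH = 30
SUBWINDOW_STEP = 15


@dataclass
class HotspotRegion:
    """A pruned window: member sites with recurrences and carrier tumors."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    sites: pd.DataFrame  # columns: pos, alt, recurrence, carriers (tuple of tumor ids)
    signature: str | None = None
    mode: str = "normal"
    load: pd.Series | None = field(default=None, repr=False)  # L_i per sub-window

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def total_variants(self) -> int:
        return int(self.sites["recurrence"].sum())

    @property
    def max_recurrence(self) -> int:
        return int(self.sites["recurrence"].max()) if len(self.sites) else 0

    @property
    def carriers(self) -> set[str]:
        out: set[str] = set()
        for c in self.sites["carriers"]:
            out.update(c)
        return out

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def tumor_weight(total_load: int) -> float:
    """Per-tumor weight w_t = 1/log2(V_t); loads below 2 clamp to 2."""
    if total_load < 2:
        warnings.warn(
            f"tumor load {total_load} < 2 clamped to 2 for weighting", stacklevel=2
        )
        total_load = 2
    return 1.0 / np.log2(total_load)


def restrict_entities(
    variants: pd.DataFrame,
    positive: pd.Series | pd.DataFrame,
    profiles: pd.DataFrame,
    signature: str | None = None,
    mode: str = "normal",
) -> pd.DataFrame:
    """Keep variants from entities with enough signature-positive tumors.

    An entity is eligible when the fraction of its tumors positive for the
    signature is >= 5% in normal mode, or >= 2% in wide mode.  ``positive``
    is a boolean per-tumor Series (or a positivity matrix with ``signature``
    naming the column).
    """
    threshold = {"normal": 0.05, "wide": 0.02}.get(mode)
    if threshold is None:
        raise ValueError(f"unknown scan mode: {mode!r}")
    if isinstance(positive, pd.DataFrame):
        if signature is None:
            raise ValueError("signature id required with a positivity matrix")
        positive = positive[signature]
    frac = (
        profiles.set_index("tumor_id")
        .assign(pos=positive)
        .groupby("entity", observed=True)["pos"]
        .mean()
    )
    eligible = set(frac[frac >= threshold].index)
    entity_of = profiles.set_index("tumor_id")["entity"]
    keep = variants["tumor_id"].map(entity_of).isin(eligible)
    return variants[keep].reset_index(drop=True)


def genome_scan_windows(
    variants: pd.DataFrame,
    chrom_sizes: dict[str, int],
    width: int = 2000,
    step: int = 1000,
    min_variants: int = 6,
) -> list[tuple[str, int, int, pd.DataFrame]]:
    """Tile half-overlapping windows from position 1 and keep variant-rich ones.

    Returns (chrom, start, end, variant subset) for every window holding at
    least ``min_variants`` records.  A final partial window past the last
    full tile is retained when it meets the same threshold.
    """
    missing = set(variants["chrom"]) - set(chrom_sizes)
    if missing:
        raise ValueError(f"chrom_sizes missing chromosomes: {sorted(missing)}")
    out: list[tuple[str, int, int, pd.DataFrame]] = []
    for chrom, sub in variants.groupby("chrom", sort=True):
        size = chrom_sizes[chrom]
        starts = list(range(1, max(size - width + 2, 2), step))
        last_end = starts[-1] + width - 1 if starts else 0
        if last_end < size:  # final partial window up to the chromosome end
            starts.append(starts[-1] + step if starts else 1)
        pos = sub["pos"].values
        order = np.argsort(pos, kind="stable")
        pos_sorted = pos[order]
        for start in starts:
            end = min(start + width - 1, size)
            lo, hi = np.searchsorted(pos_sorted, [start, end + 1])
            if hi - lo >= min_variants:
                out.append((chrom, start, end, sub.iloc[order[lo:hi]].reset_index(drop=True)))
    return out


def _subwindow_starts(start: int, end: int, width: int, step: int) -> np.ndarray:
    n = max(int(np.ceil((end - start + 1 - width) / step)) + 1, 1)
    return start + step * np.arange(n)


def bin_variants(
    variants: pd.DataFrame,
    start: int,
    end: int,
    width: int = SUBWINDOW_WIDTH,
    step: int = SUBWINDOW_STEP,
) -> pd.DataFrame:
    """Count each tumor's variants per overlapping sub-window (l_it).

    Sub-windows of ``width`` bp tile the region at ``step`` bp; with the
    default half-overlap a variant interior to the tiling falls in exactly
    two sub-windows.  Returns a sub-windows x tumors count frame indexed by
    sub-window start.
    """
    starts = _subwindow_starts(start, end, width, step)
    tumors = sorted(variants["tumor_id"].unique())
    counts = np.zeros((len(starts), len(tumors)), dtype=np.int64)
    trow = {t: i for i, t in enumerate(tumors)}
    if len(variants):
        for pos, tumor in zip(variants["pos"].values, variants["tumor_id"].values):
            off = pos - start
            lo = max(int(np.ceil((off - width + 1) / step)), 0)
            hi = min(off // step, len(starts) - 1)
            for i in range(lo, hi + 1):
                counts[i, trow[tumor]] += 1
    grid = pd.DataFrame(counts, index=pd.Index(starts, name="subwindow_start"), columns=tumors)
    return grid


def weighted_load(grid: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """Weighted mutational load L_i = sum_t w_t * l_it per sub-window."""
    missing = set(grid.columns) - set(weights.index)
    if missing:
        raise ValueError(f"weights missing for tumors: {sorted(missing)[:5]}")
    w = weights.reindex(grid.columns).values
    return pd.Series(grid.values @ w, index=grid.index, name="L")


def select_hotspot_windows(load: pd.Series | np.ndarray) -> np.ndarray:
    """Indices of sub-windows passing all three hotspot conditions.

    L_i >= max(L)/2; L_i > 3*mean(L); L_i >= mean(L) + 3*sd(L) with the
    sample (n-1) standard deviation.  A single-window vector has undefined
    sd, treated as 0.  The selection is invariant to positive rescaling.
    """
    L = np.asarray(load, dtype=float)
    if L.size == 0:
        raise ValueError("empty load vector")
    mean = L.mean()
    sd = L.std(ddof=1) if L.size > 1 else 0.0
    mask = (L >= L.max() / 2) & (L > 3 * mean) & (L >= mean + 3 * sd)
    return np.flatnonzero(mask)


def prune_region(
    chrom: str,
    start: int,
    end: int,
    variants: pd.DataFrame,
    weights: pd.Series,
    signature: str | None = None,
    mode: str = "normal",
) -> HotspotRegion | None:
    """Prune one candidate window to its hotspot sites, or None.

    Composition of bin_variants -> weighted_load -> select_hotspot_windows;
    member sites are the (pos, alt) keys inside selected sub-windows, with
    recurrence = number of carrier tumors of that substitution.
    """
    if len(variants) == 0:
        return None
    grid = bin_variants(variants, start, end)
    load = weighted_load(grid, weights)
    selected = select_hotspot_windows(load)
    if selected.size == 0:
        return None
    sub_starts = load.index.values[selected]
    in_any = np.zeros(len(variants), dtype=bool)
    pos = variants["pos"].values
    for s in sub_starts:
        in_any |= (pos >= s) & (pos <= s + SUBWINDOW_WIDTH - 1)
    members = variants[in_any]
    if len(members) == 0:
        return None
    sites = (
        members.groupby(["pos", "alt"], sort=True)["tumor_id"]
        .agg(tuple)
        .rename("carriers")
        .reset_index()
    )
    sites["recurrence"] = sites["carriers"].map(len)
    return HotspotRegion(
        chrom=chrom,
        start=start,
        end=end,
        sites=sites[["pos", "alt", "recurrence", "carriers"]],
        signature=signature,
        mode=mode,
        load=load,
    )


def hotspots_to_bed(hotspots: list[HotspotRegion]) -> pd.DataFrame:
    """Export hotspot regions as a BED-like frame (0-based half-open)."""
    rows = []
    for h in hotspots:
        rows.append(
            {
                "chrom": h.chrom,
                "start": h.start - 1,
                "end": h.end,
                "name": h.signature or ".",
                "n_sites": h.n_sites,
                "max_recurrence": h.max_recurrence,
                "sites": ";".join(f"{p}{a}R{r}" for p, a, r in
                                  h.sites[["pos", "alt", "recurrence"]].itertuples(index=False)),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "n_sites",
                                       "max_recurrence", "sites"])
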