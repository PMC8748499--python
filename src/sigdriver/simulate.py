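"""Seeded synthetic tumor cohorts with ground-truthed signature hotspots.

The generator emulates, at desk scale, the structure of a whole-genome
pan-cancer cohort: a random reference genome, tumors grouped into
entities, per-tumor signature exposures drawn from a Dirichlet, per-tumor
mutational loads drawn from a truncated log-normal, and background
mutations sampled from the exposure-weighted mixture of signature
profiles and placed at genome positions whose sequence context matches
the sampled class.  Planted hotspots couple a recurrent substitution to a
target signature by shifting carrier exposures by a chosen number of
residual standard deviations.

Every draw flows from the config seed; identical configs give
byte-identical outputs.  A truth manifest records planted hotspots and
their carriers for downstream power bookkeeping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import BASES, context_classes_96
from .variants import compute_tumor_loads

__all__ = [
    "PlantedHotspot",
    "SimulationConfig",
    "SimulationResult",
    "synthetic_signatures",
    "random_genome",
    "simulate_cohort",
    "simulate_null_cohort",
    "write_dataset",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PlantedHotspot:
    """A causal site: carriers of a recurrent substitution get an exposure shift."""

    signature: str
    effect_size: float  # exposure shift in residual standard deviations
    carrier_fraction: float
    chrom: str = "chr1"
    position: int | None = None  # chosen to match the signature's top context if None


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_tumors: int = 300
    entities: dict[str, float] = field(
        default_factory=lambda: {"ENT-A": 0.4, "ENT-B": 0.35, "ENT-C": 0.25}
    )
    n_signatures: int = 4
    signatures: pd.DataFrame | None = None  # overrides n_signatures when given
    # per-tumor load: log-normal(mu, sigma) truncated to [lo, hi]
    load_log_mu: float = math.log(2000.0)
    load_log_sigma: float = 1.0
    load_min: int = 50
    load_max: int = 100_000
    genome_length: int = 1_000_000
    context_mode: str = "trinucleotide"
    dirichlet_alpha: float = 1.0
    hotspots: tuple[PlantedHotspot, ...] = ()

    def validate(self) -> None:
        if not math.isclose(sum(self.entities.values()), 1.0, abs_tol=1e-9):
            raise ValueError("entity proportions must sum to 1")
        if not all(math.isfinite(h.effect_size) for h in self.hotspots):
            raise ValueError("effect sizes must be finite")
        if not 1_000 <= self.genome_length <= 50_000_000:
            raise ValueError("genome_length out of supported range")


@dataclass
class SimulationResult:
    variants: pd.DataFrame
    profiles: pd.DataFrame
    exposures: pd.DataFrame  # true (post-shift) normalized exposures
    signatures: pd.DataFrame
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    truth: dict


def synthetic_signatures(
    k: int, seed: int | np.random.Generator, concentration: float = 0.1
) -> pd.DataFrame:
    """Draw k sparse synthetic signatures over the 96 classes.

    A small Dirichlet concentration gives the peaked, near-disjoint
    profiles real mutational processes show, which keeps the assignment
    problem well conditioned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(96, concentration), size=k)
    sigs = pd.DataFrame(
        profiles,
        index=pd.Index([f"SIG-{i + 1}" for i in range(k)], name="signature"),
        columns=context_classes_96(),
    )
    return sigs


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _context_buckets(seq: str, mode: str) -> dict[tuple[str, str, str], np.ndarray]:
    """Positions (1-based) per pyrimidine-strand context key (five, ref, three)."""
    offset = 1 if mode == "trinucleotide" else 2
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    base_idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        base_idx[ord(b)] = i
    b = base_idx[codes]
    n = len(seq)
    center = np.arange(offset, n - offset)
    ref = b[center]
    five = b[center - offset]
    three = b[center + offset]
    pyrimidine = (ref == 1) | (ref == 3)  # C or T on the plus strand
    # reverse-complement scene for purine references
    comp = np.array([3, 2, 1, 0], dtype=np.int8)
    key_ref = np.where(pyrimidine, ref, comp[ref])
    key_five = np.where(pyrimidine, five, comp[three])
    key_three = np.where(pyrimidine, three, comp[five])
    keys = key_ref * 16 + key_five * 4 + key_three
    buckets: dict[tuple[str, str, str], np.ndarray] = {}
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    bounds = np.searchsorted(sorted_keys, np.arange(65))
    for code in np.unique(sorted_keys):
        lo, hi = bounds[code], bounds[code + 1]
        ref_b = BASES[code // 16]
        five_b = BASES[(code % 16) // 4]
        three_b = BASES[code % 4]
        buckets[(five_b, ref_b, three_b)] = center[order[lo:hi]] + 1  # to 1-based
    return buckets


def _alt_on_plus(seq: str, pos1: int, sub: str) -> tuple[str, str]:
    """Plus-strand (ref, alt) for a pyrimidine-strand substitution at pos1."""
    ref_plus = seq[pos1 - 1]
    alt_pyr = sub[2]
    if ref_plus == sub[0]:
        return ref_plus, alt_pyr
    return ref_plus, _COMPLEMENT[alt_pyr]


def simulate_cohort(config: SimulationConfig) -> SimulationResult:
    """Generate a full synthetic cohort with planted signature hotspots."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    seq = random_genome(config.genome_length, rng)
    buckets = _context_buckets(seq, config.context_mode)
    if any(len(v) == 0 for v in buckets.values()) or len(buckets) < 32:
        raise ValueError("genome too short to host all sequence contexts")

    signatures = (
        config.signatures
        if config.signatures is not None
        else synthetic_signatures(config.n_signatures, rng)
    )
    signatures = signatures.copy()
    signatures.attrs["context_mode"] = config.context_mode
    sig_names = list(signatures.index)
    k = len(sig_names)

    tumors = [f"T{i:04d}" for i in range(config.n_tumors)]
    entity_names = list(config.entities)
    entities = rng.choice(entity_names, size=config.n_tumors, p=list(config.entities.values()))
    sexes = rng.choice(["female", "male"], size=config.n_tumors)
    exposures = rng.dirichlet(np.full(k, config.dirichlet_alpha), size=config.n_tumors)

    # plant hotspots: pick carriers, shift their target-signature exposure by
    # effect * residual SD (exposure spread after entity-mean centering)
    truth_hotspots = []
    planted = []
    for hs in config.hotspots:
        j = sig_names.index(hs.signature)
        centered = exposures[:, j] - pd.Series(exposures[:, j]).groupby(entities).transform("mean").values
        resid_sd = float(np.std(centered, ddof=1))
        n_carriers = int(round(hs.carrier_fraction * config.n_tumors))
        carriers = rng.choice(config.n_tumors, size=n_carriers, replace=False)
        exposures[carriers, j] = np.clip(
            exposures[carriers, j] + hs.effect_size * resid_sd, 0.0, None
        )
        top_class = signatures.iloc[j].idxmax()
        five, sub, three = top_class[0], top_class[2:5], top_class[6]
        if hs.position is None:
            bucket = buckets[(five, sub[0], three)]
            position = int(bucket[rng.integers(len(bucket))])
        else:
            position = hs.position
        ref_plus, alt_plus = _alt_on_plus(seq, position, sub)
        planted.append((carriers, position, ref_plus, alt_plus))
        truth_hotspots.append(
            {
                "chrom": hs.chrom,
                "position": position,
                "ref": ref_plus,
                "alt": alt_plus,
                "signature": hs.signature,
                "effect_size": hs.effect_size,
                "carriers": [tumors[c] for c in sorted(carriers)],
            }
        )
    exposures /= exposures.sum(axis=1, keepdims=True)

    loads = np.exp(rng.normal(config.load_log_mu, config.load_log_sigma, config.n_tumors))
    loads = np.clip(loads, config.load_min, config.load_max).astype(np.int64)

    # background mutations: multinomial over classes, positions by context
    class_counts = np.vstack(
        [rng.multinomial(v, p) for v, p in zip(loads, exposures @ signatures.values)]
    )
    labels = context_classes_96()
    frames = []
    for kk, label in enumerate(labels):
        total = int(class_counts[:, kk].sum())
        if total == 0:
            continue
        five, sub, three = label[0], label[2:5], label[6]
        bucket = buckets[(five, sub[0], three)]
        pos_draw = bucket[rng.integers(0, len(bucket), size=total)]
        tumor_rep = np.repeat(np.arange(config.n_tumors), class_counts[:, kk])
        alt_pyr = sub[2]
        refs = np.frombuffer(seq.encode(), dtype=np.uint8)[pos_draw - 1]
        ref_chars = np.array([chr(c) for c in refs])
        # purine plus-strand reference means the scene was reverse-complemented
        alts = np.where(ref_chars == sub[0], alt_pyr, _COMPLEMENT[alt_pyr])
        frames.append(
            pd.DataFrame(
                {
                    "tumor_id": np.array(tumors, dtype=object)[tumor_rep],
                    "chrom": chrom,
                    "pos": pos_draw,
                    "ref": ref_chars,
                    "alt": alts,
                }
            )
        )
    for carriers, position, ref_plus, alt_plus in planted:
        frames.append(
            pd.DataFrame(
                {
                    "tumor_id": [tumors[c] for c in sorted(carriers)],
                    "chrom": chrom,
                    "pos": position,
                    "ref": ref_plus,
                    "alt": alt_plus,
                }
            )
        )
    variants = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["tumor_id", "chrom", "pos", "ref", "alt"]
    )
    variants = variants.drop_duplicates(subset=["tumor_id", "chrom", "pos", "alt"])
    variants = variants.sort_values(["tumor_id", "chrom", "pos", "alt"]).reset_index(drop=True)

    profile_meta = pd.DataFrame(
        {"tumor_id": tumors, "entity": entities, "sex": sexes}
    )
    profiles = compute_tumor_loads(variants, profile_meta)
    exposure_df = pd.DataFrame(
        exposures, index=pd.Index(tumors, name="tumor_id"), columns=sig_names
    )
    exposure_df.attrs["normalized"] = True
    truth = {
        "seed": config.seed,
        "n_tumors": config.n_tumors,
        "context_mode": config.context_mode,
        "hotspots": truth_hotspots,
        "causal_sites": [
            {"chrom": h["chrom"], "position": h["position"], "alt": h["alt"]}
            for h in truth_hotspots
            if h["effect_size"] != 0
        ],
    }
    return SimulationResult(
        variants=variants,
        profiles=profiles,
        exposures=exposure_df,
        signatures=signatures,
        genome={chrom: seq},
        chrom_sizes={chrom: config.genome_length},
        truth=truth,
    )


def simulate_null_cohort(config: SimulationConfig) -> SimulationResult:
    """Same generative process with every effect size forced to zero.

    Planted positions keep their recurrent substitutions (so eligible
    regions exist) but carry no exposure coupling; the truth manifest
    lists no causal sites.
    """
    null_hotspots = tuple(replace(h, effect_size=0.0) for h in config.hotspots)
    return simulate_cohort(replace(config, hotspots=null_hotspots))


def write_dataset(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the formats the pipeline consumes.

    MAF-like variants TSV, profiles TSV, true exposures TSV, signature
    TSV (classes x signatures), reference FASTA and a JSON truth manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": outdir / "variants.tsv",
        "profiles": outdir / "profiles.tsv",
        "exposures": outdir / "true_exposures.tsv",
        "signatures": outdir / "signatures.tsv",
        "genome": outdir / "genome.fa",
        "truth": outdir / "truth.json",
    }
    result.variants.to_csv(paths["variants"], sep="\t", index=False)
    result.profiles.to_csv(paths["profiles"], sep="\t", index=False)
    result.exposures.to_csv(paths["exposures"], sep="\t")
    result.signatures.T.rename_axis("class").to_csv(paths["signatures"], sep="\t")
    with open(paths["genome"], "w") as fh:
        for chrom, seq in result.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth, fh, indent=2, sort_keys=True)
    return paths
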