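"""End-to-end orchestration: catalog -> exposures -> scan -> test -> classify.

`scan_cohort` is the library entry point for in-memory data; `run_scan`
and `run_simulate` wrap it behind file-based configs for the command
line.  Every tunable consumed anywhere in a run is registered in
``DEFAULT_THRESHOLDS`` and echoed into the run manifest together with the
seed and the per-signature test counts, so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as anno
from .association import (
    AssociationResult,
    bonferroni_adjust,
    eligibility_check,
    fit_null_model,
    inflation_lambda,
    test_hotspot,
)
from .contexts import build_catalog
from .exposures import fit_exposures, positivity, read_exposure_table, read_signature_matrix
from .pruning import genome_scan_windows, prune_region, restrict_entities, tumor_weight
from .simulate import PlantedHotspot, SimulationConfig, simulate_cohort, write_dataset
from .variants import (
    compute_tumor_loads,
    filter_panel_artifacts,
    read_panel_of_normals,
    read_variant_table,
)

__all__ = ["DEFAULT_THRESHOLDS", "RunConfig", "ScanOutcome", "scan_cohort", "run_scan", "run_simulate"]

logger = logging.getLogger(__name__)

# registry of every tunable a run consumes; all of them land in the manifest
DEFAULT_THRESHOLDS: dict[str, float | int | str] = {
    "panel_max_fraction": 0.01,
    "positivity_threshold": 0.05,
    "entity_fraction_normal": 0.05,
    "entity_fraction_wide": 0.02,
    "window_width": 2000,
    "window_step": 1000,
    "min_window_variants": 6,
    "subwindow_width": 30,
    "subwindow_step": 15,
    "min_site_recurrence": 6,
    "min_region_variants": 10,
    "min_region_recurrence": 3,
    "resampling_B": 999,
    "resampling_B_max": 99999,
    "lambda_max": 1.5,
    "alpha": 0.05,
    "enrichment_n_perm": 100000,
    "min_mappability": 0.25,
    "hypergeometric_background": 21000,
    "putative_min_recurrence": 10,
}


@dataclass
class ScanOutcome:
    """Association tables plus the per-signature inflation report."""

    results: pd.DataFrame
    hotspots: dict[str, list]  # signature -> HotspotRegion list (eligible, tested)
    lambdas: pd.Series
    removed_signatures: list[str]
    m_per_signature: dict[str, int]


def scan_cohort(
    variants: pd.DataFrame,
    profiles: pd.DataFrame,
    exposures: pd.DataFrame,
    chrom_sizes: dict[str, int],
    signatures: list[str] | None = None,
    mode: str = "normal",
    seed: int = 0,
    thresholds: dict | None = None,
    perturb: bool = True,
) -> ScanOutcome:
    """Scan the genome and test every eligible hotspot per signature.

    For each signature: restrict to entities with enough signature-positive
    tumors, tile 2 kb/1 kb windows, prune each candidate window to hotspot
    sub-windows, keep eligible hotspots (deduplicated across overlapping
    windows by their member-site sets), and run the kernel association test
    with resampling calibration.  Bonferroni correction uses the number of
    tests performed for that signature.  Signature test series with
    inflation lambda above ``lambda_max`` are flagged and removed.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if signatures is None:
        signatures = list(exposures.columns)
    rng = np.random.default_rng(seed)
    pos_matrix = positivity(exposures, threshold=th["positivity_threshold"])
    weights = pd.Series(
        [tumor_weight(v) for v in profiles["total_load"]],
        index=profiles["tumor_id"].values,
    )
    rows = []
    kept_hotspots: dict[str, list] = {}
    lambdas: dict[str, float] = {}
    m_per_signature: dict[str, int] = {}
    for signature in signatures:
        v_sig = restrict_entities(variants, pos_matrix, profiles, signature, mode=mode)
        if len(v_sig) == 0:
            m_per_signature[signature] = 0
            lambdas[signature] = np.nan
            continue
        tested_entities = set(
            profiles.set_index("tumor_id").loc[v_sig["tumor_id"].unique(), "entity"]
        )
        prof_sig = profiles[profiles["entity"].isin(tested_entities)].reset_index(drop=True)
        windows = genome_scan_windows(
            v_sig,
            chrom_sizes,
            width=th["window_width"],
            step=th["window_step"],
            min_variants=th["min_window_variants"],
        )
        hotspots = []
        seen_site_sets = set()
        for chrom, start, end, wvars in windows:
            hs = prune_region(chrom, start, end, wvars, weights, signature=signature, mode=mode)
            if hs is None or not eligibility_check(hs):
                continue
            key = (chrom, tuple(map(tuple, hs.sites[["pos", "alt"]].values)))
            if key in seen_site_sets:
                continue
            seen_site_sets.add(key)
            hotspots.append(hs)
        m = len(hotspots)
        m_per_signature[signature] = m
        if m == 0:
            lambdas[signature] = np.nan
            continue
        null = fit_null_model(exposures, prof_sig, signature)
        sig_results: list[AssociationResult] = []
        for hs in hotspots:
            try:
                res = test_hotspot(
                    hs,
                    exposures,
                    prof_sig,
                    signature,
                    B=th["resampling_B"],
                    seed=rng,
                    null=null,
                    perturb=perturb,
                )
            except Exception as exc:  # a single degenerate region must not kill the run
                logger.warning("scan: %s on %s failed: %s", signature, hs.region_id, exc)
                continue
            sig_results.append(res)
        p_adj = bonferroni_adjust([r.p_resampled for r in sig_results], m)
        for r, pa in zip(sig_results, p_adj):
            r.p_adjusted = float(pa)
        p_raws = np.array([r.p_raw for r in sig_results])
        lambdas[signature] = inflation_lambda(p_raws) if p_raws.size >= 10 else np.nan
        kept_hotspots[signature] = hotspots
        for r, hs in zip(sig_results, hotspots):
            rows.append(
                {
                    "region": r.region_id,
                    "signature": signature,
                    "n_sites": r.n_sites,
                    "n_carriers": r.n_carriers,
                    "p_raw": r.p_raw,
                    "p_resampled": r.p_resampled,
                    "p_adjusted": r.p_adjusted,
                    "direction": r.direction,
                    "top_pos": int(hs.sites.loc[hs.sites["recurrence"].idxmax(), "pos"]),
                    "top_alt": hs.sites.loc[hs.sites["recurrence"].idxmax(), "alt"],
                    "top_recurrence": hs.max_recurrence,
                    "perturbation_ratios": ";".join(
                        f"{x:.4g}" for x in (r.perturbation["ratio"] if r.perturbation is not None else [])
                    ),
                }
            )
    results = pd.DataFrame(
        rows,
        columns=[
            "region", "signature", "n_sites", "n_carriers", "p_raw", "p_resampled",
            "p_adjusted", "direction", "top_pos", "top_alt", "top_recurrence",
            "perturbation_ratios",
        ],
    )
    lam = pd.Series(lambdas, name="lambda")
    removed = [s for s, v in lam.items() if np.isfinite(v) and v > th["lambda_max"]]
    return ScanOutcome(
        results=results,
        hotspots=kept_hotspots,
        lambdas=lam,
        removed_signatures=removed,
        m_per_signature=m_per_signature,
    )


def annotate_and_classify(
    outcome: ScanOutcome,
    chromhmm: pd.DataFrame,
    genes: pd.DataFrame,
    driver_genes: set[str],
    cgc_genes: set[str],
    elements: pd.DataFrame,
    mappability: pd.DataFrame,
    expression_effects: dict[str, bool] | None = None,
    seed: int = 0,
    thresholds: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Annotate significant hotspots and call driver-associated signatures.

    Returns (annotated hotspot table, per-signature enrichment/classification
    table, driver-call table).  Significance gate, permutation rounds,
    mappability cutoff and the recurrence criterion all come from the
    threshold registry.  BH correction of enrichment p-values runs across
    the signature set, separately per test family.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    alpha = th["alpha"]
    expression_effects = expression_effects or {}
    res = outcome.results
    significant = res[
        (res["p_adjusted"] < alpha) & ~res["signature"].isin(outcome.removed_signatures)
    ].copy()
    ann_rows = []
    for row in significant.itertuples(index=False):
        chrom = row.region.split(":")[0]
        enhancer, tss = anno.annotate_chromhmm(chromhmm, chrom, row.top_pos)
        coding, nearest = anno.annotate_coding(genes, chrom, row.top_pos)
        ann_rows.append(
            {
                "region": row.region,
                "signature": row.signature,
                "chrom": chrom,
                "top_pos": row.top_pos,
                "top_recurrence": row.top_recurrence,
                "p_adjusted": row.p_adjusted,
                "direction": row.direction,
                "enhancer": enhancer,
                "tss": tss,
                "coding": coding,
                "nearest_gene": nearest,
                "known_driver": nearest in driver_genes,
                "cgc_gene": nearest in cgc_genes,
            }
        )
    annotated = pd.DataFrame(
        ann_rows,
        columns=["region", "signature", "chrom", "top_pos", "top_recurrence",
                 "p_adjusted", "direction", "enhancer", "tss", "coding",
                 "nearest_gene", "known_driver", "cgc_gene"],
    )
    sig_rows = []
    rng = np.random.default_rng(seed)
    for signature in sorted(significant["signature"].unique()):
        sub = annotated[annotated["signature"] == signature]
        sites = sub[["chrom", "top_pos"]].rename(columns={"top_pos": "pos"})
        p_perm = anno.permutation_enrichment(
            sites, elements, mappability,
            n_perm=int(th["enrichment_n_perm"]),
            min_mappability=th["min_mappability"],
            seed=rng,
        )
        hit_genes = set(sub["nearest_gene"].dropna())
        p_driver = anno.hypergeometric_enrichment(
            hit_genes, driver_genes, background_size=int(th["hypergeometric_background"])
        )
        sig_rows.append(
            {
                "signature": signature,
                "p_elements": p_perm,
                "p_driver": p_driver,
                "cgc_overlap": int(sub["cgc_gene"].sum()),
            }
        )
    signature_calls = pd.DataFrame(
        sig_rows, columns=["signature", "p_elements", "p_driver", "cgc_overlap"]
    )
    if len(signature_calls):
        signature_calls["q_elements"] = anno.bh_adjust(signature_calls["p_elements"])
        signature_calls["q_driver"] = anno.bh_adjust(signature_calls["p_driver"])
        signature_calls["driver_associated"] = [
            anno.classify_driver_associated_signature(qd, qe, c, alpha=alpha)
            for qd, qe, c in signature_calls[
                ["q_driver", "q_elements", "cgc_overlap"]
            ].itertuples(index=False)
        ]
    else:
        for col in ("q_elements", "q_driver"):
            signature_calls[col] = pd.Series(dtype=float)
        signature_calls["driver_associated"] = pd.Series(dtype=bool)
    assoc = dict(zip(signature_calls["signature"], signature_calls["driver_associated"]))
    call_rows = []
    for row in annotated.itertuples(index=False):
        hotspot_id = f"{row.region}|{row.signature}"
        call = anno.classify_putative_driver(
            hotspot_id,
            enhancer=row.enhancer,
            tss=row.tss,
            coding=row.coding,
            signature_driver_associated=bool(assoc.get(row.signature, False)),
            top_recurrence=row.top_recurrence,
            expression_effect=expression_effects.get(hotspot_id),
            min_recurrence=int(th["putative_min_recurrence"]),
        )
        call_rows.append(
            {
                "hotspot_id": hotspot_id,
                "region": row.region,
                "signature": row.signature,
                "driver_associated_signature": call.signature_driver_associated,
                "putative_driver": call.putative_driver,
                "criteria": ";".join(sorted(call.criteria)),
            }
        )
    driver_calls = pd.DataFrame(
        call_rows,
        columns=["hotspot_id", "region", "signature", "driver_associated_signature",
                 "putative_driver", "criteria"],
    )
    return annotated, signature_calls, driver_calls


@dataclass
class RunConfig:
    """File-based run configuration (YAML on disk)."""

    variants: Path
    profiles: Path
    genome: Path
    signatures: Path | None = None
    exposures: Path | None = None  # externally computed exposures, overrides fitting
    panel: Path | None = None
    context_mode: str = "trinucleotide"
    mode: str = "normal"
    seed: int = 0
    out: Path = Path("sigdriver-out")
    thresholds: dict = field(default_factory=dict)
    test_signatures: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        paths = {k: Path(v) for k, v in raw.items()
                 if k in {"variants", "profiles", "genome", "signatures", "exposures",
                          "panel", "out"} and v is not None}
        other = {k: v for k, v in raw.items() if k not in paths}
        cfg = cls(**paths, **other)
        for name in ("variants", "profiles", "genome", "signatures", "exposures", "panel"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name} = {p} does not exist")
        return cfg


def _load_genome(path: Path) -> dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def run_scan(config: RunConfig) -> Path:
    """Execute a full scan from files and write a results directory.

    Writes per-signature association tables, the inflation-lambda report
    with removed signatures, the hotspot site table and a JSON manifest
    (package version, seed, every threshold, tests per signature).
    Returns the output directory.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    th = dict(DEFAULT_THRESHOLDS)
    th.update(config.thresholds)
    variants = read_variant_table(config.variants, format="maf-like-tsv")
    if config.panel is not None:
        panel = read_panel_of_normals(config.panel)
        variants = filter_panel_artifacts(variants, panel, th["panel_max_fraction"])
    profiles = pd.read_csv(config.profiles, sep="\t", dtype={"tumor_id": str})
    profiles = compute_tumor_loads(variants, profiles)
    genome = _load_genome(config.genome)
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    if config.exposures is not None:
        exposures = read_exposure_table(config.exposures)
    else:
        if config.signatures is None:
            raise ValueError("either a signature matrix or an exposure table is required")
        signatures = read_signature_matrix(config.signatures)
        catalog = build_catalog(
            variants, genome, mode=config.context_mode, tumors=list(profiles["tumor_id"])
        )
        exposures = fit_exposures(catalog, signatures)
        exposures.to_csv(out / "exposures.tsv", sep="\t")
    outcome = scan_cohort(
        variants,
        profiles,
        exposures,
        chrom_sizes,
        signatures=config.test_signatures,
        mode=config.mode,
        seed=config.seed,
        thresholds=config.thresholds,
    )
    outcome.results.to_csv(out / "associations.tsv", sep="\t", index=False)
    lam_report = outcome.lambdas.rename_axis("signature").reset_index()
    lam_report["removed"] = lam_report["signature"].isin(outcome.removed_signatures)
    lam_report.to_csv(out / "lambda_report.tsv", sep="\t", index=False)
    manifest = {
        "sigdriver_version": _pkg_version("sigdriver"),
        "seed": config.seed,
        "mode": config.mode,
        "context_mode": config.context_mode,
        "thresholds": th,
        "tests_per_signature": outcome.m_per_signature,
        "removed_signatures": outcome.removed_signatures,
        "inputs": {
            "variants": str(config.variants),
            "profiles": str(config.profiles),
            "genome": str(config.genome),
            "signatures": str(config.signatures),
            "exposures": str(config.exposures),
            "panel": str(config.panel),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def run_simulate(
    seed: int,
    out: str | Path,
    n_tumors: int = 300,
    genome_length: int = 1_000_000,
    n_signatures: int = 4,
    hotspots: list[dict] | None = None,
    **config_kwargs,
) -> Path:
    """Generate a synthetic dataset directory with a manifest."""
    planted = tuple(PlantedHotspot(**h) for h in (hotspots or []))
    cfg = SimulationConfig(
        seed=seed,
        n_tumors=n_tumors,
        genome_length=genome_length,
        n_signatures=n_signatures,
        hotspots=planted,
        **config_kwargs,
    )
    result = simulate_cohort(cfg)
    out = Path(out)
    write_dataset(result, out)
    manifest = {
        "sigdriver_version": _pkg_version("sigdriver"),
        "seed": seed,
        "n_tumors": n_tumors,
        "genome_length": genome_length,
        "n_signatures": n_signatures,
        "hotspots": [h.__dict__ for h in planted],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
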