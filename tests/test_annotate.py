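"""Chromatin-state/coding annotation, enrichment tests and driver calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sigdriver.annotate import (
    annotate_chromhmm,
    annotate_coding,
    bh_adjust,
    classify_driver_associated_signature,
    classify_putative_driver,
    hypergeometric_enrichment,
    permutation_enrichment,
)


def _track(n_enh, n_back, n_quies=0, enh_state="EnhA1", back_state="Tx"):
    rows = []
    for i in range(n_enh):
        rows.append((f"E{i:03d}", "chr1", 0, 1000, enh_state))
    for i in range(n_back):
        rows.append((f"B{i:03d}", "chr1", 0, 1000, back_state))
    for i in range(n_quies):
        rows.append((f"Q{i:03d}", "chr1", 0, 1000, "Quies"))
    return pd.DataFrame(rows, columns=["epigenome", "chrom", "start", "end", "state"])


class TestChromHMM:
    def test_ratio_above_half_is_enhancer(self):
        enh, tss = annotate_chromhmm(_track(40, 60), "chr1", 500)
        assert enh and not tss

    def test_ratio_below_half_not_enhancer(self):
        enh, _ = annotate_chromhmm(_track(10, 80), "chr1", 500)
        assert not enh

    def test_foreground_with_zero_background_counts(self):
        enh, _ = annotate_chromhmm(_track(5, 0, n_quies=20), "chr1", 500)
        assert enh  # Quies is in neither set; the ratio is unbounded

    def test_site_outside_tracks(self):
        enh, tss = annotate_chromhmm(_track(5, 5), "chr1", 99999)
        assert (enh, tss) == (False, False)

    def test_tss_rule(self):
        enh, tss = annotate_chromhmm(_track(30, 20, enh_state="TssA"), "chr1", 500)
        assert tss and not enh


class TestCoding:
    @pytest.fixture()
    def genes(self):
        return pd.DataFrame(
            [
                ("GENEA", "chr1", 1000, 2000, "gene"),
                ("GENEA", "chr1", 1200, 1500, "CDS"),
                ("GENEB", "chr1", 3000, 4000, "gene"),
            ],
            columns=["gene", "chrom", "start", "end", "feature"],
        )

    def test_inside_cds(self, genes):
        coding, nearest = annotate_coding(genes, "chr1", 1300)
        assert coding and nearest == "GENEA"

    def test_intergenic_nearest(self, genes):
        # 500 bp past GENEA's end, 500+ bp before GENEB's start
        coding, nearest = annotate_coding(genes, "chr1", 2500)
        assert not coding and nearest == "GENEA"

    def test_equidistant_tie_alphabetical(self):
        genes = pd.DataFrame(
            [
                ("ZGENE", "chr1", 0, 100, "gene"),
                ("AGENE", "chr1", 300, 400, "gene"),
            ],
            columns=["gene", "chrom", "start", "end", "feature"],
        )
        _, nearest = annotate_coding(genes, "chr1", 201)  # 101 bp from both
        assert nearest == "AGENE"

    def test_empty_model(self):
        empty = pd.DataFrame(columns=["gene", "chrom", "start", "end", "feature"])
        assert annotate_coding(empty, "chr1", 1) == (False, None)


class TestPermutationEnrichment:
    @pytest.fixture()
    def toy(self):
        mappability = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "score": [1.0]}
        )
        elements = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        return elements, mappability

    def test_floor_when_observed_beats_all(self, toy):
        elements, mappability = toy
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [150, 160]})
        p = permutation_enrichment(sites, elements, mappability, n_perm=999, seed=1)
        assert p >= 1 / 1000
        assert p < 0.05

    def test_saturating_elements_give_one(self):
        mappability = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500], "score": [1.0]}
        )
        elements = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [250]})
        assert permutation_enrichment(sites, elements, mappability, n_perm=999, seed=2) == 1.0

    def test_matches_exact_binomial(self, toy):
        """On a 1000 bp genome with one 100 bp element the permutation p is
        a Monte-Carlo estimate of an exact binomial tail."""
        elements, mappability = toy
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [150, 700]})  # 1 hit
        n_perm = 20000
        p = permutation_enrichment(sites, elements, mappability, n_perm=n_perm, seed=3)
        f = 0.1  # element fraction of the mappable genome
        exact = sum(math.comb(2, k) * f**k * (1 - f) ** (2 - k) for k in (1, 2))
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 3 * se + 2 / n_perm

    def test_low_mappability_removed(self):
        mappability = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [500, 1000],
             "score": [0.1, 1.0]}
        )
        elements = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [600]})
        # the element lies wholly in removed territory: no draw can hit it
        p = permutation_enrichment(sites, elements, mappability, n_perm=499, seed=4)
        assert p == 1.0

    def test_zero_mappable_raises(self):
        mappability = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [100], "score": [0.0]}
        )
        with pytest.raises(ValueError, match="mappable"):
            permutation_enrichment(
                pd.DataFrame({"chrom": ["chr1"], "pos": [50]}),
                pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}),
                mappability,
                n_perm=99,
            )


class TestHypergeometric:
    def test_printed_example(self):
        # N=20, K=5, n=4, overlap=4 -> 5/C(20,4) = 5/4845
        hits = {f"g{i}" for i in range(4)}
        targets = hits | {"g99"}
        p = hypergeometric_enrichment(hits, targets, background_size=20)
        assert p == pytest.approx(5 / 4845)

    def test_zero_overlap_is_one(self):
        p = hypergeometric_enrichment({"a"}, {"b"}, background_size=100)
        assert p == 1.0

    def test_matches_enumeration_for_small_universe(self):
        """Exact enumeration over all draws reproduces the tail for N <= 25."""
        N, K, n = 25, 7, 6
        for overlap in range(0, min(K, n) + 1):
            hits = {f"t{i}" for i in range(overlap)} | {f"h{i}" for i in range(n - overlap)}
            targets = {f"t{i}" for i in range(K)}
            p = hypergeometric_enrichment(hits, targets, background_size=N)
            exact = sum(
                math.comb(K, x) * math.comb(N - K, n - x) for x in range(overlap, min(K, n) + 1)
            ) / math.comb(N, n)
            assert p == pytest.approx(exact, rel=1e-12)


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computation(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1, 12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestDriverClassification:
    def test_signature_rule_truth_table(self):
        assert classify_driver_associated_signature(0.001, 0.0005, 5)
        assert not classify_driver_associated_signature(0.001, 0.0005, 3)  # strict > 3
        assert not classify_driver_associated_signature(0.2, 0.0005, 5)
        assert not classify_driver_associated_signature(0.001, 0.2, 5)

    def test_putative_driver_gate_property(self):
        """Without a driver-associated signature no flag combination yields
        a putative driver; with it, any single criterion suffices."""
        for enh, tss, cod, expr, rec in itertools.product(
            [False, True], [False, True], [False, True], [None, True], [0, 10]
        ):
            for assoc in (False, True):
                call = classify_putative_driver(
                    "h1", enhancer=enh, tss=tss, coding=cod,
                    signature_driver_associated=assoc,
                    top_recurrence=rec, expression_effect=expr,
                )
                any_criterion = enh or tss or cod or bool(expr) or rec >= 10
                assert call.putative_driver == (assoc and any_criterion)

    def test_recurrence_criterion_boundary(self):
        call = classify_putative_driver(
            "h", enhancer=False, tss=False, coding=False,
            signature_driver_associated=True, top_recurrence=10,
        )
        assert call.putative_driver and call.criteria == frozenset({"recurrence"})
        call9 = classify_putative_driver(
            "h", enhancer=False, tss=False, coding=False,
            signature_driver_associated=True, top_recurrence=9,
        )
        assert not call9.putative_driver
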