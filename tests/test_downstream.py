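"""Downstream enrichment and clustering analyses."""

import numpy as np
import pandas as pd
import pytest

from lncsurv import (
    GeneInterval,
    classify_prognostic,
    cluster_rows,
    cross_dataset_validation,
    essentiality_enrichment,
    fisher_exact_one_sided,
    gene_cna_signal,
    patient_cna_enrichment,
    select_top_variable,
)

from .oracles import complete_linkage_brute, fisher_upper_tail


def meta_frame(z, meta_p=None, fdr=None):
    n = len(z)
    return pd.DataFrame(
        {
            "meta_z": z,
            "meta_p": meta_p if meta_p is not None else [0.5] * n,
            "fdr_bh": fdr if fdr is not None else [0.5] * n,
        },
        index=[f"L{i}" for i in range(n)],
    )


class TestClassifyPrognostic:
    def test_metabric_scheme_assigns_hazardous(self):
        meta = meta_frame([2.5], fdr=[0.005])
        haz, prot, non = classify_prognostic(meta, "metabric_cna")
        assert haz == {"L0"} and not prot

    def test_metabric_scheme_assigns_protective(self):
        meta = meta_frame([-2.5], fdr=[0.005])
        haz, prot, non = classify_prognostic(meta, "metabric_cna")
        assert prot == {"L0"} and not haz

    def test_cross_dataset_scheme_leaves_middle_band_unassigned(self):
        meta = meta_frame([2, 2, 2], fdr=[0.01, 0.07, 0.2])
        haz, prot, non = classify_prognostic(meta, "cross_dataset")
        assert haz == {"L0"}
        assert non == {"L2"}          # 0.05 <= FDR <= 0.1 stays out

    def test_all_schemes_match_literal_rule_application(self, rng):
        z = rng.normal(size=100)
        meta_p = rng.uniform(0.0001, 1, 100)
        fdr = np.minimum(meta_p * 3, 1.0)
        meta = meta_frame(z, meta_p=meta_p, fdr=fdr)
        from lncsurv.downstream import SCHEMES

        for name, rule in SCHEMES.items():
            haz, prot, _ = classify_prognostic(meta, name)
            p = meta[rule["p_col"]]
            sig = p <= rule["cutoff"] if rule["inclusive"] else \
                p < rule["cutoff"]
            assert haz == set(meta.index[sig & (meta.meta_z > 0)])
            assert prot == set(meta.index[sig & (meta.meta_z < 0)])

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            classify_prognostic(meta_frame([1.0]), "nope")


class TestFisherOneSided:
    def test_example_table(self):
        odds, p = fisher_exact_one_sided([[10, 5], [2, 20]])
        assert odds == pytest.approx(20.0)
        assert p == pytest.approx(
            fisher_upper_tail([[10, 5], [2, 20]]), abs=1e-12
        )

    def test_flat_table_no_enrichment(self):
        odds, p = fisher_exact_one_sided([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p > 0.5

    def test_zero_cell_conventions(self):
        odds, p = fisher_exact_one_sided([[3, 0], [2, 4]])
        assert np.isinf(odds)
        assert 0 < p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_one_sided([[1, -2], [3, 4]])

    def test_matches_hypergeometric_enumeration_sweep(self):
        # every 2x2 table with all margins <= 12
        for a in range(13):
            for b in range(13 - a):
                for c in range(13 - a):
                    for d in range(13):
                        if a + b > 12 or c + d > 12 or a + c > 12 \
                                or b + d > 12:
                            continue
                        if a + b + c + d == 0:
                            continue
                        t = [[a, b], [c, d]]
                        _, p = fisher_exact_one_sided(t)
                        assert p == pytest.approx(
                            fisher_upper_tail(t), abs=1e-10
                        ), t


class TestCrossDatasetValidation:
    def test_identical_result_sets_are_maximally_concordant(self, rng):
        z = rng.normal(size=60) * 3
        fdr = rng.uniform(0, 1, 60)
        df = pd.DataFrame(
            {"z": z, "fdr_bh": fdr}, index=[f"L{i}" for i in range(60)]
        )
        res = cross_dataset_validation(df, df)
        assert res["pearson_r"] == pytest.approx(1.0)
        for direction in ("hazardous", "protective"):
            e = res[direction]
            a, b = e.table[0]
            c, d = e.table[1]
            assert b == 0 and c == 0       # no disagreement possible

    def test_independent_screens_have_near_zero_correlation(self, rng):
        n = 500
        mk = lambda: pd.DataFrame(
            {"z": rng.normal(size=n), "fdr_bh": rng.uniform(0, 1, n)},
            index=[f"L{i}" for i in range(n)],
        )
        res = cross_dataset_validation(mk(), mk())
        assert abs(res["pearson_r"]) < 3 / np.sqrt(n)

    def test_concordant_simulation_enriches_both_directions(self, rng):
        # two noisy z-score readouts of the same true effects
        n = 400
        true = np.concatenate([np.full(80, 4.0), np.full(80, -4.0),
                               np.zeros(240)])
        idx = [f"L{i}" for i in range(n)]

        def screen():
            z = true + rng.normal(size=n)
            p = 2 * __import__("scipy.stats", fromlist=["norm"]).norm.sf(
                np.abs(z))
            from lncsurv import adjust_pvalues
            return pd.DataFrame(
                {"z": z, "fdr_bh": adjust_pvalues(np.clip(p, 1e-300, 1))},
                index=idx,
            )

        res = cross_dataset_validation(screen(), screen())
        assert res["hazardous"].odds_ratio > 1
        assert res["protective"].odds_ratio > 1
        assert res["pearson_r"] > 0.8

    def test_empty_overlap_rejected(self):
        a = pd.DataFrame({"z": [1.0], "fdr_bh": [0.5]}, index=["A"])
        b = pd.DataFrame({"z": [1.0], "fdr_bh": [0.5]}, index=["B"])
        with pytest.raises(ValueError):
            cross_dataset_validation(a, b)


class TestEssentialityEnrichment:
    @staticmethod
    def _screen(essential, universe, noise=False, rng=None):
        rows = []
        for g in universe:
            if g in essential:
                rows.append({"gene": g, "avg_phenotype_score": -1.0,
                             "p": 0.01})
            else:
                rows.append({"gene": g, "avg_phenotype_score": 0.1,
                             "p": 0.9})
        return pd.DataFrame(rows)

    def test_perfect_overlap_gives_maximal_or(self):
        universe = [f"L{i}" for i in range(40)]
        haz = set(universe[:10])
        prot = set(universe[10:20])
        screen = self._screen(haz, universe)
        res = essentiality_enrichment(haz, prot, screen)
        assert np.isinf(res["hazardous"].odds_ratio)
        assert res["hazardous"].p < 1e-6
        assert res["protective"].odds_ratio < 1

    def test_random_essential_set_centres_at_unity(self, rng):
        universe = [f"L{i}" for i in range(200)]
        haz = set(universe[:40])
        prot = set(universe[40:80])
        log_ors = []
        for _ in range(50):
            ess = set(rng.choice(universe, size=50, replace=False))
            screen = self._screen(ess, universe)
            r = essentiality_enrichment(haz, prot, screen)["hazardous"]
            if np.isfinite(r.log2_or):
                log_ors.append(r.log2_or)
        assert abs(np.mean(log_ors)) < 0.3

    def test_empty_screen_rejected(self):
        with pytest.raises(ValueError):
            essentiality_enrichment({"a"}, {"b"},
                                    pd.DataFrame(columns=["gene",
                                                          "avg_phenotype_score",
                                                          "p"]))


def seg_frame(rows):
    return pd.DataFrame(
        rows, columns=["patient", "chrom", "start", "end", "signal", "call"]
    )


class TestGeneCnaSignal:
    def test_unweighted_mean_of_overlapping_segments(self):
        prof = seg_frame([
            ("P", "chr1", 0, 100, 0.4, 1),
            ("P", "chr1", 100, 200, 0.0, 0),
        ])
        iv = GeneInterval("G", "chr1", 50, 150)
        assert gene_cna_signal(iv, prof) == pytest.approx(0.2)

    def test_fully_containing_segment(self):
        prof = seg_frame([("P", "chr1", 0, 1000, -0.3, -1)])
        iv = GeneInterval("G", "chr1", 10, 20)
        assert gene_cna_signal(iv, prof) == pytest.approx(-0.3)

    def test_three_segment_straddle_matches_interval_oracle(self, rng):
        segs = [("P", "chr2", i * 100, (i + 1) * 100,
                 float(rng.normal()), 0) for i in range(10)]
        prof = seg_frame(segs)
        iv = GeneInterval("G", "chr2", 150, 390)
        # independent literal intersection: half-open overlap > 0
        hits = [s for s in segs
                if iv.start < s[3] and s[2] < iv.end]
        expected = np.mean([s[4] for s in hits])
        assert len(hits) == 3
        assert gene_cna_signal(iv, prof) == pytest.approx(expected)

    def test_splitting_equal_signal_segment_changes_nothing(self):
        whole = seg_frame([("P", "chr1", 0, 200, 0.5, 1)])
        split = seg_frame([("P", "chr1", 0, 100, 0.5, 1),
                           ("P", "chr1", 100, 200, 0.5, 1)])
        iv = GeneInterval("G", "chr1", 20, 180)
        assert gene_cna_signal(iv, whole) == gene_cna_signal(iv, split)

    def test_unknown_chromosome_gives_nan(self):
        prof = seg_frame([("P", "chr1", 0, 100, 0.1, 0)])
        with pytest.warns(UserWarning):
            out = gene_cna_signal(GeneInterval("G", "chrX", 0, 10), prof)
        assert np.isnan(out)

    def test_no_overlap_gives_nan(self):
        prof = seg_frame([("P", "chr1", 0, 100, 0.1, 0)])
        assert np.isnan(gene_cna_signal(GeneInterval("G", "chr1", 500, 600),
                                        prof))


class TestPatientCnaEnrichment:
    @staticmethod
    def _setup(rng, n_haz=12, n_prot=12, amp_haz=10, amp_prot=2):
        genes = [f"L{i}" for i in range(n_haz + n_prot)]
        haz, prot = set(genes[:n_haz]), set(genes[n_haz:])
        intervals = pd.DataFrame(
            [{"gene": g, "chrom": "chr1", "start": i * 1000,
              "end": i * 1000 + 500, "strand": "+"}
             for i, g in enumerate(genes)]
        )
        rows = []
        amped = set(list(haz)[:amp_haz]) | set(list(prot)[:amp_prot])
        for i, g in enumerate(genes):
            call = 1 if g in amped else 0
            rows.append(("P1", "chr1", i * 1000, i * 1000 + 1000,
                         0.5 if call else 0.0, call))
        return haz, prot, intervals, {"P1": seg_frame(rows)}

    def test_concordant_amplification_enriched(self, rng):
        haz, prot, intervals, profiles = self._setup(rng)
        res = patient_cna_enrichment(haz, prot, intervals, profiles,
                                     "amplification", min_cell=2)
        r = res["P1"]
        assert r.tested
        assert r.odds_ratio > 1
        assert r.log2_or > 0

    def test_min_cell_rule_skips_patient(self, rng):
        haz, prot, intervals, profiles = self._setup(rng, amp_prot=4)
        res = patient_cna_enrichment(haz, prot, intervals, profiles,
                                     "amplification", min_cell=5)
        # cell c (amplified protective) has 4 counts -> not tested, no FDR
        assert not res["P1"].tested
        assert res["P1"].fdr_bh is None

    def test_direction_and_set_swap_symmetry(self, rng):
        haz, prot, intervals, profiles = self._setup(rng)
        # flip every call so deletions mirror the amplification pattern
        flipped = {
            p: df.assign(call=-df["call"], signal=-df["signal"])
            for p, df in profiles.items()
        }
        amp = patient_cna_enrichment(haz, prot, intervals, profiles,
                                     "amplification", min_cell=2)["P1"]
        dele = patient_cna_enrichment(prot, haz, intervals, flipped,
                                      "deletion", min_cell=2)["P1"]
        assert amp.odds_ratio == pytest.approx(dele.odds_ratio)
        assert amp.p == pytest.approx(dele.p)

    def test_empty_prognostic_sets_rejected(self, rng):
        _, _, intervals, profiles = self._setup(rng)
        with pytest.raises(ValueError):
            patient_cna_enrichment(set(), {"L1"}, intervals, profiles)


class TestTopVariableSelection:
    def test_constant_rows_rank_last(self, rng):
        mat = pd.DataFrame(
            np.vstack([rng.normal(size=(3, 10)), np.ones((2, 10))]),
            index=["a", "b", "c", "flat1", "flat2"],
        )
        top = select_top_variable(mat, k=3)
        assert "flat1" not in top.index and "flat2" not in top.index

    def test_k_equal_to_rows_is_identity_up_to_order(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 8)),
                           index=[f"g{i}" for i in range(6)])
        top = select_top_variable(mat, k=6)
        assert set(top.index) == set(mat.index)

    def test_matches_naive_variance_sort(self, rng):
        mat = pd.DataFrame(rng.normal(size=(1000, 15)),
                           index=[f"g{i:04d}" for i in range(1000)])
        top = select_top_variable(mat, k=100)
        naive = mat.var(axis=1, ddof=1).sort_values(ascending=False)
        assert set(top.index) == set(naive.index[:100])

    def test_oversized_k_warns_and_keeps_all(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 5)))
        with pytest.warns(UserWarning):
            top = select_top_variable(mat, k=10)
        assert len(top) == 4


class TestClusterRows:
    def test_duplicate_rows_merge_first_at_zero_distance(self, rng):
        base = rng.normal(size=(4, 10))
        mat = pd.DataFrame(
            np.vstack([base, base[0]]),
            index=["a", "b", "c", "d", "a_copy"],
        )
        Z, order = cluster_rows(mat)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_planted_blocks_split_at_top_bipartition(self, rng):
        block1 = rng.normal(size=(5, 20)) + 0
        block2 = rng.normal(size=(5, 20))
        sig = np.sign(rng.normal(size=20)) * 5
        mat = pd.DataFrame(
            np.vstack([block1 + sig, block2 - sig]),
            index=[f"g{i}" for i in range(10)],
        )
        from scipy.cluster.hierarchy import fcluster

        Z, order = cluster_rows(mat)
        labels = fcluster(Z, t=2, criterion="maxclust")
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_merge_sequence_matches_brute_force_agglomeration(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 7)),
                           index=[f"g{i}" for i in range(5)])
        vals = mat.to_numpy()
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
            axis=1, keepdims=True
        )
        expected = complete_linkage_brute(z)
        Z, _ = cluster_rows(mat)
        for step, (ca, cb, dist) in enumerate(expected):
            assert Z[step, 2] == pytest.approx(dist, rel=1e-9)

    def test_row_permutation_invariance_up_to_relabeling(self, rng):
        mat = pd.DataFrame(rng.normal(size=(6, 9)),
                           index=[f"g{i}" for i in range(6)])
        Z1, order1 = cluster_rows(mat)
        perm = rng.permutation(6)
        Z2, order2 = cluster_rows(mat.iloc[perm])
        np.testing.assert_allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]),
                                   rtol=1e-9)

    def test_zero_variance_rows_excluded_with_warning(self, rng):
        mat = pd.DataFrame(
            np.vstack([rng.normal(size=(3, 8)), np.zeros((1, 8))]),
            index=["a", "b", "c", "flat"],
        )
        with pytest.warns(UserWarning):
            Z, order = cluster_rows(mat)
        assert "flat" not in order
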