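"""Windowed F_ST / LSBL / pi / pi-ratio / outlier calling against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_gm, two_pop_map
from sweepscan import sweep
from sweepscan.datamodel import GeneAnnotation, MISSING, OutlierSet, WindowSet


class TestMakeWindows:
    def test_100kb_chromosome_gives_three_windows(self):
        ws = sweep.make_windows({"chr1": 100_000})
        assert list(zip(ws.start.tolist(), ws.end.tolist())) == [
            (0, 50_000),
            (25_000, 75_000),
            (50_000, 100_000),
        ]

    def test_short_chromosome_single_window(self):
        ws = sweep.make_windows({"chr1": 40_000})
        assert list(zip(ws.start.tolist(), ws.end.tolist())) == [(0, 40_000)]

    def test_1mb_window_count_matches_enumeration(self):
        ws = sweep.make_windows({"chr1": 1_000_000})
        assert len(ws) == 39  # floor((L - size)/step) + 1, no redundant tail

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            sweep.make_windows({"chr1": 100_000}, size=10_000, step=20_000)

    @pytest.mark.parametrize("length", [1, 25_000, 60_001, 123_456, 2_000_000])
    def test_windows_cover_every_position(self, length):
        ws = sweep.make_windows({"c": length})
        covered = np.zeros(length, dtype=bool)
        for s, e in zip(ws.start, ws.end):
            covered[s:e] = True
        assert covered.all()


class TestSiteFst:
    def test_fixed_difference_theta_one(self):
        gm = make_gm([[0] * 5 + [2] * 5])
        comp = sweep.site_fst(gm, two_pop_map(gm, 5), "P1", "P2")
        assert comp.theta()[0] == pytest.approx(1.0)

    def test_identical_populations_nonpositive_theta(self):
        gm = make_gm([[0, 1, 2, 0, 1, 2]])
        comp = sweep.site_fst(gm, two_pop_map(gm, 3), "P1", "P2")
        assert comp.a[0] <= 0 and comp.theta()[0] <= 0

    def test_worked_table_matches_longhand(self):
        # popA: 6 x 0/0, 4 x 0/1 ; popB: 2 x 0/0, 8 x 1/1
        row = [0] * 6 + [1] * 4 + [0] * 2 + [2] * 8
        gm = make_gm([row])
        comp = sweep.site_fst(gm, two_pop_map(gm, 10), "P1", "P2")
        a, b, c = oracles.wc_fst_components_longhand(row[:10], row[10:])
        assert comp.a[0] == pytest.approx(a, abs=1e-12)
        assert comp.b[0] == pytest.approx(b, abs=1e-12)
        assert comp.c[0] == pytest.approx(c, abs=1e-12)

    def test_random_tables_match_longhand(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            nA, nB = rng.integers(2, 12, size=2)
            row = rng.integers(0, 3, size=nA + nB).tolist()
            if len(set(row)) == 1:
                row[0] = (row[0] + 1) % 3
            gm = make_gm([row], samples=[f"s{i}" for i in range(nA + nB)])
            comp = sweep.site_fst(gm, two_pop_map(gm, int(nA)), "P1", "P2")
            a, b, c = oracles.wc_fst_components_longhand(row[:nA], row[nA:])
            np.testing.assert_allclose([comp.a[0], comp.b[0], comp.c[0]], [a, b, c],
                                       atol=1e-10)

    def test_missing_genotypes_pairwise_dropped(self):
        row = [0, MISSING, 1, 1, 2, 2, MISSING, 2]
        gm = make_gm([row])
        comp = sweep.site_fst(gm, two_pop_map(gm, 4), "P1", "P2")
        a, b, c = oracles.wc_fst_components_longhand(row[:4], row[4:])
        np.testing.assert_allclose([comp.a[0], comp.b[0], comp.c[0]], [a, b, c],
                                   atol=1e-12)

    def test_underpowered_site_flagged_missing(self):
        row = [0, MISSING, MISSING, MISSING, 2, 2, 2, 2]
        gm = make_gm([row])
        comp = sweep.site_fst(gm, two_pop_map(gm, 4), "P1", "P2")
        assert np.isnan(comp.a[0])

    def test_unknown_population_rejected(self):
        gm = make_gm([[0, 1, 2, 1]])
        with pytest.raises(KeyError):
            sweep.site_fst(gm, two_pop_map(gm, 2), "P1", "nope")


class TestWindowedFst:
    def test_single_site_window_equals_theta(self):
        gm = make_gm([[0, 0, 1, 2]], pos=[10])
        pm = two_pop_map(gm, 2)
        comp = sweep.site_fst(gm, pm, "P1", "P2")
        ws = sweep.make_windows({"chr1": 1000}, size=1000, step=1000)
        stats = sweep.windowed_fst(comp, ws, min_snps=1)
        assert stats.value[0] == pytest.approx(comp.theta()[0])

    def test_all_fixed_difference_window_is_one(self):
        gm = make_gm([[0, 0, 2, 2]] * 5, pos=[10, 20, 30, 40, 50])
        comp = sweep.site_fst(gm, two_pop_map(gm, 2), "P1", "P2")
        ws = sweep.make_windows({"chr1": 100}, size=100, step=100)
        assert sweep.windowed_fst(comp, ws, min_snps=1).value[0] == pytest.approx(1.0)

    def test_ratio_of_averages_matches_oracle(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 3, size=(3, 12)).tolist()
        gm = make_gm(rows, pos=[5, 15, 25], samples=[f"s{i}" for i in range(12)])
        pm = two_pop_map(gm, 6)
        comp = sweep.site_fst(gm, pm, "P1", "P2")
        ws = sweep.make_windows({"chr1": 30}, size=30, step=30)
        got = sweep.windowed_fst(comp, ws, min_snps=1).value[0]
        parts = [oracles.wc_fst_components_longhand(r[:6], r[6:]) for r in rows]
        want = sum(p[0] for p in parts) / sum(sum(p) for p in parts)
        assert got == pytest.approx(want, abs=1e-12)

    def test_min_snps_gate(self):
        gm = make_gm([[0, 0, 1, 2]], pos=[10])
        comp = sweep.site_fst(gm, two_pop_map(gm, 2), "P1", "P2")
        ws = sweep.make_windows({"chr1": 1000}, size=1000, step=1000)
        assert np.isnan(sweep.windowed_fst(comp, ws, min_snps=5).value[0])


def _stats(values, ws=None, name="x"):
    values = np.asarray(values, dtype=float)
    if ws is None:
        n = len(values)
        ws = WindowSet(
            chrom=np.array(["chr1"] * n, dtype=object),
            start=np.arange(n) * 100,
            end=np.arange(n) * 100 + 100,
            size=100,
            step=100,
        )
    return sweep.WindowStats(ws, np.full(len(values), 10), values, name)


class TestLsbl:
    def test_worked_triple(self):
        la = sweep.lsbl(_stats([0.5]), _stats([0.3]), _stats([0.2]), "A")
        assert la.value[0] == pytest.approx(0.3)

    def test_symmetric_inputs_halve(self):
        la = sweep.lsbl(_stats([0.4]), _stats([0.4]), _stats([0.4]), "A")
        assert la.value[0] == pytest.approx(0.2)

    @given(
        st.lists(
            st.tuples(*[st.floats(-0.05, 1.0) for _ in range(3)]),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_branch_additivity_identity(self, triples):
        ab, ac, bc = (np.array(x) for x in zip(*triples))
        la = sweep.lsbl(_stats(ab), _stats(ac), _stats(bc), "A")
        lb = sweep.lsbl(_stats(ab), _stats(ac), _stats(bc), "B")
        np.testing.assert_allclose(la.value + lb.value, ab, atol=1e-15)

    def test_misaligned_windows_rejected(self):
        a = _stats([0.5, 0.4])
        ws2 = WindowSet(
            chrom=np.array(["chr2"] * 2, dtype=object),
            start=np.array([0, 100]),
            end=np.array([100, 200]),
            size=100,
            step=100,
        )
        with pytest.raises(ValueError, match="misaligned"):
            sweep.lsbl(a, _stats([0.3, 0.3], ws2), _stats([0.2, 0.2]), "A")

    def test_missing_input_propagates(self):
        la = sweep.lsbl(_stats([np.nan]), _stats([0.3]), _stats([0.2]), "A")
        assert np.isnan(la.value[0])


class TestWindowedPi:
    def test_two_haplotypes_three_diffs_per_kb(self):
        # one diploid sample = 2 haplotypes; 3 heterozygous sites in 1000 bp
        gm = make_gm([[1]] * 3, pos=[100, 200, 300], samples=["s0"])
        pm = two_pop_map(gm, 1)
        ws = sweep.make_windows({"chr1": 1000}, size=1000, step=1000)
        pi = sweep.windowed_pi(gm, pm, "P1", ws, min_snps=1)
        assert pi.value[0] == pytest.approx(0.003)

    def test_monomorphic_window_zero(self):
        gm = make_gm([[0, 0], [2, 2]], pos=[10, 20])
        pm = two_pop_map(gm, 2)
        ws = sweep.make_windows({"chr1": 100}, size=100, step=100)
        assert sweep.windowed_pi(gm, pm, "P1", ws, min_snps=1).value[0] == 0.0

    def test_site_pi_equals_enumerated_pairwise_mean(self):
        """pi per site equals the mean over all haplotype pairs, for every
        genotype table with up to 6 haplotypes (3 diploids)."""
        import itertools

        for table in itertools.product([0, 1, 2], repeat=3):
            gm = make_gm([list(table)], samples=["a", "b", "c"])
            pm = two_pop_map(gm, 3)
            ws = sweep.make_windows({"chr1": 1}, size=1, step=1)
            got = sweep.windowed_pi(gm, pm, "P1", ws, min_snps=1).value[0]
            haps = [al for g in table for al in ([0, 0], [0, 1], [1, 1])[g]]
            assert got == pytest.approx(oracles.pi_site_enumerated(haps))

    def test_allele_count_2_2_identity(self):
        gm = make_gm([[1, 1]], samples=["a", "b"])
        pm = two_pop_map(gm, 2)
        ws = sweep.make_windows({"chr1": 1}, size=1, step=1)
        assert sweep.windowed_pi(gm, pm, "P1", ws, min_snps=1).value[0] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("n_h", [4, 20, 200])
    def test_unbiased_at_known_frequency(self, n_h):
        """Mean per-site pi approaches 2p(1-p) as haplotypes accumulate."""
        rng = np.random.default_rng(n_h)
        p = 0.3
        n_sites = 2_000
        haps = (rng.random((n_sites, n_h)) < p).astype(np.int8)
        geno = haps[:, 0::2] + haps[:, 1::2]
        gm = make_gm(geno, pos=np.arange(1, n_sites + 1),
                     samples=[f"s{i}" for i in range(n_h // 2)])
        pm = two_pop_map(gm, n_h // 2)
        ws = sweep.make_windows({"chr1": n_sites}, size=n_sites, step=n_sites)
        pi = sweep.windowed_pi(gm, pm, "P1", ws, min_snps=1)
        mean_site_pi = pi.value[0]  # 1 site per bp, so per-bp pi = mean site pi
        se = np.sqrt(2 * p * (1 - p) / n_sites)  # loose Monte-Carlo bound
        assert mean_site_pi == pytest.approx(2 * p * (1 - p), abs=5 * se)


class TestPiRatio:
    def test_direct_ratio(self):
        r = sweep.pi_ratio(_stats([0.004]), _stats([0.001]))
        assert r.value[0] == pytest.approx(4.0)

    def test_floor_guard_yields_missing_not_inf(self):
        r = sweep.pi_ratio(_stats([0.004]), _stats([1e-9]), min_pi=1e-5)
        assert np.isnan(r.value[0])

    def test_neutral_median_near_one(self, neutral_sim):
        gm, pm = neutral_sim.gm, neutral_sim.popmap
        ws = sweep.make_windows({"chr1": neutral_sim.config.chrom_length})
        pf = sweep.windowed_pi(gm, pm, pm.focal, ws)
        pc = sweep.windowed_pi(gm, pm, pm.contrast, ws)
        med = np.nanmedian(sweep.pi_ratio(pc, pf).value)
        assert 0.8 <= med <= 1.25


class TestCallOutliers:
    def test_thousand_distinct_windows_give_ten(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(1000) / 1000.0
        out = sweep.call_outliers(_stats(vals), q=0.99)
        assert len(out) == 10
        assert set(out.windows["value"]) == set(np.sort(vals)[-10:])

    def test_all_equal_values_all_selected_with_warning(self):
        with pytest.warns(UserWarning):
            out = sweep.call_outliers(_stats([0.5] * 20), q=0.99)
        assert len(out) == 20

    def test_matches_sort_slice_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=200)
        vals[rng.choice(200, 15, replace=False)] = np.nan
        with pytest.warns(UserWarning):
            out = sweep.call_outliers(_stats(vals), q=0.99)
        thr, members = oracles.quantile_outliers_sortslice(vals, 0.99)
        assert out.threshold_value == pytest.approx(thr)
        got = set(out.windows["start"] // 100)
        assert got == set(members)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            sweep.call_outliers(_stats([np.nan, np.nan]))


class TestAnnotateAndOverlap:
    def _outliers(self, windows):
        df = pd.DataFrame(windows, columns=["chrom", "start", "end"])
        df["n_snps"] = 10
        df["value"] = 1.0
        return OutlierSet("x", 0.5, df)

    def test_one_bp_overlap_included(self):
        genes = GeneAnnotation([("chr1", 100, 200, "gA")])
        out = sweep.annotate_windows(self._outliers([("chr1", 150, 50_150)]), genes)
        assert out.genes == ("gA",)

    def test_adjacent_gene_excluded(self):
        genes = GeneAnnotation([("chr1", 60_000, 70_000, "gB")])
        out = sweep.annotate_windows(self._outliers([("chr1", 0, 50_000)]), genes)
        assert out.genes == ()

    def test_toy_layout_matches_bruteforce(self):
        genes = [
            ("chr1", 0, 5_000, "g1"),
            ("chr1", 30_000, 55_000, "g2"),
            ("chr1", 80_000, 90_000, "g3"),
            ("chr2", 10_000, 20_000, "g4"),
            ("chr2", 100_000, 110_000, "g5"),
        ]
        windows = [("chr1", 25_000, 75_000), ("chr2", 0, 50_000), ("chr2", 50_000, 100_000)]
        out = sweep.annotate_windows(self._outliers(windows), GeneAnnotation(genes))
        assert set(out.genes) == oracles.overlap_bruteforce(windows, genes)

    def test_gene_set_intersection(self):
        res = sweep.overlap_genes({"a", "b", "c"}, {"b", "c", "d"})
        assert res["shared"] == ["b", "c"]
        assert res["only_a"] == ["a"] and res["only_b"] == ["d"]

    def test_disjoint_sets_empty_shared(self):
        assert sweep.overlap_genes({"a"}, {"b"})["shared"] == []
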