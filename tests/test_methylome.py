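"""Methylome pipeline: coverage filter, HMR segmentation, recurrence scan
against a brute-force window oracle, DMR testing, selection and enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from icepipe import methylome as me
from icepipe.errors import ValidationError
from icepipe.intervals import GenomicInterval
from icepipe.io import MethylomeSample
from icepipe.simulate import SimulationConfig, simulate_methylomes


def sample_from(rows, sample_id="s1"):
    return MethylomeSample(
        sample_id, pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    )


def brute_force_recurrence(hmrs_by_sample, n_samples, window=100, min_fraction=0.05,
                           focal_max=10_000):
    """Window-by-window oracle: enumerate every window explicitly."""
    focal = {
        s: [h for h in hs if h.interval.length <= focal_max]
        for s, hs in hmrs_by_sample.items()
    }
    chroms = sorted({h.interval.chrom for hs in focal.values() for h in hs})
    out = []
    for chrom in chroms:
        max_end = max(
            h.interval.end for hs in focal.values() for h in hs if h.interval.chrom == chrom
        )
        qualifying = []
        for w in range(0, (max_end // window) + 1):
            win = GenomicInterval(chrom, w * window, (w + 1) * window)
            n = sum(
                1
                for hs in focal.values()
                if any(h.interval.overlaps(win) for h in hs)
            )
            qualifying.append(n / n_samples >= min_fraction - 1e-12)
        w = 0
        while w < len(qualifying):
            if not qualifying[w]:
                w += 1
                continue
            w2 = w
            while w2 + 1 < len(qualifying) and qualifying[w2 + 1]:
                w2 += 1
            region = GenomicInterval(chrom, w * window, (w2 + 1) * window)
            n_overlap = sum(
                1
                for hs in focal.values()
                if any(h.interval.overlaps(region) for h in hs)
            )
            out.append(me.RecurrentHmr(region, n_overlap / n_samples))
            w = w2 + 1
    return sorted(out, key=lambda r: (r.interval.chrom, r.interval.start))


class TestCoverageFilter:
    def test_boundary_of_five_reads(self):
        s = sample_from([("chr1", 100, 3, 2), ("chr1", 200, 2, 2), ("chr1", 300, 0, 5)])
        out = me.filter_coverage(s, min_reads=5)
        assert list(out.records["pos"]) == [100, 300]

    def test_empty_sample(self):
        out = me.filter_coverage(sample_from([]))
        assert len(out) == 0


class TestHmrCalling:
    def make(self, betas_by_pos):
        rows = [("chr1", pos, int(round(b * 20)), 20 - int(round(b * 20)))
                for pos, b in betas_by_pos]
        return sample_from(rows)

    def test_low_run_flanked_by_high(self):
        pts = [(100 + 50 * i, 0.05) for i in range(10)]
        s = self.make([(50, 0.9)] + pts + [(700, 0.9)])
        (h,) = me.call_hmrs_simple(s)
        assert h.n_cpg == 10
        assert h.interval == GenomicInterval("chr1", 99, 550)
        assert h.mean_beta == pytest.approx(0.05, abs=0.02)

    def test_short_runs_rejected(self):
        s = self.make([(100, 0.1), (150, 0.1), (200, 0.9)])
        assert me.call_hmrs_simple(s) == []

    def test_gap_splits_runs(self):
        left = [(100 + 50 * i, 0.1) for i in range(4)]
        right = [(max(p for p, _ in left) + 600 + 50 * i, 0.1) for i in range(4)]
        s = self.make(left + right)
        hmrs = me.call_hmrs_simple(s)
        assert len(hmrs) == 2

    def test_zero_coverage_cpg_is_not_low(self):
        rows = [("chr1", 100 + 50 * i, 1, 9) for i in range(4)]
        rows[1] = ("chr1", 150, 0, 0)  # uncovered: breaks the run
        assert me.call_hmrs_simple(sample_from(rows)) == []


class TestRecurrenceScan:
    def hmr(self, sample, start, end, chrom="chr1"):
        return me.Hmr(sample, GenomicInterval(chrom, start, end), 5, 0.1)

    def test_exactly_five_percent_qualifies(self):
        hmrs = {f"s{i}": [] for i in range(20)}
        hmrs["s0"] = [self.hmr("s0", 1000, 1400)]
        out = me.recurrence_scan(hmrs, n_samples=20)
        assert len(out) == 1
        assert out[0].interval == GenomicInterval("chr1", 1000, 1400)
        assert out[0].sample_fraction == pytest.approx(0.05)

    def test_oversized_hmr_discarded(self):
        hmrs = {"s0": [self.hmr("s0", 0, 12_000)], "s1": []}
        assert me.recurrence_scan(hmrs, n_samples=2) == []

    def test_staggered_hmrs_merge(self):
        hmrs = {f"s{i}": [] for i in range(20)}
        hmrs["s0"] = [self.hmr("s0", 1000, 1300)]
        hmrs["s1"] = [self.hmr("s1", 1200, 1500)]
        out = me.recurrence_scan(hmrs, n_samples=20)
        assert len(out) == 1
        assert out[0].interval == GenomicInterval("chr1", 1000, 1500)
        assert out[0].sample_fraction == pytest.approx(0.10)
        assert out == brute_force_recurrence(hmrs, 20)

    def test_zero_samples_is_error(self):
        with pytest.raises(ValidationError):
            me.recurrence_scan({}, n_samples=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        hmrs = {}
        for i in range(15):
            hs = []
            for _ in range(rng.integers(0, 12)):
                chrom = "chr1" if rng.random() < 0.7 else "chr2"
                start = int(rng.integers(0, 30_000))
                length = int(rng.integers(50, 15_000))  # some exceed focal_max
                hs.append(self.hmr(f"s{i}", start, start + length, chrom))
            hmrs[f"s{i}"] = hs
        got = me.recurrence_scan(hmrs, n_samples=15, min_fraction=0.2)
        want = brute_force_recurrence(hmrs, 15, min_fraction=0.2)
        assert [(r.interval, pytest.approx(r.sample_fraction)) for r in got] == [
            (r.interval, r.sample_fraction) for r in want
        ]

    def test_fractions_at_least_threshold_and_regions_disjoint_sorted(self):
        sim = simulate_methylomes(SimulationConfig(
            seed=41, n_case_meth=10, n_control_meth=10, n_genes=100, n_segments=100,
            chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000},
            n_background_regions=50, n_recurrent_hmr=30, n_diff_regions=30,
            n_private_hmr=40,
        ))
        filt = [me.filter_coverage(s) for s in sim.case_samples + sim.control_samples]
        hmrs = {s.sample_id: me.call_hmrs_simple(s) for s in filt}
        out = me.recurrence_scan(hmrs)
        assert all(r.sample_fraction >= 0.05 - 1e-12 for r in out)
        for r1, r2 in zip(out, out[1:]):
            if r1.interval.chrom == r2.interval.chrom:
                assert r1.interval.end <= r2.interval.start


class TestContextClassification:
    iv = GenomicInterval("chr1", 1000, 1200)

    def test_promoter_wins_over_enhancer(self):
        group, ctx = me.classify_hmr_context(
            self.iv, [GenomicInterval("chr1", 1100, 1300)],
            [GenomicInterval("chr1", 900, 1100)], [], [], [], [],
        )
        assert group == "promoter" and ctx == "open_sea"

    def test_enhancer_only(self):
        group, _ = me.classify_hmr_context(
            self.iv, [], [GenomicInterval("chr1", 900, 1100)], [], [], [], [],
        )
        assert group == "enhancer"

    def test_nothing_overlaps(self):
        assert me.classify_hmr_context(self.iv, [], [], [], [], [], []) == ("none", "open_sea")

    def test_cgi_precedence_and_bed_order_independence(self, rng):
        islands = [GenomicInterval("chr1", 1150, 1250)]
        shores = [GenomicInterval("chr1", 950, 1150), GenomicInterval("chr1", 1250, 1450)]
        for _ in range(3):
            perm_shores = [shores[i] for i in rng.permutation(2)]
            _, ctx = me.classify_hmr_context(self.iv, [], [], [], islands, perm_shores, [])
            assert ctx == "island"


class TestRegionMatrix:
    def test_coverage_weighted_pooling(self):
        s = sample_from([("chr1", 101, 5, 5), ("chr1", 151, 10, 0)])
        mat, kept = me.region_methylation_matrix([GenomicInterval("chr1", 100, 200)], [s])
        assert mat.loc["chr1:100-200", "s1"] == pytest.approx(0.75)

    def test_missing_when_no_covered_cpg(self):
        s1 = sample_from([("chr1", 101, 5, 5)], "a")
        s2 = sample_from([("chr2", 101, 5, 5)], "b")
        mat, kept = me.region_methylation_matrix([GenomicInterval("chr1", 100, 200)], [s1, s2])
        assert np.isnan(mat.loc["chr1:100-200", "b"])

    def test_region_without_cpgs_dropped_with_warning(self):
        s = sample_from([("chr1", 101, 5, 5)])
        with pytest.warns(UserWarning, match="dropped"):
            mat, kept = me.region_methylation_matrix(
                [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 5000, 5100)], [s]
            )
        assert list(mat.index) == ["chr1:100-200"]
        assert kept == [GenomicInterval("chr1", 100, 200)]

    def test_equals_brute_force_read_pooling(self, rng):
        regions = [GenomicInterval("chr1", 100 * i, 100 * i + 80) for i in range(20)]
        samples = []
        for j in range(5):
            rows = []
            for pos in sorted(rng.choice(2000, size=300, replace=False)):
                m, u = int(rng.integers(0, 20)), int(rng.integers(0, 20))
                rows.append(("chr1", pos + 1, m, u))
            samples.append(sample_from(rows, f"s{j}"))
        mat, _ = me.region_methylation_matrix(regions, samples)
        for j, s in enumerate(samples):
            for iv in regions:
                sub = s.records[(s.records.pos - 1 >= iv.start) & (s.records.pos - 1 < iv.end)]
                cov = (sub.meth + sub.unmeth).sum()
                want = sub.meth.sum() / cov if cov else np.nan
                got = mat.loc[me.region_id(iv), s.sample_id]
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)


class TestDmrTest:
    def make_matrix(self, case, ctrl):
        case_ids = [f"c{i}" for i in range(case.shape[1])]
        ctrl_ids = [f"n{i}" for i in range(ctrl.shape[1])]
        mat = pd.DataFrame(
            np.hstack([case, ctrl]), columns=case_ids + ctrl_ids,
            index=[f"chr1:{i}-{i+1}" for i in range(case.shape[0])],
        )
        return mat, case_ids, ctrl_ids

    def test_matches_scipy_reference(self, rng):
        case = rng.uniform(0.2, 0.9, size=(50, 12))
        ctrl = rng.uniform(0.2, 0.9, size=(50, 10))
        mat, ci, ni = self.make_matrix(case, ctrl)
        out = me.dmr_test(mat, ci, ni)
        for k in range(50):
            t, p = ttest_ind(case[k], ctrl[k], equal_var=True)
            assert out["t_statistic"].iloc[k] == pytest.approx(t, abs=1e-8)
            assert out["p"].iloc[k] == pytest.approx(p, abs=1e-8)
        order = out["p"].rank(method="first")
        qs = out.sort_values("p")["q"].to_numpy()
        assert (np.diff(qs) >= -1e-12).all()  # BH monotone in p rank

    def test_welch_variant_matches_scipy(self, rng):
        case = rng.uniform(0.2, 0.9, size=(20, 8))
        ctrl = rng.uniform(0.2, 0.9, size=(20, 14))
        mat, ci, ni = self.make_matrix(case, ctrl)
        out = me.dmr_test(mat, ci, ni, equal_var=False)
        for k in range(20):
            t, p = ttest_ind(case[k], ctrl[k], equal_var=False)
            assert out["t_statistic"].iloc[k] == pytest.approx(t, abs=1e-8)
            assert out["p"].iloc[k] == pytest.approx(p, abs=1e-8)

    def test_degenerate_constant_rows_excluded(self):
        case = np.full((2, 5), 0.5)
        ctrl = np.full((2, 5), 0.5)
        mat, ci, ni = self.make_matrix(case, ctrl)
        out = me.dmr_test(mat, ci, ni)
        assert out["excluded"].all()
        assert not out["is_dmr"].any()

    def test_planted_shift_recovered(self, rng):
        """delta = -0.2 at sd 0.05, n = 48 vs 45: detected with tight delta."""
        n_regions = 60
        case = np.clip(rng.normal(0.65, 0.05, size=(n_regions, 48)), 0, 1)
        ctrl = np.clip(rng.normal(0.85, 0.05, size=(n_regions, 45)), 0, 1)
        null = np.clip(rng.normal(0.85, 0.05, size=(40, 48 + 45)), 0, 1)
        mat, ci, ni = self.make_matrix(
            np.vstack([case, null[:, :48]]), np.vstack([ctrl, null[:, 48:]])
        )
        out = me.dmr_test(mat, ci, ni)
        planted = out.iloc[:n_regions]
        assert planted["is_dmr"].all()
        assert planted["delta"].mean() == pytest.approx(-0.2, abs=0.03)
        assert (planted["direction"] == "hypo").all()

    def test_null_false_positive_rate(self, rng):
        null = np.clip(rng.normal(0.8, 0.05, size=(400, 30)), 0, 1)
        mat, ci, ni = self.make_matrix(null[:, :15], null[:, 15:])
        out = me.dmr_test(mat, ci, ni)
        frac = out["is_dmr"].mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)


class TestHypoFractionAndSelection:
    def test_hypo_fraction_arithmetic(self):
        df = pd.DataFrame({"direction": ["hypo", "hypo", "hyper"], "is_dmr": [True] * 3})
        assert me.hypo_fraction(df) == pytest.approx(2 / 3)
        all_neg = pd.DataFrame({"direction": ["hypo"] * 4, "is_dmr": [True] * 4})
        assert me.hypo_fraction(all_neg) == 1.0
        with pytest.raises(ValidationError):
            me.hypo_fraction(pd.DataFrame({"direction": [], "is_dmr": []}))

    @pytest.mark.parametrize(
        "fraction, delta, kept",
        [
            (0.12, -0.15, True),
            (0.12, -0.05, False),
            (0.08, -0.30, False),
            (0.10, -0.15, False),  # strict > on recurrence
        ],
    )
    def test_selection_thresholds(self, fraction, delta, kept):
        iv = GenomicInterval("chr1", 0, 500)
        region = me.RecurrentHmr(iv, fraction)
        out = me.select_recurrent_differential([region], {me.region_id(iv): delta})
        assert bool(out) is kept


class TestGeneMapping:
    parts = [
        (GenomicInterval("chr2", 95_692_000, 95_693_000), "MAL", "promoter"),
        (GenomicInterval("chr2", 95_693_000, 95_694_000), "MAL", "exon"),
        (GenomicInterval("chr2", 95_694_000, 95_695_000), "OTHER", "exon"),
    ]

    def test_promoter_hit_maps_to_gene(self):
        dmrs = [GenomicInterval("chr2", 95_692_705, 95_692_728)]
        assert me.map_dmrs_to_genes(dmrs, self.parts) == ["MAL"]

    def test_intergenic_dmr_maps_nowhere(self):
        assert me.map_dmrs_to_genes([GenomicInterval("chr2", 10, 20)], self.parts) == []

    def test_overlapping_genes_both_reported_once(self):
        dmrs = [
            GenomicInterval("chr2", 95_693_500, 95_694_500),
            GenomicInterval("chr2", 95_693_600, 95_693_700),
        ]
        assert me.map_dmrs_to_genes(dmrs, self.parts) == ["MAL", "OTHER"]


class TestEnrichment:
    def test_hypergeometric_worked_example(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"setA": universe[:5]}
        query = universe[1:5] + [universe[10]]
        out = me.geneset_enrichment(query, sets, universe)
        assert out["overlap"].iloc[0] == 4
        assert out["p"].iloc[0] == pytest.approx(76 / 15504)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = me.geneset_enrichment(universe[10:12], {"s": universe[:5]}, universe)
        assert out["p"].iloc[0] == 1.0

    def test_bh_worked_example(self):
        from statsmodels.stats.multitest import multipletests

        qs = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert qs == pytest.approx([0.03, 0.03, 0.03])

    def test_empty_universe_is_error(self):
        with pytest.raises(ValidationError):
            me.geneset_enrichment(["a"], {"s": ["a"]}, [])


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", range(20))
    def test_planted_dmrs_recovered_across_seeds(self, seed):
        """Sensitivity >= 0.9 and hypo fraction near the planted 0.9 on the
        full pipeline (HMR calling -> recurrence -> matrix -> t-test)."""
        cfg = SimulationConfig(
            seed=300 + seed, n_genes=100, n_segments=100,
            chrom_lengths={"chr1": 1_200_000, "chr2": 1_200_000},
            n_background_regions=80, n_recurrent_hmr=20, n_diff_regions=40,
            n_private_hmr=40,
        )
        sim = simulate_methylomes(cfg)
        filt = [me.filter_coverage(s) for s in sim.case_samples + sim.control_samples]
        hmrs = {s.sample_id: me.call_hmrs_simple(s) for s in filt}
        recurrent = me.recurrence_scan(hmrs)
        mat, kept = me.region_methylation_matrix(recurrent, filt)
        out = me.dmr_test(
            mat,
            [s.sample_id for s in sim.case_samples],
            [s.sample_id for s in sim.control_samples],
        )
        dmr_ivs = [kept[i] for i in np.flatnonzero(out["is_dmr"].to_numpy())]
        detected = 0
        for row in sim.truth_diff.itertuples():
            iv = GenomicInterval(row.chrom, row.start, row.end)
            detected += any(d.overlaps(iv) for d in dmr_ivs)
        assert detected >= 0.9 * len(sim.truth_diff)
        assert me.hypo_fraction(out) == pytest.approx(
            (sim.truth_diff["direction"] == "hypo").mean(), abs=0.08
        )
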