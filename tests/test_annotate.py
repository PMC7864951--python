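import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spermage.annotate import (
    AnnotationTrack,
    annotate_features,
    assign_nearest_gene,
    direction_summary,
    export_gene_list,
    fisher_enrichment,
    spearman_locus,
)
from spermage.regions import MethylRegion

from .conftest import make_dataset


def region(rid, chrom, start, end):
    return MethylRegion(rid, chrom, ("pA", "pB"), start, end)


def track(name, tuples):
    return AnnotationTrack(name, pd.DataFrame(tuples, columns=["chrom", "start", "end"]))


class TestAnnotateFeatures:
    def test_boundary_overlap_and_halfopen_abutment(self):
        # region spans 1-based positions 101..200 -> half-open [100, 200)
        r = region("r1", "chr1", 101, 200)
        overlap = track("t1", [("chr1", 199, 300)])   # 1 bp overlap
        abut = track("t2", [("chr1", 200, 300)])      # touches, no overlap
        mem = annotate_features([r], [overlap, abut])
        assert bool(mem.loc["r1", "t1"]) is True
        assert bool(mem.loc["r1", "t2"]) is False

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(0)
        regions = []
        for i in range(200):
            s = int(rng.integers(0, 100_000))
            regions.append(region(f"r{i}", "chr1", s + 1, s + int(rng.integers(1, 500))))
        ivs = []
        for _ in range(500):
            s = int(rng.integers(0, 100_000))
            ivs.append(("chr1", s, s + int(rng.integers(1, 400))))
        tr = track("t", ivs)
        mem = annotate_features(regions, [tr])["t"]
        for r in regions:
            s, e = r.start - 1, r.end
            want = any(s < te and ts < e for _, ts, te in ivs)
            assert bool(mem[r.region_id]) == want

    def test_chromosome_mismatch_raises(self):
        r = region("r1", "chrX", 101, 200)
        with pytest.raises(ValueError, match="chrX"):
            annotate_features([r], [track("t", [("chr1", 0, 10)])])

    def test_partition_counts_sum(self):
        """Mutually exclusive, exhaustive context tracks cover every region."""
        rng = np.random.default_rng(1)
        cuts = np.sort(rng.choice(np.arange(100, 50_000), 9, replace=False))
        bounds = [0, *cuts.tolist(), 60_000]
        names = [f"ctx{i}" for i in range(10)]
        tracks = [track(nm, [("chr1", a, b)]) for nm, (a, b) in
                  zip(names, zip(bounds[:-1], bounds[1:]))]
        regions = []
        for i in range(100):
            s = int(rng.integers(1, 59_000))
            regions.append(region(f"r{i}", "chr1", s + 1, s + 2))  # 2-bp regions
        mem = annotate_features(regions, tracks)
        counts = mem.sum(axis=1)
        # a tiny region can straddle one boundary, never more
        assert ((counts >= 1) & (counts <= 2)).all()
        assert mem.to_numpy().sum() == sum(counts)


class TestAssignNearestGene:
    def _tss(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss_pos"])

    def test_within_window_and_beyond(self):
        r = region("r1", "chr1", 1000, 1200)
        near = self._tss([("G1", "chr1", "+", 900)])
        far = self._tss([("G1", "chr1", "+", 2801)])  # 1601 bp from the end
        assert assign_nearest_gene([r], near).loc["r1", "gene_id"] == "G1"
        assert assign_nearest_gene([r], far).loc["r1", "gene_id"] is None

    def test_tss_inside_region_distance_zero(self):
        r = region("r1", "chr1", 1000, 1200)
        out = assign_nearest_gene([r], self._tss([("G1", "chr1", "-", 1100)]))
        assert out.loc["r1", "distance"] == 0

    def test_equidistant_tie_breaks_lexicographically(self):
        r = region("r1", "chr1", 1000, 1200)
        tss = self._tss([("GB", "chr1", "+", 500), ("GA", "chr1", "+", 1700)])
        out = assign_nearest_gene([r], tss)
        assert out.loc["r1", "gene_id"] == "GA"
        assert out.loc["r1", "ambiguous"] == "GA;GB"

    def test_malformed_rows_skipped_with_count(self):
        r = region("r1", "chr1", 1000, 1200)
        tss = self._tss([("G1", "chr1", "+", 900), (None, "chr1", "+", 950),
                         ("G2", "chr1", "+", np.nan)])
        out = assign_nearest_gene([r], tss)
        assert out.attrs["n_skipped_tss"] == 2
        assert out.loc["r1", "gene_id"] == "G1"


def _enumeration_two_sided_fisher(table):
    """Exhaustive hypergeometric oracle for the two-sided Fisher p."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = stats.hypergeom.pmf(x, n, r1, c1)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherEnrichment:
    def _inputs(self, a, b, c, d):
        n = a + b + c + d
        idx = [f"r{i}" for i in range(n)]
        member = [True] * a + [False] * b + [True] * c + [False] * d
        dmr = [True] * (a + b) + [False] * (c + d)
        membership = pd.DataFrame({"f": member}, index=idx)
        return pd.Series(dmr, index=idx), membership

    @pytest.mark.parametrize("table", [(1, 9, 11, 3), (5, 5, 50, 50), (0, 10, 10, 0),
                                       (3, 0, 2, 7), (8, 2, 1, 9)])
    def test_matches_enumeration_oracle(self, table):
        dmr, mem = self._inputs(*table)
        res = fisher_enrichment(dmr, mem, "f")
        expect = _enumeration_two_sided_fisher(np.array(table).reshape(2, 2))
        assert res.p == pytest.approx(expect, rel=1e-9)

    def test_known_value_and_no_association(self):
        dmr, mem = self._inputs(1, 9, 11, 3)
        assert fisher_enrichment(dmr, mem, "f").p == pytest.approx(0.00276, abs=5e-5)
        dmr, mem = self._inputs(5, 5, 50, 50)
        res = fisher_enrichment(dmr, mem, "f")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_all_margin30_tables_match_oracle(self):
        """Every 2x2 table with all margins <= 30 (subsampled grid)."""
        rng = np.random.default_rng(2)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, 4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            if a + b == 0:
                continue
            dmr, mem = self._inputs(int(a), int(b), int(c), int(d))
            res = fisher_enrichment(dmr, mem, "f")
            expect = _enumeration_two_sided_fisher(np.array([[a, b], [c, d]]))
            assert res.p == pytest.approx(expect, rel=1e-8, abs=1e-12)

    def test_direction_label_matches_or(self):
        for table in [(8, 2, 2, 8), (2, 8, 8, 2)]:
            dmr, mem = self._inputs(*table)
            res = fisher_enrichment(dmr, mem, "f")
            assert (res.direction == "enriched") == (res.odds_ratio > 1)

    def test_empty_dmr_set_raises(self):
        dmr, mem = self._inputs(0, 0, 5, 5)
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(dmr, mem, "f")

    def test_swap_invariance(self):
        """Swapping both rows and both columns leaves p unchanged."""
        dmr, mem = self._inputs(7, 3, 4, 9)
        p1 = fisher_enrichment(dmr, mem, "f").p
        dmr2, mem2 = self._inputs(9, 4, 3, 7)  # rows and columns swapped
        p2 = fisher_enrichment(dmr2, mem2, "f").p
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestDirectionSummary:
    def _dmr_table(self, dirs):
        return pd.DataFrame({"region_id": [f"r{i}" for i in range(len(dirs))],
                             "direction": dirs})

    def test_percentages_and_empty_feature(self):
        tab = self._dmr_table(["hyper", "hyper", "hyper", "hypo"])
        mem = pd.DataFrame({"f1": [True] * 4, "f2": [False] * 4},
                           index=[f"r{i}" for i in range(4)])
        out = direction_summary(tab, mem)
        assert out.loc["f1", "pct_hyper"] == pytest.approx(75.0)
        assert np.isnan(out.loc["f2", "pct_hyper"])
        assert out.loc["f2", "n_dmrs"] == 0

    def test_configured_hyper_fraction_recovered(self):
        rng = np.random.default_rng(3)
        n = 500
        dirs = np.where(rng.random(n) < 0.88, "hyper", "hypo")
        tab = self._dmr_table(list(dirs))
        mem = pd.DataFrame({"open_sea": [True] * n}, index=tab["region_id"])
        out = direction_summary(tab, mem)
        assert out.loc["open_sea", "pct_hyper"] == pytest.approx(88.0, abs=5.0)


class TestSpearmanLocus:
    def test_perfect_monotone(self):
        n = 20
        age = np.linspace(25, 45, n)
        beta = np.tile(np.linspace(0.2, 0.8, n), (2, 1))
        ds = make_dataset(beta, subject_ids=[f"s{i}" for i in range(n)])
        rho, _ = spearman_locus(ds, ["cg00000"], age)
        assert rho == pytest.approx(1.0)
        rho2, _ = spearman_locus(ds, ["cg00001"], age[::-1])
        assert rho2 == pytest.approx(-1.0)

    def test_tied_data_matches_rank_oracle(self):
        rng = np.random.default_rng(4)
        vals = np.round(rng.uniform(0.2, 0.4, 20), 2)  # forces ties
        age = np.round(rng.uniform(25, 45, 20), 0)
        ds = make_dataset(vals[None, :], subject_ids=[f"s{i}" for i in range(20)])
        rho, _ = spearman_locus(ds, ["cg00000"], age)
        rv = stats.rankdata(vals)
        ra = stats.rankdata(age)
        expect = np.corrcoef(rv, ra)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_raises(self):
        ds = make_dataset(np.full((1, 10), 0.3))
        with pytest.raises(ValueError):
            spearman_locus(ds, ["cg00000"], np.arange(10.0))


class TestExportGeneList:
    def _map(self):
        return pd.DataFrame({"gene_id": ["G2", "G1", "G2", None]},
                            index=["r1", "r2", "r3", "r4"])

    def test_dedup_sorted(self, tmp_path):
        genes = export_gene_list(self._map(), ["r1", "r2", "r3"], tmp_path / "g.txt")
        assert genes == ["G1", "G2"]
        lines = (tmp_path / "g.txt").read_text().splitlines()
        assert lines == ["gene_id", "G1", "G2"]

    def test_empty_subset_writes_header(self, tmp_path):
        genes = export_gene_list(self._map(), [], tmp_path / "g.txt")
        assert genes == []
        assert (tmp_path / "g.txt").read_text() == "gene_id\n"

    def test_all_assigned_equals_distinct(self):
        m = self._map()
        genes = export_gene_list(m, list(m.index))
        assert len(genes) == m["gene_id"].dropna().nunique()
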