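import numpy as np
import pandas as pd
import pytest

from conftest import make_calls
from evcirc.catalog import (
    INTERGENIC,
    ComparisonStats,
    abundance_bins,
    assign_host_gene,
    call_bona_fide,
    circs_per_gene,
    comparison_stats,
)
from evcirc.io import InputError, read_bed_calls, read_ciri_calls, write_bed_calls, write_ciri_calls
from evcirc.simulate import SimConfig, simulate_counts, simulate_detector_calls


def brute_force_consensus(calls_a, calls_b, min_reads=2):
    """Oracle: plain set intersection then the per-pool support filter."""
    key = lambda df: {
        (r.contig, r.start, r.end, r.strand): max(
            getattr(r, c) for c in df.columns if c not in ("contig", "start", "end", "strand")
        )
        for r in df.itertuples()
    }
    a, b = key(calls_a), key(calls_b)
    return {k for k in set(a) & set(b) if b[k] >= min_reads}


class TestCallBonaFide:
    def test_empty_inputs(self):
        empty = pd.DataFrame(columns=["contig", "start", "end", "strand", "p1"])
        assert len(call_bona_fide(empty, empty)) == 0

    def test_support_filter(self):
        # junction only in A is dropped even at 50 reads; a shared junction
        # with one pool at the 2-read floor is kept
        a = make_calls(
            [("chr1", 100, 150, "+"), ("chr1", 200, 300, "+")], [(50, 0), (2, 0)]
        )
        b = make_calls([("chr1", 200, 300, "+")], [(2, 0)])
        cat = call_bona_fide(a, b)
        assert list(cat.index) == ["chr1:201-300"]

    def test_per_pool_reading_excludes_spread_support(self):
        # twelve pools of a single read each: total 12 but max per pool 1
        a = make_calls([("chr1", 10, 90, "+")], [tuple([1] * 12)])
        b = make_calls([("chr1", 10, 90, "+")], [tuple([1] * 12)])
        assert len(call_bona_fide(a, b)) == 0

    def test_counts_come_from_quantifying_detector(self):
        a = make_calls([("chr1", 10, 90, "+")], [(99, 99)])
        b = make_calls([("chr1", 10, 90, "+")], [(3, 1)])
        cat = call_bona_fide(a, b)
        assert cat.loc["chr1:11-90", ["p1", "p2"]].tolist() == [3, 1]

    def test_strand_is_part_of_junction_identity(self):
        a = make_calls([("chr1", 10, 90, "+")], [(5,)])
        b = make_calls([("chr1", 10, 90, "-")], [(5,)])
        assert len(call_bona_fide(a, b)) == 0

    def test_duplicate_keys_rejected(self):
        a = make_calls([("chr1", 10, 90, "+"), ("chr1", 10, 90, "+")], [(5,), (6,)])
        with pytest.raises(InputError):
            call_bona_fide(a, a)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(0, 15))
            junctions = [
                (f"chr{rng.integers(1, 3)}", int(s), int(s) + int(rng.integers(50, 200)),
                 "+" if rng.random() < 0.5 else "-")
                for s in rng.integers(0, 500, size=n)
            ]
            junctions = list(dict.fromkeys(junctions))
            counts = rng.integers(0, 4, size=(len(junctions), 3))
            calls = make_calls(junctions, [tuple(c) for c in counts])
            mask_a = rng.random(len(junctions)) < 0.7
            mask_b = rng.random(len(junctions)) < 0.7
            a, b = calls.loc[mask_a], calls.loc[mask_b]
            cat = call_bona_fide(a, b)
            got = {(r.contig, r.start, r.end, r.strand) for r in cat.itertuples()}
            assert got == brute_force_consensus(a, b)

    def test_min_reads_monotonicity(self):
        rng = np.random.default_rng(13)
        junctions = [("chr1", int(s), int(s) + 100, "+") for s in range(0, 2000, 150)]
        counts = rng.integers(0, 10, size=(len(junctions), 4))
        calls = make_calls(junctions, [tuple(c) for c in counts])
        sizes = [len(call_bona_fide(calls, calls, min_reads=m)) for m in range(1, 8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_consensus_recall_matches_independent_miss_rates(self, small_sim):
        cfg, circ_counts, _, truth = small_sim
        cfg2 = cfg.replace(detector_miss_rate_a=0.2, detector_miss_rate_b=0.3, n_circ=600)
        cc, _, tr = simulate_counts(cfg2)
        a, b = simulate_detector_calls(tr, cc, cfg2)
        cat = call_bona_fide(a, b)
        eligible = (cc.max(axis=1) >= 2).sum()
        recall = len(cat) / eligible
        # expected (1-0.2)(1-0.3) = 0.56 within binomial error
        se = np.sqrt(0.56 * 0.44 / eligible)
        assert abs(recall - 0.56) < 4 * se


class TestHostGenes:
    genes = pd.DataFrame(
        [
            {"gene_id": "G1", "gene_name": "BIG", "biotype": "protein_coding",
             "contig": "chr1", "start": 0, "end": 10_000, "strand": "+"},
            {"gene_id": "G2", "gene_name": "NESTED", "biotype": "protein_coding",
             "contig": "chr1", "start": 1_000, "end": 3_000, "strand": "+"},
            {"gene_id": "G3", "gene_name": "MINUS", "biotype": "protein_coding",
             "contig": "chr1", "start": 0, "end": 10_000, "strand": "-"},
        ]
    )

    def _cat(self, start, end, strand):
        return pd.DataFrame(
            {"contig": ["chr1"], "start": [start], "end": [end], "strand": [strand],
             "host_gene": [INTERGENIC]},
            index=[f"chr1:{start + 1}-{end}"],
        )

    def test_contained_same_strand(self):
        out = assign_host_gene(self._cat(4_000, 5_000, "+"), self.genes)
        assert out["host_gene"].iloc[0] == "BIG"

    def test_no_overlap_is_intergenic(self):
        out = assign_host_gene(self._cat(20_000, 21_000, "+"), self.genes)
        assert out["host_gene"].iloc[0] == INTERGENIC

    def test_nested_genes_larger_reciprocal_overlap_wins(self):
        out = assign_host_gene(self._cat(1_200, 2_800, "+"), self.genes)
        assert out["host_gene"].iloc[0] == "NESTED"

    def test_strand_required(self):
        out = assign_host_gene(self._cat(4_000, 5_000, "-"), self.genes)
        assert out["host_gene"].iloc[0] == "MINUS"

    def test_planted_multiplicity_recovered(self):
        cfg = SimConfig(n_circ=80, n_genes=120, seed=4, planted_multi_circ=31,
                        detector_miss_rate_a=0.0, detector_miss_rate_b=0.0,
                        frac_intergenic=0.0, nb_mean_log_range=(1.5, 2.5))
        cc, _, truth = simulate_counts(cfg)
        a, b = simulate_detector_calls(truth, cc, cfg)
        cat = call_bona_fide(a, b)
        genes = truth.attrs["genes"]
        cat = assign_host_gene(cat, genes)
        per_gene, _ = circs_per_gene(cat)
        # the planted gene carries 31 circRNAs in truth; every one has
        # detectable counts at this expression floor
        assert per_gene.max() == 31
        truth_hosts = truth.loc[cat.index, "host_gene"]
        assert (cat["host_gene"] == truth_hosts).all()


class TestCircsPerGene:
    def test_all_distinct(self):
        cat = pd.DataFrame({"host_gene": ["A", "B", "C"]})
        _, fracs = circs_per_gene(cat)
        assert fracs["1"] == 100.0

    def test_hand_counted_fractions(self):
        hosts = ["g%d" % i for i in range(10)] + ["h1"] * 3 + ["h2"] * 3 + ["h3"] * 3 + \
                ["h4"] * 3 + ["h5"] * 3 + ["big"] * 12
        cat = pd.DataFrame({"host_gene": hosts})
        _, fracs = circs_per_gene(cat)
        assert fracs["1"] == pytest.approx(62.5)
        assert fracs["2-10"] == pytest.approx(31.25)
        assert fracs[">10"] == pytest.approx(6.25)

    def test_intergenic_excluded(self):
        cat = pd.DataFrame({"host_gene": ["A", INTERGENIC, INTERGENIC]})
        per_gene, fracs = circs_per_gene(cat)
        assert len(per_gene) == 1 and fracs["1"] == 100.0


class TestAbundanceBins:
    def test_all_zero(self):
        assert abundance_bins(pd.DataFrame({"p1": [0, 0]}))["[0,10)"] == 100.0

    def test_bin_edges_closed_below(self):
        fr = abundance_bins(pd.DataFrame({"p1": [500.0]}))
        assert fr[">=500"] == 100.0

    def test_hand_counts(self):
        fr = abundance_bins(pd.DataFrame({"p1": [5, 10, 49, 50, 499, 500]}))
        assert fr.tolist() == pytest.approx([100 / 6, 200 / 6, 200 / 6, 100 / 6])


class TestComparisonStats:
    meta = pd.DataFrame(
        {"status": ["A", "A", "B", "B"], "sex": ["M", "F", "M", "F"]},
        index=["a1", "a2", "b1", "b2"],
    )

    def test_identical_detection_all_shared(self):
        counts = pd.DataFrame(
            {"a1": [3, 1], "a2": [0, 2], "b1": [1, 1], "b2": [0, 5]}, index=["t1", "t2"]
        )
        s = comparison_stats(counts, self.meta, "A", "B")
        assert (s.n_exclusive_a, s.n_exclusive_b, s.n_shared) == (0, 0, 2)
        assert s.pct_shared == 100.0

    def test_partition_and_percentages(self):
        counts = pd.DataFrame(
            {"a1": [3, 0, 0, 0], "a2": [0, 0, 0, 0], "b1": [0, 1, 0, 2], "b2": [0, 0, 0, 0]},
            index=["onlyA", "onlyB", "neither", "shared"],
        )
        counts.loc["shared", "a1"] = 1
        s = comparison_stats(counts, self.meta, "A", "B")
        assert (s.n_exclusive_a, s.n_exclusive_b, s.n_shared) == (1, 1, 1)
        assert s.pct_exclusive_a + s.pct_exclusive_b + s.pct_shared == pytest.approx(100.0)
        assert "neither" not in s.exclusive_a_ids + s.exclusive_b_ids + s.shared_ids

    def test_invariant_to_pool_order_and_swap(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 3, size=(30, 4)), columns=self.meta.index,
            index=[f"t{i}" for i in range(30)],
        )
        s = comparison_stats(counts, self.meta, "A", "B")
        shuffled = counts[["b2", "a1", "b1", "a2"]]
        s2 = comparison_stats(shuffled, self.meta, "A", "B")
        assert s.to_dict() == s2.to_dict()
        assert comparison_stats(counts, self.meta, "B", "A").to_dict() == s.swapped().to_dict()

    def test_group_without_pools_rejected(self):
        counts = pd.DataFrame({"a1": [1], "a2": [1], "b1": [1], "b2": [1]}, index=["t"])
        with pytest.raises(InputError):
            comparison_stats(counts, self.meta, "A", "C")

    @pytest.mark.parametrize(
        "na,nb,shared,expect",
        [
            (1731, 1413, 2942, {"pct_exclusive_a": 28.4, "pct_exclusive_b": 23.2}),
            (658, 2734, 1939, {"pct_shared": 36.4}),
            (1364, 7629, 6481, {"pct_exclusive_a": 8.8, "pct_exclusive_b": 49.3}),
        ],
    )
    def test_percentage_arithmetic(self, na, nb, shared, expect):
        s = ComparisonStats("X", "Y", na, nb, shared)
        for key, val in expect.items():
            assert round(getattr(s, key), 1) == val


class TestCallTableRoundtrips:
    def test_bed_and_ciri_coordinate_normalization(self, tmp_path):
        calls = make_calls([("chr2", 99, 250, "-")], [(4, 1)])
        write_bed_calls(calls, tmp_path / "a.bed")
        write_ciri_calls(calls, tmp_path / "b.tsv")
        a = read_bed_calls(tmp_path / "a.bed", ["p1", "p2"])
        b = read_ciri_calls(tmp_path / "b.tsv")
        # both conventions normalize to the same 0-based half-open key
        for df in (a, b):
            assert df.loc[0, ["contig", "start", "end", "strand"]].tolist() == ["chr2", 99, 250, "-"]
            assert df.loc[0, ["p1", "p2"]].tolist() == [4, 1]
        # raw files differ: BED start 99, CIRI2 start 100
        assert "\t99\t" in (tmp_path / "a.bed").read_text()
        assert "\t100\t" in (tmp_path / "b.tsv").read_text()
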