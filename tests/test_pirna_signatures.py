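import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from pirnadev import pirna_signatures as sig
from pirnadev import smallrna_io as sio
from pirnadev import synthetic_data as syn
from pirnadev.smallrna_io import AlignmentHit, SmallRnaRead


def hit(read_id, region="chr", start=0, strand="+", mm=0, n_hits=1, length=23):
    return AlignmentHit(read_id, region, start, strand, mm, n_hits, length)


def read(read_id, seq=None, count=1, length=23):
    return SmallRnaRead(read_id, seq if seq is not None else "A" * length, count)


class TestWeightedCoverage:
    def test_single_unique_hit(self):
        reads = {"r": read("r", count=2)}
        cov = sig.weighted_coverage([hit("r", start=10)], reads, {"chr": 100})
        assert (cov["chr"][10:33] == 2.0).all()
        assert cov["chr"].sum() == pytest.approx(2.0 * 23)

    def test_antisense_negative(self):
        reads = {"r": read("r")}
        cov = sig.weighted_coverage([hit("r", strand="-")], reads, {"chr": 100})
        assert (cov["chr"][:23] == -1.0).all()

    def test_multihit_division(self):
        reads = {"r": read("r", count=4)}
        hits = [hit("r", start=0, n_hits=2), hit("r", start=50, n_hits=2)]
        cov = sig.weighted_coverage(hits, reads, {"chr": 100})
        assert cov["chr"][0] == 2.0 and cov["chr"][50] == 2.0

    def test_norm_factor_scales(self):
        reads = {"r": read("r")}
        cov = sig.weighted_coverage([hit("r")], reads, {"chr": 100}, norm_factor=0.5)
        assert cov["chr"][0] == 0.5

    def test_out_of_bounds_hit_rejected(self):
        reads = {"r": read("r")}
        with pytest.raises(ValueError, match="bounds"):
            sig.weighted_coverage([hit("r", start=90)], reads, {"chr": 100})

    def test_unknown_region_rejected(self):
        with pytest.raises(KeyError):
            sig.weighted_coverage([hit("r", region="nope")], {"r": read("r")}, {"chr": 100})

    def test_per_read_weight_conservation(self, aligned_library, toy_genome):
        reads, hits = aligned_library["reads"], aligned_library["hits"]
        factor = 0.8
        totals = {rid: 0.0 for rid in reads}
        for h in hits:
            totals[h.read_id] += reads[h.read_id].count * factor / h.n_hits_region_set
        for rid, total in totals.items():
            assert total == pytest.approx(reads[rid].count * factor)
        # and per-strand coverage integrates to the same grand total
        lengths = {n: len(s) for n, s in toy_genome.items()}
        for strand in "+-":
            sub = [h for h in hits if h.strand == strand]
            cov = sig.weighted_coverage(sub, reads, lengths, factor)
            integral = sum(np.abs(t).sum() for t in cov.values())
            expected = sum(
                reads[h.read_id].count * factor / h.n_hits_region_set * h.length
                for h in sub
            )
            assert integral == pytest.approx(expected)


class TestSizeDistribution:
    def test_single_length_sense_only(self):
        reads = {"r": read("r", length=26)}
        table = sig.size_distribution([hit("r", length=26)], reads, "chr")
        assert table.loc[26, "+"] == 1.0
        assert table.drop(index=26).to_numpy().sum() == 0

    def test_empty_hits_all_zero(self):
        table = sig.size_distribution([], {}, "chr")
        assert (table.to_numpy() == 0).all()

    def test_out_of_range_lengths_excluded(self):
        reads = {"r": SmallRnaRead("r", "A" * 19)}
        table = sig.size_distribution([hit("r", length=19)], reads, "chr", (20, 29))
        assert table.to_numpy().sum() == 0

    def test_recovers_simulated_mode(self, small_cluster):
        spec = syn.PiRnaLibrarySpec(
            n_reads=3000, size_dist={24: 0.2, 25: 0.6, 26: 0.2}, seed=31
        )
        records, _ = syn.simulate_library(small_cluster, spec)
        inserts = [sio.trim_adapter(r.sequence, spec.adapter).insert for r in records]
        reads = sio.collapse_reads(inserts)
        hits = sio.match_reads(reads, small_cluster, 0)
        table = sig.size_distribution(hits, {r.read_id: r for r in reads}, "cluster")
        assert table.sum(axis=1).idxmax() == 25

    def test_strand_swap_transposes(self):
        reads = {"a": read("a", length=24), "b": read("b", length=25)}
        hits = [hit("a", strand="+", length=24), hit("b", strand="-", length=25)]
        flipped = [
            AlignmentHit(h.read_id, h.region, h.start, "-" if h.strand == "+" else "+",
                         h.mismatches, h.n_hits_region_set, h.length)
            for h in hits
        ]
        t1 = sig.size_distribution(hits, reads, "chr")
        t2 = sig.size_distribution(flipped, reads, "chr")
        pd.testing.assert_series_equal(t1["+"], t2["-"], check_names=False)
        pd.testing.assert_series_equal(t1["-"], t2["+"], check_names=False)


class TestU1Bias:
    def test_all_t_start(self):
        reads = {"r": read("r", seq="T" + "A" * 22)}
        assert sig.u1_bias([hit("r")], reads, "chr") == 1.0

    def test_even_split(self):
        reads = {
            "t": read("t", seq="T" + "A" * 22),
            "a": read("a", seq="A" * 23),
        }
        hits = [hit("t"), hit("a", start=40)]
        assert sig.u1_bias(hits, reads, "chr") == 0.5

    def test_empty_denominator_is_none(self):
        assert sig.u1_bias([], {}, "chr") is None

    def test_weighted_by_count(self):
        reads = {
            "t": read("t", seq="T" + "A" * 22, count=3),
            "a": read("a", seq="A" * 23, count=1),
        }
        hits = [hit("t"), hit("a", start=40)]
        assert sig.u1_bias(hits, reads, "chr") == pytest.approx(0.75)

    def test_recovers_simulated_bias(self, aligned_library):
        est = sig.u1_bias(aligned_library["hits"], aligned_library["reads"], "cluster")
        p = aligned_library["spec"].u1_bias
        n = (aligned_library["truth"].origin == "cluster").sum()
        assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestPingpongSignature:
    def test_single_pair_overlap_ten(self):
        reads = {"s": read("s"), "a": read("a", length=24)}
        hits = [
            hit("s", start=100, strand="+"),
            # antisense 5' end at start+length-1 = 109 -> overlap 10
            hit("a", start=86, strand="-", length=24),
        ]
        hist = sig.pingpong_signature(hits, reads, "chr")
        assert hist[9] == 1.0 and hist.sum() == 1.0

    def test_no_antisense_all_zero(self):
        reads = {"s": read("s")}
        assert sig.pingpong_signature([hit("s")], reads, "chr").sum() == 0

    def test_size_range_filter(self):
        reads = {"s": read("s", length=29), "a": read("a", length=24)}
        hits = [hit("s", start=100, length=29), hit("a", start=86, strand="-", length=24)]
        # 29-nt read outside the 23..28 window contributes nothing
        assert sig.pingpong_signature(hits, reads, "chr").sum() == 0

    def test_equals_bruteforce_pair_count(self, small_cluster):
        spec = syn.PiRnaLibrarySpec(n_reads=200, pingpong_fraction=0.5, seed=23)
        records, _ = syn.simulate_library(small_cluster, spec)
        inserts = [sio.trim_adapter(r.sequence, spec.adapter).insert for r in records]
        reads = sio.collapse_reads(inserts)
        rmap = {r.read_id: r for r in reads}
        hits = sio.match_reads(reads, small_cluster, 1)
        in_range = [h for h in hits if 23 <= h.length <= 28 and h.region == "cluster"]
        expected = oracles.pairwise_overlap_histogram(in_range, rmap)
        hist = sig.pingpong_signature(hits, rmap, "cluster")
        for o in range(1, 29):
            assert hist[o - 1] == pytest.approx(expected[o]), f"overlap {o}"

    def test_strand_swap_reflects_histogram_for_fixed_length(self):
        # relabeling strands maps a pair at overlap o to one at
        # L1 + L2 - o; with all reads the same length L the histogram is
        # reflected about L
        rng = np.random.default_rng(29)
        L = 24
        reads, hits = {}, []
        for i in range(120):
            rid = f"r{i}"
            reads[rid] = SmallRnaRead(rid, "A" * L)
            strand = "+" if i % 2 else "-"
            hits.append(hit(rid, start=int(rng.integers(0, 300)), strand=strand, length=L))
        flipped = [
            AlignmentHit(h.read_id, h.region, h.start,
                         "-" if h.strand == "+" else "+",
                         h.mismatches, h.n_hits_region_set, h.length)
            for h in hits
        ]
        h1 = sig.pingpong_signature(hits, reads, "chr")
        h2 = sig.pingpong_signature(flipped, reads, "chr")
        for o in range(1, 29):
            mirror = 2 * L - o
            if 1 <= mirror <= 28:
                assert h2[o - 1] == pytest.approx(h1[mirror - 1]), o


class TestPingpongZscore:
    def test_flat_histogram_zero(self):
        assert sig.pingpong_zscore(np.full(28, 5.0)) == 0.0

    def test_single_spike_degenerate(self):
        hist = np.zeros(28)
        hist[9] = 1.0
        assert sig.pingpong_zscore(hist) is None

    def test_spike_at_ten_positive(self):
        rng = np.random.default_rng(0)
        hist = rng.uniform(1, 2, 28)
        hist[9] = 50.0
        assert sig.pingpong_zscore(hist) > 3

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            sig.pingpong_zscore(np.zeros(10))


class TestTeRpkm:
    def test_unit_case(self):
        reads = {"r": read("r", count=10)}
        hits = [hit("r", region="te1", strand="-")]
        table = sig.te_antisense_rpkm(hits, reads, {"te1": 1000}, 1.0, 1_000_000)
        assert table.loc[0, "rpkm"] == pytest.approx(10.0)

    def test_zero_reads_zero_rpkm(self):
        table = sig.te_antisense_rpkm([], {}, {"te1": 1000}, 1.0, 1e6)
        assert table.loc[0, "rpkm"] == 0.0
        assert (table.rpkm == 0).equals(table.antisense_norm_count == 0)

    def test_sense_hits_ignored(self):
        reads = {"r": read("r")}
        table = sig.te_antisense_rpkm(
            [hit("r", region="te1", strand="+")], reads, {"te1": 1000}, 1.0, 1e6
        )
        assert table.loc[0, "rpkm"] == 0.0

    def test_doubling_length_halves_rpkm(self):
        rng = np.random.default_rng(3)
        reads = {f"r{i}": read(f"r{i}", count=int(c)) for i, c in
                 enumerate(rng.integers(1, 20, size=30))}
        hits = [hit(f"r{i}", region="te1", strand="-") for i in range(30)]
        t1 = sig.te_antisense_rpkm(hits, reads, {"te1": 500}, 0.7, 2e6)
        t2 = sig.te_antisense_rpkm(hits, reads, {"te1": 1000}, 0.7, 2e6)
        assert t1.loc[0, "rpkm"] == pytest.approx(2 * t2.loc[0, "rpkm"])

    def test_zero_length_te_rejected(self):
        with pytest.raises(ValueError):
            sig.te_antisense_rpkm([], {}, {"te1": 0}, 1.0, 1e6)


class TestGlkdScatter:
    def _table(self, counts):
        return pd.DataFrame(
            {
                "name": list(counts),
                "length": 1000,
                "antisense_norm_count": list(counts.values()),
                "rpkm": 0.0,
            }
        )

    def test_identity_gives_zero_ratio(self):
        t = self._table({"te1": 100, "te2": 5})
        out = sig.glkd_scatter(t, t)
        assert (out.log2_ratio_test_over_control == 0).all()

    def test_quarter_is_minus_two(self):
        control = self._table({"te1": 100_000})
        test = self._table({"te1": 25_000})
        out = sig.glkd_scatter(control, test)
        assert out.loc[0, "log2_ratio_test_over_control"] == pytest.approx(-2, abs=1e-3)

    def test_mismatched_te_sets_rejected_with_names(self):
        with pytest.raises(ValueError, match="te2"):
            sig.glkd_scatter(self._table({"te1": 1, "te2": 1}), self._table({"te1": 1}))

    def test_depleted_tes_rank_below_untouched(self, toy_genome):
        te_refs = syn.make_te_references(seed=2, n_te=6, length=600)
        germline = {f"TE_{i}" for i in range(3)}
        rng = np.random.default_rng(4)

        def sample_counts(depleted):
            counts = {}
            for name in te_refs:
                lam = 200 * (0.1 if depleted and name in germline else 1.0)
                counts[name] = float(rng.poisson(lam))
            return self._table(counts)

        out = sig.glkd_scatter(sample_counts(False), sample_counts(True))
        ranked = out.set_index("name").log2_ratio_test_over_control
        assert ranked[list(germline)].max() < ranked[
            [n for n in te_refs if n not in germline]
        ].min()

    def test_finite_with_zero_counts(self):
        control = self._table({"te1": 0})
        test = self._table({"te1": 0})
        out = sig.glkd_scatter(control, test, pseudocount=1.0)
        assert np.isfinite(out.to_numpy()[:, 1:].astype(float)).all()


class TestCoverageToBedgraph:
    def test_run_length_encoding(self):
        cov = {"chr": np.array([0.0, 1.0, 1.0, -2.0, 0.0])}
        df = sig.coverage_to_bedgraph(cov)
        rows = [tuple(r) for r in df.itertuples(index=False)]
        assert rows == [("chr", 1, 3, 1.0), ("chr", 3, 4, -2.0)]
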