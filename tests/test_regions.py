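import numpy as np
import pytest

from paracns.classify import ParalogPair
from paracns.regions import (
    CNSRecord,
    GeneModel,
    assign_cns,
    count_cns_for_genes,
    define_regions,
    kendall_tau_b,
    ratio_vs_cns_correlation,
)
from paracns.synthetic import neighbor_map
from oracles import containment_oracle, kendall_oracle


def plus_gene(s=5000, e=8000, **kw):
    return GeneModel(gene="g", chrom="chr1", strand="+", cds_start=s, cds_end=e, **kw)


class TestDefineRegions:
    def test_promoter_windows_plus_strand(self):
        rs = define_regions(plus_gene())
        assert rs["promoter_1500"] == ((3500, 4900),)
        assert rs["promoter_1000"] == ((4000, 4900),)
        assert rs["promoter_500"] == ((4500, 4900),)
        assert rs["utr5"] == ((4900, 5000),)
        assert rs["utr3"] == ((8000, 8200),)
        assert rs["downstream"] == ((8300, 9000),)

    def test_promoter_windows_minus_strand(self):
        g = GeneModel(gene="g", chrom="chr1", strand="-", cds_start=5000, cds_end=8000)
        rs = define_regions(g)
        assert rs["promoter_1500"] == ((8100, 9500),)
        assert rs["utr5"] == ((8000, 8100),)
        assert rs["utr3"] == ((4800, 5000),)
        assert rs["downstream"] == ((4000, 4700),)

    def test_neighbor_fully_occludes_promoter(self):
        left = GeneModel(gene="n", chrom="chr1", strand="+", cds_start=0, cds_end=4950)
        rs = define_regions(plus_gene(), neighbors=(left, None))
        assert rs["promoter_1500"] == ()

    def test_neighbor_shortens_promoter(self):
        left = GeneModel(gene="n", chrom="chr1", strand="+", cds_start=100, cds_end=4200)
        rs = define_regions(plus_gene(), neighbors=(left, None))
        assert rs["promoter_1500"] == ((4200, 4900),)

    def test_downstream_clipped_by_chromosome_end(self):
        rs = define_regions(plus_gene(), chrom_length=8500)
        assert rs["utr3"] == ((8000, 8200),)
        assert rs["downstream"] == ((8300, 8500),)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            define_regions(plus_gene(), windows=(750,))

    def test_introns_inside_cds(self):
        g = plus_gene(introns=((5500, 5700), (6200, 6300)))
        rs = define_regions(g)
        assert rs["introns"] == ((5500, 5700), (6200, 6300))


class TestAssignCns:
    def cns(self, s, e, chrom="chr1"):
        return CNSRecord(chrom=chrom, start=s, end=e)

    def test_full_containment_counts(self):
        rs = define_regions(plus_gene())
        out = assign_cns([self.cns(4000, 4050)], rs)
        assert out.counts["promoter_1500"] == 1
        assert out.base_sums["promoter_1500"] == 50
        assert out.counts["promoter_1000"] == 1
        assert out.counts["promoter_500"] == 0

    def test_straddling_cns_counts_for_neither(self):
        rs = define_regions(plus_gene())
        out = assign_cns([self.cns(4890, 4910)], rs)  # spans promoter | utr5 boundary
        assert out.counts["promoter_1500"] == 0
        assert out.counts["utr5"] == 0

    def test_zero_rule(self):
        rs = define_regions(plus_gene())
        out = assign_cns([], rs)
        assert all(v == 0 for v in out.counts.values())
        assert all(v == 0 for v in out.base_sums.values())

    def test_other_chromosome_ignored(self):
        rs = define_regions(plus_gene())
        out = assign_cns([self.cns(4000, 4050, chrom="chr9")], rs)
        assert out.counts["promoter_1500"] == 0

    def test_window_monotonicity_on_random_cns(self):
        rng = np.random.default_rng(2)
        rs = define_regions(plus_gene())
        cns = [self.cns(s, s + int(rng.integers(10, 80)))
               for s in rng.integers(3000, 9500, size=200)]
        out = assign_cns(cns, rs)
        assert out.counts["promoter_500"] <= out.counts["promoter_1000"]
        assert out.counts["promoter_1000"] <= out.counts["promoter_1500"]

    def test_matches_base_by_base_oracle_on_random_genes(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            s = int(rng.integers(2000, 6000))
            e = s + int(rng.integers(600, 4000))
            n_int = int(rng.integers(0, 3))
            introns = []
            pos = s + 50
            for _ in range(n_int):
                istart = pos + int(rng.integers(0, 100))
                iend = istart + int(rng.integers(20, 200))
                if iend < e - 50:
                    introns.append((istart, iend))
                    pos = iend
            gene = GeneModel(
                gene="g", chrom="chr1",
                strand="+" if rng.random() < 0.5 else "-",
                cds_start=s, cds_end=e, introns=tuple(introns),
            )
            rs = define_regions(gene)
            cns = [
                self.cns(int(p), int(p) + int(rng.integers(5, 90)))
                for p in rng.integers(max(0, s - 2500), e + 2500, size=60)
            ]
            out = assign_cns(cns, rs)
            oc, os_ = containment_oracle(cns, rs)
            assert dict(out.counts) == oc
            assert dict(out.base_sums) == os_


def test_batch_counts_equal_per_gene_assignment(small_bundle):
    neighbors = neighbor_map(small_bundle.annotation)
    track = small_bundle.cns_tracks[1]
    batch = count_cns_for_genes(
        small_bundle.annotation, track, neighbors, small_bundle.chrom_lengths
    )
    for gene in small_bundle.annotation[:40]:
        rs = define_regions(gene, neighbors[gene.gene],
                            chrom_length=small_bundle.chrom_lengths[gene.chrom])
        single = assign_cns(track, rs)
        assert dict(batch[gene.gene].counts) == dict(single.counts)
        assert dict(batch[gene.gene].base_sums) == dict(single.base_sums)


class TestKendallTauB:
    def test_perfect_concordance_and_discordance(self):
        assert kendall_tau_b([1, 2, 3], [1, 2, 3]).coefficient == pytest.approx(1.0)
        assert kendall_tau_b([1, 2, 3], [3, 2, 1]).coefficient == pytest.approx(-1.0)

    def test_tied_example(self):
        res = kendall_tau_b([1, 2, 2, 3], [1, 3, 2, 4])
        assert res.coefficient == pytest.approx(5 / np.sqrt(30), abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1, 1, 1], [1, 2, 3])

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            x = rng.integers(0, 8, size=n).astype(float)
            y = rng.integers(0, 8, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert kendall_tau_b(x, y).coefficient == pytest.approx(
                kendall_oracle(x, y), abs=1e-9
            )


class TestRatioVsCns:
    def make_counts(self, gene, promoter):
        from paracns.regions import RegionCNSCounts

        return RegionCNSCounts(
            gene=gene,
            counts={"promoter_1500": promoter},
            base_sums={"promoter_1500": promoter * 30},
        )

    def make_pairs_and_counts(self, taus):
        pairs, counts = [], {}
        for i, (ratio, cns_count) in enumerate(taus):
            h, low = f"h{i}", f"l{i}"
            pairs.append(
                ParalogPair(gene_a=h, gene_b=low, ratio=ratio,
                            group="differential", higher=h, lower=low)
            )
            counts[low] = self.make_counts(low, cns_count)
            counts[h] = self.make_counts(h, 3)
        return pairs, counts

    def test_negative_coupling_detected(self):
        # CNS count strictly decreasing in ratio -> tau-b = -1
        pairs, counts = self.make_pairs_and_counts(
            [(7 + i, 10 - i) for i in range(8)]
        )
        res = ratio_vs_cns_correlation(pairs, counts, "lower", "promoter_1500")
        assert res.coefficient == pytest.approx(-1.0)

    def test_constant_counts_rejected(self):
        pairs, counts = self.make_pairs_and_counts([(7 + i, 5) for i in range(6)])
        with pytest.raises(ValueError):
            ratio_vs_cns_correlation(pairs, counts, "lower", "promoter_1500")

    def test_missing_counts_skipped_with_log(self, caplog):
        pairs, counts = self.make_pairs_and_counts(
            [(7 + i, 10 - i) for i in range(8)]
        )
        del counts["l0"]
        with caplog.at_level("INFO"):
            res = ratio_vs_cns_correlation(pairs, counts, "lower", "promoter_1500")
        assert res.n == 7
        assert "l0" in caplog.text

    def test_base_sum_measure_agrees_in_sign(self):
        pairs, counts = self.make_pairs_and_counts(
            [(7 + i, 10 - i) for i in range(8)]
        )
        count_res = ratio_vs_cns_correlation(pairs, counts, "lower", "promoter_1500")
        base_res = ratio_vs_cns_correlation(
            pairs, counts, "lower", "promoter_1500", measure="base_sum"
        )
        assert np.sign(count_res.coefficient) == np.sign(base_res.coefficient)
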