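import filecmp
from pathlib import Path

import numpy as np
import pytest

from paracns.classify import ParalogPair, classify_pairs, filter_pairs
from paracns.expression import profile_table
from paracns.io import read_bed
from paracns.regions import CNSRecord
from paracns.synthetic import (
    SimulationConfig,
    read_bundle,
    recovery_config,
    simulate_bundle,
    write_bundle,
)


class TestConfigValidation:
    def test_fractions_must_not_exceed_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_pairs=10, frac_similar=0.7, frac_differential=0.5)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_pairs=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_pairs=10, n_tissues=1)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_pairs=10, ortholog_loss_prob={"lower": 1.5})

    def test_roundtrip_through_dict(self):
        cfg = SimulationConfig(n_pairs=25, seed=3, cns_loss_beta=0.5)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestBundleStructure:
    def test_counts_conserved(self):
        bundle = simulate_bundle(SimulationConfig(n_pairs=100, seed=1))
        assert len(bundle.pairs) == 100
        assert len(bundle.annotation) == 200
        assert len(bundle.expression) == 200

    def test_every_pair_gene_annotated_and_expressed(self, small_bundle):
        annotated = {g.gene for g in small_bundle.annotation}
        expressed = set(small_bundle.expression.index)
        for row in small_bundle.pairs.itertuples():
            assert {row.gene_a, row.gene_b} <= annotated
            assert {row.gene_a, row.gene_b} <= expressed

    def test_same_seed_gives_identical_bundles(self):
        cfg = SimulationConfig(n_pairs=30, seed=17)
        assert simulate_bundle(cfg) == simulate_bundle(cfg)

    def test_different_seeds_differ(self):
        b1 = simulate_bundle(SimulationConfig(n_pairs=30, seed=1))
        b2 = simulate_bundle(SimulationConfig(n_pairs=30, seed=2))
        assert not b1.expression.equals(b2.expression)

    def test_genes_do_not_overlap_on_chromosomes(self, small_bundle):
        by_chrom = {}
        for g in small_bundle.annotation:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.cds_start)
            for a, b in zip(genes, genes[1:]):
                assert a.cds_end < b.cds_start  # >= 1 bp gap

    def test_injected_ratios_match_downstream_classification(self, small_bundle):
        profiles = profile_table(small_bundle.expression)
        means = profiles["mean"].to_dict()
        pairs = [ParalogPair(r.gene_a, r.gene_b) for r in small_bundle.pairs.itertuples()]
        lengths = {g.gene: g.protein_length for g in small_bundle.annotation}
        filtered = filter_pairs(pairs, lengths, set(small_bundle.expression.index))
        assert len(filtered) == len(pairs)  # generated pairs all pass the filters
        classified = classify_pairs(filtered, means)
        observed = {p.group for p in classified}
        truth_groups = dict(
            zip(
                small_bundle.truth.gene_a,
                small_bundle.truth.group,
            )
        )
        for p in classified:
            assert p.group == truth_groups[p.gene_a]
        assert observed == {"similar", "differential", "intermediate"}

    def test_group_dnds_medians_ordered(self):
        # lower > similar > higher under the default location pattern
        bundle = simulate_bundle(recovery_config(n_pairs=400, seed=2))
        role = {}
        for row in bundle.truth.itertuples():
            if row.group == "differential":
                role[row.higher] = "higher"
                role[row.lower] = "lower"
            else:
                role[row.gene_a] = row.group
                role[row.gene_b] = row.group
        dnds = {"similar": [], "higher": [], "lower": []}
        for row in bundle.orthologs.itertuples():
            if row.ortholog is None or not isinstance(row.ortholog, str):
                continue
            r = role.get(row.gene)
            if r in dnds and row.dS > 0:
                dnds[r].append(row.dN / row.dS)
        med = {k: np.median(v) for k, v in dnds.items()}
        assert med["lower"] > med["similar"] > med["higher"]


def test_no_spurious_cns_correlation_without_injected_loss():
    """With cns_loss_beta=0 the promoter count / expression-ratio tau-b of
    lower-expressed genes is non-significant at 0.01 in >= 18 of 20 seeds."""
    from helpers import promoter_correlation

    non_significant = 0
    for seed in range(20):
        bundle = simulate_bundle(recovery_config(n_pairs=150, seed=seed,
                                                 cns_loss_beta=0.0))
        res = promoter_correlation(bundle, "lower")
        non_significant += res.p_value >= 0.01
    assert non_significant >= 18


class TestRoundTrip:
    def test_write_then_read_reproduces_bundle(self, small_bundle, tmp_path):
        write_bundle(small_bundle, tmp_path)
        assert read_bundle(tmp_path) == small_bundle

    def test_write_is_byte_deterministic(self, tmp_path):
        cfg = SimulationConfig(n_pairs=25, seed=4)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(simulate_bundle(cfg), d1)
        write_bundle(simulate_bundle(cfg), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_bed_track_parseable(self, small_bundle, tmp_path):
        manifest = write_bundle(small_bundle, tmp_path)
        records = read_bed(tmp_path / manifest["files"]["cns_dataset1"], dataset=1)
        assert records == small_bundle.cns_tracks[1]
        assert all(isinstance(r, CNSRecord) for r in records)

    def test_empty_cns_track_round_trips(self, tmp_path):
        path = tmp_path / "empty.bed"
        from paracns.io import write_bed

        write_bed([], path)
        assert path.exists() and path.read_text() == ""
        assert read_bed(path) == []

    def test_name_based_exclusion_filters_labelled_records(self, tmp_path):
        from paracns.io import write_bed

        records = [
            CNSRecord(chrom="chr1", start=10, end=40, name="cns_1"),
            CNSRecord(chrom="chr1", start=50, end=80, name="sncCNS_2"),
        ]
        path = tmp_path / "track.bed"
        write_bed(records, path)
        kept = read_bed(path, exclude_name="sncCNS")
        assert [r.name for r in kept] == ["cns_1"]
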