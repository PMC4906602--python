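"""Shared downstream-analysis helpers for bundle-level tests."""

from paracns.classify import ParalogPair, classify_pairs, filter_pairs
from paracns.expression import profile_table
from paracns.regions import count_cns_for_genes, ratio_vs_cns_correlation
from paracns.synthetic import neighbor_map


def classified_differential_pairs(bundle):
    """Run the real classification path on a bundle's own tables."""
    means = profile_table(bundle.expression)["mean"].to_dict()
    pairs = [ParalogPair(r.gene_a, r.gene_b) for r in bundle.pairs.itertuples()]
    lengths = {g.gene: g.protein_length for g in bundle.annotation}
    filtered = filter_pairs(pairs, lengths, set(bundle.expression.index))
    classified = classify_pairs(filtered, means)
    return [p for p in classified if p.group == "differential"]


def promoter_correlation(bundle, role):
    """Kendall tau-b between pair expression ratio and dataset-1 promoter
    CNS counts of the requested role's genes."""
    counts = count_cns_for_genes(
        bundle.annotation,
        bundle.cns_tracks[1],
        neighbor_map(bundle.annotation),
        bundle.chrom_lengths,
    )
    diff = classified_differential_pairs(bundle)
    return ratio_vs_cns_correlation(diff, counts, role, "promoter_1500")
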