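"""Seeded synthetic inputs for the whole pipeline.

The generator emulates the schemas and the statistical structure of the
real inputs (gene annotation, a genes x tissues RMA-style expression
matrix, a WGD paralog-pair list, three CNS BED tracks, an ortholog
dN/dS table, ortholog expression Z scores, a TF binding-site table and
an mRNA half-life table) under explicit, injectable effect sizes:

* pair expression ratios are drawn so the requested fractions of pairs
  fall below the similar threshold and above the differential threshold;
* for differentially expressed pairs, the lower-expressed gene's CNS
  count per region is Poisson with mean
  ``cns_rate_base * exp(-cns_loss_beta * max(ratio - ratio_differential_min, 0))``
  — CNS loss accumulates with expression divergence beyond the
  differential threshold, while the higher-expressed gene keeps the base
  rate (the two coincide at the threshold and under ``cns_loss_beta=0``);
* dN/dS is drawn per group around ``dnds_location``;
* ortholog presence is Bernoulli with per-group-role loss probabilities;
* ortholog expression Z scores are drawn with per-group correlation;
* TF binding sites are placed in promoter CNSs with a tunable density
  tilt toward the higher-expression group; mRNA half-lives optionally
  shift with 3' UTR CNS presence.

One global integer seed drives a hierarchy of named substreams
(``numpy`` ``SeedSequence`` spawn keys), so adding a table never
perturbs the draws of earlier ones.  No generative choice here is taken
from real data; every distribution is a documented stand-in (see
docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from paracns import io
from paracns.cns_props import gc_content
from paracns.regions import CNSRecord, GeneModel, define_regions

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "simulate_bundle",
    "write_bundle",
    "read_bundle",
    "recovery_config",
    "draw_halflives",
    "TF_FAMILIES",
]

#: named substreams of the global seed (spawn keys); append-only
_STREAMS = {
    "groups": 0,
    "expression": 1,
    "annotation": 2,
    "cns": 3,
    "orthologs": 4,
    "tfbs": 5,
    "halflife": 6,
}

#: ~30 plant transcription-factor families (scaled-down stand-in catalogue)
TF_FAMILIES = (
    "MYB", "HD-ZIP", "bZIP", "WRKY", "NAC", "AP2-EREBP", "bHLH", "MADS",
    "C2H2", "GATA", "DOF", "TCP", "ARF", "HSF", "GRAS", "SBP", "E2F",
    "LBD", "CAMTA", "ZF-HD", "TRIHELIX", "EIN3", "ABI3VP1", "ARR-B",
    "BES1", "BBR-BPC", "CPP", "WOX", "YABBY", "NF-Y",
)

#: per-region-class multipliers of the base CNS rate (promoter = 1)
_REGION_RATE = {
    "promoter_1500": 1.0,
    "utr5": 0.2,
    "introns": 0.5,
    "utr3": 0.3,
    "downstream": 0.4,
}
#: per-dataset multipliers (dataset 1 = closest species group, densest)
_DATASET_RATE = {1: 1.0, 2: 0.7, 3: 0.5}

_GROUPS = ("similar", "differential", "intermediate")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and injectable effect sizes.

    Defaults mirror the reference study's conditions: 15 tissues, the
    similar/differential fractions of its 1312-pair set (245 and 156),
    thresholds 1.25 and 7 on the log2-scale expression ratio, group
    dN/dS locations 0.17/0.13/0.24, and ortholog-loss probabilities
    matching the observed 144/156 vs 155/156 retention.
    """

    n_pairs: int
    n_tissues: int = 15
    frac_similar: float = 245 / 1312
    frac_differential: float = 156 / 1312
    ratio_similar_max: float = 1.25
    ratio_differential_min: float = 7.0
    cns_rate_base: float = 2.0
    cns_loss_beta: float = 1.0
    dnds_location: Mapping[str, float] = field(
        default_factory=lambda: {"similar": 0.17, "higher": 0.13, "lower": 0.24}
    )
    ortholog_loss_prob: Mapping[str, float] = field(
        default_factory=lambda: {"similar": 0.04, "higher": 0.006, "lower": 0.08}
    )
    ortholog_expr_corr: Mapping[str, float] = field(
        default_factory=lambda: {"similar": 0.64, "higher": 0.54, "lower": 0.49}
    )
    tfbs_enrichment: float = 0.0
    halflife_effect: float = 0.0
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.frac_similar < 0 or self.frac_differential < 0:
            raise ValueError("group fractions must be nonnegative")
        if self.frac_similar + self.frac_differential > 1 + 1e-12:
            raise ValueError("frac_similar + frac_differential must be <= 1")
        if self.ratio_similar_max <= 1 or self.ratio_differential_min <= self.ratio_similar_max:
            raise ValueError("need 1 < ratio_similar_max < ratio_differential_min")
        if self.cns_rate_base <= 0:
            raise ValueError("cns_rate_base must be positive")
        if self.cns_loss_beta < 0:
            raise ValueError("cns_loss_beta must be nonnegative")
        for name, probs in (("ortholog_loss_prob", self.ortholog_loss_prob),):
            for k, v in probs.items():
                if not 0 <= v <= 1:
                    raise ValueError(f"{name}[{k!r}] = {v} outside [0, 1]")
        for k, v in self.dnds_location.items():
            if v <= 0:
                raise ValueError(f"dnds_location[{k!r}] must be positive")
        if self.tfbs_enrichment < 0:
            raise ValueError("tfbs_enrichment must be nonnegative")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("dnds_location", "ortholog_loss_prob", "ortholog_expr_corr"):
            d[k] = dict(d[k])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**d)


def recovery_config(n_pairs: int = 300, seed: int = 0, **overrides) -> SimulationConfig:
    """Calibration design for injected-effect recovery.

    A differential-group-focused design (half the pairs differential, so
    roughly 150 differential pairs at the default size) chosen by a
    prior power analysis of the CNS-loss model; used by the recovery and
    null-calibration checks.
    """
    params = dict(
        n_pairs=n_pairs,
        frac_similar=0.3,
        frac_differential=0.5,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SyntheticBundle:
    """All pipeline inputs plus the injected-parameter truth record."""

    config: SimulationConfig
    annotation: list[GeneModel]
    chrom_lengths: dict[str, int]
    expression: pd.DataFrame
    pairs: pd.DataFrame
    cns_tracks: dict[int, list[CNSRecord]]
    orthologs: pd.DataFrame
    zscores: pd.DataFrame
    tfbs: pd.DataFrame
    halflife: pd.DataFrame
    truth: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticBundle):
            return NotImplemented
        return (
            self.config == other.config
            and self.annotation == other.annotation
            and self.chrom_lengths == other.chrom_lengths
            and self.expression.equals(other.expression)
            and self.pairs.equals(other.pairs)
            and set(self.cns_tracks) == set(other.cns_tracks)
            and all(self.cns_tracks[d] == other.cns_tracks[d] for d in self.cns_tracks)
            and self.orthologs.equals(other.orthologs)
            and self.zscores.equals(other.zscores)
            and self.tfbs.equals(other.tfbs)
            and self.halflife.equals(other.halflife)
            and self.truth.equals(other.truth)
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    bases = rng.choice(
        np.array(["A", "C", "G", "T"]),
        size=length,
        p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
    )
    return "".join(bases)


def draw_halflives(
    rng: np.random.Generator, has_utr3_cns: np.ndarray, effect: float
) -> np.ndarray:
    """mRNA half-lives (minutes), log-normal around ~4 h, with an optional
    multiplicative shift ``exp(effect)`` for genes carrying a 3' UTR CNS."""
    base = np.exp(rng.normal(np.log(240.0), 0.6, size=len(has_utr3_cns)))
    return base * np.exp(effect * has_utr3_cns.astype(float))


def _draw_pairs(config: SimulationConfig) -> pd.DataFrame:
    """Group labels, target expression ratios and means for every pair."""
    rng = config.rng("groups")
    n = config.n_pairs
    n_sim = int(round(config.frac_similar * n))
    n_diff = int(round(config.frac_differential * n))
    if n_sim + n_diff > n:
        n_diff = n - n_sim
    groups = ["similar"] * n_sim + ["differential"] * n_diff
    groups += ["intermediate"] * (n - len(groups))

    rows = []
    for p, group in enumerate(groups):
        if group == "similar":
            ratio = 1.0 + rng.random() * (config.ratio_similar_max - 1.0)
            high = rng.uniform(4.0, 14.0)
        elif group == "differential":
            ratio = config.ratio_differential_min + min(rng.exponential(2.5), 15.0)
            high = rng.uniform(9.0, 15.5)
        else:
            ratio = rng.uniform(config.ratio_similar_max, config.ratio_differential_min)
            high = rng.uniform(6.0, 14.0)
        low = high / ratio
        a_is_higher = bool(rng.integers(0, 2))
        gene_a, gene_b = f"G{p:05d}A", f"G{p:05d}B"
        mean_a, mean_b = (high, low) if a_is_higher else (low, high)
        rows.append(
            {
                "pair": p,
                "gene_a": gene_a,
                "gene_b": gene_b,
                "group": group,
                "ratio": ratio,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "higher": gene_a if a_is_higher else gene_b,
                "lower": gene_b if a_is_higher else gene_a,
            }
        )
    return pd.DataFrame(rows)


def _gene_role(truth_row: pd.Series, gene: str) -> str:
    """Group-role label of one gene: similar/intermediate pairs carry the
    group label; differential pairs split into higher/lower."""
    if truth_row["group"] != "differential":
        return truth_row["group"]
    return "higher" if truth_row["higher"] == gene else "lower"


def _simulate_expression(config: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    rng = config.rng("expression")
    tissues = [f"T{i + 1:02d}" for i in range(config.n_tissues)]
    genes, rows = [], []
    for row in truth.itertuples():
        for gene, mean in ((row.gene_a, row.mean_a), (row.gene_b, row.mean_b)):
            concentration = np.exp(rng.uniform(np.log(2.0), np.log(30.0)))
            weights = rng.gamma(concentration, 1.0, size=config.n_tissues)
            values = mean * weights / weights.mean()
            genes.append(gene)
            rows.append(values)
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=tissues)


def _simulate_annotation(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[list[GeneModel], dict[str, int]]:
    rng = config.rng("annotation")
    gene_order: list[tuple[str, int]] = []  # (gene, protein_length)
    for _ in truth.itertuples():
        la = int(rng.integers(120, 600))
        lb = la - int(rng.integers(0, int(0.04 * la) + 1))  # passes the 5 % filter
        gene_order.append(la)
        gene_order.append(lb)
    gene_ids = [
        g for row in truth.itertuples() for g in (row.gene_a, row.gene_b)
    ]

    per_chrom = -(-len(gene_ids) // config.n_chromosomes)  # ceil
    genes: list[GeneModel] = []
    chrom_lengths: dict[str, int] = {}
    cursor = 0
    chrom_idx = 0
    for i, (gene, plen) in enumerate(zip(gene_ids, gene_order)):
        if i % per_chrom == 0:
            if i > 0:
                chrom_lengths[f"chr{chrom_idx}"] = cursor + int(rng.integers(1200, 3000))
            chrom_idx += 1
            cursor = 1800
        chrom = f"chr{chrom_idx}"
        # mixed gap sizes so neighbor shortening is actually exercised
        if rng.random() < 0.3:
            gap = int(rng.integers(150, 1200))
        else:
            gap = int(rng.integers(1700, 4000))
        cds_start = cursor + gap
        cds_len = 3 * plen
        n_introns = min(int(rng.poisson(1.5)), 4)
        intron_lens = [int(rng.integers(80, 300)) for _ in range(n_introns)]
        # split the coding length into n_introns + 1 exon segments (>= 30 bp)
        n_seg = n_introns + 1
        extra = rng.multinomial(cds_len - 30 * n_seg, np.full(n_seg, 1.0 / n_seg))
        seg_lens = [30 + int(x) for x in extra]
        introns = []
        pos = cds_start
        for seg, ilen in zip(seg_lens[:-1], intron_lens):
            pos += seg
            introns.append((pos, pos + ilen))
            pos += ilen
        cds_end = cds_start + cds_len + sum(intron_lens)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene=gene,
                chrom=chrom,
                strand=strand,
                cds_start=cds_start,
                cds_end=cds_end,
                introns=tuple(introns),
                protein_length=plen,
            )
        )
        cursor = cds_end
    chrom_lengths[f"chr{chrom_idx}"] = cursor + int(rng.integers(1200, 3000))
    return genes, chrom_lengths


def neighbor_map(
    annotation: list[GeneModel],
) -> dict[str, tuple[GeneModel | None, GeneModel | None]]:
    """Nearest annotated gene span on either side, per gene (any strand)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, tuple[GeneModel | None, GeneModel | None]] = {}
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.cds_start)
        for i, g in enumerate(chrom_genes):
            left = chrom_genes[i - 1] if i > 0 else None
            right = chrom_genes[i + 1] if i + 1 < len(chrom_genes) else None
            out[g.gene] = (left, right)
    return out


def _simulate_cns(
    config: SimulationConfig,
    truth: pd.DataFrame,
    annotation: list[GeneModel],
    chrom_lengths: dict[str, int],
) -> dict[int, list[CNSRecord]]:
    rng = config.rng("cns")
    neighbors = neighbor_map(annotation)
    models = {g.gene: g for g in annotation}
    role: dict[str, str] = {}
    ratio: dict[str, float] = {}
    for row in truth.itertuples():
        for gene in (row.gene_a, row.gene_b):
            role[gene] = _gene_role(truth.loc[row.Index], gene)
            ratio[gene] = row.ratio

    tracks: dict[int, list[CNSRecord]] = {}
    for dataset, dataset_mult in _DATASET_RATE.items():
        records: list[CNSRecord] = []
        for gene_model in annotation:
            gene = gene_model.gene
            regions = define_regions(
                gene_model,
                neighbors[gene],
                chrom_length=chrom_lengths[gene_model.chrom],
            )
            loss = 1.0
            if role[gene] == "lower":
                excess = max(ratio[gene] - config.ratio_differential_min, 0.0)
                loss = float(np.exp(-config.cns_loss_beta * excess))
            for region_class, class_mult in _REGION_RATE.items():
                intervals = regions[region_class]
                usable = [(s, e) for s, e in intervals if e - s >= 12]
                rate = config.cns_rate_base * dataset_mult * class_mult * loss
                count = rng.poisson(rate)
                if count == 0 or not usable:
                    continue
                lengths = np.array([e - s for s, e in usable], dtype=float)
                weights = lengths / lengths.sum()
                for _ in range(count):
                    s, e = usable[rng.choice(len(usable), p=weights)]
                    max_len = min(60, e - s)
                    length = int(rng.integers(12, max_len + 1))
                    start = int(rng.integers(s, e - length + 1))
                    gc_target = float(rng.beta(3.5, 6.5))
                    seq = _random_sequence(rng, length, gc_target)
                    records.append(
                        CNSRecord(
                            chrom=gene_model.chrom,
                            start=start,
                            end=start + length,
                            dataset=dataset,
                            name=f"d{dataset}_{gene}_{region_class}_{len(records)}",
                            sequence=seq,
                            gc=gc_content(seq),
                        )
                    )
        # sparse background CNSs anywhere on the chromosomes
        for chrom, clen in chrom_lengths.items():
            for _ in range(rng.poisson(0.15 * len(annotation) / len(chrom_lengths))):
                length = int(rng.integers(12, 61))
                start = int(rng.integers(0, clen - length))
                gc_target = float(rng.beta(3.5, 6.5))
                seq = _random_sequence(rng, length, gc_target)
                records.append(
                    CNSRecord(
                        chrom=chrom,
                        start=start,
                        end=start + length,
                        dataset=dataset,
                        name=f"d{dataset}_bg_{chrom}_{len(records)}",
                        sequence=seq,
                        gc=gc_content(seq),
                    )
                )
        records.sort(key=lambda r: (r.chrom, r.start, r.end, r.name))
        tracks[dataset] = records
    return tracks


def _simulate_orthologs(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = config.rng("orthologs")
    ortho_rows, z_rows = [], []
    for row in truth.itertuples():
        for gene in (row.gene_a, row.gene_b):
            grole = _gene_role(truth.loc[row.Index], gene)
            loss_key = grole if grole in config.ortholog_loss_prob else "similar"
            present = rng.random() >= config.ortholog_loss_prob.get(loss_key, 0.04)
            if not present:
                ortho_rows.append(
                    {"gene": gene, "ortholog": None, "pct_identity": np.nan,
                     "dN": np.nan, "dS": np.nan}
                )
                continue
            loc = config.dnds_location.get(
                grole, config.dnds_location.get("similar", 0.17)
            )
            dnds = rng.gamma(6.0, loc / 6.0)
            ds = rng.uniform(0.08, 0.35)
            ortho_rows.append(
                {
                    "gene": gene,
                    "ortholog": f"{gene}_AL",
                    "pct_identity": round(float(rng.uniform(85.0, 99.5)), 2),
                    "dN": float(dnds * ds),
                    "dS": float(ds),
                }
            )
            rho = config.ortholog_expr_corr.get(
                grole, config.ortholog_expr_corr.get("similar", 0.6)
            )
            z_self = rng.normal()
            z_orth = rho * z_self + np.sqrt(1 - rho**2) * rng.normal()
            z_rows.append({"gene": gene, "z_self": float(z_self), "z_ortholog": float(z_orth)})
    return pd.DataFrame(ortho_rows), pd.DataFrame(z_rows)


def _simulate_tfbs(
    config: SimulationConfig,
    truth: pd.DataFrame,
    cns_tracks: dict[int, list[CNSRecord]],
    annotation: list[GeneModel],
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    rng = config.rng("tfbs")
    higher_genes = set(truth.loc[truth["group"] == "differential", "higher"])
    # promoter CNSs of dataset 1 are the placement pool; CNSs of
    # higher-expression genes are weighted by exp(tfbs_enrichment)
    pool = [r for r in cns_tracks[1] if "_promoter_1500_" in r.name]

    def _gene_of(record: CNSRecord) -> str:
        return record.name.split("_")[1]

    if pool:
        w = np.array(
            [np.exp(config.tfbs_enrichment) if _gene_of(r) in higher_genes else 1.0
             for r in pool]
        )
        w = w / w.sum()
    rows = []
    for family in TF_FAMILIES:
        n_factors = 2
        n_cns_sites = rng.poisson(0.12 * len(pool)) if pool else 0
        for _ in range(n_cns_sites):
            cns = pool[int(rng.choice(len(pool), p=w))]
            length = int(rng.integers(6, 13))
            start = int(rng.integers(cns.start - 2, max(cns.start - 1, cns.end - 6)))
            rows.append(
                {
                    "factor": f"{family}_{int(rng.integers(1, n_factors + 1))}",
                    "family": family,
                    "chrom": cns.chrom,
                    "start": start,
                    "end": start + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "score": round(float(rng.uniform(0.25, 1.0)), 3),
                }
            )
        # background sites scattered over the chromosomes
        for _ in range(rng.poisson(0.5 * max(n_cns_sites, 1))):
            chrom = list(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
            length = int(rng.integers(6, 13))
            start = int(rng.integers(0, chrom_lengths[chrom] - length))
            rows.append(
                {
                    "factor": f"{family}_{int(rng.integers(1, n_factors + 1))}",
                    "family": family,
                    "chrom": chrom,
                    "start": start,
                    "end": start + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "score": round(float(rng.uniform(0.25, 1.0)), 3),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["factor", "family", "chrom", "start", "end", "strand", "score"],
    )


def _simulate_halflife(
    config: SimulationConfig,
    truth: pd.DataFrame,
    cns_tracks: dict[int, list[CNSRecord]],
) -> pd.DataFrame:
    rng = config.rng("halflife")
    genes = [g for row in truth.itertuples() for g in (row.gene_a, row.gene_b)]
    utr3_genes = {
        _cns_gene(r) for r in cns_tracks[1] if "_utr3_" in r.name
    }
    has_cns = np.array([g in utr3_genes for g in genes])
    values = draw_halflives(rng, has_cns, config.halflife_effect)
    keep = rng.random(len(genes)) >= 0.08  # ~8 % of genes lack half-life data
    return pd.DataFrame(
        {"gene": np.array(genes)[keep], "halflife_min": values[keep]}
    ).reset_index(drop=True)


def _cns_gene(record: CNSRecord) -> str:
    return record.name.split("_")[1]


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate all pipeline inputs; deterministic given ``config.seed``."""
    truth = _draw_pairs(config)
    expression = _simulate_expression(config, truth)
    annotation, chrom_lengths = _simulate_annotation(config, truth)
    cns_tracks = _simulate_cns(config, truth, annotation, chrom_lengths)
    orthologs, zscores = _simulate_orthologs(config, truth)
    tfbs = _simulate_tfbs(config, truth, cns_tracks, annotation, chrom_lengths)
    halflife = _simulate_halflife(config, truth, cns_tracks)
    pairs = truth[["gene_a", "gene_b"]].copy()
    return SyntheticBundle(
        config=config,
        annotation=annotation,
        chrom_lengths=chrom_lengths,
        expression=expression,
        pairs=pairs,
        cns_tracks=cns_tracks,
        orthologs=orthologs,
        zscores=zscores,
        tfbs=tfbs,
        halflife=halflife,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict:
    """Write every table of a bundle; returns the manifest (also saved).

    CNS tracks go out as BED (0-based half-open, native); all other
    tables are tab-delimited with headers.  The truth record and the
    generating configuration are saved alongside.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    io.write_annotation(bundle.annotation, directory / "annotation.tsv")
    files["annotation"] = "annotation.tsv"
    pd.DataFrame(
        sorted(bundle.chrom_lengths.items()), columns=["chrom", "length"]
    ).to_csv(directory / "chrom_lengths.tsv", sep="\t", index=False)
    files["chrom_lengths"] = "chrom_lengths.tsv"
    io.write_matrix(bundle.expression, directory / "expression.tsv")
    files["expression"] = "expression.tsv"
    io.write_table(bundle.pairs, directory / "pairs.tsv")
    files["pairs"] = "pairs.tsv"
    for dataset, records in sorted(bundle.cns_tracks.items()):
        name = f"cns_dataset{dataset}.bed"
        io.write_bed(records, directory / name)
        files[f"cns_dataset{dataset}"] = name
    io.write_table(bundle.orthologs, directory / "orthologs.tsv")
    files["orthologs"] = "orthologs.tsv"
    io.write_table(bundle.zscores, directory / "zscores.tsv")
    files["zscores"] = "zscores.tsv"
    io.write_table(bundle.tfbs, directory / "tfbs.tsv")
    files["tfbs"] = "tfbs.tsv"
    io.write_table(bundle.halflife, directory / "halflife.tsv")
    files["halflife"] = "halflife.tsv"
    io.write_table(bundle.truth, directory / "truth_pairs.tsv")
    files["truth_pairs"] = "truth_pairs.tsv"

    manifest = {
        "seed": bundle.config.seed,
        "config": bundle.config.to_dict(),
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def read_bundle(directory: str | Path) -> SyntheticBundle:
    """Read a bundle written by :func:`write_bundle` back into memory."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = SimulationConfig.from_dict(manifest["config"])
    files = manifest["files"]

    annotation = io.read_annotation(directory / files["annotation"])
    chrom_df = pd.read_csv(directory / files["chrom_lengths"], sep="\t")
    chrom_lengths = dict(zip(chrom_df["chrom"], chrom_df["length"].astype(int)))
    expression = io.read_matrix(directory / files["expression"])
    pairs = io.read_table(directory / files["pairs"], string_columns=["gene_a", "gene_b"])
    cns_tracks = {
        d: io.read_bed(directory / files[f"cns_dataset{d}"], dataset=d)
        for d in (1, 2, 3)
        if f"cns_dataset{d}" in files
    }
    orthologs = io.read_table(
        directory / files["orthologs"], string_columns=["gene", "ortholog"]
    )
    zscores = io.read_table(directory / files["zscores"], string_columns=["gene"])
    tfbs = io.read_table(
        directory / files["tfbs"], string_columns=["factor", "family", "chrom", "strand"]
    )
    halflife = io.read_table(directory / files["halflife"], string_columns=["gene"])
    truth = io.read_table(
        directory / files["truth_pairs"],
        string_columns=["gene_a", "gene_b", "group", "higher", "lower"],
    )
    return SyntheticBundle(
        config=config,
        annotation=annotation,
        chrom_lengths=chrom_lengths,
        expression=expression,
        pairs=pairs,
        cns_tracks=cns_tracks,
        orthologs=orthologs,
        zscores=zscores,
        tfbs=tfbs,
        halflife=halflife,
        truth=truth,
    )
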