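"""End-to-end orchestration: config, staged execution, results, report.

``run_pipeline`` sequences the analyses — expression profiling, pair
classification, coding/expression divergence contrasts, CNS-region
correlations, CNS property and TF-motif enrichment tests, and the mRNA
half-life contrast — over either files on disk or a freshly simulated
bundle.  Every randomized step takes a substream derived from the global
seed, every filter logs its input/output counts, and the results carry
provenance (seed, config hash, package version) so reports are
self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from paracns import io
from paracns._version import __version__
from paracns.classify import ParalogPair, classify_pairs, filter_pairs, sample_similar
from paracns.cns_props import (
    TFBSRecord,
    filter_tfbs,
    resample_mean_test,
    tfbs_family_enrichment,
)
from paracns.divergence import (
    compare_correlations,
    fisher_exact_two_sided,
    group_dnds_test,
    ortholog_retention_table,
    permutation_rho_distribution,
    spearman_rho,
)
from paracns.expression import profile_table
from paracns.halflife import halflife_signed_rank, select_contrast_pairs
from paracns.regions import (
    REGION_CLASSES,
    count_cns_for_genes,
    ratio_vs_cns_correlation,
)
from paracns.synthetic import (
    SimulationConfig,
    SyntheticBundle,
    neighbor_map,
    read_bundle,
    simulate_bundle,
)

__all__ = ["PipelineConfig", "ResultsBundle", "PipelineError", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)

SECTIONS = ("classify", "divergence", "cns", "enrich", "halflife")

#: pipeline substream ids (offset so they never collide with generator streams)
_PIPE_STREAMS = {"sample_similar": 100, "permutation": 101, "enrichment": 102,
                 "properties": 103}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline inputs (file paths XOR a simulation block) and thresholds."""

    simulate: SimulationConfig | None = None
    inputs: Mapping[str, str] | None = None
    similar_max: float = 1.25
    differential_min: float = 7.0
    protein_len_tol: float = 0.05
    tfbs_min_score: float = 0.5
    permutation_iterations: int = 10000
    resampling_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "config must contain exactly one of a simulate block or input paths"
            )

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], seed: int | None = None) -> "PipelineConfig":
        raw = dict(raw)
        if seed is not None:
            raw["seed"] = seed
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", raw.get("seed", 0))
            sim = SimulationConfig.from_dict(sim)
        return cls(simulate=sim, **{k: v for k, v in raw.items()})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        if self.inputs is not None:
            d["inputs"] = dict(self.inputs)
        return d

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def sub_seed(self, stream: str) -> int:
        """Derived integer seed for one named randomized step (< 2^31)."""
        state = np.random.SeedSequence(
            self.seed, spawn_key=(_PIPE_STREAMS[stream],)
        ).generate_state(1)[0]
        return int(state >> 1)


@dataclass
class ResultsBundle:
    """Machine-readable results of the requested pipeline sections."""

    provenance: dict
    filter_log: dict = field(default_factory=dict)
    classification: pd.DataFrame | None = None
    divergence: dict | None = None
    cns_correlations: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    cns_properties: pd.DataFrame | None = None
    halflife: dict | None = None

    def to_dict(self) -> dict:
        def df(x):
            return None if x is None else x.to_dict(orient="records")

        return {
            "provenance": self.provenance,
            "filter_log": self.filter_log,
            "classification": df(self.classification),
            "divergence": self.divergence,
            "cns_correlations": df(self.cns_correlations),
            "enrichment": df(self.enrichment),
            "cns_properties": df(self.cns_properties),
            "halflife": self.halflife,
        }


def _load_inputs(paths: Mapping[str, str]) -> SyntheticBundle:
    """Assemble a bundle-shaped object from input files on disk."""
    if "bundle_dir" in paths:
        return read_bundle(paths["bundle_dir"])
    raise PipelineError(
        "stage load: only bundle directories are supported as file inputs "
        "(key 'bundle_dir'); individual-table loading goes through paracns.io"
    )


def _ortholog_maps(bundle: SyntheticBundle):
    presence = {row.gene: row.ortholog is not None and not pd.isna(row.ortholog)
                for row in bundle.orthologs.itertuples()}
    dnds: dict[str, float] = {}
    n_zero_ds = 0
    for row in bundle.orthologs.itertuples():
        if row.ortholog is None or pd.isna(row.ortholog):
            continue
        if row.dS == 0:
            n_zero_ds += 1  # dN/dS undefined; excluded
            continue
        dnds[row.gene] = row.dN / row.dS
    if n_zero_ds:
        logger.info("excluded %d orthologs with dS = 0 from dN/dS", n_zero_ds)
    zmap = {row.gene: (row.z_self, row.z_ortholog) for row in bundle.zscores.itertuples()}
    return presence, dnds, zmap


def run_pipeline(
    config: PipelineConfig, only: Sequence[str] | None = None
) -> ResultsBundle:
    """Execute the pipeline; ``only`` restricts the populated sections.

    Expression profiling and pair classification always run (every other
    stage depends on them); the classification table is reported only
    when requested.  Deterministic given ``config.seed``.
    """
    sections = set(SECTIONS if only is None else only)
    unknown = sections - set(SECTIONS)
    if unknown:
        raise PipelineError(f"stage config: unknown sections {sorted(unknown)}")

    if config.simulate is not None:
        bundle = simulate_bundle(config.simulate)
    else:
        bundle = _load_inputs(config.inputs)

    results = ResultsBundle(
        provenance={
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "package": "paracns",
            "version": __version__,
        }
    )

    # --- expression + classification (prerequisite for everything) ---
    try:
        profiles = profile_table(bundle.expression)
        means = profiles["mean"].to_dict()
        protein_lengths = {g.gene: g.protein_length for g in bundle.annotation}
        raw_pairs = [
            ParalogPair(gene_a=row.gene_a, gene_b=row.gene_b)
            for row in bundle.pairs.itertuples()
        ]
        filtered = filter_pairs(
            raw_pairs, protein_lengths, set(bundle.expression.index),
            tolerance=config.protein_len_tol,
        )
        classified = classify_pairs(
            filtered, means,
            similar_max=config.similar_max,
            differential_min=config.differential_min,
        )
        similar = [p for p in classified if p.group == "similar"]
        differential = [p for p in classified if p.group == "differential"]
        results.filter_log = {
            "pairs_input": len(raw_pairs),
            "pairs_filtered": len(filtered),
            "pairs_similar": len(similar),
            "pairs_differential": len(differential),
            "pairs_intermediate": len(filtered) - len(similar) - len(differential),
        }
        logger.info("classification: %s", results.filter_log)
        similar_selected = (
            sample_similar(similar, config.sub_seed("sample_similar"))
            if similar else []
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage classify: {exc}") from exc

    if "classify" in sections:
        tau = profiles["tau"].to_dict()
        results.classification = pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a, "gene_b": p.gene_b,
                    "expr_a": p.expr_a, "expr_b": p.expr_b,
                    "tau_a": tau.get(p.gene_a), "tau_b": tau.get(p.gene_b),
                    "ratio": p.ratio, "group": p.group,
                    "higher": p.higher, "lower": p.lower,
                }
                for p in classified
            ]
        )

    presence, dnds_map, zmap = _ortholog_maps(bundle)

    if "divergence" in sections:
        try:
            results.divergence = _divergence_section(
                config, similar, similar_selected, differential, presence, dnds_map, zmap
            )
        except Exception as exc:
            raise PipelineError(f"stage divergence: {exc}") from exc

    counts_by_dataset = None
    if sections & {"cns", "enrich", "halflife"}:
        try:
            neighbors = neighbor_map(bundle.annotation)
            counts_by_dataset = {
                d: count_cns_for_genes(
                    bundle.annotation, records, neighbors, bundle.chrom_lengths
                )
                for d, records in bundle.cns_tracks.items()
            }
        except Exception as exc:
            raise PipelineError(f"stage cns: {exc}") from exc

    if "cns" in sections:
        try:
            results.cns_correlations = _cns_section(differential, counts_by_dataset)
        except Exception as exc:
            raise PipelineError(f"stage cns: {exc}") from exc

    if "enrich" in sections:
        try:
            enr, props = _enrichment_section(
                config, bundle, similar_selected, differential
            )
            results.enrichment = enr
            results.cns_properties = props
        except Exception as exc:
            raise PipelineError(f"stage enrich: {exc}") from exc

    if "halflife" in sections:
        try:
            utr3_counts = {
                g: rec.counts["utr3"] for g, rec in counts_by_dataset[1].items()
            }
            halflife_map = dict(
                zip(bundle.halflife["gene"], bundle.halflife["halflife_min"])
            )
            contrast = select_contrast_pairs(classified, utr3_counts, halflife_map)
            if contrast:
                test = halflife_signed_rank(contrast)
                results.halflife = {
                    "n_pairs": test.n, "w_statistic": test.w_statistic,
                    "p_value": test.p_value, "method": test.method,
                    "n_contrast_pairs": len(contrast),
                }
            else:
                results.halflife = {"n_contrast_pairs": 0}
        except Exception as exc:
            raise PipelineError(f"stage halflife: {exc}") from exc

    return results


def _divergence_section(
    config, similar, similar_selected, differential, presence, dnds_map, zmap
) -> dict:
    out: dict[str, Any] = {}
    # ortholog retention among differential pairs
    known = [p for p in differential
             if p.lower in presence and p.higher in presence]
    if known:
        table = ortholog_retention_table(known, presence)
        out["retention_table"] = table.tolist()
        out["retention_fisher_p"] = fisher_exact_two_sided(table)
    # dN/dS by group
    groups = {
        "similar": [dnds_map[g] for g in similar_selected if g in dnds_map],
        "higher": [dnds_map[p.higher] for p in differential if p.higher in dnds_map],
        "lower": [dnds_map[p.lower] for p in differential if p.lower in dnds_map],
    }
    if all(len(v) >= 2 for v in groups.values()):
        res = group_dnds_test(groups)
        out["dnds"] = {
            "h_statistic": res.h_statistic,
            "p_value": res.p_value,
            "pairwise_p": {f"{a}|{b}": p for (a, b), p in res.pairwise_p.items()},
            "medians": res.medians,
            "means": res.means,
            "n": {k: len(v) for k, v in groups.items()},
        }
    # Z-score expression correlations
    def rho_of(genes):
        pts = [zmap[g] for g in genes if g in zmap]
        if len(pts) < 3:
            return None
        r = spearman_rho([p[0] for p in pts], [p[1] for p in pts])
        return {"rho": r.coefficient, "n": r.n, "p_value": r.p_value}

    out["spearman"] = {
        "all": rho_of(list(zmap)),
        "higher": rho_of([p.higher for p in differential]),
        "lower": rho_of([p.lower for p in differential]),
    }
    # permutation distribution over the similar pairs
    eligible = [
        (zmap[p.gene_a], zmap[p.gene_b])
        for p in similar
        if p.gene_a in zmap and p.gene_b in zmap
    ]
    if eligible:
        dist = permutation_rho_distribution(
            eligible,
            iterations=config.permutation_iterations,
            seed=config.sub_seed("permutation"),
        )
        out["permutation"] = {
            "iterations": dist.iterations,
            "median": dist.median,
            "interval_95": list(dist.interval_95),
            "n_pairs": len(eligible),
        }
    # Fisher-z contrasts of the group correlations against all orthologs
    sp = out["spearman"]
    for role in ("higher", "lower"):
        if sp["all"] and sp[role]:
            z, p = compare_correlations(
                sp[role]["rho"], sp[role]["n"], sp["all"]["rho"], sp["all"]["n"]
            )
            out[f"compare_{role}_vs_all"] = {"z": z, "p_value": p}
    return out


def _cns_section(differential, counts_by_dataset) -> pd.DataFrame:
    rows = []
    for dataset, counts in sorted(counts_by_dataset.items()):
        for region_class in REGION_CLASSES:
            for role in ("higher", "lower"):
                for measure in ("count", "base_sum"):
                    try:
                        r = ratio_vs_cns_correlation(
                            differential, counts, role, region_class, measure
                        )
                        tau, n, p = r.coefficient, r.n, r.p_value
                        note = ""
                    except ValueError as exc:
                        tau, p = np.nan, np.nan
                        n = len(differential)
                        note = str(exc)
                    rows.append(
                        {
                            "dataset": dataset, "region_class": region_class,
                            "role": role, "measure": measure,
                            "tau_b": tau, "n": n, "p_value": p, "note": note,
                        }
                    )
    return pd.DataFrame(rows)


def _enrichment_section(config, bundle, similar_selected, differential):
    track1 = bundle.cns_tracks[1]
    sites = [
        TFBSRecord(
            factor=row.factor, family=row.family, chrom=row.chrom,
            start=int(row.start), end=int(row.end), strand=row.strand,
            conservation_score=float(row.score),
        )
        for row in bundle.tfbs.itertuples()
    ]
    sites = filter_tfbs(sites, min_score=config.tfbs_min_score)
    families = sorted({row.family for row in bundle.tfbs.itertuples()})

    def promoter_cns_of(genes: set[str]):
        return [r for r in track1
                if "_promoter_1500_" in r.name and r.name.split("_")[1] in genes]

    pool = [r for r in track1 if "_promoter_1500_" in r.name]
    group_genes = {
        "similar": set(similar_selected),
        "higher": {p.higher for p in differential},
        "lower": {p.lower for p in differential},
    }
    enr_seed = config.sub_seed("enrichment")
    enr_rows = []
    for i, (group, genes) in enumerate(group_genes.items()):
        group_cns = promoter_cns_of(genes)
        if not group_cns:
            continue
        for res in tfbs_family_enrichment(
            group_cns, pool, sites, families,
            iterations=config.resampling_iterations,
            seed=enr_seed + i,
        ):
            enr_rows.append(
                {
                    "group": group, "family": res.family,
                    "observed": res.observed, "expected": res.expected,
                    "fold": res.fold, "p_value": res.p_value,
                    "direction": res.direction,
                }
            )
    enrichment = pd.DataFrame(enr_rows)

    # CNS length / GC vs the promoter pool, per dataset and region class
    prop_seed = config.sub_seed("properties")
    prop_rows = []
    for dataset, track in sorted(bundle.cns_tracks.items()):
        pool_d = [r for r in track if "_promoter_1500_" in r.name]
        if not pool_d:
            continue
        for region_tag in ("promoter_1500", "introns", "utr3"):
            for j, (group, genes) in enumerate(group_genes.items()):
                group_cns = [
                    r for r in track
                    if f"_{region_tag}_" in r.name and r.name.split("_")[1] in genes
                ]
                if not group_cns or len(group_cns) > len(pool_d):
                    continue
                for prop in ("length", "gc"):
                    obs = [getattr(r, "length") if prop == "length" else r.gc
                           for r in group_cns]
                    pool_vals = [getattr(r, "length") if prop == "length" else r.gc
                                 for r in pool_d]
                    if any(v is None for v in obs + pool_vals):
                        continue
                    p, fold = resample_mean_test(
                        obs, pool_vals,
                        iterations=config.resampling_iterations,
                        seed=prop_seed + 10 * dataset + j,
                    )
                    prop_rows.append(
                        {
                            "dataset": dataset, "region_class": region_tag,
                            "group": group, "property": prop,
                            "n": len(obs), "fold": fold, "p_value": p,
                        }
                    )
    return enrichment, pd.DataFrame(prop_rows)


def write_report(bundle: ResultsBundle, directory: str | Path) -> list[str]:
    """Write tab-delimited result tables plus a human-readable summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    (directory / "results.json").write_text(
        json.dumps(bundle.to_dict(), indent=2, default=_json_default) + "\n"
    )
    written.append("results.json")

    for name, df in (
        ("classification.tsv", bundle.classification),
        ("cns_correlations.tsv", bundle.cns_correlations),
        ("enrichment.tsv", bundle.enrichment),
        ("cns_properties.tsv", bundle.cns_properties),
    ):
        if df is not None:
            io.write_table(df, directory / name)
            written.append(name)

    lines = ["Paralog expression / CNS divergence report", "=" * 44, ""]
    lines.append(f"seed: {bundle.provenance['seed']}   "
                 f"config: {bundle.provenance['config_hash']}   "
                 f"paracns {bundle.provenance['version']}")
    lines.append("")
    if bundle.filter_log:
        lines.append("Pair filtering and classification:")
        for k, v in bundle.filter_log.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    if bundle.divergence:
        d = bundle.divergence
        if "retention_table" in d:
            (lp, la), (hp, ha) = d["retention_table"]
            lines.append("Ortholog retention (differential pairs):")
            lines.append(f"  lower-expressed : {lp} present, {la} absent")
            lines.append(f"  higher-expressed: {hp} present, {ha} absent")
            lines.append(f"  Fisher exact two-sided p = {d['retention_fisher_p']:.4g}")
            lines.append("")
        if "dnds" in d:
            lines.append("dN/dS by group (median [mean], n):")
            for g in ("similar", "higher", "lower"):
                lines.append(
                    f"  {g:8s}: {d['dnds']['medians'][g]:.3f} "
                    f"[{d['dnds']['means'][g]:.3f}], n={d['dnds']['n'][g]}"
                )
            lines.append(f"  Kruskal-Wallis H = {d['dnds']['h_statistic']:.2f}, "
                         f"p = {d['dnds']['p_value']:.3g}")
            for pair, p in d["dnds"]["pairwise_p"].items():
                lines.append(f"  Dunn {pair}: p = {p:.3g}")
            lines.append("")
        if d.get("spearman"):
            lines.append("Expression Z-score correlations (Spearman):")
            for k, v in d["spearman"].items():
                if v:
                    lines.append(f"  {k:8s}: rho = {v['rho']:.3f} (n={v['n']}, "
                                 f"p={v['p_value']:.3g})")
            lines.append("")
        if "permutation" in d:
            p = d["permutation"]
            lines.append(
                f"Similar-pair permutation ({p['iterations']} selections, "
                f"{p['n_pairs']} pairs): median rho = {p['median']:.3f}, "
                f"95 % interval [{p['interval_95'][0]:.3f}, {p['interval_95'][1]:.3f}]"
            )
            lines.append("")
    else:
        lines.append("Divergence section: not run")
        lines.append("")
    if bundle.cns_correlations is not None:
        sub = bundle.cns_correlations.query("measure == 'count'")
        lines.append("CNS count vs expression-ratio correlations (Kendall tau-b):")
        for row in sub.itertuples():
            if pd.isna(row.tau_b):
                continue
            lines.append(
                f"  dataset {row.dataset} {row.region_class:14s} {row.role:6s}: "
                f"tau-b = {row.tau_b:+.3f} (n={row.n}, p={row.p_value:.3g})"
            )
        lines.append("")
    else:
        lines.append("CNS section: not run")
        lines.append("")
    if bundle.enrichment is not None and len(bundle.enrichment):
        sig = bundle.enrichment.query("p_value < 0.01 and direction != 'absent'")
        lines.append(
            f"TFBS family enrichment: {len(bundle.enrichment)} measurements, "
            f"{len(sig)} significant at p < 0.01"
        )
        for row in sig.itertuples():
            lines.append(f"  {row.group}/{row.family}: {row.direction} "
                         f"({row.fold:.2f} fold, p={row.p_value:.3g})")
        lines.append("")
    else:
        lines.append("Enrichment section: not run")
        lines.append("")
    if bundle.halflife is not None:
        h = bundle.halflife
        if h.get("n_contrast_pairs"):
            lines.append(
                f"mRNA half-life contrast: n = {h['n_contrast_pairs']} pairs, "
                f"W = {h['w_statistic']:.1f}, p = {h['p_value']:.3g} ({h['method']})"
            )
        else:
            lines.append("mRNA half-life contrast: no eligible pairs")
    else:
        lines.append("Half-life section: not run")
    (directory / "report.txt").write_text("\n".join(lines) + "\n")
    written.append("report.txt")
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
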