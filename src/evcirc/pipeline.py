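"""End-to-end orchestration: simulate -> catalog -> biotype -> diffexp -> sponge -> structure.

One configuration object drives every stage; all global thresholds default
to the study values (consensus support 2 reads/pool, FC 1.5, p 0.05,
super-sponge 20 BS, density bands 0.01/0.05, -dG/nt bands 0.2/0.25) and
are overridable. Reruns with the same configuration and seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from scipy import stats as sps

from evcirc import biotypes, catalog as cat, diffexp, io, sponge, structure
from evcirc.simulate import SimConfig, simulate_counts, simulate_detector_calls, simulate_sequences_and_sites

log = logging.getLogger("evcirc")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    outdir: str = "evcirc_out"
    sim: SimConfig = field(default_factory=SimConfig)
    contrasts: tuple[tuple[str, str], ...] = (("RR-MS", "HC"), ("SP-MS", "HC"), ("SP-MS", "RR-MS"))
    min_reads: int = 2
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    super_bs: int = 20
    density_lo: float = 0.01
    density_hi: float = 0.05
    dgnt_lo: float = 0.2
    dgnt_hi: float = 0.25
    #: cap on sequences folded with the built-in engine (ids sorted, first n).
    structure_max_seqs: int = 150
    k_shared: int = 5

    def validate(self) -> None:
        self.sim.validate()
        if min(self.min_reads, self.fc_threshold, self.p_threshold, self.super_bs) <= 0:
            raise ValueError("thresholds must be positive")
        levels = set(self.sim.groups)
        for a, b in self.contrasts:
            if a not in levels or b not in levels:
                raise ValueError(f"contrast ({a}, {b}) uses unknown group labels")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        for key in ("groups", "nb_mean_log_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        return cls(sim=SimConfig(**sim_raw), **raw)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("simulate")
def _simulate(cfg: PipelineConfig, inputs: Path):
    sim = cfg.sim
    circ_counts, linear_counts, truth = simulate_counts(sim)
    calls_a, calls_b = simulate_detector_calls(truth, circ_counts, sim)
    seqs, sites = simulate_sequences_and_sites(truth, sim)
    genes = truth.attrs["genes"]
    meta = sim.metadata()
    io.write_bed_calls(calls_a, inputs / "detector_A.bed")
    io.write_ciri_calls(calls_b, inputs / "detector_B.tsv")
    io.write_counts(linear_counts, inputs / "linear_counts.tsv")
    io.write_metadata(meta, inputs / "pools.tsv")
    io.write_gtf(genes, inputs / "annotation.gtf")
    io.write_fasta(seqs, inputs / "circ_sequences.fa")
    io.write_sites(sites, inputs / "mirna_sites.tsv")
    truth.to_csv(inputs / "truth.tsv", sep="\t")
    return meta


@_stage("catalog")
def _catalog(cfg: PipelineConfig, inputs: Path, meta: pd.DataFrame):
    calls_a = io.read_bed_calls(inputs / "detector_A.bed", list(meta.index))
    calls_b = io.read_ciri_calls(inputs / "detector_B.tsv")
    genes = io.read_gtf_genes(inputs / "annotation.gtf")
    catalog = cat.call_bona_fide(calls_a, calls_b, min_reads=cfg.min_reads)
    catalog = cat.assign_host_gene(catalog, genes)
    return catalog, genes


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and write a consolidated JSON + text report.

    Returns the summary dict; artifacts land under ``cfg.outdir``
    (``inputs/`` for the simulated source tables, ``results/`` for stage
    outputs, plus ``summary.json`` and ``report.txt``).
    """
    cfg.validate()
    out = Path(cfg.outdir)
    inputs = out / "inputs"
    results = out / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)

    log.info("simulating inputs (seed=%d)", cfg.sim.seed)
    meta = _simulate(cfg, inputs)
    pools = list(meta.index)

    log.info("building consensus catalog")
    catalog, genes = _catalog(cfg, inputs, meta)
    catalog.to_csv(results / "catalog.tsv", sep="\t")
    circ_counts = catalog[pools]
    linear_counts = io.read_counts(inputs / "linear_counts.tsv")

    per_gene, multiplicity_fracs = cat.circs_per_gene(catalog)
    abundance = {
        "circ": cat.abundance_bins(circ_counts).round(2).to_dict(),
        "linear": cat.abundance_bins(linear_counts).round(2).to_dict(),
    }

    venn = {}
    for a, b in cfg.contrasts:
        key = f"{a}_vs_{b}"
        venn[key] = {
            "circ": cat.comparison_stats(circ_counts, meta, a, b).to_dict(),
            "linear": cat.comparison_stats(linear_counts, meta, a, b).to_dict(),
        }

    log.info("typing transcripts")
    gene_biotypes = genes.set_index("gene_id")["biotype"]
    combined = pd.concat([circ_counts, linear_counts])
    categories = biotypes.classify_table(
        pd.concat([pd.Series("circRNA", index=circ_counts.index), gene_biotypes]),
        circ_ids=set(circ_counts.index),
    )
    dists = {g: biotypes.type_distribution(combined, categories, meta, g) for g in cfg.sim.groups}
    type_tables = {
        g: {
            "pct": d.percentages.round(2).to_dict(),
            "ncrna_pct": d.ncrna_percentages.round(2).to_dict(),
        }
        for g, d in dists.items()
    }
    type_tests = {}
    glist = list(cfg.sim.groups)
    for i, a in enumerate(glist):
        for b in glist[i + 1 :]:
            try:
                stat, p = biotypes.compare_distributions(dists[a], dists[b])
                type_tests[f"{a}_vs_{b}"] = {"chi2": round(stat, 3), "p": p}
            except biotypes.DistributionError:
                continue

    log.info("differential expression (%d contrasts)", len(cfg.contrasts))
    de_summaries = {}
    for a, b in cfg.contrasts:
        key = f"{a}_vs_{b}"
        design = diffexp.DesignSpec.from_metadata(meta, (a, b))
        de_summaries[key] = {}
        for kind, counts in (("circ", circ_counts), ("linear", linear_counts)):
            try:
                table = diffexp.nb_wald(counts, design)
                table, summary = diffexp.call_de(table, cfg.fc_threshold, cfg.p_threshold)
                excl = diffexp.call_exclusive(counts, meta, (a, b))
                full = pd.concat([table, excl])
                hosts = (
                    catalog["host_gene"]
                    if kind == "circ"
                    else genes.set_index("gene_id")["gene_name"]
                )
                candidates = diffexp.rank_candidates(full, k_shared=cfg.k_shared, host_genes=hosts)
                full.to_csv(results / f"de_{kind}_{key}.tsv", sep="\t")
                candidates.to_csv(results / f"candidates_{kind}_{key}.tsv", sep="\t", index=False)
                summary["n_exclusive_a"] = int((excl["call"] == f"exclusive-{a}").sum())
                summary["n_exclusive_b"] = int((excl["call"] == f"exclusive-{b}").sum())
                de_summaries[key][kind] = summary
            except Exception as exc:
                raise StageError(f"stage 'diffexp' failed ({kind}, {key}): {exc}") from exc

    log.info("sponge scoring")
    sites = io.read_sites(inputs / "mirna_sites.tsv")
    seqs = io.read_fasta(inputs / "circ_sequences.fa")
    lengths = pd.Series({cid: len(s) for cid, s in seqs.items()}, name="spliced_length")
    records = sponge.sponge_records(sites, lengths)
    records.to_csv(results / "sponge_records.tsv", sep="\t")
    sponge_summary = sponge.classify_sponges(records, cfg.super_bs, cfg.density_lo, cfg.density_hi)
    try:
        r, p = sponge.length_bs_correlation(records)
        sponge_summary["length_bs_pearson_r"] = round(r, 4)
        sponge_summary["length_bs_pearson_p"] = p
    except io.InputError:
        pass
    sponge_summary["median_spliced_length"] = float(lengths.median())

    log.info("structure scoring (built-in engine, up to %d sequences)", cfg.structure_max_seqs)
    fold_ids = sorted(set(seqs) & set(circ_counts.index))[: cfg.structure_max_seqs]
    srecords = structure.score_sequences(
        {cid: seqs[cid] for cid in fold_ids}, hi=cfg.dgnt_hi, lo=cfg.dgnt_lo
    )
    srecords.to_csv(results / "structure_records.tsv", sep="\t")
    class_counts = (
        srecords["structure_class"].value_counts().reindex(list(structure.CLASSES)).fillna(0)
    )
    structure_summary = {
        "n_scored": int(len(srecords)),
        "class_counts": class_counts.astype(int).to_dict(),
        "class_pct": (100.0 * class_counts / max(len(srecords), 1)).round(2).to_dict(),
    }
    # per-group distributions over circRNAs detected in each group's pools
    group_tables = {}
    for g in cfg.sim.groups:
        det = (circ_counts[meta.index[meta["status"] == g]] >= 1).any(axis=1)
        ids = [cid for cid in fold_ids if det.get(cid, False)]
        if ids:
            group_tables[g] = (
                srecords.loc[ids, "structure_class"]
                .value_counts()
                .reindex(list(structure.CLASSES))
                .fillna(0)
                .astype(int)
            )
    structure_tests = {}
    gl = [g for g in cfg.sim.groups if g in group_tables]
    for i, a in enumerate(gl):
        for b in gl[i + 1 :]:
            tab = pd.DataFrame({a: group_tables[a], b: group_tables[b]}).T
            tab = tab.loc[:, tab.sum(axis=0) > 0]
            if (tab.iloc[0] == tab.iloc[1]).all():
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = sps.chi2_contingency(tab.values, correction=False)
            structure_tests[f"{a}_vs_{b}"] = {"chi2": round(float(stat), 3), "p": float(p)}

    summary = {
        "config": {
            "seed": cfg.sim.seed,
            "n_pools": len(pools),
            "groups": list(cfg.sim.groups),
            "thresholds": {
                "min_reads": cfg.min_reads,
                "fc": cfg.fc_threshold,
                "p": cfg.p_threshold,
                "super_bs": cfg.super_bs,
                "density": [cfg.density_lo, cfg.density_hi],
                "neg_dG_per_nt": [cfg.dgnt_lo, cfg.dgnt_hi],
            },
        },
        "catalog": {
            "n_bona_fide": int(len(catalog)),
            "n_intergenic": int((catalog["host_gene"] == cat.INTERGENIC).sum()),
            "n_host_genes": int(per_gene.size),
            "max_circs_per_gene": int(per_gene.max()) if len(per_gene) else 0,
            "multiplicity_pct": multiplicity_fracs.round(2).to_dict(),
            "abundance_pct": abundance,
        },
        "venn": venn,
        "biotypes": {"distributions": type_tables, "tests": type_tests},
        "diffexp": de_summaries,
        "sponge": sponge_summary,
        "structure": {"overall": structure_summary, "tests": structure_tests},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_report(summary, out / "report.txt")
    return summary


def _write_report(summary: dict, path: Path) -> None:
    lines = ["evcirc pipeline report", "=" * 22, ""]
    c = summary["catalog"]
    lines += [
        f"bona fide circRNAs: {c['n_bona_fide']} ({c['n_intergenic']} intergenic, "
        f"{c['n_host_genes']} host genes, max {c['max_circs_per_gene']} circRNAs/gene)",
        "",
    ]
    for key, v in summary["venn"].items():
        circ = v["circ"]
        lines.append(
            f"{key} (circ): exclusive {circ['n_exclusive_a']} ({circ['pct_exclusive_a']}%) / "
            f"{circ['n_exclusive_b']} ({circ['pct_exclusive_b']}%), "
            f"shared {circ['n_shared']} ({circ['pct_shared']}%)"
        )
    lines.append("")
    for key, v in summary["diffexp"].items():
        s = v["circ"]
        lines.append(
            f"{key} (circ DE): {s['n_up']} up / {s['n_down']} down "
            f"({s['n_up_padj']}/{s['n_down_padj']} at adjusted p)"
        )
    sp = summary["sponge"]
    lines += [
        "",
        f"sponge: {sp['n_super_sponges']} super-sponges, "
        f"density classes {sp['density_class_counts']}",
        f"structure: {summary['structure']['overall']['class_pct']}",
        "",
    ]
    path.write_text("\n".join(lines))
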