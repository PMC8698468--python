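"""Synthetic pooled RNA-seq data emulating the plasma-EV study design.

The generator reproduces the statistical structure the downstream analyses
assume: twelve pools (4 RR-MS, 4 SP-MS, 4 HC; sex balanced within groups),
negative-binomial back-splice-junction and gene-level counts with planted
differential expression and group-exclusive transcripts, two detector call
sets with independent miss rates, spliced lengths with a configurable
median (386 bp for the EV compartment, 476 bp for leukocytes),
length-proportional miRNA binding sites, and spliced sequences engineered
to span the three -dG/nt structure classes.

All outputs are deterministic under a fixed seed. Ground truth is returned
alongside the data so recovery tests can be exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from evcirc.io import junction_id


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: structure-class mixture (highly structured, poorly structured) per
#: compartment; the remainder is the undetermined band. The EV mixture
#: reflects a cargo depleted of highly structured circRNAs relative to cells.
STRUCTURE_FRACS = {"ev": (0.22, 0.34), "cell": (0.35, 0.25)}

#: gene-biotype sampling weights for the toy annotation (linear genes).
BIOTYPE_WEIGHTS = {
    "protein_coding": 0.78,
    "lncRNA": 0.10,
    "misc_RNA": 0.04,
    "miRNA": 0.02,
    "snRNA": 0.02,
    "snoRNA": 0.015,
    "scaRNA": 0.005,
    "rRNA": 0.005,
    "Mt_tRNA": 0.005,
    "processed_pseudogene": 0.015,
}

_CONTIG_LEN = 5_000_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the pooled design: 4 pools per group for the three
    groups RR-MS / SP-MS / HC, sex alternating within each group so that a
    ~status + sex design stays estimable.
    """

    n_pools_per_group: int = 4
    groups: tuple[str, ...] = ("RR-MS", "SP-MS", "HC")
    n_circ: int = 400
    n_genes: int = 800
    #: log10 interval baseline NB means are drawn from (per pool).
    nb_mean_log_range: tuple[float, float] = (0.5, 2.5)
    #: NB dispersion alpha (var = mu + alpha mu^2), shared across transcripts.
    nb_dispersion: float = 0.1
    #: fraction of transcripts with a planted fold change (in groups[0]).
    frac_de: float = 0.1
    planted_lfc: float = 2.0
    #: fraction of transcripts exclusive to each group (structural zeros
    #: in every pool of the other groups).
    frac_exclusive_per_group: float = 0.05
    length_median_ev: float = 386.0
    length_median_cell: float = 476.0
    #: lognormal sigma of spliced lengths.
    length_sigma: float = 0.5
    compartment: str = "ev"
    detector_miss_rate_a: float = 0.1
    detector_miss_rate_b: float = 0.1
    #: expected binding sites per kb for the dominant miRNA of each circRNA.
    bs_per_kb: float = 8.0
    n_mirnas: int = 5
    frac_intergenic: float = 0.03
    #: if > 0, the first host gene is forced to carry exactly this many circRNAs.
    planted_multi_circ: int = 0
    #: append the CiRS-7 reference record (1485 nt, 70 miR-7 sites).
    spike_cirs7: bool = False
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_de": self.frac_de,
            "frac_exclusive_per_group": self.frac_exclusive_per_group,
            "detector_miss_rate_a": self.detector_miss_rate_a,
            "detector_miss_rate_b": self.detector_miss_rate_b,
            "frac_intergenic": self.frac_intergenic,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.n_pools_per_group < 1 or self.n_circ < 1 or self.n_genes < 1:
            raise ConfigError("n_pools_per_group, n_circ and n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.length_median_ev <= 0 or self.length_median_cell <= 0:
            raise ConfigError("length medians must be positive")
        if self.compartment not in STRUCTURE_FRACS:
            raise ConfigError(f"compartment must be one of {sorted(STRUCTURE_FRACS)}")
        if len(self.groups) < 1:
            raise ConfigError("at least one group is required")
        total_excl = self.frac_exclusive_per_group * len(self.groups) + self.frac_de
        if total_excl > 1.0:
            raise ConfigError("frac_de + per-group exclusive fractions exceed 1")

    @property
    def pools(self) -> list[str]:
        return [
            f"{g.replace('-', '')}_p{i + 1}"
            for g in self.groups
            for i in range(self.n_pools_per_group)
        ]

    def metadata(self) -> pd.DataFrame:
        """Per-pool status and sex; sex alternates M/F within each group."""
        status = [g for g in self.groups for _ in range(self.n_pools_per_group)]
        sex = ["M" if i % 2 == 0 else "F" for _ in self.groups for i in range(self.n_pools_per_group)]
        return pd.DataFrame({"status": status, "sex": sex}, index=pd.Index(self.pools, name="pool"))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# genome / annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Tile ``n_genes`` genes with gaps over a toy multi-contig genome."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    biotypes = list(BIOTYPE_WEIGHTS)
    weights = np.array(list(BIOTYPE_WEIGHTS.values()))
    weights = weights / weights.sum()
    rows = []
    contig_i, pos = 0, 10_000
    for i in range(cfg.n_genes):
        length = int(rng.integers(3_000, 30_000))
        gap = int(rng.integers(1_500, 6_000))
        if pos + length + gap > _CONTIG_LEN:
            contig_i += 1
            pos = 10_000
        rows.append(
            {
                "gene_id": f"GENE{i + 1:05d}",
                "gene_name": f"GENE{i + 1:05d}",
                "biotype": str(rng.choice(biotypes, p=weights)),
                "contig": f"chr{contig_i + 1}",
                "start": pos,
                "end": pos + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        pos += length + gap
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts + truth
# ---------------------------------------------------------------------------

def _plant_effects(n: int, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign a unique status per transcript: null, de (signed) or exclusive."""
    status = np.array(["null"] * n, dtype=object)
    lfc = np.zeros(n)
    target_group = np.array([""] * n, dtype=object)
    idx = rng.permutation(n)
    cursor = 0
    n_de = int(round(cfg.frac_de * n))
    de_idx = idx[cursor : cursor + n_de]
    cursor += n_de
    status[de_idx] = "de"
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc[de_idx] = signs * cfg.planted_lfc
    target_group[de_idx] = cfg.groups[0]
    n_excl = int(round(cfg.frac_exclusive_per_group * n))
    for g in cfg.groups:
        g_idx = idx[cursor : cursor + n_excl]
        cursor += n_excl
        status[g_idx] = "exclusive"
        target_group[g_idx] = g
    return pd.DataFrame({"status": status, "true_lfc": lfc, "target_group": target_group})


def _nb_draw(mu: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with mean mu and var mu + alpha mu^2."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, np.clip(p, 1e-12, 1.0))


def _simulate_matrix(
    ids: list[str], cfg: SimConfig, rng: np.random.Generator, mean_scale: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(ids)
    meta = cfg.metadata()
    pools = list(meta.index)
    lo, hi = cfg.nb_mean_log_range
    base = mean_scale * 10 ** rng.uniform(lo, hi, size=n)
    truth = _plant_effects(n, cfg, rng)
    truth.index = pd.Index(ids, name="transcript_id")
    mu = np.tile(base[:, None], (1, len(pools))).astype(float)
    group_of = meta["status"].to_numpy()
    for i in range(n):
        st = truth["status"].iloc[i]
        if st == "de":
            in_target = group_of == truth["target_group"].iloc[i]
            mu[i, in_target] *= 2.0 ** truth["true_lfc"].iloc[i]
        elif st == "exclusive":
            mu[i, group_of != truth["target_group"].iloc[i]] = 0.0
    counts = _nb_draw(mu, cfg.nb_dispersion, rng)
    counts[mu == 0.0] = 0  # structural zeros, not sampling zeros
    return pd.DataFrame(counts, index=truth.index, columns=pools), truth


def simulate_counts(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate circular and linear count matrices plus ground truth.

    Returns ``(circ_counts, linear_counts, truth)`` where ``truth`` carries one
    row per transcript (circular and linear) with its planted status
    (null / de / exclusive), signed true log2 fold change, target group,
    and — for circRNAs — junction coordinates, host gene, spliced length
    and target structure class.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 23])
    genes = simulate_annotation(cfg)

    # -- geometry: place each circRNA inside a host gene (or a gap) --------
    n = cfg.n_circ
    median = cfg.length_median_ev if cfg.compartment == "ev" else cfg.length_median_cell
    lengths = np.round(np.exp(np.log(median) + cfg.length_sigma * rng.standard_normal(n))).astype(int)
    lengths = np.maximum(lengths, 60)

    n_intergenic = int(round(cfg.frac_intergenic * n))
    host_idx = np.full(n, -1)
    genic = np.arange(n_intergenic, n)
    weights = rng.exponential(1.0, size=len(genes))
    weights /= weights.sum()
    host_idx[genic] = rng.choice(len(genes), size=len(genic), p=weights)
    if cfg.planted_multi_circ > 0:
        k = min(cfg.planted_multi_circ, len(genic))
        host_idx[genic[:k]] = 0

    contigs, starts, ends, strands, hosts = [], [], [], [], []
    for i in range(n):
        L = int(lengths[i])
        if host_idx[i] >= 0:
            g = genes.iloc[host_idx[i]]
            glen = g.end - g.start
            span = min(glen - 20, int(L * rng.uniform(1.0, 3.0)))
            span = max(span, 40)
            lengths[i] = min(L, span)
            offset = int(rng.integers(0, glen - span))
            contigs.append(g.contig)
            starts.append(int(g.start + offset))
            ends.append(int(g.start + offset + span))
            strands.append(g.strand)
            hosts.append(g.gene_name)
        else:
            # drop into the tail gap beyond the last gene of a contig
            contig = f"chr{int(rng.integers(1, genes['contig'].str[3:].astype(int).max() + 1))}"
            last_end = genes.loc[genes["contig"] == contig, "end"].max()
            span = int(L * rng.uniform(1.0, 2.0))
            s = int(last_end + 10_000 + rng.integers(0, 50_000))
            contigs.append(contig)
            starts.append(s)
            ends.append(s + span)
            strands.append("+" if rng.random() < 0.5 else "-")
            hosts.append("intergenic")

    circ_ids = [junction_id(c, s, e) for c, s, e in zip(contigs, starts, ends)]
    circ_counts, circ_truth = _simulate_matrix(circ_ids, cfg, rng)
    circ_truth["contig"] = contigs
    circ_truth["start"] = starts
    circ_truth["end"] = ends
    circ_truth["strand"] = strands
    circ_truth["host_gene"] = hosts
    circ_truth["spliced_length"] = lengths

    hs, ps = STRUCTURE_FRACS[cfg.compartment]
    classes = rng.choice(
        ["highly structured", "poorly structured", "undetermined"],
        size=n,
        p=[hs, ps, 1.0 - hs - ps],
    )
    circ_truth["structure_class"] = classes
    circ_truth["kind"] = "circ"

    gene_ids = list(genes["gene_id"])
    linear_counts, linear_truth = _simulate_matrix(gene_ids, cfg, rng, mean_scale=3.0)
    linear_truth["kind"] = "linear"

    truth = pd.concat([circ_truth, linear_truth])
    truth.attrs["genes"] = genes
    return circ_counts, linear_counts, truth


# ---------------------------------------------------------------------------
# detector call sets
# ---------------------------------------------------------------------------

def simulate_detector_calls(
    circ_truth: pd.DataFrame, circ_counts: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit two detector call tables with independent per-junction miss rates.

    Each true junction enters detector A with probability ``1 - miss_rate_a``
    and detector B independently with ``1 - miss_rate_b``; both tables share
    the junction key space and carry the true per-pool BSJ counts (detector B
    plays the quantification role downstream).
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 37])
    base = circ_truth.loc[circ_counts.index, ["contig", "start", "end", "strand"]].copy()
    base["start"] = base["start"].astype(int)
    base["end"] = base["end"].astype(int)
    for p in circ_counts.columns:
        base[p] = circ_counts[p].values
    in_a = rng.random(len(base)) >= cfg.detector_miss_rate_a
    in_b = rng.random(len(base)) >= cfg.detector_miss_rate_b
    return base.loc[in_a].reset_index(drop=True), base.loc[in_b].reset_index(drop=True)


# ---------------------------------------------------------------------------
# sequences and miRNA sites
# ---------------------------------------------------------------------------

_GC = np.array(list("GC"))
_COMP = {"G": "C", "C": "G", "A": "U", "U": "A"}


def _structured_sequence(length: int, target_score: float, rng: np.random.Generator) -> str:
    """Sequence whose maximum nested pairing is exactly round(target * length).

    A G/C stem of that size folds back on itself across a 3-nt loop; the
    remainder is adenine filler, which cannot pair with G or C, so the
    pair-count bound min(#G, #C) equals the stem size and the built-in
    folding engine recovers exactly ``stem`` pairs.
    """
    stem = int(round(target_score * length))
    stem = max(0, min(stem, (length - 3) // 2))
    half = "".join(rng.choice(_GC, size=stem))
    rc = "".join(_COMP[b] for b in reversed(half))
    seq = half + "AAA" + rc
    return seq + "A" * (length - len(seq))


_SCORE_RANGES = {
    "highly structured": (0.28, 0.42),
    "undetermined": (0.205, 0.245),
    "poorly structured": (0.02, 0.15),
}


def simulate_sequences_and_sites(
    circ_truth: pd.DataFrame, cfg: SimConfig
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate spliced sequences and a miRNA binding-site table.

    Sequences realize the per-circRNA target structure class by construction
    (see :func:`_structured_sequence`). Site counts for the dominant miRNA of
    each circRNA are Poisson with mean ``bs_per_kb * length / 1000``, giving
    the linear length/binding-site relationship observed for super-sponge
    catalogs; other miRNAs receive a small background rate.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 53])
    circ = circ_truth[circ_truth["kind"] == "circ"] if "kind" in circ_truth.columns else circ_truth
    seqs: dict[str, str] = {}
    rows = []
    mirnas = [f"miR-{i + 1}" for i in range(cfg.n_mirnas)]
    for cid, rec in circ.iterrows():
        L = int(rec["spliced_length"])
        lo, hi = _SCORE_RANGES[rec["structure_class"]]
        seqs[cid] = _structured_sequence(L, rng.uniform(lo, hi), rng)
        dom = int(rng.integers(0, cfg.n_mirnas))
        lam = cfg.bs_per_kb * L / 1000.0
        for j, m in enumerate(mirnas):
            n_sites = int(rng.poisson(lam if j == dom else 0.15 * lam))
            if n_sites > 0:
                rows.append({"circ_id": cid, "mirna_id": m, "n_sites": n_sites})
    if cfg.spike_cirs7:
        seqs["CiRS-7"] = _structured_sequence(1485, 0.22, rng)
        rows.append({"circ_id": "CiRS-7", "mirna_id": "miR-7", "n_sites": 70})
    sites = pd.DataFrame(rows, columns=["circ_id", "mirna_id", "n_sites"])
    return seqs, sites
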