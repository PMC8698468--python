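"""Twelve-category transcript typing and read-distribution comparison.

Every transcript maps to exactly one of twelve categories: protein coding,
lncRNA, pre-miRNA, miscellaneous RNA, snRNA, snoRNA, scaRNA, rRNA, tRNA,
circRNA, other RNA (pseudogenes, ribozymes, mitochondrial RNAs, ...) and
nondefined. Consensus circRNAs are category ``circRNA`` by definition,
regardless of their host gene's biotype; annotation biotype strings are
mapped through a shipped, editable table; anything unmapped is
``nondefined``. Group distributions are compared on read totals (sums of
per-pool mean counts per category) with a Pearson chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy import stats

CATEGORIES = (
    "protein coding",
    "lncRNA",
    "pre-miRNA",
    "miscellaneous RNA",
    "snRNA",
    "snoRNA",
    "scaRNA",
    "rRNA",
    "tRNA",
    "circRNA",
    "other RNA",
    "nondefined",
)

NONDEFINED = "nondefined"
CIRC = "circRNA"


class DistributionError(ValueError):
    """Not enough usable categories for a distribution comparison."""


def default_biotype_map() -> dict[str, str]:
    """The shipped biotype-string -> category mapping (editable TSV)."""
    with resources.files("evcirc.data").joinpath("biotype_map.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return dict(zip(table["biotype"], table["category"]))


def load_biotype_map(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["biotype"], table["category"]))


def classify(biotype: str, biotype_map: dict[str, str] | None = None, is_circ: bool = False) -> str:
    """Map one transcript to its category; circRNAs are definitional."""
    if is_circ:
        return CIRC
    mapping = default_biotype_map() if biotype_map is None else biotype_map
    return mapping.get(biotype, NONDEFINED)


def classify_table(
    transcript_biotypes: pd.Series,
    circ_ids: set[str] | None = None,
    biotype_map: dict[str, str] | None = None,
) -> pd.Series:
    """Vectorized classification of a transcript-id -> biotype series."""
    mapping = default_biotype_map() if biotype_map is None else biotype_map
    circ_ids = circ_ids or set()
    out = transcript_biotypes.map(lambda b: mapping.get(b, NONDEFINED))
    out[out.index.isin(circ_ids)] = CIRC
    return out.rename("category")


@dataclass(frozen=True)
class TypeDistribution:
    """Per-category read totals and percentages for one group of pools."""

    group: str
    totals: pd.Series  # indexed by the 12 categories

    @property
    def percentages(self) -> pd.Series:
        return 100.0 * self.totals / self.totals.sum()

    @property
    def ncrna_percentages(self) -> pd.Series:
        """Percentages out of non-protein-coding reads only."""
        nc = self.totals.drop("protein coding")
        return 100.0 * nc / nc.sum()


def type_distribution(
    counts: pd.DataFrame, categories: pd.Series, metadata: pd.DataFrame, group: str
) -> TypeDistribution:
    """Per-category totals of per-pool mean read counts within one group."""
    pools = metadata.index[metadata["status"] == group]
    if len(pools) == 0:
        raise DistributionError(f"group {group!r} has no pools")
    missing = counts.index.difference(categories.index)
    if len(missing) > 0:
        raise DistributionError(f"{len(missing)} transcripts lack a category")
    means = counts[pools].mean(axis=1)
    totals = means.groupby(categories.loc[counts.index].values).sum()
    totals = totals.reindex(list(CATEGORIES)).fillna(0.0)
    totals.index.name = "category"
    return TypeDistribution(group, totals)


def compare_distributions(dist1: TypeDistribution, dist2: TypeDistribution) -> tuple[float, float]:
    """Pearson chi-squared on the 2 x k table of rounded per-type read totals.

    Categories with zero total in both distributions are dropped; no
    continuity correction is applied.
    """
    table = pd.DataFrame({dist1.group: dist1.totals, dist2.group: dist2.totals}).round().astype(int)
    table = table.loc[(table.sum(axis=1) > 0)]
    if len(table) < 2:
        raise DistributionError("fewer than 2 usable categories")
    stat, p, _, _ = stats.chi2_contingency(table.T.values, correction=False)
    return float(stat), float(p)
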