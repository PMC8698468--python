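"""Bona fide circRNA catalog construction and set/abundance statistics.

A back-splice junction is accepted as a bona fide circRNA when it is found
by both detectors and supported by at least ``min_reads`` BSJ reads in some
pool of the quantifying detector. Junction equality requires an exact
coordinate and strand match after normalizing both call tables to 0-based
half-open coordinates; reports use 1-based inclusive ``chr:start-end`` ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from evcirc.io import JUNCTION_COLS, InputError, junction_id

INTERGENIC = "intergenic"

#: base-mean abundance bin edges (reads/sample); lower edges closed.
ABUNDANCE_EDGES = (0.0, 10.0, 50.0, 500.0, np.inf)
ABUNDANCE_LABELS = ("[0,10)", "[10,50)", "[50,500)", ">=500")


def _key_frame(calls: pd.DataFrame) -> pd.DataFrame:
    if not set(JUNCTION_COLS).issubset(calls.columns):
        raise InputError(f"call table requires columns {JUNCTION_COLS}")
    if (calls["start"] >= calls["end"]).any():
        raise InputError("call table contains start >= end; coordinates not normalizable")
    out = calls.copy()
    out.index = pd.Index(
        [
            (c, int(s), int(e), st)
            for c, s, e, st in zip(out["contig"], out["start"], out["end"], out["strand"])
        ],
        tupleize_cols=False,
    )
    if out.index.has_duplicates:
        raise InputError("duplicate junction keys within one detector's table")
    return out


def call_bona_fide(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, min_reads: int = 2
) -> pd.DataFrame:
    """Intersect two detector call sets and apply the per-pool support filter.

    Parameters
    ----------
    calls_a, calls_b:
        Normalized call tables (columns ``contig, start, end, strand`` plus
        one count column per pool). ``calls_b`` is the quantifying detector:
        the catalog carries its counts.
    min_reads:
        A junction is kept when its maximum per-pool BSJ count in the
        quantifying detector is at least this value ("at least two reads in
        a given pool" under the default).

    Returns
    -------
    DataFrame indexed by junction id with coordinate columns, per-pool
    counts, and a ``host_gene`` column initialized to the intergenic
    sentinel (see :func:`assign_host_gene`).
    """
    a = _key_frame(calls_a)
    b = _key_frame(calls_b)
    pools = [c for c in b.columns if c not in JUNCTION_COLS]
    common = b.loc[b.index.intersection(a.index)]
    if len(common) == 0:
        cat = common.copy()
    else:
        support = common[pools].max(axis=1)
        cat = common.loc[support >= min_reads].copy()
    cat.index = pd.Index(
        [junction_id(c, s, e) for c, s, e in zip(cat["contig"], cat["start"], cat["end"])],
        name="circ_id",
    )
    cat["host_gene"] = INTERGENIC
    return cat.sort_values(["contig", "start", "end"])


def assign_host_gene(catalog: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each circRNA to the same-strand gene containing its junction.

    A circRNA is assigned to a gene when its junction interval lies entirely
    within the gene body on the same strand; junctions contained in no gene
    stay ``intergenic``. When nested genes both contain the junction, the
    larger reciprocal overlap (i.e. the smaller containing gene) wins, with
    lexicographic gene id as the final tie-break.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    info = {}
    for row in genes.itertuples():
        trees.setdefault((row.contig, row.strand), IntervalTree()).addi(
            row.start, row.end, row.gene_id
        )
        info[row.gene_id] = (row.gene_name, row.end - row.start)
    out = catalog.copy()
    assigned = []
    for row in out.itertuples():
        tree = trees.get((row.contig, row.strand))
        best = None
        if tree is not None:
            span = row.end - row.start
            for iv in tree.overlap(row.start, row.end):
                if iv.begin <= row.start and iv.end >= row.end:
                    name, glen = info[iv.data]
                    # reciprocal overlap of a contained junction = span / gene length
                    cand = (span / glen, iv.data, name)
                    if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                        best = cand
        assigned.append(best[2] if best is not None else INTERGENIC)
    out["host_gene"] = assigned
    return out


def circs_per_gene(catalog: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-host-gene circRNA multiplicity and binned gene fractions.

    Returns ``(per_gene_counts, bin_fractions)`` where the bins are the
    multiplicity classes 1, 2-10 and >10 and fractions are percentages of
    host genes (intergenic circRNAs excluded from the denominator).
    """
    hosted = catalog.loc[catalog["host_gene"] != INTERGENIC, "host_gene"]
    per_gene = hosted.value_counts().sort_index()
    if len(per_gene) == 0:
        fracs = pd.Series([0.0, 0.0, 0.0], index=["1", "2-10", ">10"])
        return per_gene, fracs
    bins = pd.cut(per_gene, bins=[0, 1, 10, np.inf], labels=["1", "2-10", ">10"])
    fracs = bins.value_counts().reindex(["1", "2-10", ">10"]).fillna(0) / len(per_gene) * 100.0
    return per_gene, fracs


def abundance_bins(counts: pd.DataFrame) -> pd.Series:
    """Fractions of transcripts per base-mean bin ([0,10), [10,50), [50,500), >=500)."""
    if counts.shape[1] < 1:
        raise InputError("count matrix needs at least one pool")
    means = counts.mean(axis=1)
    binned = pd.cut(means, bins=list(ABUNDANCE_EDGES), labels=list(ABUNDANCE_LABELS), right=False)
    return binned.value_counts().reindex(list(ABUNDANCE_LABELS)).fillna(0) / len(means) * 100.0


@dataclass(frozen=True)
class ComparisonStats:
    """Group-exclusive / shared set sizes for one pairwise comparison.

    Percentages are computed over the union of transcripts detected in
    either group, matching the convention that each Venn percentage is
    taken out of the total number of transcripts in that comparison.
    """

    group_a: str
    group_b: str
    n_exclusive_a: int
    n_exclusive_b: int
    n_shared: int
    exclusive_a_ids: tuple[str, ...] = ()
    exclusive_b_ids: tuple[str, ...] = ()
    shared_ids: tuple[str, ...] = ()

    @property
    def n_union(self) -> int:
        return self.n_exclusive_a + self.n_exclusive_b + self.n_shared

    @property
    def pct_exclusive_a(self) -> float:
        return 100.0 * self.n_exclusive_a / self.n_union

    @property
    def pct_exclusive_b(self) -> float:
        return 100.0 * self.n_exclusive_b / self.n_union

    @property
    def pct_shared(self) -> float:
        return 100.0 * self.n_shared / self.n_union

    def swapped(self) -> "ComparisonStats":
        return ComparisonStats(
            self.group_b,
            self.group_a,
            self.n_exclusive_b,
            self.n_exclusive_a,
            self.n_shared,
            self.exclusive_b_ids,
            self.exclusive_a_ids,
            self.shared_ids,
        )

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_exclusive_a": self.n_exclusive_a,
            "n_exclusive_b": self.n_exclusive_b,
            "n_shared": self.n_shared,
            "pct_exclusive_a": round(self.pct_exclusive_a, 1),
            "pct_exclusive_b": round(self.pct_exclusive_b, 1),
            "pct_shared": round(self.pct_shared, 1),
        }


def comparison_stats(
    counts: pd.DataFrame, metadata: pd.DataFrame, group_a: str, group_b: str
) -> ComparisonStats:
    """Partition the detected union into exclusive-A / exclusive-B / shared.

    A transcript counts as detected in a group when it has at least one read
    in at least one of the group's pools. Transcripts detected in neither
    group do not enter the comparison.
    """
    pools_a = metadata.index[metadata["status"] == group_a]
    pools_b = metadata.index[metadata["status"] == group_b]
    if len(pools_a) == 0 or len(pools_b) == 0:
        raise InputError(f"group without pools in comparison {group_a} vs {group_b}")
    det_a = (counts[pools_a] >= 1).any(axis=1)
    det_b = (counts[pools_b] >= 1).any(axis=1)
    excl_a = counts.index[det_a & ~det_b]
    excl_b = counts.index[det_b & ~det_a]
    shared = counts.index[det_a & det_b]
    return ComparisonStats(
        group_a,
        group_b,
        len(excl_a),
        len(excl_b),
        len(shared),
        tuple(excl_a),
        tuple(excl_b),
        tuple(shared),
    )
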