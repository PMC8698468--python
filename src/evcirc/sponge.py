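"""miRNA-sponge potential scoring for circRNAs.

Two criteria are implemented: the classical "super-sponge" rule (more than
20 predicted binding sites for a single miRNA) and the refined binding-site
density, the maximum per-miRNA site count divided by the spliced length.
The validated sponge CiRS-7 anchors the density scale: 70 miR-7 sites over
1485 nt give a density of 0.05, while a density below 0.01 (fewer than one
site per 100 nt) marks negligible sponge potential.

Classification always uses the exact density ratio; the half-up 2-decimal
rounding exists only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from evcirc.io import InputError

SUPER_SPONGE_BS = 20  # strict: "more than 20" means >= 21
DENSITY_LO = 0.01
DENSITY_HI = 0.05

DENSITY_CLASSES = ("<0.01", "[0.01,0.05)", ">=0.05")


def max_bs(sites: pd.DataFrame, circ_id: str) -> tuple[str | None, int]:
    """Maximum per-miRNA binding-site count for one circRNA.

    Ties are broken by lexicographic miRNA id; a circRNA absent from the
    table has zero sites and no miRNA.
    """
    rows = sites.loc[sites["circ_id"] == circ_id]
    if len(rows) == 0:
        return None, 0
    per_mirna = rows.groupby("mirna_id")["n_sites"].sum().sort_index()
    best = per_mirna.idxmax()  # first index at the max -> lexicographic tie-break
    return str(best), int(per_mirna.loc[best])


def bs_density(max_bs_count: int, spliced_length: float) -> tuple[float, float]:
    """Binding-site density: exact ratio and its 2-dp half-up display value."""
    if spliced_length <= 0:
        raise InputError("spliced length must be positive")
    exact = max_bs_count / spliced_length
    display = float(Decimal(repr(exact)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return exact, display


def _density_class(exact: float, lo: float, hi: float) -> str:
    if exact >= hi:
        return ">=0.05"
    if exact >= lo:
        return "[0.01,0.05)"
    return "<0.01"


def sponge_records(sites: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Per-circRNA sponge scores for every circRNA in ``lengths``.

    Returns a table with the dominant miRNA, its site count, the exact and
    display densities, the super-sponge flag and the density class.
    """
    per = (
        sites.groupby(["circ_id", "mirna_id"])["n_sites"].sum().reset_index()
        if len(sites)
        else pd.DataFrame(columns=["circ_id", "mirna_id", "n_sites"])
    )
    rows = []
    grouped = {cid: g for cid, g in per.groupby("circ_id")}
    for cid, length in lengths.items():
        g = grouped.get(cid)
        if g is None:
            mirna, n = None, 0
        else:
            g = g.sort_values("mirna_id", kind="mergesort")
            # argmax on the id-sorted table -> lexicographic tie-break
            best = g.iloc[int(np.argmax(g["n_sites"].values))]
            mirna, n = str(best["mirna_id"]), int(best["n_sites"])
        exact, display = bs_density(n, float(length))
        rows.append(
            {
                "circ_id": cid,
                "spliced_length": float(length),
                "mirna_id": mirna,
                "max_bs": n,
                "density": exact,
                "density_display": display,
                "super_sponge": n > SUPER_SPONGE_BS,
                "density_class": _density_class(exact, DENSITY_LO, DENSITY_HI),
            }
        )
    columns = [
        "circ_id",
        "spliced_length",
        "mirna_id",
        "max_bs",
        "density",
        "density_display",
        "super_sponge",
        "density_class",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("circ_id")


def classify_sponges(
    records: pd.DataFrame,
    super_bs: int = SUPER_SPONGE_BS,
    density_lo: float = DENSITY_LO,
    density_hi: float = DENSITY_HI,
) -> dict:
    """Summary counts: super-sponges and density classes (exact ratios)."""
    classes = records["density"].map(lambda d: _density_class(d, density_lo, density_hi))
    counts = classes.value_counts().reindex(list(DENSITY_CLASSES)).fillna(0).astype(int)
    return {
        "n_records": int(len(records)),
        "n_super_sponges": int((records["max_bs"] > super_bs).sum()),
        "density_class_counts": counts.to_dict(),
        "n_candidate_density": int(counts["[0.01,0.05)"] + counts[">=0.05"]),
    }


def length_bs_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between spliced length and max binding sites."""
    if len(records) < 3:
        raise InputError("need at least 3 records for a correlation")
    x = records["spliced_length"].to_numpy(dtype=float)
    y = records["max_bs"].to_numpy(dtype=float)
    if np.allclose(x.var(), 0) or np.allclose(y.var(), 0):
        raise InputError("zero variance in lengths or binding-site counts")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class LengthComparison:
    set_a: str
    set_b: str
    median_a: float
    median_b: float
    ratio: float
    t_p: float
    ranksum_p: float


def length_summary(length_sets: dict[str, pd.Series | np.ndarray]) -> pd.DataFrame:
    """Medians and pairwise comparisons between labelled length sets.

    Each pair is compared with a two-sample t-test on log-transformed
    lengths (lengths are heavy tailed) and a Mann-Whitney rank-sum test as
    the distribution-free alternative; the median ratio (larger set first)
    is reported alongside.
    """
    labels = list(length_sets)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            xa = np.asarray(length_sets[a], dtype=float)
            xb = np.asarray(length_sets[b], dtype=float)
            if len(xa) == 0 or len(xb) == 0:
                raise InputError("length sets must be nonempty")
            med_a, med_b = float(np.median(xa)), float(np.median(xb))
            if np.array_equal(np.sort(xa), np.sort(xb)):
                t_p, u_p = 1.0, 1.0
            else:
                t_p = float(stats.ttest_ind(np.log(xa), np.log(xb), equal_var=False).pvalue)
                u_p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "median_a": med_a,
                    "median_b": med_b,
                    "median_ratio": med_a / med_b if med_b > 0 else np.inf,
                    "t_log_p": t_p,
                    "ranksum_p": u_p,
                }
            )
    return pd.DataFrame(rows)
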