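"""Length-normalized folding energy (-dG/nt) and structure classification.

A circRNA is classified from the magnitude of its minimum folding free
energy per nucleotide: highly structured when -dG/nt > 0.25, poorly
structured when -dG/nt < 0.2, and undetermined inside the closed band
[0.2, 0.25] (both printed thresholds are strict inequalities, so boundary
scores fall in the band).

Folding energies come from a pluggable engine. Production use ingests
externally computed thermodynamic energies from a TSV; the built-in engine
is a Nussinov-style base-pair maximizer (nested Watson-Crick and GU wobble
pairs, minimum hairpin loop of 3, no pseudoknots) that assigns -1 kcal/mol
per pair. It is explicitly non-thermodynamic — a self-contained scorer
that preserves the -dG/nt pipeline without an external folding tool — and
the engine identity is recorded in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from evcirc.io import InputError

HI_THRESHOLD = 0.25
LO_THRESHOLD = 0.2
MIN_LOOP = 3
PAIR_ENERGY = 1.0  # kcal/mol per base pair in the built-in engine

CLASSES = ("highly structured", "poorly structured", "undetermined")

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# allowed pairs: AU, UA, CG, GC, GU, UG
_PAIRABLE = np.zeros((4, 4), dtype=np.uint8)
for _a, _b in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIRABLE[_a, _b] = 1


def normalized_mfe(dG: float, length: float) -> float:
    """-dG/nt: folding free energy magnitude per nucleotide."""
    if length <= 0:
        raise InputError("spliced length must be positive")
    if dG > 0:
        raise InputError(
            "dG must be <= 0 (minimum free energies are non-positive; "
            "pass the signed energy, not its magnitude)"
        )
    return -dG / length


def classify_structure(score: float, hi: float = HI_THRESHOLD, lo: float = LO_THRESHOLD) -> str:
    """Classify a -dG/nt score; the closed band [lo, hi] is undetermined."""
    if score > hi:
        return "highly structured"
    if score < lo:
        return "poorly structured"
    return "undetermined"


def encode_sequence(sequence: str) -> np.ndarray:
    """Validate and encode an RNA/DNA sequence (T transparently mapped to U)."""
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise InputError(f"invalid base {exc.args[0]!r} in sequence") from None


def _nussinov_impl(codes, pairable, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            if pairable[codes[i], codes[j]]:
                inner = M[i + 1, j - 1] if j - 1 >= i + 1 else 0
                if inner + 1 > best:
                    best = inner + 1
            for k in range(i + min_loop + 1, j):
                if pairable[codes[i], codes[k]]:
                    left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    cand = left + 1 + (M[k + 1, j] if k + 1 <= j else 0)
                    if cand > best:
                        best = cand
            M[i, j] = best
    return M[0, n - 1]


try:  # JIT-compile the O(n^3) recursion when numba is available
    from numba import njit

    _nussinov = njit(cache=False)(_nussinov_impl)
except ImportError:  # pragma: no cover
    _nussinov = _nussinov_impl


def fold_energy(sequence: str, pair_energy: float = PAIR_ENERGY) -> float:
    """Built-in folding engine: -(pair_energy x maximum nested base pairs).

    Maximizes nested Watson-Crick/GU pairs with a minimum hairpin loop of
    ``MIN_LOOP`` unpaired bases and returns the pair count as a pseudo free
    energy (kcal/mol, <= 0).
    """
    if len(sequence) < 4:
        raise InputError("sequence must be at least 4 nt")
    codes = encode_sequence(sequence)
    pairs = int(_nussinov(codes, _PAIRABLE, MIN_LOOP))
    return -pair_energy * pairs


def score_sequences(
    sequences: dict[str, str],
    external_energies: pd.DataFrame | None = None,
    hi: float = HI_THRESHOLD,
    lo: float = LO_THRESHOLD,
) -> pd.DataFrame:
    """StructureRecord table for a set of spliced sequences.

    When ``external_energies`` (columns ``circ_id, dG``) is given those
    energies are used unchanged (external engine); otherwise each sequence
    is folded with the built-in pair-maximization engine. The ``engine``
    column records which one produced each energy.
    """
    ext = (
        external_energies.set_index("circ_id")["dG"]
        if external_energies is not None
        else pd.Series(dtype=float)
    )
    rows = []
    for cid, seq in sequences.items():
        if cid in ext.index:
            dG, engine = float(ext.loc[cid]), "external"
        else:
            dG, engine = fold_energy(seq), "builtin-pairmax"
        score = normalized_mfe(dG, len(seq))
        rows.append(
            {
                "circ_id": cid,
                "spliced_length": len(seq),
                "dG": dG,
                "neg_dG_per_nt": score,
                "structure_class": classify_structure(score, hi=hi, lo=lo),
                "engine": engine,
            }
        )
    return pd.DataFrame(rows).set_index("circ_id")


def structure_distribution(
    records: pd.DataFrame, group_labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group class fractions and pairwise chi-squared comparisons.

    ``group_labels`` maps circ ids to group names. Returns the fraction
    table (percent, groups x classes) and a table of pairwise chi-squared
    statistics/p-values on the class counts.
    """
    labels = group_labels.reindex(records.index)
    counts = (
        records.assign(group=labels.values)
        .groupby("group")["structure_class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CLASSES), fill_value=0)
    )
    if (counts.sum(axis=1) == 0).any() or labels.isna().any():
        raise InputError("every group needs at least one classified record")
    fractions = counts.div(counts.sum(axis=1), axis=0) * 100.0
    groups = list(counts.index)
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            table = counts.loc[[a, b]]
            table = table.loc[:, table.sum(axis=0) > 0]
            if (table.loc[a] == table.loc[b]).all():
                stat, p = 0.0, 1.0
            else:
                stat, p, _, _ = stats.chi2_contingency(table.values, correction=False)
            rows.append({"group_a": a, "group_b": b, "chi2": float(stat), "pvalue": float(p)})
    return fractions, pd.DataFrame(rows)
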