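import numpy as np
import pandas as pd
import pytest

from evcirc.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured simulated study (12 pools, 3 groups)."""
    cfg = SimConfig(n_circ=120, n_genes=240, seed=11)
    circ_counts, linear_counts, truth = simulate_counts(cfg)
    return cfg, circ_counts, linear_counts, truth


def make_calls(junctions, pool_counts):
    """Build a normalized call table from (contig, start, end, strand) tuples."""
    rows = []
    n_pools = max((len(c) for c in pool_counts), default=3)
    for (contig, start, end, strand), counts in zip(junctions, pool_counts):
        row = {"contig": contig, "start": start, "end": end, "strand": strand}
        row.update({f"p{i + 1}": c for i, c in enumerate(counts)})
        rows.append(row)
    columns = ["contig", "start", "end", "strand"] + [f"p{i + 1}" for i in range(n_pools)]
    return pd.DataFrame(rows, columns=columns)


def brute_force_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Exhaustive enumeration of nested pairings (independent folding oracle).

    Recursively enumerates every nested matching with Watson-Crick/GU pairs
    and hairpin loops of at least ``min_loop`` unpaired bases, returning the
    maximum pair count. Exponential; for short sequences only.
    """
    seq = sequence.upper().replace("T", "U")
    allowed = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

    def best(i, j):
        if j - i <= min_loop:
            return 0
        top = best(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in allowed:
                top = max(top, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return top

    return best(0, len(seq) - 1)
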