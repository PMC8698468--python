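"""Readers and writers for the tabular formats the pipeline consumes.

Coordinate conventions
----------------------
Detector call tables come in two flavours: BED-style tables (find_circ-like)
are 0-based half-open, while CIRI2-style TSV tables are 1-based inclusive.
Internally every junction is normalized to 0-based half-open coordinates;
reports render junction ids as 1-based inclusive ``chr:start-end`` strings,
the convention used for circRNA identifiers in the literature.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class InputError(ValueError):
    """Malformed or inconsistent input table."""


JUNCTION_COLS = ["contig", "start", "end", "strand"]


def junction_id(contig: str, start0: int, end0: int) -> str:
    """Render a 0-based half-open interval as a 1-based inclusive id."""
    return f"{contig}:{start0 + 1}-{end0}"


def parse_junction_id(jid: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive ``chr:start-end`` id to 0-based half-open."""
    m = re.fullmatch(r"(.+):(\d+)-(\d+)", jid)
    if m is None:
        raise InputError(f"unparseable junction id: {jid!r}")
    contig, s1, e1 = m.group(1), int(m.group(2)), int(m.group(3))
    return contig, s1 - 1, e1


# ---------------------------------------------------------------------------
# detector call tables
# ---------------------------------------------------------------------------

def write_bed_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write detector calls as BED6+ (0-based half-open, per-pool count columns)."""
    pools = [c for c in calls.columns if c not in JUNCTION_COLS]
    out = pd.DataFrame(
        {
            "chrom": calls["contig"],
            "chromStart": calls["start"].astype(int),
            "chromEnd": calls["end"].astype(int),
            "name": [junction_id(c, s, e) for c, s, e in zip(calls["contig"], calls["start"], calls["end"])],
            "score": calls[pools].sum(axis=1).astype(int),
            "strand": calls["strand"],
        }
    )
    for p in pools:
        out[p] = calls[p].astype(int).values
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed_calls(path: str | Path, pool_names: list[str]) -> pd.DataFrame:
    """Read a BED6+ detector table; columns 7+ are per-pool BSJ read counts."""
    names = ["chrom", "chromStart", "chromEnd", "name", "score", "strand"] + list(pool_names)
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    if (df["chromStart"] >= df["chromEnd"]).any():
        raise InputError("BED call table contains start >= end")
    calls = pd.DataFrame(
        {
            "contig": df["chrom"].astype(str),
            "start": df["chromStart"].astype(int),
            "end": df["chromEnd"].astype(int),
            "strand": df["strand"].astype(str),
        }
    )
    for p in pool_names:
        calls[p] = df[p].astype(int).values
    return calls


def write_ciri_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write detector calls as a CIRI2-style TSV (1-based inclusive, header)."""
    pools = [c for c in calls.columns if c not in JUNCTION_COLS]
    out = pd.DataFrame(
        {
            "circRNA_ID": [
                f"{c}:{s + 1}|{e}" for c, s, e in zip(calls["contig"], calls["start"], calls["end"])
            ],
            "chr": calls["contig"],
            "circRNA_start": calls["start"].astype(int) + 1,
            "circRNA_end": calls["end"].astype(int),
            "strand": calls["strand"],
        }
    )
    for p in pools:
        out[p] = calls[p].astype(int).values
    out.to_csv(path, sep="\t", index=False)


def read_ciri_calls(path: str | Path) -> pd.DataFrame:
    """Read a CIRI2-style TSV and normalize to 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t")
    required = {"chr", "circRNA_start", "circRNA_end", "strand"}
    if not required.issubset(df.columns):
        raise InputError(f"CIRI2-style table missing columns {sorted(required - set(df.columns))}")
    pools = [c for c in df.columns if c not in {"circRNA_ID", "chr", "circRNA_start", "circRNA_end", "strand"}]
    calls = pd.DataFrame(
        {
            "contig": df["chr"].astype(str),
            "start": df["circRNA_start"].astype(int) - 1,
            "end": df["circRNA_end"].astype(int),
            "strand": df["strand"].astype(str),
        }
    )
    if (calls["start"] >= calls["end"]).any():
        raise InputError("CIRI2-style table contains start >= end after normalization")
    for p in pools:
        calls[p] = df[p].astype(int).values
    return calls


# ---------------------------------------------------------------------------
# count matrices, metadata, miRNA-site and energy tables
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="transcript_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="pool")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if not {"status", "sex"}.issubset(meta.columns):
        raise InputError("pool metadata requires 'status' and 'sex' columns")
    return meta


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_sites(path: str | Path) -> pd.DataFrame:
    sites = pd.read_csv(path, sep="\t")
    if not {"circ_id", "mirna_id", "n_sites"}.issubset(sites.columns):
        raise InputError("site table requires columns circ_id, mirna_id, n_sites")
    return sites


def write_energies(energies: pd.DataFrame, path: str | Path) -> None:
    energies.to_csv(path, sep="\t", index=False)


def read_energies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"circ_id", "dG"}.issubset(df.columns):
        raise InputError("energy table requires columns circ_id, dG")
    return df


# ---------------------------------------------------------------------------
# annotation (GTF) and sequences (FASTA)
# ---------------------------------------------------------------------------

def write_gtf(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene records (0-based half-open in memory) as GTF (1-based inclusive).

    ``genes`` needs columns gene_id, gene_name, biotype, contig, start, end,
    strand.
    """
    with open(path, "w") as fh:
        for row in genes.itertuples():
            attrs = (
                f'gene_id "{row.gene_id}"; gene_name "{row.gene_name}"; '
                f'gene_biotype "{row.biotype}";'
            )
            fh.write(
                f"{row.contig}\tevcirc\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Read gene records from a GTF into a 0-based half-open gene table."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            id_spec={"gene": "gene_id"},
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # malformed annotation
        raise InputError(f"failed to parse GTF {path}: {exc}") from exc
    rows = []
    for g in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": g.id,
                "gene_name": (g.attributes.get("gene_name") or [g.id])[0],
                "biotype": (g.attributes.get("gene_biotype") or ["nondefined"])[0],
                "contig": g.seqid,
                "start": g.start - 1,
                "end": g.end,
                "strand": g.strand,
            }
        )
    return pd.DataFrame(rows)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
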