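"""Readers and writers for the plain-text formats exchanged by the pipeline.

Formats
-------
sync
    popoolation2 interchange format for pooled allele counts: one line per
    site, tab-separated ``contig  pos  ref  A:T:C:G:N:del [A:T:C:G:N:del ...]``
    with one colon-separated count column per pool.  Positions are 1-based.
    Counts are strandless.
BED
    Gene models as BED4+ (``contig  start  end  gene_id [gc_content]``),
    0-based half-open intervals.  An optional ``sequence`` column may be
    given instead of ``gc_content``, in which case GC fraction is computed
    from it.
TSV
    Site classes, gene classes, term maps, expression tables and every
    output table.  Missing values are encoded as ``NA``.

Coordinate conventions are converted at this boundary only: BED intervals
are 0-based half-open, sync and site-class positions are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: order of the colon-separated count fields in a sync column
SYNC_BASES = ("A", "T", "C", "G", "N", "del")

SITE_CLASSES = ("NS", "SYN", "OTHER")


class SyncFormatError(ValueError):
    """Raised when a sync line violates the format (with its line number)."""


@dataclass(frozen=True)
class SyncRecord:
    """One site of pooled read counts.

    ``counts`` has shape (n_pools, 6) in :data:`SYNC_BASES` order; every
    entry is a non-negative integer and ``pos`` is 1-based.
    """

    contig: str
    pos: int
    ref_base: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise ValueError("counts must have shape (n_pools, 6)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_pools(self) -> int:
        return self.counts.shape[0]


def _parse_count_field(field: str, lineno: int) -> list[int]:
    parts = field.split(":")
    if len(parts) != 6:
        raise SyncFormatError(
            f"line {lineno}: expected 6 colon-separated counts, got "
            f"{len(parts)} in field {field!r}"
        )
    try:
        vals = [int(p) for p in parts]
    except ValueError as exc:
        raise SyncFormatError(f"line {lineno}: non-integer count in {field!r}") from exc
    if any(v < 0 for v in vals):
        raise SyncFormatError(f"line {lineno}: negative count in {field!r}")
    return vals


def read_sync(
    path: str | Path,
    pool_sizes: Sequence[int] | None = None,
) -> Iterator[SyncRecord]:
    """Stream validated :class:`SyncRecord` objects from a sync file.

    Parameters
    ----------
    path
        Path to a popoolation2-style sync file.
    pool_sizes
        Haploid pool sizes, one per expected count column.  When given, the
        number of count columns on every line must match ``len(pool_sizes)``.

    Raises
    ------
    SyncFormatError
        On a malformed line, naming its line number.
    """
    path = Path(path)
    expected = len(pool_sizes) if pool_sizes is not None else None
    n_records = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncFormatError(
                    f"line {lineno}: expected at least 4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            contig, pos_s, ref = fields[0], fields[1], fields[2]
            count_fields = fields[3:]
            if expected is not None and len(count_fields) != expected:
                raise SyncFormatError(
                    f"line {lineno}: expected {expected} pool columns, "
                    f"got {len(count_fields)}"
                )
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SyncFormatError(f"line {lineno}: bad position {pos_s!r}") from exc
            if pos < 1:
                raise SyncFormatError(f"line {lineno}: position must be >= 1")
            counts = np.array(
                [_parse_count_field(f, lineno) for f in count_fields], dtype=np.int64
            )
            n_records += 1
            yield SyncRecord(contig=contig, pos=pos, ref_base=ref, counts=counts)
    if n_records == 0:
        logger.warning("sync file %s contained no records", path)


def write_sync(records: Iterable[SyncRecord], path: str | Path) -> None:
    """Write records to ``path`` in sync format (inverse of :func:`read_sync`)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            cols = "\t".join(":".join(str(int(c)) for c in row) for row in rec.counts)
            fh.write(f"{rec.contig}\t{rec.pos}\t{rec.ref_base}\t{cols}\n")


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def read_gene_annotation(
    bed_path: str | Path,
    siteclass_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene models (BED) and the per-site class table (TSV).

    Returns
    -------
    genes : DataFrame
        Columns ``gene_id, contig, start, end, length, gc_content`` indexed
        0..n-1.  ``start/end`` are 0-based half-open.
    site_classes : DataFrame
        Columns ``contig, pos, gene_id, site_class`` with ``pos`` 1-based.
        Sites falling outside their gene's interval are dropped with a
        warning; a duplicated gene_id in the BED is an error.
    """
    genes = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
    )
    if genes.shape[1] < 4:
        raise ValueError("gene BED must have at least 4 columns (BED4)")
    genes = genes.rename(
        columns={0: "contig", 1: "start", 2: "end", 3: "gene_id"}
    )
    if genes.shape[1] >= 5:
        extra = genes[4]
        if extra.dtype == object and extra.astype(str).str.fullmatch(r"[ACGTNacgtn]+").all():
            genes["gc_content"] = extra.astype(str).map(_gc_fraction)
        else:
            genes["gc_content"] = pd.to_numeric(extra)
    else:
        genes["gc_content"] = np.nan
    genes = genes[["gene_id", "contig", "start", "end", "gc_content"]].copy()
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene_id in BED: {list(dups)[:5]}")
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("BED interval with start >= end")
    genes["length"] = genes["end"] - genes["start"]
    bad_gc = genes["gc_content"].dropna()
    if ((bad_gc < 0) | (bad_gc > 1)).any():
        raise ValueError("gc_content outside [0, 1]")

    sc = pd.read_csv(siteclass_path, sep="\t", dtype={"contig": str, "gene_id": str})
    required = {"contig", "pos", "gene_id", "site_class"}
    if not required.issubset(sc.columns):
        raise ValueError(f"site-class table must have columns {sorted(required)}")
    if not sc["site_class"].isin(SITE_CLASSES).all():
        bad = sorted(set(sc["site_class"]) - set(SITE_CLASSES))
        raise ValueError(f"unknown site classes: {bad}")
    unknown = set(sc["gene_id"]) - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"site-class table names unknown genes: {sorted(unknown)[:5]}")

    merged = sc.merge(
        genes[["gene_id", "contig", "start", "end"]],
        on="gene_id",
        suffixes=("", "_gene"),
    )
    # 1-based pos p lies in [start, end) iff start < p <= end
    inside = (
        (merged["contig"] == merged["contig_gene"])
        & (merged["pos"] > merged["start"])
        & (merged["pos"] <= merged["end"])
    )
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.warning(
            "dropping %d site-class entries outside their gene interval", n_dropped
        )
    sc = merged.loc[inside, ["contig", "pos", "gene_id", "site_class"]].reset_index(
        drop=True
    )
    return genes.reset_index(drop=True), sc


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write a gene-model table back to BED4+1 (gc_content as 5th column)."""
    out = genes[["contig", "start", "end", "gene_id", "gc_content"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table to TSV with ``NA`` for missing values.

    Column order is preserved as given (deterministic); the file round-trips
    through :func:`read_table` to an equal frame.
    """
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (``NA`` -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


# write_gene_stats / read_gene_stats are thin, named aliases so downstream
# code reads naturally at call sites.
write_gene_stats = write_table
read_gene_stats = read_table


def read_gene_classes(path: str | Path) -> pd.DataFrame:
    """Read a long-format gene-class membership table.

    Expected columns: ``gene_id, label`` (one row per membership).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "label"}.issubset(df.columns):
        raise ValueError("gene-class table must have columns gene_id, label")
    return df


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a GO-style term map TSV (columns ``term_id, gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"term_id", "gene_id"}.issubset(df.columns):
        raise ValueError("term map must have columns term_id, gene_id")
    return {t: set(g["gene_id"]) for t, g in df.groupby("term_id")}


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression table (``gene_id, fpkm, log2fc_sex, bias_class``).

    ``log2fc_sex`` follows the female-minus-male convention: positive values
    are female-biased.  ``bias_class`` must be FBG, MBG or UNBIASED.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"gene_id", "fpkm", "log2fc_sex", "bias_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")
    if (df["fpkm"].dropna() < 0).any():
        raise ValueError("fpkm must be non-negative")
    bad = set(df["bias_class"].dropna()) - {"FBG", "MBG", "UNBIASED"}
    if bad:
        raise ValueError(f"unknown bias_class values: {sorted(bad)}")
    return df
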