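"""Readers and writers for the formats the scan touches.

Per-sample methylation call tables (MethylDackel-style bedGraph or a
generic four-column TSV), reference FASTA for CG/CHG/CHH context
assignment, BED/GFF3 feature annotations, Hi-C style segmentation
tables, and per-site result tracks.

All coordinates are 0-based, half-open internally and in every output;
GFF3 input (1-based, closed) is converted on read, and that conversion
is the only place +/-1 arithmetic occurs.  Chromosome names are matched
as exact text (no "chr" aliasing).
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DIALECTS",
    "ParseError",
    "IndexRequiredError",
    "MethylationTableHandle",
    "read_methylation_table",
    "write_methylation_table",
    "ContextMap",
    "assign_context",
    "read_features",
    "read_segmentation",
    "write_segmentation",
    "write_site_stats",
    "read_site_stats",
]

DIALECTS = ("methyldackel_bedgraph", "generic_tsv")

#: Columns of an in-memory methylation table.
TABLE_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]

_SITE_STAT_FLOATS = ["met", "jsd", "h_mix", "h_avg"]


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line."""


class IndexRequiredError(ValueError):
    """Region query requested on input that is not sorted/indexed."""


@dataclasses.dataclass(frozen=True)
class MethylationTableHandle:
    """A per-sample methylation table on disk."""

    sample_id: str
    path: str
    dialect: str = "methyldackel_bedgraph"
    indexed: bool = False

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}")


def _is_sorted(df: pd.DataFrame) -> bool:
    """Rows grouped by chromosome (no revisits) with non-decreasing pos."""
    chroms = df["chrom"].to_numpy()
    if len(chroms) == 0:
        return True
    change = np.flatnonzero(chroms[1:] != chroms[:-1])
    seen_blocks = len(change) + 1
    if len(pd.unique(chroms)) != seen_blocks:
        return False
    pos = df["pos"].to_numpy()
    same = chroms[1:] == chroms[:-1]
    return bool(np.all(pos[1:][same] >= pos[:-1][same]))


def read_methylation_table(source, dialect: str | None = None, region=None) -> pd.DataFrame:
    """Read one methylation table into a DataFrame.

    Parameters
    ----------
    source
        A path or a :class:`MethylationTableHandle`.
    dialect
        ``"methyldackel_bedgraph"`` (chrom, 0-based start, end,
        percentage, methylated count, unmethylated count; the percentage
        column is ignored because the counts are authoritative) or
        ``"generic_tsv"`` (chrom, 0-based position, methylated count,
        unmethylated count).  Taken from the handle when given there.
    region
        Optional ``(chrom, start, end)`` half-open interval.  For a
        bgzip-compressed, tabix-indexed file (``.gz`` path) the query
        uses the index; plain text is scanned and filtered, which
        requires the file to be coordinate-sorted.

    Returns a DataFrame with columns chrom, pos, n_meth, n_unmeth in
    file order.
    """
    if isinstance(source, MethylationTableHandle):
        path, dialect = source.path, dialect or source.dialect
    else:
        path = os.fspath(source)
    if dialect is None:
        dialect = "methyldackel_bedgraph"
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    if region is not None and str(path).endswith(".gz"):
        return _read_tabix(path, dialect, region)

    ncols = 6 if dialect == "methyldackel_bedgraph" else 4
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            skiprows=_count_track_lines(path),
            dtype=str,
        )
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(ncols))
    if len(raw.columns) < ncols and len(raw):
        raise ParseError(f"{path}: expected {ncols} columns for dialect {dialect!r}, "
                         f"found {len(raw.columns)}")

    if dialect == "methyldackel_bedgraph":
        df = pd.DataFrame({
            "chrom": raw[0].astype(str) if len(raw) else pd.Series(dtype=str),
            "pos": _int_col(raw, 1, path),
            "n_meth": _int_col(raw, 4, path),
            "n_unmeth": _int_col(raw, 5, path),
        })
        end = _int_col(raw, 2, path)
        bad = np.flatnonzero(end.to_numpy() != df["pos"].to_numpy() + 1)
        if bad.size:
            raise ParseError(f"{path}: line {_line_no(path, bad[0])}: "
                             "bedGraph interval is not a single base")
    else:
        df = pd.DataFrame({
            "chrom": raw[0].astype(str) if len(raw) else pd.Series(dtype=str),
            "pos": _int_col(raw, 1, path),
            "n_meth": _int_col(raw, 2, path),
            "n_unmeth": _int_col(raw, 3, path),
        })
    if len(df) and (df[["n_meth", "n_unmeth"]].to_numpy() < 0).any():
        raise ParseError(f"{path}: negative read count")

    if region is not None:
        if not _is_sorted(df):
            raise IndexRequiredError(
                f"{path}: region query on unsorted input; index required "
                "(sort the table or supply a tabix-indexed .gz file)")
        chrom, start, end_ = region
        df = df[(df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end_)]
        df = df.reset_index(drop=True)
    return df


def _count_track_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                n += 1
            else:
                break
    return n


def _line_no(path, data_row: int) -> int:
    """1-based file line number of a 0-based data row (skipping headers)."""
    offset = _count_track_lines(path)
    with open(path) as fh:
        seen = 0
        for i, line in enumerate(fh, start=1):
            if i <= offset or line.startswith("#"):
                continue
            if seen == data_row:
                return i
            seen += 1
    return data_row + offset + 1


def _int_col(raw: pd.DataFrame, col: int, path) -> pd.Series:
    if not len(raw):
        return pd.Series(dtype=np.int64)
    try:
        return pd.to_numeric(raw[col], errors="raise").astype(np.int64)
    except (ValueError, TypeError):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = np.flatnonzero(numeric.isna().to_numpy())
        row = bad[0] if bad.size else 0
        raise ParseError(
            f"{path}: line {_line_no(path, row)}: malformed value "
            f"{raw[col].iloc[row]!r} in column {col + 1}") from None


def _read_tabix(path, dialect, region) -> pd.DataFrame:
    import pysam  # deferred: only needed for indexed access

    chrom, start, end = region
    rows = []
    with pysam.TabixFile(str(path)) as tbx:
        try:
            it = tbx.fetch(chrom, start, end)
        except ValueError:
            it = iter(())
        for line in it:
            f = line.rstrip("\n").split("\t")
            if dialect == "methyldackel_bedgraph":
                rows.append((f[0], int(f[1]), int(f[4]), int(f[5])))
            else:
                rows.append((f[0], int(f[1]), int(f[2]), int(f[3])))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_methylation_table(df: pd.DataFrame, path, dialect: str = "methyldackel_bedgraph",
                            track_line: bool = True) -> None:
    """Write a methylation table in the requested dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "methyldackel_bedgraph":
            if track_line:
                fh.write('track type="bedGraph" description="methylation levels"\n')
            n = df["n_meth"] + df["n_unmeth"]
            pct = np.where(n > 0, np.round(100.0 * df["n_meth"] / np.maximum(n, 1)), 0)
            for chrom, pos, m, u, p in zip(df["chrom"], df["pos"], df["n_meth"],
                                           df["n_unmeth"], pct.astype(int)):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{p}\t{m}\t{u}\n")
        else:
            for chrom, pos, m, u in zip(df["chrom"], df["pos"], df["n_meth"], df["n_unmeth"]):
                fh.write(f"{chrom}\t{pos}\t{m}\t{u}\n")


# ---------------------------------------------------------------------------
# sequence context

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_H = frozenset("ACT")


def assign_context(seq: str, pos: int, strand: str | None = None) -> str | None:
    """Sequence context (CG / CHG / CHH) of the cytosine at ``pos``.

    ``strand`` may be "+", "-", or None to infer it from the base (C on
    the forward strand, G marking a reverse-strand cytosine).  Returns
    None for non-cytosine positions and for cytosines too close to a
    sequence end (or next to an ambiguous base) to be resolved.  A CG
    call needs only one downstream base and is resolvable at the
    penultimate position.
    """
    if pos < 0 or pos >= len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    base = seq[pos].upper()
    if strand is None:
        if base == "C":
            strand = "+"
        elif base == "G":
            strand = "-"
        else:
            return None
    if strand == "+":
        if base != "C":
            return None
        b1 = seq[pos + 1].upper() if pos + 1 < len(seq) else ""
        if b1 == "G":
            return "CG"
        if b1 in _H:
            b2 = seq[pos + 2].upper() if pos + 2 < len(seq) else ""
            if b2 == "G":
                return "CHG"
            if b2 in _H:
                return "CHH"
        return None
    if strand == "-":
        if base != "G":
            return None
        b1 = seq[pos - 1].upper().translate(_COMPLEMENT) if pos >= 1 else ""
        if b1 == "G":
            return "CG"
        if b1 in _H:
            b2 = seq[pos - 2].upper().translate(_COMPLEMENT) if pos >= 2 else ""
            if b2 == "G":
                return "CHG"
            if b2 in _H:
                return "CHH"
        return None
    raise ValueError(f"strand must be '+', '-' or None, got {strand!r}")


class ContextMap:
    """Per-position CG/CHG/CHH assignment backed by reference sequences."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ContextMap":
        from pyfaidx import Fasta

        with Fasta(str(path)) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def context_at(self, chrom: str, pos: int, strand: str | None = None) -> str | None:
        return assign_context(self._seqs[chrom], pos, strand)

    def annotate(self, chrom, pos) -> np.ndarray:
        """Vectorized context lookup; unknown/non-C positions map to "unknown"."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), "unknown", dtype=object)
        for c in pd.unique(chrom):
            seq = self._seqs.get(c)
            if seq is None:
                continue
            idx = np.flatnonzero(chrom == c)
            for i in idx:
                ctx = assign_context(seq, int(pos[i]))
                if ctx is not None:
                    out[i] = ctx
        return out.astype(str)

    def cytosine_table(self, chroms: Iterable[str] | None = None) -> pd.DataFrame:
        """All resolvable cytosines on both strands: chrom, pos, strand, context."""
        records = []
        for chrom in (chroms or self.chroms):
            seq = self._seqs[chrom]
            for pos, base in enumerate(seq):
                if base == "C":
                    ctx = assign_context(seq, pos, "+")
                    if ctx:
                        records.append((chrom, pos, "+", ctx))
                elif base == "G":
                    ctx = assign_context(seq, pos, "-")
                    if ctx:
                        records.append((chrom, pos, "-", ctx))
        return pd.DataFrame(records, columns=["chrom", "pos", "strand", "context"])


# ---------------------------------------------------------------------------
# features and segmentations

FEATURE_COLUMNS = ["chrom", "start", "end", "strand", "id", "category"]


def read_features(path, fmt: str | None = None, category_field: str | int | None = None
                  ) -> pd.DataFrame:
    """Read BED or GFF3 annotations into a feature table.

    The result has columns chrom, start, end, strand, id, category with
    0-based half-open intervals.  For GFF3 the 1-based closed
    coordinates are converted, the feature id is taken from the ``ID``
    (falling back to ``Name``) attribute, and the category defaults to
    the type column unless ``category_field`` names another attribute.
    For BED, column 4 is the id; the category is column 5 for 5-column
    files (or the 0-based column index given as ``category_field``),
    and column 6 is the strand when present.
    """
    path = os.fspath(path)
    if fmt is None:
        low = path.lower()
        fmt = "GFF3" if low.endswith((".gff", ".gff3")) else "BED"
    fmt = fmt.upper()
    if fmt == "BED":
        df = _read_bed(path, category_field)
    elif fmt == "GFF3":
        df = _read_gff3(path, category_field)
    else:
        raise ValueError(f"unknown feature format {fmt!r}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        fid = df.loc[bad[0], "id"]
        raise ParseError(f"{path}: feature {fid!r} has start >= end after conversion")
    return df.reset_index(drop=True)


def _read_bed(path, category_field) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    ncol = len(raw.columns)
    if ncol < 4:
        raise ParseError(f"{path}: BED input needs >= 4 columns, found {ncol}")
    df = pd.DataFrame({
        "chrom": raw[0].astype(str),
        "start": pd.to_numeric(raw[1]).astype(np.int64),
        "end": pd.to_numeric(raw[2]).astype(np.int64),
        "strand": raw[5].astype(str) if ncol >= 6 else "+",
        "id": raw[3].astype(str),
    })
    if isinstance(category_field, int):
        df["category"] = raw[category_field].astype(str)
    elif ncol == 5:
        df["category"] = raw[4].astype(str)
    else:
        df["category"] = "feature"
    return df[FEATURE_COLUMNS]


def _parse_gff_attrs(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path, category_field) -> pd.DataFrame:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}: line {lineno}: GFF3 needs 9 columns, found {len(f)}")
            attrs = _parse_gff_attrs(f[8])
            fid = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}-{f[4]}"))
            if isinstance(category_field, str):
                category = attrs.get(category_field, f[2])
            else:
                category = f[2]
            try:
                start = int(f[3]) - 1  # GFF3 is 1-based closed
                end = int(f[4])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: malformed coordinates") from None
            records.append((f[0], start, end, f[6] if f[6] in "+-" else "+", fid, category))
    return pd.DataFrame(records, columns=FEATURE_COLUMNS)


def read_segmentation(path) -> pd.DataFrame:
    """Read a segmentation TSV: chrom, start, end, eigenvalue (or sign).

    A header line is detected and skipped.  Returns chrom, start, end,
    eigen, sign (+1 loose / -1 compacted; the sign of the eigenvalue).
    """
    with open(path) as fh:
        first = fh.readline()
    has_header = False
    f = first.rstrip("\n").split("\t")
    if len(f) >= 4:
        try:
            float(f[1])
        except ValueError:
            has_header = True
    raw = pd.read_csv(path, sep="\t", header=0 if has_header else None, comment="#")
    raw.columns = ["chrom", "start", "end", "eigen"] + list(raw.columns[4:])
    df = raw[["chrom", "start", "end", "eigen"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["eigen"] = df["eigen"].astype(float)
    df["sign"] = np.where(df["eigen"] < 0, -1, 1).astype(np.int64)
    return df


def write_segmentation(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "eigen"]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# site-stat tracks

def write_site_stats(stats: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write per-site scan results.

    ``tsv`` keeps every column (floats at 6 decimals); ``bedgraph_jsd``
    and ``bedgraph_met`` emit single-signal bedGraph tracks.  Input must
    be coordinate-sorted with unique (chrom, pos).
    """
    if not _is_sorted(stats):
        raise ValueError("site stats must be coordinate-sorted before writing")
    if stats.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate (chrom, pos) coordinates in site stats")
    if fmt == "tsv":
        out = stats.copy()
        for col in _SITE_STAT_FLOATS:
            if col in out:
                out[col] = out[col].map(lambda v: f"{v:.6f}")
        out.to_csv(path, sep="\t", index=False)
    elif fmt in ("bedgraph_jsd", "bedgraph_met"):
        col = "jsd" if fmt == "bedgraph_jsd" else "met"
        with open(path, "w") as fh:
            for chrom, pos, v in zip(stats["chrom"], stats["pos"], stats[col]):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:.6f}\n")
    else:
        raise ValueError(f"unknown site-stat format {fmt!r}")


def read_site_stats(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_site_stats`."""
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df
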