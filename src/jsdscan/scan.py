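"""Population-wide genome scan and genome-scale summaries.

Aligns many per-sample methylation tables position by position, computes
the plug-in JSD / MET statistics at every covered cytosine, classifies
sites in the phase plane, and aggregates the per-site results into
C-type proportion tables, fixed-width binned tracks, and Spearman
correlation / hierarchical clustering of binned signals.

A sample with no row at a position is treated as having zero coverage
there and contributes zero weight, so the scan needs no imputation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import spearmanr

from . import divergence, io
from .divergence import CTYPES, PhasePlaneThresholds

__all__ = [
    "MergeError",
    "scan_population",
    "ctype_proportions",
    "bin_signal",
    "correlate_signals",
]

SCAN_COLUMNS = ["chrom", "pos", "context", "met", "jsd", "h_mix", "h_avg",
                "coverage", "samples_covered", "ctype"]


class MergeError(ValueError):
    """Tables cannot be merged position-synchronously."""


def _as_table(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    return io.read_methylation_table(obj)


def _merge_chrom_order(orders: list[list[str]], names: list[str]) -> list[str]:
    """Merge per-table chromosome orders into one consistent order."""
    merged: list[str] = []
    for order, name in zip(orders, names):
        idx = [merged.index(c) for c in order if c in merged]
        if idx != sorted(idx):
            raise MergeError(f"inconsistent chromosome ordering in table {name!r}")
        prev = -1
        for c in order:
            if c in merged:
                prev = merged.index(c)
            else:
                merged.insert(prev + 1, c)
                prev += 1
    return merged


def scan_population(tables, context_map: io.ContextMap | None = None,
                    thresholds: PhasePlaneThresholds | None = None,
                    min_samples: int = 2, min_coverage: int = 1,
                    weighting: str = "coverage",
                    sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Scan a population of methylation tables into per-site statistics.

    Parameters
    ----------
    tables
        List of methylation tables: DataFrames (chrom, pos, n_meth,
        n_unmeth), paths, or :class:`~jsdscan.io.MethylationTableHandle`
        objects.  Each must be coordinate-sorted; chromosome order must
        be mutually consistent.
    context_map
        Optional :class:`~jsdscan.io.ContextMap`; when given, every site
        is annotated with its CG/CHG/CHH context, otherwise "unknown".
    thresholds
        Phase-plane thresholds for the C-type classification.
    min_samples, min_coverage
        Sites covered by fewer samples / fewer total reads are dropped.
        Defaults keep sites with at least 2 covered samples (a single
        covered sample always yields JSD 0).
    weighting
        "coverage" (plug-in weights n_ij / n_i) or "equal".

    Returns a DataFrame sorted by (chrom, pos) with columns
    chrom, pos, context, met, jsd, h_mix, h_avg, coverage,
    samples_covered, ctype.
    """
    if len(tables) < 1:
        raise ValueError("need at least one methylation table")
    names = (sample_ids or [getattr(t, "sample_id", f"table{i}")
                            for i, t in enumerate(tables)])
    dfs = [_as_table(t) for t in tables]
    for df, name in zip(dfs, names):
        if not io._is_sorted(df):
            raise MergeError(f"table {name!r} is not coordinate-sorted")
        if df.duplicated(["chrom", "pos"]).any():
            raise MergeError(f"table {name!r} has duplicate positions")

    chrom_order = _merge_chrom_order(
        [list(pd.unique(df["chrom"])) for df in dfs], list(names))
    rank = {c: i for i, c in enumerate(chrom_order)}

    def keys_of(df: pd.DataFrame) -> np.ndarray:
        r = df["chrom"].map(rank).to_numpy(dtype=np.int64)
        return r * np.int64(1 << 40) + df["pos"].to_numpy(dtype=np.int64)

    all_keys = np.unique(np.concatenate([keys_of(df) for df in dfs])
                         if any(len(d) for d in dfs) else np.array([], dtype=np.int64))
    n_sites, s = len(all_keys), len(dfs)
    meth = np.zeros((n_sites, s), dtype=np.int64)
    unmeth = np.zeros((n_sites, s), dtype=np.int64)
    for j, df in enumerate(dfs):
        idx = np.searchsorted(all_keys, keys_of(df))
        meth[idx, j] = df["n_meth"].to_numpy()
        unmeth[idx, j] = df["n_unmeth"].to_numpy()

    chrom_idx = (all_keys >> np.int64(40)).astype(int)
    pos = (all_keys & np.int64((1 << 40) - 1)).astype(np.int64)
    stats = divergence.jsd_from_counts(meth, unmeth)

    if weighting == "equal":
        # recompute h_avg/jsd with uniform weights over covered samples
        n_ij = (meth + unmeth).astype(float)
        covered = n_ij > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            p_j = np.where(covered, meth / np.maximum(n_ij, 1.0), 0.0)
        h_j = divergence.binary_entropy(p_j)
        n_cov = np.maximum(covered.sum(axis=1), 1)
        mix = (np.where(covered, p_j, 0.0)).sum(axis=1) / n_cov
        stats["h_mix"] = divergence.binary_entropy(mix)
        stats["h_avg"] = (np.where(covered, h_j, 0.0)).sum(axis=1) / n_cov
        stats["jsd"] = np.maximum(stats["h_mix"] - stats["h_avg"], 0.0)
    elif weighting != "coverage":
        raise ValueError(f"unknown weighting {weighting!r}")

    out = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(chrom_idx, categories=chrom_order
                                           ).astype(str),
        "pos": pos,
        "met": stats["met"],
        "jsd": stats["jsd"],
        "h_mix": stats["h_mix"],
        "h_avg": stats["h_avg"],
        "coverage": stats["coverage"],
        "samples_covered": stats["samples_covered"],
    })
    keep = (out["coverage"] >= max(min_coverage, 1)) & (out["samples_covered"] >= min_samples)
    out = out[keep].reset_index(drop=True)
    out["context"] = (context_map.annotate(out["chrom"], out["pos"])
                      if context_map is not None else "unknown")
    out["ctype"] = divergence.classify(out["met"], out["jsd"], thresholds)
    return out[SCAN_COLUMNS]


def ctype_proportions(sites: pd.DataFrame, by: str = "context") -> pd.DataFrame:
    """Percentage of each C type per group (default: per context).

    Rows sum to 100.  An empty input yields an empty table with a
    warning.
    """
    if len(sites) == 0:
        warnings.warn("empty site stream: proportion table is empty")
        return pd.DataFrame(columns=list(CTYPES))
    counts = (sites.groupby([by, "ctype"], observed=True).size().unstack("ctype")
              .reindex(columns=list(CTYPES)).fillna(0.0))
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def bin_signal(sites: pd.DataFrame, bin_width: int, statistic="mean_jsd",
               chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Aggregate per-site values over non-overlapping, genome-tiling bins.

    ``statistic`` is ``"mean_met"``, ``"mean_jsd"``, or
    ``("ctype_fraction", label)`` for the fraction of sites of one C
    type.  Bins are half-open ``[k*w, (k+1)*w)``; with ``chrom_sizes``
    every chromosome is tiled completely (final bin truncated to the
    chromosome length), otherwise tiling stops at the last covered bin.
    Bins with no contributing sites carry value NaN, never 0.

    Returns chrom, start, end, value, n_sites.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(statistic, str) and statistic in ("mean_met", "mean_jsd"):
        values = sites[statistic.removeprefix("mean_")].to_numpy(dtype=float)
    elif isinstance(statistic, (tuple, list)) and statistic[0] == "ctype_fraction":
        label = statistic[1]
        if label not in CTYPES:
            raise ValueError(f"unknown C type {label!r}")
        values = (sites["ctype"] == label).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    df = pd.DataFrame({"chrom": sites["chrom"].to_numpy(),
                       "bin": sites["pos"].to_numpy(dtype=np.int64) // bin_width,
                       "value": values})
    grouped = df.groupby(["chrom", "bin"], observed=True)["value"].agg(["mean", "count"])

    chroms = list(pd.unique(sites["chrom"])) if chrom_sizes is None else list(chrom_sizes)
    frames = []
    for chrom in chroms:
        if chrom_sizes is not None:
            size = chrom_sizes[chrom]
            n_bins = int(np.ceil(size / bin_width))
        else:
            here = df[df["chrom"] == chrom]
            if not len(here):
                continue
            n_bins = int(here["bin"].max()) + 1
            size = n_bins * bin_width
        idx = np.arange(n_bins)
        sub = (grouped.loc[chrom].reindex(idx) if chrom in grouped.index.get_level_values(0)
               else pd.DataFrame({"mean": np.nan, "count": 0}, index=idx))
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": idx * bin_width,
            "end": np.minimum((idx + 1) * bin_width, size),
            "value": sub["mean"].to_numpy(dtype=float),
            "n_sites": sub["count"].fillna(0).to_numpy(dtype=np.int64),
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "value", "n_sites"])
    return pd.concat(frames, ignore_index=True)


def correlate_signals(signals: dict[str, pd.DataFrame], method: str = "average"):
    """Pairwise Spearman correlation and hierarchical clustering of tracks.

    ``signals`` maps a name to a binned track (chrom, start, value) on
    identical binning.  For each pair, bins missing (NaN) in either
    member are dropped; a pair sharing fewer than 3 bins raises an
    error naming it.  Clustering uses the distance 1 - rho with the
    given linkage (default average).

    Returns ``(rho, Z, order)``: the correlation DataFrame, the scipy
    linkage matrix, and the leaf-order list of names.
    """
    names = list(signals)
    if len(names) < 2:
        raise ValueError("need at least two signals to correlate")
    frames = []
    for name in names:
        df = signals[name]
        frames.append(df.set_index([df["chrom"].astype(str), df["start"]])["value"]
                      .rename(name))
    wide = pd.concat(frames, axis=1)
    k = len(names)
    rho = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pair = wide.iloc[:, [a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"signals {names[a]!r} and {names[b]!r} share fewer than 3 bins")
            r = spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
            rho[a, b] = rho[b, a] = r
    rho_df = pd.DataFrame(rho, index=names, columns=names)
    dist = 1.0 - rho
    condensed = dist[np.triu_indices(k, 1)]
    Z = linkage(condensed, method=method)
    order = [names[i] for i in leaves_list(Z)]
    return rho_df, Z, order
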