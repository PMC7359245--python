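"""Feature-anchored statistics and randomization tests.

Metagene profiles (length-scaled bodies with fixed-width flanks),
metastable-gene (MSG) selection by MSC proportion, MSG fraction tracks,
relative-distance spatial association, and the two permutation tests:
the Hi-C compacted/loose structural domain (CSD/LSD) sign-permutation
test and the MSG-near-TE gene-set randomization test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .divergence import CTYPES

__all__ = [
    "MetaProfile",
    "PermutationResult",
    "RelativeDistanceResult",
    "metagene_profile",
    "count_ctypes_by_feature",
    "msc_proportion",
    "select_msgs",
    "msg_fraction_track",
    "relative_distance",
    "csd_lsd_test",
    "msg_te_proximity_test",
]


@dataclasses.dataclass(frozen=True)
class MetaProfile:
    """Mean signal across features: upstream flank, scaled body, downstream."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    counts_upstream: np.ndarray
    counts_body: np.ndarray
    counts_downstream: np.ndarray
    flank_width: int
    flank_bin: int
    body_bins: int
    n_features: int

    @property
    def values(self) -> np.ndarray:
        """Concatenated profile (upstream, body, downstream)."""
        return np.concatenate([self.upstream, self.body, self.downstream])

    @property
    def counts(self) -> np.ndarray:
        return np.concatenate(
            [self.counts_upstream, self.counts_body, self.counts_downstream])


@dataclasses.dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null, and empirical p-values.

    ``p_raw`` is the fraction of null samples at least as extreme as the
    observed value (the convention reported in the source analyses,
    which may be exactly 0); ``p_smoothed`` is the add-one estimate
    (b + 1) / (n + 1), never 0.
    """

    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_permutations: int
    p_raw: float
    p_smoothed: float
    meta: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class RelativeDistanceResult:
    """Histogram of query-to-reference relative distances on [0, 0.5]."""

    distances: np.ndarray
    frequencies: np.ndarray
    bin_edges: np.ndarray
    n_used: int
    n_skipped: int


def _sites_by_chrom(sites: pd.DataFrame, value_col: str):
    out = {}
    for chrom, sub in sites.groupby("chrom", observed=True, sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        out[str(chrom)] = (pos[order], sub[value_col].to_numpy(dtype=float)[order])
    return out


def metagene_profile(sites: pd.DataFrame, features: pd.DataFrame, signal: str = "jsd",
                     flank_width: int = 2000, flank_bin: int = 50,
                     body_bins: int = 60) -> MetaProfile:
    """Arithmetic-mean profile of a per-site signal across features.

    Flanks of ``flank_width`` bases are cut into fixed ``flank_bin``-bp
    bins; the feature body is length-scaled into ``body_bins`` bins so
    features of different lengths align.  Minus-strand features are
    orientation-flipped before binning.  Each bin's value is the mean
    over all (feature, site) pairs mapping to it; empty bins are NaN.
    """
    if len(features) == 0:
        raise ValueError("need at least one feature")
    if flank_width % flank_bin != 0:
        raise ValueError("flank_width must be a multiple of flank_bin")
    n_flank = flank_width // flank_bin
    total = 2 * n_flank + body_bins
    sums = np.zeros(total)
    counts = np.zeros(total, dtype=np.int64)
    by_chrom = _sites_by_chrom(sites, signal)

    short = 0
    for chrom, start, end, strand in zip(features["chrom"], features["start"],
                                         features["end"], features["strand"]):
        if end - start < body_bins:
            short += 1
        if str(chrom) not in by_chrom:
            continue
        pos, val = by_chrom[str(chrom)]
        lo, hi = np.searchsorted(pos, [start - flank_width, end + flank_width])
        p, v = pos[lo:hi], val[lo:hi]
        if not len(p):
            continue
        bins = np.empty(len(p), dtype=np.int64)
        up = p < start
        down = p >= end
        body = ~up & ~down
        bins[up] = (p[up] - (start - flank_width)) // flank_bin
        rel = (p[body] - start) / (end - start)
        bins[body] = n_flank + np.minimum((rel * body_bins).astype(np.int64),
                                          body_bins - 1)
        bins[down] = n_flank + body_bins + (p[down] - end) // flank_bin
        if strand == "-":
            bins = total - 1 - bins
        np.add.at(sums, bins, v)
        np.add.at(counts, bins, 1)
    if short:
        warnings.warn(f"{short} feature(s) shorter than body_bins bases; "
                      "mapped proportionally")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    u, b, d = np.split(means, [n_flank, n_flank + body_bins])
    cu, cb, cd = np.split(counts, [n_flank, n_flank + body_bins])
    return MetaProfile(u, b, d, cu, cb, cd, flank_width, flank_bin, body_bins,
                       len(features))


def count_ctypes_by_feature(sites: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Count classified sites of each C type inside each feature body.

    Returns a DataFrame indexed by feature id with one column per C
    type plus ``total``.  A site overlapping several features counts in
    each of them.
    """
    code = {c: k for k, c in enumerate(CTYPES)}
    by_chrom = {}
    for chrom, sub in sites.groupby("chrom", observed=True, sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        codes = sub["ctype"].map(code).to_numpy(dtype=np.int64)[order]
        by_chrom[str(chrom)] = (pos[order], codes)
    rows = np.zeros((len(features), len(CTYPES)), dtype=np.int64)
    for i, (chrom, start, end) in enumerate(zip(features["chrom"], features["start"],
                                                features["end"])):
        if str(chrom) not in by_chrom:
            continue
        pos, codes = by_chrom[str(chrom)]
        lo, hi = np.searchsorted(pos, [start, end])
        if hi > lo:
            rows[i] = np.bincount(codes[lo:hi], minlength=len(CTYPES))
    out = pd.DataFrame(rows, columns=list(CTYPES), index=features["id"].to_numpy())
    out.index.name = "id"
    out["total"] = out[list(CTYPES)].sum(axis=1)
    return out


def msc_proportion(ctype_counts: pd.DataFrame, min_sites: int = 5) -> pd.Series:
    """Per-feature MSC proportion among classified sites.

    Features with fewer than ``min_sites`` classified sites are dropped.
    """
    eligible = ctype_counts[ctype_counts["total"] >= min_sites]
    return eligible["MSC"] / eligible["total"]


def select_msgs(ctype_counts: pd.DataFrame, quantile: float = 0.95,
                min_sites: int = 5) -> set[str]:
    """Metastable genes: top (1 - quantile) fraction by MSC proportion.

    Genes strictly above the ``quantile`` cut of the MSC-proportion
    distribution are selected; genes tied with any selected gene share
    its proportion and are therefore included as well.  If no gene
    exceeds the cut (e.g. all proportions equal, or all zero) the
    result is empty with a warning.
    """
    prop = msc_proportion(ctype_counts, min_sites=min_sites)
    if len(prop) == 0:
        warnings.warn("no eligible genes for MSG selection")
        return set()
    cut = float(np.quantile(prop.to_numpy(), quantile))
    selected = set(prop.index[prop > cut])
    if not selected:
        warnings.warn("no gene exceeds the MSC-proportion quantile cut; "
                      "empty MSG set")
    return selected


def msg_fraction_track(msgs: set[str], genes: pd.DataFrame, bin_width: int,
                       chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Fraction of MSGs among genes per genomic bin.

    Each gene is assigned to the bin containing its start.  Bins with
    no genes carry NaN.  Returns chrom, start, end, value, n_genes.
    """
    ids = set(genes["id"])
    unknown = set(msgs) - ids
    if unknown:
        raise KeyError(f"MSG id(s) not present in gene set: {sorted(unknown)[:5]}")
    df = pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "bin": genes["start"].to_numpy(dtype=np.int64) // bin_width,
        "is_msg": genes["id"].isin(msgs).to_numpy(dtype=float),
    })
    grouped = df.groupby(["chrom", "bin"], observed=True)["is_msg"].agg(["mean", "count"])
    chroms = list(pd.unique(df["chrom"])) if chrom_sizes is None else list(chrom_sizes)
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
        if chrom in grouped.index.get_level_values(0):
            sub = grouped.loc[chrom].reindex(idx)
        else:
            sub = pd.DataFrame({"mean": np.nan, "count": 0}, index=idx)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": idx * bin_width,
            "end": np.minimum((idx + 1) * bin_width, size),
            "value": sub["mean"].to_numpy(dtype=float),
            "n_genes": sub["count"].fillna(0).to_numpy(dtype=np.int64),
        }))
    return pd.concat(frames, ignore_index=True)


def _midpoints(features: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": features["chrom"].astype(str).to_numpy(),
        "mid": ((features["start"].to_numpy(dtype=np.int64)
                 + features["end"].to_numpy(dtype=np.int64)) / 2.0),
    })


def relative_distance(query: pd.DataFrame, reference: pd.DataFrame,
                      n_histogram_bins: int = 50) -> RelativeDistanceResult:
    """Relative distance of query features to the reference set.

    For each query midpoint, the distance to the nearest reference
    midpoint scaled by the spacing of its two flanking reference
    midpoints, a number in [0, 0.5].  Under spatial independence the
    distribution is uniform (expected frequency 1/bins per bin).
    Queries outside the reference span, and chromosomes with fewer than
    two references, are skipped and counted.
    """
    q = _midpoints(query)
    r = _midpoints(reference)
    dists = []
    skipped = 0
    for chrom, sub in q.groupby("chrom", sort=False):
        mids = np.sort(r.loc[r["chrom"] == chrom, "mid"].to_numpy())
        if len(mids) < 2:
            skipped += len(sub)
            continue
        x = sub["mid"].to_numpy()
        inside = (x >= mids[0]) & (x <= mids[-1])
        skipped += int((~inside).sum())
        x = x[inside]
        right = np.clip(np.searchsorted(mids, x, side="left"), 1, len(mids) - 1)
        left = right - 1
        span = mids[right] - mids[left]
        d = np.minimum(x - mids[left], mids[right] - x) / span
        dists.append(d)
    d_all = np.concatenate(dists) if dists else np.array([])
    hist, edges = np.histogram(d_all, bins=n_histogram_bins, range=(0.0, 0.5))
    freq = hist / max(len(d_all), 1)
    return RelativeDistanceResult(d_all, freq, edges, len(d_all), skipped)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def csd_lsd_test(values, signs, n_permutations: int = 1000, rng=None) -> PermutationResult:
    """Sign-permutation test for higher signal in compacted domains.

    ``values`` is the binned genomic signal (MET or JSD mean per bin),
    ``signs`` the Hi-C eigenvalue signs per bin (+1 loose / -1
    compacted).  The statistic is ``mean(values[sign < 0]) -
    mean(values[sign > 0])``; the null permutes the sign labels over
    bins, keeping the counts of each sign fixed.  ``p_raw`` is one-sided
    for "null difference >= observed"; ``meta['p_positive']`` holds the
    alternative convention P(null difference > 0).

    NaN-valued bins are dropped together with their signs.
    """
    values = np.asarray(values, dtype=float)
    signs = np.asarray(signs)
    if values.shape != signs.shape:
        raise ValueError("values and signs must align bin-for-bin")
    keep = ~np.isnan(values)
    values, signs = values[keep], signs[keep]
    neg = signs < 0
    n_neg, n_pos = int(neg.sum()), int((~neg).sum())
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both eigenvalue signs must be present in the segmentation")
    observed = float(values[neg].mean() - values[~neg].mean())

    gen = _as_rng(rng)
    total = values.sum()
    masks = np.tile(neg, (n_permutations, 1))
    masks = gen.permuted(masks, axis=1)
    sum_neg = masks @ values
    null = sum_neg / n_neg - (total - sum_neg) / n_pos
    b = int((null >= observed).sum())
    return PermutationResult(
        statistic_name="mean(S | e<0) - mean(S | e>0)",
        observed=observed,
        null_values=null,
        n_permutations=n_permutations,
        p_raw=b / n_permutations,
        p_smoothed=(b + 1) / (n_permutations + 1),
        meta={"p_positive": float((null > 0).mean()),
              "n_csd_bins": n_neg, "n_lsd_bins": n_pos},
    )


def _near_te(genes: pd.DataFrame, tes: pd.DataFrame, near_dist: int) -> np.ndarray:
    """Boolean per gene: the interval extended by near_dist overlaps a TE."""
    near = np.zeros(len(genes), dtype=bool)
    if len(tes) == 0:
        return near
    gs = genes["start"].to_numpy(dtype=np.int64) - near_dist
    ge = genes["end"].to_numpy(dtype=np.int64) + near_dist
    gchrom = genes["chrom"].astype(str).to_numpy()
    for chrom, sub in tes.groupby(tes["chrom"].astype(str), sort=False):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # merge overlapping TE intervals (vectorized sweep)
        cummax = np.maximum.accumulate(ends)
        new = np.ones(len(starts), dtype=bool)
        new[1:] = starts[1:] > cummax[:-1]
        first = np.flatnonzero(new)
        ms = starts[first]
        me = np.maximum.reduceat(ends, first)
        g = gchrom == chrom
        if not g.any():
            continue
        # overlap iff some merged interval has start < gene_end and end > gene_start
        idx = np.searchsorted(ms, ge[g], side="left")
        hit = np.zeros(int(g.sum()), dtype=bool)
        has_prev = idx > 0
        hit[has_prev] = me[idx[has_prev] - 1] > gs[g][has_prev]
        near[np.flatnonzero(g)] |= hit
    return near


def msg_te_proximity_test(msgs: set[str], background_genes: pd.DataFrame,
                          tes: pd.DataFrame, near_dist: int = 2000,
                          n_draws: int = 10000, rng=None) -> PermutationResult:
    """Randomization test: are MSGs near TEs more often than random genes?

    The statistic g is the fraction of MSGs whose span extended by
    ``near_dist`` overlaps any TE.  The null draws ``n_draws`` gene sets
    of size |msgs| uniformly without replacement from the background
    (protein-coding, non-TEG genes); ``p_raw = P(g_null >= g_observed)``.
    """
    ids = background_genes["id"].to_numpy()
    id_index = {g: i for i, g in enumerate(ids)}
    missing = [g for g in msgs if g not in id_index]
    if missing:
        raise ValueError(f"MSG id(s) not in background gene set: {missing[:5]}")
    m = len(msgs)
    if m == 0:
        raise ValueError("empty MSG set")
    if m > len(ids):
        raise ValueError("more MSGs than background genes")
    near = _near_te(background_genes, tes, near_dist)
    msg_idx = np.fromiter((id_index[g] for g in msgs), dtype=np.int64, count=m)
    observed = float(near[msg_idx].mean())

    gen = _as_rng(rng)
    n = len(ids)
    null = np.empty(n_draws)
    chunk = max(1, min(n_draws, int(2e7) // max(n, 1)))
    done = 0
    while done < n_draws:
        c = min(chunk, n_draws - done)
        keys = gen.random((c, n))
        take = np.argpartition(keys, m - 1, axis=1)[:, :m]
        null[done:done + c] = near[take].sum(axis=1) / m
        done += c
    b = int((null >= observed).sum())
    return PermutationResult(
        statistic_name="fraction of MSGs near TE",
        observed=observed,
        null_values=null,
        n_permutations=n_draws,
        p_raw=b / n_draws,
        p_smoothed=(b + 1) / (n_draws + 1),
        meta={"near_dist": near_dist, "n_msgs": m, "n_background": n,
              "background_near_fraction": float(near.mean())},
    )
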