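"""Plug-in Jensen-Shannon divergence over population methylation counts.

The central object is a per-cytosine contingency table: one row per
methylome (sampling unit) and one column per methylation state
(methylated, unmethylated; K >= 2 states in the generalized case).
From such a table this module computes

* the coverage-weighted mixture distribution and its Shannon entropy,
* the coverage-weighted average of the per-methylome entropies,
* their difference, the plug-in Jensen-Shannon divergence (JSD, in bit),
* the weighted methylation level MET (total methylated reads over
  total reads), and
* a four-way classification of sites in the (MET, JSD) phase plane into
  low-/high-/medium-methylated and metastable cytosines
  (LMC / HMC / MMC / MSC).

The plug-in (empirical) estimator replaces probabilities with read-count
frequencies.  With coverage weights ``pi_j = n_j / n`` it is the maximum
likelihood estimator of population JSD and coincides with the mutual
information between the "methylome" and "state" margins of the pooled
contingency table.  It is bounded by ``0 <= JSD <= log2(K)`` and, for
K = 2, by the binary entropy of MET (the phase-plane envelope).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "CTYPES",
    "NoCoverageError",
    "SiteCountMatrix",
    "SiteStat",
    "PhasePlaneThresholds",
    "binary_entropy",
    "shannon_entropy",
    "met",
    "plugin_jsd",
    "jsd_from_counts",
    "classify_site",
    "classify",
    "site_breakdown",
]

#: The four cytosine types partitioning the (MET, JSD) phase plane.
CTYPES = ("LMC", "HMC", "MMC", "MSC")

_LOG2 = np.log(2.0)


class NoCoverageError(ValueError):
    """Raised when a site has zero total read coverage."""


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * log(p) with the convention 0 * log 0 = 0."""
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = p[mask] * np.log(p[mask])
    return out


def binary_entropy(p, base: float = 2.0):
    """Entropy of a Bernoulli(p) distribution, vectorized.

    Uses the 0*log 0 = 0 convention, so the function is continuous on
    [0, 1] with value 0 at both endpoints.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    h = -(_xlogx(p) + _xlogx(q)) / np.log(base) + 0.0  # +0.0 avoids -0.0
    return h if h.ndim else float(h)


def shannon_entropy(probs: Sequence[float], base: float = 2.0, *, atol: float = 1e-9) -> float:
    """Shannon entropy of a discrete distribution.

    Parameters
    ----------
    probs
        Probabilities, one per event of the sample space.  Must be
        non-negative and sum to 1 within ``atol``.
    base
        Logarithm base; 2 (the default) yields bits.

    Raises
    ------
    ValueError
        If an entry is negative (the offending index is named) or the
        probabilities do not sum to 1.
    """
    p = np.asarray(probs, dtype=float)
    neg = np.flatnonzero(p < 0)
    if neg.size:
        raise ValueError(f"negative probability at index {neg[0]}: {p[neg[0]]!r}")
    total = p.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"probabilities sum to {total!r}, not 1 (tolerance {atol})")
    return float(-_xlogx(p).sum() / np.log(base))


def _entropy_rows(P: np.ndarray, base: float = 2.0) -> np.ndarray:
    """Entropy of each row of a (rows x K) matrix of distributions."""
    return -_xlogx(P).sum(axis=1) / np.log(base) + 0.0


@dataclasses.dataclass(frozen=True)
class SiteCountMatrix:
    """Read counts at one genomic site: one row per methylome.

    ``counts[j, k]`` is the number of reads of state ``k`` in methylome
    ``j``; for methylation data K = 2 with column 0 the methylated and
    column 1 the unmethylated state.
    """

    counts: np.ndarray
    chrom: str | None = None
    pos: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError(f"counts must be 2-D (methylomes x states), got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError(f"counts needs >= 1 row and >= 2 state columns, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", arr.astype(float))

    @property
    def n_methylomes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_states(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        """Per-methylome coverage n_j."""
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        """Total coverage n at the site."""
        return float(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class SiteStat:
    """Per-site scan output: MET, JSD and its two entropy terms."""

    met: float
    jsd: float
    h_mix: float
    h_avg: float
    coverage: int
    samples_covered: int
    chrom: str | None = None
    pos: int | None = None
    strand: str = "+"
    context: str = "unknown"


@dataclasses.dataclass(frozen=True)
class PhasePlaneThresholds:
    """Phase-plane boundaries for the four-way C-type classification.

    Low-methylated sites have MET < ``met_low``, high-methylated sites
    MET > ``met_high``; the middle band splits at ``jsd_metastable``
    (bit) into medium-methylated (below) and metastable (above).
    Boundary values of MET fall in the middle band.
    """

    met_low: float = 0.2
    met_high: float = 0.8
    jsd_metastable: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.met_low < self.met_high < 1.0):
            raise ValueError(
                f"need 0 < met_low < met_high < 1, got {self.met_low}, {self.met_high}"
            )
        if not (0.0 < self.jsd_metastable < 1.0):
            raise ValueError(f"need 0 < jsd_metastable < 1, got {self.jsd_metastable}")


def met(site: SiteCountMatrix) -> float:
    """Weighted methylation level: total state-0 reads over total reads."""
    n = site.total
    if n <= 0:
        raise NoCoverageError("site has zero total coverage")
    return float(site.counts[:, 0].sum() / n)


def plugin_jsd(site: SiteCountMatrix, weighting: str = "coverage") -> SiteStat:
    """Plug-in JSD estimate at one site.

    With ``weighting="coverage"`` (the default and the estimator with
    minimum variance) each methylome j receives weight
    ``pi_j = n_j / n``; rows with zero coverage get weight 0 and do not
    contribute to the average entropy.  With ``weighting="equal"``
    covered rows receive uniform weight ``1 / s_covered``.

    Returns a :class:`SiteStat`; ``jsd = h_mix - h_avg`` in bit.
    """
    if weighting not in ("coverage", "equal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts = site.counts
    n_j = counts.sum(axis=1)
    n = n_j.sum()
    if n <= 0:
        raise NoCoverageError("site has zero total coverage")
    covered = n_j > 0
    P = counts[covered] / n_j[covered, None]
    if weighting == "coverage":
        pi = n_j[covered] / n
    else:
        pi = np.full(int(covered.sum()), 1.0 / covered.sum())
    mixture = pi @ P
    h_mix = float(-_xlogx(mixture).sum() / _LOG2)
    h_avg = float(pi @ _entropy_rows(P))
    jsd = max(h_mix - h_avg, 0.0)
    return SiteStat(
        met=float(counts[:, 0].sum() / n),
        jsd=jsd,
        h_mix=h_mix,
        h_avg=h_avg,
        coverage=int(round(n)),
        samples_covered=int(covered.sum()),
        chrom=site.chrom,
        pos=site.pos,
        strand=site.strand,
    )


def jsd_from_counts(meth: np.ndarray, unmeth: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized binary-state plug-in JSD over many sites.

    Parameters
    ----------
    meth, unmeth
        Integer arrays of shape (n_sites, n_samples) with methylated
        and unmethylated read counts; a zero total for a sample at a
        site means "not covered there" and contributes zero weight.

    Returns
    -------
    dict of 1-D arrays keyed ``met``, ``jsd``, ``h_mix``, ``h_avg``,
    ``coverage``, ``samples_covered``.  Sites with zero total coverage
    yield NaN statistics (filter on ``coverage`` downstream).
    """
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if meth.shape != unmeth.shape or meth.ndim != 2:
        raise ValueError("meth and unmeth must be equal-shape 2-D arrays")
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("counts must be non-negative")
    n_ij = meth + unmeth
    n_i = n_ij.sum(axis=1)
    ok = n_i > 0
    safe_n = np.where(n_i > 0, n_i, 1.0)
    met_arr = np.where(ok, meth.sum(axis=1) / safe_n, np.nan)
    h_mix = np.where(ok, binary_entropy(np.where(ok, met_arr, 0.0)), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_j = np.where(n_ij > 0, meth / np.where(n_ij > 0, n_ij, 1.0), 0.0)
    h_j = binary_entropy(p_j)
    h_avg = np.where(ok, (n_ij * h_j).sum(axis=1) / safe_n, np.nan)
    jsd = np.where(ok, np.maximum(h_mix - h_avg, 0.0), np.nan)
    covered = (n_ij > 0).sum(axis=1)
    jsd = np.where(ok & (covered <= 1), 0.0, jsd)  # one distribution: exactly 0
    return {
        "met": met_arr,
        "jsd": jsd,
        "h_mix": h_mix,
        "h_avg": h_avg,
        "coverage": n_i.astype(np.int64),
        "samples_covered": (n_ij > 0).sum(axis=1).astype(np.int64),
    }


def classify_site(met_value: float, jsd_value: float,
                  thresholds: PhasePlaneThresholds | None = None) -> str:
    """Classify one (MET, JSD) point into LMC / HMC / MMC / MSC."""
    t = thresholds or PhasePlaneThresholds()
    if met_value < t.met_low:
        return "LMC"
    if met_value > t.met_high:
        return "HMC"
    return "MSC" if jsd_value > t.jsd_metastable else "MMC"


def classify(met_values, jsd_values,
             thresholds: PhasePlaneThresholds | None = None) -> np.ndarray:
    """Vectorized phase-plane classification; returns an array of labels."""
    t = thresholds or PhasePlaneThresholds()
    met_values = np.asarray(met_values, dtype=float)
    jsd_values = np.asarray(jsd_values, dtype=float)
    lmc = met_values < t.met_low
    hmc = met_values > t.met_high
    msc = ~lmc & ~hmc & (jsd_values > t.jsd_metastable)
    return np.select([lmc, hmc, msc], ["LMC", "HMC", "MSC"], default="MMC")


def site_breakdown(site: SiteCountMatrix, weighting: str = "coverage"):
    """Worked per-methylome breakdown of the JSD terms at one site.

    Returns a DataFrame with one row per methylome (columns ``n1``,
    ``n2``, ``mu`` methylation level, ``pi`` weight, ``H`` entropy,
    ``piH`` weighted entropy) and a final ``mixture`` row whose ``H`` is
    the mixture entropy and whose ``piH`` is the average entropy; their
    difference is the site JSD.  Values are unrounded.
    """
    import pandas as pd

    if site.n_states != 2:
        raise ValueError("site_breakdown requires a binary (two-state) site")
    stat = plugin_jsd(site, weighting=weighting)
    counts = site.counts
    n_j = counts.sum(axis=1)
    covered = n_j > 0
    mu = np.where(covered, counts[:, 0] / np.where(covered, n_j, 1.0), np.nan)
    if weighting == "coverage":
        pi = n_j / n_j.sum()
    else:
        pi = np.where(covered, 1.0 / covered.sum(), 0.0)
    H = np.where(covered, binary_entropy(np.where(covered, mu, 0.0)), np.nan)
    rows = pd.DataFrame(
        {
            "n1": counts[:, 0],
            "n2": counts[:, 1],
            "mu": mu,
            "pi": pi,
            "H": H,
            "piH": pi * np.where(covered, H, 0.0),
        },
        index=[f"P{j + 1}" for j in range(site.n_methylomes)],
    )
    mixture = pd.DataFrame(
        {
            "n1": [counts[:, 0].sum()],
            "n2": [counts[:, 1].sum()],
            "mu": [stat.met],
            "pi": [np.nan],
            "H": [stat.h_mix],
            "piH": [stat.h_avg],
        },
        index=["mixture"],
    )
    return pd.concat([rows, mixture])
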