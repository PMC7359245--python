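"""Synthetic methylome populations and toy annotations with known truth.

The generator emulates the kind of data a population-scale bisulfite
study produces: per-sample methylation tables whose per-site read
counts are binomial draws around a site- and sample-specific
methylation level theta, with negative-binomial coverage heterogeneity
across samples, over a toy genome whose cytosines have controlled
CG/CHG/CHH contexts.

Four site models cover the population structures seen in real
methylomes: ``conserved_low`` and ``conserved_high`` (all individuals
share a low / high theta: LMC / HMC regions), ``intermediate`` (all
share theta ~ 0.5: MMC-like), and ``metastable`` (each individual
independently carries the high state with probability
``metastable_mix``, so the population segregates into methylated and
unmethylated subpopulations: the MSC signature).  Everything is
deterministic given the spec seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = [
    "SITE_MODEL_KINDS",
    "SiteModel",
    "CoverageModel",
    "PopulationSpec",
    "SimulatedPopulation",
    "SimulatedAnnotations",
    "simulate_population",
    "simulate_annotations",
    "simulate_binned_signal",
    "simulate_msg_study",
    "write_population",
]

SITE_MODEL_KINDS = ("conserved_low", "conserved_high", "intermediate", "metastable")

_MOTIF = {"CG": "CG", "CHG": "CAG", "CHH": "CAT"}


@dataclasses.dataclass(frozen=True)
class SiteModel:
    """Methylation-level parameters of the four site kinds.

    ``theta_low``/``theta_high`` fold in bisulfite non-conversion and
    sequencing error, which is why they are not exactly 0 and 1.
    """

    theta_low: float = 0.03
    theta_high: float = 0.97
    theta_mid: float = 0.5
    metastable_mix: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_low < self.theta_mid < self.theta_high < 1.0):
            raise ValueError("need 0 < theta_low < theta_mid < theta_high < 1")
        if not (0.0 < self.metastable_mix < 1.0):
            raise ValueError("need 0 < metastable_mix < 1")


@dataclasses.dataclass(frozen=True)
class CoverageModel:
    """Negative-binomial per-site, per-sample read depth.

    ``dispersion`` is the NB size parameter (variance = mean +
    mean^2/dispersion); ``math.inf`` gives the Poisson limit.  The
    default reflects the strong depth heterogeneity of public BS-seq
    runs pooled from many studies.
    """

    mean: float = 30.0
    dispersion: float = 10.0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("coverage mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("coverage dispersion must be positive")

    def sample(self, rng: np.random.Generator, shape) -> np.ndarray:
        if math.isinf(self.dispersion):
            return rng.poisson(self.mean, shape)
        size = self.dispersion
        return rng.negative_binomial(size, size / (size + self.mean), shape)


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """Study design of a simulated methylome population."""

    n_samples: int = 10
    n_sites: int = 1000
    genome_length: int = 20000
    context_composition: tuple[float, float, float] = (0.15, 0.15, 0.70)  # CG, CHG, CHH
    site_model_mixture: tuple[float, float, float, float] = (0.70, 0.20, 0.08, 0.02)
    site_model: SiteModel = SiteModel()
    coverage: CoverageModel = CoverageModel()
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_sites < 1:
            raise ValueError("need at least one sample and one site")
        if abs(sum(self.context_composition) - 1.0) > 1e-9:
            raise ValueError("context composition must sum to 1")
        if abs(sum(self.site_model_mixture) - 1.0) > 1e-9:
            raise ValueError("site model mixture must sum to 1")
        if self.genome_length < 4 * (self.n_sites + 1):
            raise ValueError("impossible composition: genome too short for the "
                             "requested number of cytosine sites")


@dataclasses.dataclass(frozen=True)
class SimulatedPopulation:
    """Generator output: tables, per-site truth, and the toy genome."""

    tables: list[pd.DataFrame]
    truth: pd.DataFrame
    sequences: dict[str, str]
    sample_ids: list[str]


def simulate_population(spec: PopulationSpec) -> SimulatedPopulation:
    """Draw a methylome population under the spec.

    Cytosines are planted at regular spacing on an A/T filler sequence
    using 3-bp context motifs (CG / CAG / CAT), so each planted site's
    context is controlled exactly.  For every site i and sample j a
    methylation level theta_ij is set by the site's model (metastable
    sites re-draw the high/low state per sample), coverage n_ij comes
    from the coverage model, and the methylated count is
    Binomial(n_ij, theta_ij).  Samples omit rows with zero coverage,
    as a methylation caller would.

    The truth table records chrom, pos, context, kind and, for
    metastable sites, the number of high-state samples.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.site_model
    spacing = spec.genome_length // (spec.n_sites + 1)
    positions = (np.arange(spec.n_sites) + 1) * spacing

    contexts = rng.choice(["CG", "CHG", "CHH"], size=spec.n_sites,
                          p=list(spec.context_composition))
    kinds = rng.choice(list(SITE_MODEL_KINDS), size=spec.n_sites,
                       p=list(spec.site_model_mixture))

    seq = rng.choice(list("AT"), size=spec.genome_length)
    for pos, ctx in zip(positions, contexts):
        motif = _MOTIF[ctx]
        seq[pos:pos + len(motif)] = list(motif)
    sequence = "".join(seq)

    theta = np.empty((spec.n_sites, spec.n_samples))
    theta[kinds == "conserved_low"] = m.theta_low
    theta[kinds == "conserved_high"] = m.theta_high
    theta[kinds == "intermediate"] = m.theta_mid
    meta = kinds == "metastable"
    high = rng.random((int(meta.sum()), spec.n_samples)) < m.metastable_mix
    theta[meta] = np.where(high, m.theta_high, m.theta_low)
    n_high = np.zeros(spec.n_sites, dtype=np.int64)
    n_high[meta] = high.sum(axis=1)

    coverage = spec.coverage.sample(rng, (spec.n_sites, spec.n_samples))
    meth = rng.binomial(coverage, theta)
    unmeth = coverage - meth

    sample_ids = [f"sample{j:03d}" for j in range(spec.n_samples)]
    tables = []
    for j in range(spec.n_samples):
        covered = coverage[:, j] > 0
        tables.append(pd.DataFrame({
            "chrom": spec.chrom,
            "pos": positions[covered],
            "n_meth": meth[covered, j],
            "n_unmeth": unmeth[covered, j],
        }))
    truth = pd.DataFrame({
        "chrom": spec.chrom,
        "pos": positions,
        "context": contexts,
        "kind": kinds,
        "n_high": n_high,
    })
    return SimulatedPopulation(tables, truth, {spec.chrom: sequence}, sample_ids)


@dataclasses.dataclass(frozen=True)
class SimulatedAnnotations:
    """Toy gene/TE annotations, planted MSG truth, and a segmentation."""

    genes: pd.DataFrame
    tes: pd.DataFrame
    msgs: set[str]
    segmentation: pd.DataFrame


def simulate_annotations(genome_length: int, n_genes: int = 100, n_tes: int = 40,
                         msg_fraction: float = 0.05, seed: int = 0,
                         chrom: str = "chr1", gene_length: int = 1500,
                         te_length: int = 400, near_dist: int = 2000,
                         near_prob_msg: float = 0.8, near_prob_bg: float = 0.2,
                         segment_bin: int = 50000) -> SimulatedAnnotations:
    """Place non-overlapping genes, TEs biased towards planted MSGs, and
    an alternating-sign segmentation.

    Each gene sits in its own slot of the genome; a TE, when attached,
    is placed in the gap downstream of its host gene within
    ``near_dist``.  Planted MSG genes host a TE with probability
    ``near_prob_msg`` versus ``near_prob_bg`` for background genes,
    mimicking the association of metastable genes with targeted TEs.
    ``n_tes`` caps the number of TEs actually placed.
    """
    rng = np.random.default_rng(seed)
    slot = genome_length // n_genes
    if slot < gene_length + te_length + near_dist // 2 + 10:
        raise ValueError("placement error: genome too crowded for the requested "
                         "genes and TEs")
    starts = np.arange(n_genes) * slot + 10
    strands = rng.choice(["+", "-"], size=n_genes)
    ids = [f"gene{i:04d}" for i in range(n_genes)]
    genes = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + gene_length,
        "strand": strands, "id": ids, "category": "gene",
    })

    n_msg = int(round(msg_fraction * n_genes))
    msg_idx = rng.choice(n_genes, size=n_msg, replace=False)
    is_msg = np.zeros(n_genes, dtype=bool)
    is_msg[msg_idx] = True
    p_host = np.where(is_msg, near_prob_msg, near_prob_bg)
    host = rng.random(n_genes) < p_host
    host_idx = np.flatnonzero(host)
    if len(host_idx) > n_tes:
        host_idx = rng.choice(host_idx, size=n_tes, replace=False)
    te_rows = []
    for k, gi in enumerate(sorted(host_idx)):
        gap = int(rng.integers(0, max(near_dist - te_length, 1)))
        ts = int(genes.loc[gi, "end"]) + gap
        te_rows.append((chrom, ts, ts + te_length, "+", f"te{k:04d}", "TE"))
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "strand", "id",
                                         "category"])

    n_bins = max(int(np.ceil(genome_length / segment_bin)), 2)
    signs = np.ones(n_bins, dtype=np.int64)
    signs[: n_bins // 2] = -1
    signs = rng.permutation(signs)
    bin_starts = np.arange(n_bins) * segment_bin
    segmentation = pd.DataFrame({
        "chrom": chrom,
        "start": bin_starts,
        "end": np.minimum(bin_starts + segment_bin, genome_length),
        "eigen": signs.astype(float),
        "sign": signs,
    })
    return SimulatedAnnotations(genes, tes, {ids[i] for i in msg_idx}, segmentation)


def simulate_binned_signal(segmentation: pd.DataFrame, baseline: float = 0.3,
                           shift: float = 0.0, noise_sd: float = 0.1,
                           seed: int = 0) -> np.ndarray:
    """Per-bin signal with an optional planted shift in compacted bins.

    Bins with negative eigenvalue sign get ``baseline + shift``, the
    rest ``baseline``, plus iid Gaussian noise; used to exercise the
    CSD/LSD sign-permutation test at known ground truth.
    """
    rng = np.random.default_rng(seed)
    sign = segmentation["sign"].to_numpy()
    mean = np.where(sign < 0, baseline + shift, baseline)
    return mean + rng.normal(0.0, noise_sd, size=len(sign))


def simulate_msg_study(n_genes: int = 100, sites_per_gene: int = 20,
                       msg_fraction: float = 0.05, n_samples: int = 10,
                       msg_metastable_frac: float = 0.5,
                       bg_metastable_frac: float = 0.0,
                       site_model: SiteModel = SiteModel(),
                       coverage: CoverageModel = CoverageModel(),
                       seed: int = 0, chrom: str = "chr1"):
    """Population with MSC-dense sites planted inside a subset of genes.

    Gene bodies are tiled with CG sites; in planted MSG genes a
    fraction ``msg_metastable_frac`` of the sites follows the
    metastable model, elsewhere ``bg_metastable_frac``; all remaining
    sites are conserved (low or high at random).  Returns
    ``(tables, genes, planted_msgs, truth)`` for end-to-end recovery
    tests of the MSG selection.
    """
    rng = np.random.default_rng(seed)
    gene_length = 100 * sites_per_gene
    slot = gene_length + 4000
    starts = np.arange(n_genes) * slot + 1000
    ids = [f"gene{i:04d}" for i in range(n_genes)]
    genes = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + gene_length,
        "strand": "+", "id": ids, "category": "gene",
    })
    n_msg = int(round(msg_fraction * n_genes))
    msg_idx = set(rng.choice(n_genes, size=n_msg, replace=False).tolist())

    pos_list, kind_list = [], []
    for i, s in enumerate(starts):
        p_meta = msg_metastable_frac if i in msg_idx else bg_metastable_frac
        for k in range(sites_per_gene):
            pos_list.append(s + 50 + 100 * k)
            if rng.random() < p_meta:
                kind_list.append("metastable")
            else:
                kind_list.append("conserved_low" if rng.random() < 0.7
                                 else "conserved_high")
    positions = np.asarray(pos_list, dtype=np.int64)
    kinds = np.asarray(kind_list)
    n_sites = len(positions)

    theta = np.empty((n_sites, n_samples))
    theta[kinds == "conserved_low"] = site_model.theta_low
    theta[kinds == "conserved_high"] = site_model.theta_high
    meta = kinds == "metastable"
    high = rng.random((int(meta.sum()), n_samples)) < site_model.metastable_mix
    theta[meta] = np.where(high, site_model.theta_high, site_model.theta_low)
    cov = coverage.sample(rng, (n_sites, n_samples))
    meth = rng.binomial(cov, theta)
    tables = []
    for j in range(n_samples):
        covered = cov[:, j] > 0
        tables.append(pd.DataFrame({
            "chrom": chrom, "pos": positions[covered],
            "n_meth": meth[covered, j],
            "n_unmeth": (cov[:, j] - meth[:, j])[covered],
        }))
    truth = pd.DataFrame({"chrom": chrom, "pos": positions, "kind": kinds})
    return tables, genes, {ids[i] for i in msg_idx}, truth


def write_population(pop: SimulatedPopulation, out_dir,
                     dialect: str = "methyldackel_bedgraph") -> dict[str, str]:
    """Write a simulated population to disk in the formats the readers accept.

    Emits one methylation table per sample, the toy genome FASTA, and
    the truth table; returns a dict of the paths written.
    """
    import os

    from . import io as _io

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    ext = "bedGraph" if dialect == "methyldackel_bedgraph" else "tsv"
    for sid, table in zip(pop.sample_ids, pop.tables):
        p = os.path.join(out_dir, f"{sid}.{ext}")
        _io.write_methylation_table(table, p, dialect=dialect)
        paths[sid] = p
    fasta = os.path.join(out_dir, "genome.fa")
    with open(fasta, "w") as fh:
        for name, seq in pop.sequences.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k:k + 80] + "\n")
    paths["fasta"] = fasta
    truth = os.path.join(out_dir, "truth.tsv")
    pop.truth.to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth
    return paths
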