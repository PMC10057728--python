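"""Synthetic data with the statistical structure the analysis assumes.

Three generators:

* ``simulate_genotypes`` — a two-cluster Balding–Nichols model. Each locus
  draws an ancestral frequency p ~ U(0.05, 0.95); each cluster then draws
  its own frequency from Beta(p(1-c)/c, (1-p)(1-c)/c), whose variance is
  c p (1-p). The per-deme drift c is calibrated from the configured
  differentiation F as c = 2F/(1+F): with two demes the Nei Fst is
  referenced to the pooled pair rather than the (unobservable) ancestral
  population, and this calibration makes the configured F the expected
  per-locus Fst the scan estimates — the parameter-recovery contract of
  the generator. The planted divergent minority is constructed directly:
  the two cluster frequencies sit symmetrically about a midpoint qbar
  (uniform on the feasible range [F/(1+F), 1/(1+F)]) at displacement
  delta = sqrt(F qbar (1-qbar)), which fixes the parametric pairwise Fst
  of every divergent locus at exactly fst_divergent — independent drift
  draws would leave a large fraction of "divergent" loci undifferentiated
  (both clusters drifting to the same extreme), contradicting the
  strongly-differentiated-minority structure the scan is meant to find.
  Diploid dosages are binomial per single-seed sample; loci are
  independent (no linkage).
* ``simulate_kernel_traits`` — Gaussian per-cluster kernel/quality traits;
  the default means are the published cluster means of the core
  collection (see module constant ``DEFAULT_TRAIT_PARAMS``).
* ``simulate_dpcr_chip`` — Poisson well occupancy on a partitioned chip:
  each channel loads independently and a well is positive with
  probability 1 - exp(-lambda * v).

All three are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grain_quality import DPCRChip
from .io_formats import GenotypeMatrix, MarkerMap, WHEAT_CHROMOSOMES

#: Rounded wheat chromosome lengths in bp (1A..7D). Only relative positions
#: matter for region merging; these keep the genome at a realistic ~14 Gb.
DEFAULT_CHROMOSOME_LENGTHS: dict[str, int] = {
    "1A": 594_000_000, "1B": 690_000_000, "1D": 496_000_000,
    "2A": 781_000_000, "2B": 801_000_000, "2D": 652_000_000,
    "3A": 751_000_000, "3B": 831_000_000, "3D": 616_000_000,
    "4A": 745_000_000, "4B": 674_000_000, "4D": 510_000_000,
    "5A": 710_000_000, "5B": 714_000_000, "5D": 566_000_000,
    "6A": 618_000_000, "6B": 721_000_000, "6D": 474_000_000,
    "7A": 737_000_000, "7B": 751_000_000, "7D": 639_000_000,
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the genotype generator.

    Defaults mirror the sampling design of the core collection: two genetic
    clusters, 12 accessions per cluster genotyped as 4 single seeds each,
    and ~16,000 SNP markers of which a small minority is strongly
    differentiated.
    """

    n_accessions_per_cluster: int = 12
    n_seeds_per_accession: int = 4
    n_neutral_loci: int = 15_799
    n_divergent_loci: int = 160
    fst_neutral: float = 0.05
    fst_divergent: float = 0.6
    missing_rate: float = 0.0
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROMOSOME_LENGTHS)
    )
    seed: int = 0
    cluster_names: tuple[str, str] = ("red", "blue")

    def __post_init__(self) -> None:
        if self.n_accessions_per_cluster < 1 or self.n_seeds_per_accession < 1:
            raise ValueError("need at least one accession and one seed per accession")
        if self.n_neutral_loci + self.n_divergent_loci < 1:
            raise ValueError("need at least one locus")
        if self.n_divergent_loci >= max(self.n_neutral_loci, 1):
            raise ValueError("divergent loci must be a minority of all loci")
        for name, f in (("fst_neutral", self.fst_neutral),
                        ("fst_divergent", self.fst_divergent)):
            if not 0.0 <= f < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.fst_divergent <= self.fst_neutral:
            raise ValueError("fst_divergent must exceed fst_neutral")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SimulatedTruth:
    """Ground truth recorded alongside a simulated genotype matrix."""

    divergent_locus_ids: set[str]
    cluster_assignment: dict[str, str]            # accession -> cluster
    ancestral_freq: dict[str, float]              # marker -> p
    cluster_freqs: dict[str, dict[str, float]]    # cluster -> marker -> q

    def to_json(self, path: str | Path) -> None:
        payload = {
            "divergent_locus_ids": sorted(self.divergent_locus_ids),
            "cluster_assignment": self.cluster_assignment,
            "ancestral_freq": self.ancestral_freq,
            "cluster_freqs": self.cluster_freqs,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulatedTruth":
        d = json.loads(Path(path).read_text())
        return cls(set(d["divergent_locus_ids"]), d["cluster_assignment"],
                   d["ancestral_freq"], d["cluster_freqs"])


def drift_coefficient(fst: float | np.ndarray) -> float | np.ndarray:
    """Per-deme Balding–Nichols drift c giving expected two-cluster Fst
    equal to ``fst``: c = 2 F / (1 + F).

    Two independent demes at drift c from their common ancestor show a
    pooled-pair (Nei) differentiation of (c/2)/(1 - c/2); inverting that
    relation references the configured parameter to the quantity the scan
    measures.
    """
    return 2.0 * np.asarray(fst) / (1.0 + np.asarray(fst))


def _cluster_frequency(rng: np.random.Generator, p: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Balding–Nichols draw of a cluster frequency given ancestral p and
    per-deme drift c (variance c p (1-p)).

    c = 0 degenerates to the ancestral frequency itself (no drift).
    """
    q = p.copy()
    drift = c > 0.0
    if drift.any():
        shape = (1.0 - c[drift]) / c[drift]
        q[drift] = rng.beta(p[drift] * shape, (1.0 - p[drift]) * shape)
    return q


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, MarkerMap, SimulatedTruth]:
    """Generate a two-cluster genotype matrix, its marker map and the truth."""
    rng = np.random.default_rng(config.seed)
    m = config.n_neutral_loci + config.n_divergent_loci
    marker_ids = [f"M{i + 1:06d}" for i in range(m)]

    # plant the divergent minority at random marker ids
    divergent_idx = rng.choice(m, size=config.n_divergent_loci, replace=False)
    f_per_locus = np.full(m, config.fst_neutral)
    f_per_locus[divergent_idx] = config.fst_divergent

    p_anc = rng.uniform(0.05, 0.95, size=m)
    c_per_locus = np.asarray(drift_coefficient(f_per_locus))
    clusters = list(config.cluster_names)
    q = {c: _cluster_frequency(rng, p_anc, c_per_locus) for c in clusters}
    # planted divergent loci: symmetric displacement about a midpoint qbar,
    # making the parametric pairwise Fst exactly fst_divergent per locus
    if config.n_divergent_loci:
        fd = config.fst_divergent
        lo, hi = fd / (1.0 + fd), 1.0 / (1.0 + fd)
        qbar = rng.uniform(lo, hi, size=len(divergent_idx))
        delta = np.sqrt(fd * qbar * (1.0 - qbar))
        sign = rng.choice([-1.0, 1.0], size=len(divergent_idx))
        p_anc[divergent_idx] = qbar
        q[clusters[0]][divergent_idx] = np.clip(qbar + sign * delta, 0.0, 1.0)
        q[clusters[1]][divergent_idx] = np.clip(qbar - sign * delta, 0.0, 1.0)

    sample_ids: list[str] = []
    accession_of: dict[str, str] = {}
    cluster_of_sample: dict[str, str] = {}
    assignment: dict[str, str] = {}
    blocks = []
    n_seeds = config.n_seeds_per_accession
    for c in clusters:
        for a in range(config.n_accessions_per_cluster):
            acc = f"{c}{a + 1:02d}"
            assignment[acc] = c
            for s in range(n_seeds):
                sid = f"{acc}_s{s + 1}"
                sample_ids.append(sid)
                accession_of[sid] = acc
                cluster_of_sample[sid] = c
        blocks.append(rng.binomial(
            2, q[c][None, :],
            size=(config.n_accessions_per_cluster * n_seeds, m),
        ).astype(float))
    dosages = np.vstack(blocks)

    if config.missing_rate > 0:
        dosages[rng.random(dosages.shape) < config.missing_rate] = np.nan

    geno = GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        dosages=dosages,
        cluster_labels=pd.Series(cluster_of_sample),
        accessions=pd.Series(accession_of),
    )

    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=m, p=lengths / lengths.sum())
    pos = np.array([
        rng.integers(1, config.chromosome_lengths[chroms[i]] + 1) for i in chrom_idx
    ])
    marker_map = MarkerMap(pd.DataFrame({
        "marker_id": marker_ids,
        "chrom": [chroms[i] for i in chrom_idx],
        "pos_bp": pos,
    }))

    truth = SimulatedTruth(
        divergent_locus_ids={marker_ids[i] for i in divergent_idx},
        cluster_assignment=assignment,
        ancestral_freq=dict(zip(marker_ids, p_anc.tolist())),
        cluster_freqs={c: dict(zip(marker_ids, q[c].tolist())) for c in clusters},
    )
    return geno, marker_map, truth


# ---------------------------------------------------------------------------
# kernel / quality traits
# ---------------------------------------------------------------------------

#: Per-cluster (mean, SD) trait parameters. Means for the kernel diameters,
#: redness, hue and hardness are the published cluster means of the 24-line
#: core collection; the remaining means and all SDs are realistic values for
#: bread-wheat grain chosen once for the generator.
DEFAULT_TRAIT_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "blue": {
        "L1": (7.05, 0.15), "L2": (3.30, 0.10), "L3": (3.34, 0.10),
        "L*": (57.0, 1.0), "a*": (8.41, 0.30), "b*": (22.5, 0.8),
        "hardness": (55.7, 2.0), "TKW": (44.0, 3.0), "TW": (78.0, 1.5),
        "protein": (13.5, 0.8),
    },
    "red": {
        "L1": (6.84, 0.15), "L2": (3.13, 0.10), "L3": (3.28, 0.10),
        "L*": (57.0, 1.0), "a*": (8.59, 0.30), "b*": (22.2, 0.8),
        "hardness": (54.5, 2.0), "TKW": (37.0, 3.0), "TW": (75.0, 1.5),
        "protein": (12.5, 0.8),
    },
}


def simulate_kernel_traits(
    cluster_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    n_per_cluster: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian per-sample trait table with cluster labels.

    ``cluster_params`` maps cluster -> trait -> (mean, SD); defaults to
    :data:`DEFAULT_TRAIT_PARAMS`. SD = 0 gives every sample the cluster
    mean exactly; n_per_cluster = 0 gives an empty table with full header.
    """
    if n_per_cluster < 0:
        raise ValueError("n_per_cluster must be non-negative")
    params = cluster_params if cluster_params is not None else DEFAULT_TRAIT_PARAMS
    for cluster, traits in params.items():
        for trait, (_, sd) in traits.items():
            if sd < 0:
                raise ValueError(f"negative SD for {trait!r} in cluster {cluster!r}")
    rng = np.random.default_rng(seed)
    trait_names = list(next(iter(params.values())))
    rows = []
    for cluster, traits in params.items():
        for i in range(n_per_cluster):
            row = {"sample_id": f"{cluster}{i + 1:02d}", "cluster": cluster}
            for trait in trait_names:
                mean, sd = traits[trait]
                row[trait] = mean + sd * rng.standard_normal() if sd > 0 else mean
            rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "cluster"] + trait_names)


# ---------------------------------------------------------------------------
# digital PCR chips
# ---------------------------------------------------------------------------

def simulate_dpcr_chip(
    copies_per_ul: dict[str, float],
    n_wells: int = 20_000,
    well_volume_ul: float = 0.000809,
    seed: int = 0,
) -> DPCRChip:
    """Simulate one two-channel chip under independent Poisson loading.

    Each well is positive for a channel with probability
    1 - exp(-lambda * v); channels load independently, so double-positive
    wells arise at the product rate. Defaults match a 20,000-partition
    chip with 0.809 nL wells.
    """
    if n_wells < 1:
        raise ValueError("chip needs at least one well")
    for channel, lam in copies_per_ul.items():
        if lam < 0:
            raise ValueError(f"negative concentration for {channel!r}")
    rng = np.random.default_rng(seed)
    hits = {}
    for channel, lam in copies_per_ul.items():
        p = 1.0 - np.exp(-lam * well_volume_ul)
        hits[channel] = rng.random(n_wells) < p
    channels = list(copies_per_ul)
    double = 0
    if len(channels) >= 2:
        double = int(np.logical_and(hits[channels[0]], hits[channels[1]]).sum())
    return DPCRChip(
        n_wells=n_wells,
        well_volume_ul=well_volume_ul,
        positives={c: int(h.sum()) for c, h in hits.items()},
        double_positive=double,
        true_copies_per_ul=dict(copies_per_ul),
    )
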