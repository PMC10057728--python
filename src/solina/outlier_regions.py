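"""Outlier detection on a differentiation scan.

Two thresholding routes are provided, mirroring the analysis convention
for landrace cluster contrasts:

* a permutation null of the genome-wide **maximum** Fst, built by
  shuffling the accession-to-cluster assignment (all single seeds of an
  accession move together) and rescanning — the classical max-statistic
  family-wise control;
* the empirical 99th percentile of the observed per-marker Fst values, a
  deliberately stringent rule used when the permutation threshold is too
  liberal.

Flagged markers are merged into genomic regions by single-linkage on
their positions (consecutive flagged markers at most ``max_gap_mb``
apart join one region) and regions are annotated with candidate genes
whose intervals overlap them, optionally padded by a proximity window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst_scan import FstScanResult, fst_scan, scan_arrays
from .io_formats import Gene, GenotypeMatrix, MarkerMap, UNPLACED


@dataclass
class NullDistribution:
    """Genome-wide maximum Fst under permuted cluster assignments."""

    n_permutations: int
    max_fst_values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.max_fst_values = np.asarray(self.max_fst_values, float)
        if len(self.max_fst_values) != self.n_permutations:
            raise ValueError("one stored maximum per permutation required")

    def quantile_threshold(self, q: float = 0.95) -> float:
        if not 0.0 <= q <= 1.0:
            raise ValueError("q must lie in [0, 1]")
        if q > 1.0 - 1.0 / self.n_permutations:
            warnings.warn(
                f"quantile {q} outside the resolution of {self.n_permutations} "
                "permutations; returning the null maximum", stacklevel=2,
            )
            return float(self.max_fst_values.max())
        return float(np.quantile(self.max_fst_values, q))

    def p_value(self, observed_max: float) -> float:
        """Finite-sample permutation p for the observed maximum (+1 rule)."""
        return (1 + int((self.max_fst_values >= observed_max).sum())) / (
            1 + self.n_permutations
        )


@dataclass
class OutlierRegion:
    """A merged run of flagged markers on one chromosome, in Mb."""

    chrom: str
    start_mb: float
    end_mb: float
    n_snps: int
    member_marker_ids: list[str]
    overlapping_genes: list[str] = field(default_factory=list)
    proximal_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_mb > self.end_mb:
            raise ValueError("region start after end")
        if self.n_snps < 1:
            raise ValueError("region needs at least one flagged marker")


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permutation_null(
    geno: GenotypeMatrix,
    n_perm: int = 100,
    seed: int | None = None,
    estimator: str = "nei",
) -> NullDistribution:
    """Max-Fst null by permuting accession-to-cluster assignment.

    The permutation unit is the accession: its seeds are not independent
    samples, so they change cluster together. Cluster sizes (in
    accessions) are preserved; the observed labelling is not included in
    the null. The maximum is over all markers with defined Fst.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    acc = geno.accessions.reindex(geno.sample_ids)
    lab = geno.cluster_labels.reindex(geno.sample_ids)
    acc_cluster = (
        pd.DataFrame({"accession": acc.to_numpy(), "cluster": lab.to_numpy()})
        .drop_duplicates()
    )
    if acc_cluster["accession"].duplicated().any():
        raise ValueError("an accession spans both clusters; labels are inconsistent")
    accessions = acc_cluster["accession"].to_numpy()
    base_labels = acc_cluster["cluster"].to_numpy()
    sample_acc_idx = pd.Index(accessions).get_indexer(acc.to_numpy())

    maxima = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = base_labels[rng.permutation(len(base_labels))]
        sample_labels = shuffled[sample_acc_idx]
        mask_red = sample_labels == "red"
        *_, fst, _excl = scan_arrays(geno.dosages, mask_red, ~mask_red, estimator)
        defined = fst[~np.isnan(fst)]
        if defined.size == 0:
            raise ValueError("no defined Fst in a permutation; degenerate input")
        maxima[b] = defined.max()
    return NullDistribution(n_permutations=n_perm, max_fst_values=maxima, seed=seed)


# ---------------------------------------------------------------------------
# percentile thresholding
# ---------------------------------------------------------------------------

def percentile_threshold(
    scan: FstScanResult, q: float = 0.99
) -> tuple[float, list[str]]:
    """Empirical quantile of the defined Fst values; strict ``>`` flags.

    Linear interpolation on the sorted values; ties at the threshold are
    therefore never flagged, which behaves conservatively.
    """
    defined = scan.defined_fst()
    if len(defined) < 2:
        raise ValueError("need at least two defined Fst values")
    threshold = float(np.quantile(defined.to_numpy(), q))
    flagged_rows = scan.table.loc[defined.index].loc[
        scan.table.loc[defined.index, "Fst"] > threshold
    ]
    return threshold, flagged_rows["marker_id"].tolist()


def fraction_above(scan: FstScanResult, threshold: float) -> float:
    """Fraction of defined-Fst markers strictly above a threshold (the
    'how liberal was the permutation cut-off' report)."""
    defined = scan.defined_fst()
    return float((defined > threshold).mean())


# ---------------------------------------------------------------------------
# region merging and gene co-localization
# ---------------------------------------------------------------------------

def merge_outlier_regions(
    flagged_marker_ids: list[str],
    marker_map: MarkerMap,
    max_gap_mb: float = 15.0,
) -> list[OutlierRegion]:
    """Single-linkage merge of flagged markers into per-chromosome regions.

    Consecutive flagged markers at most ``max_gap_mb`` apart join the same
    region; region bounds are the min/max member positions (a singleton is
    a zero-width region). Unplaced markers are excluded.
    """
    coords = marker_map.mapped().set_index("marker_id")
    flagged = [m for m in flagged_marker_ids if m in coords.index]
    regions: list[OutlierRegion] = []
    sub = coords.loc[flagged].reset_index()
    for chrom, grp in sub.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos_bp", "marker_id"], kind="mergesort")
        pos_mb = grp["pos_bp"].to_numpy() / 1e6
        ids = grp["marker_id"].tolist()
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or pos_mb[i] - pos_mb[i - 1] > max_gap_mb:
                members = ids[start:i]
                regions.append(OutlierRegion(
                    chrom=str(chrom),
                    start_mb=float(pos_mb[start]),
                    end_mb=float(pos_mb[i - 1]),
                    n_snps=len(members),
                    member_marker_ids=members,
                ))
                start = i
    regions.sort(key=lambda r: (r.chrom, r.start_mb))
    return regions


def colocalize_genes(
    regions: list[OutlierRegion],
    annotation: list[Gene],
    window_mb: float = 0.0,
) -> list[OutlierRegion]:
    """Annotate regions with overlapping and nearby candidate genes.

    A gene overlaps a region when their intervals intersect; with
    ``window_mb`` > 0 the gene interval is padded on both sides and
    matches that only arise through the padding are reported separately
    as proximity hits.
    """
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in annotation}
    unmatched = gene_chroms - region_chroms
    if annotation and regions and unmatched == gene_chroms:
        warnings.warn(
            f"no chromosome shared between regions and annotation: {sorted(unmatched)}",
            stacklevel=2,
        )
    out = []
    for r in regions:
        strict, proximal = [], []
        for g in annotation:
            if g.chrom != r.chrom:
                continue
            g_start, g_end = g.start_bp / 1e6, g.end_bp / 1e6
            if g_start <= r.end_mb and g_end >= r.start_mb:
                strict.append(g.name)
            elif (g_start - window_mb <= r.end_mb and g_end + window_mb >= r.start_mb):
                proximal.append(g.name)
        out.append(OutlierRegion(
            chrom=r.chrom, start_mb=r.start_mb, end_mb=r.end_mb,
            n_snps=r.n_snps, member_marker_ids=list(r.member_marker_ids),
            overlapping_genes=sorted(strict), proximal_genes=sorted(proximal),
        ))
    return out


def regions_table(regions: list[OutlierRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom,
        "start_Mb": round(r.start_mb, 1),
        "end_Mb": round(r.end_mb, 1),
        "n_snps": r.n_snps,
        "markers": ";".join(r.member_marker_ids),
        "overlapping_genes": ";".join(r.overlapping_genes),
        "proximal_genes": ";".join(r.proximal_genes),
    } for r in regions])


# ---------------------------------------------------------------------------
# Manhattan export
# ---------------------------------------------------------------------------

def manhattan_export(
    scan: FstScanResult,
    flagged_marker_ids: list[str],
    threshold: float | None = None,
    figure_path: str | None = None,
) -> pd.DataFrame:
    """Plot-ready table (and optional figure) of the genome scan.

    Markers get a cumulative x-coordinate by concatenating chromosomes in
    sorted order; the flagged set is marked as-is (it must come from the
    thresholding step, the export recomputes nothing).
    """
    t = scan.table[scan.table["chrom"] != UNPLACED].copy()
    t = t.dropna(subset=["pos_bp"])
    offset, offsets = 0.0, {}
    for chrom, grp in t.groupby("chrom", sort=False):
        offsets[chrom] = offset
        offset += grp["pos_bp"].max() + 1.0
    t["x"] = t["pos_bp"] + t["chrom"].map(offsets)
    t["outlier_flag"] = t["marker_id"].isin(set(flagged_marker_ids))
    if threshold is not None:
        t["threshold"] = threshold
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 3))
        for i, (chrom, grp) in enumerate(t.groupby("chrom", sort=False)):
            ax.scatter(grp["x"], grp["Fst"], s=4,
                       color="0.55" if i % 2 else "0.3", rasterized=True)
        out = t[t["outlier_flag"]]
        ax.scatter(out["x"], out["Fst"], s=8, color="crimson")
        if threshold is not None:
            ax.axhline(threshold, ls="--", color="k", lw=0.8)
        ax.set_xlabel("genome position")
        ax.set_ylabel("Fst")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return t


__all__ = [
    "NullDistribution", "OutlierRegion", "permutation_null",
    "percentile_threshold", "fraction_above", "merge_outlier_regions",
    "colocalize_genes", "regions_table", "manhattan_export", "fst_scan",
]
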