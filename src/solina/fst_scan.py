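"""Per-locus differentiation between the two genetic clusters.

The estimator is the Nei / Nei–Chesser decomposition of gene diversity
with sample-size correction, computed marker by marker between the "red"
and "blue" clusters:

    Ho  = mean over clusters of the observed heterozygote fraction
    Hs  = nt/(nt-1) * (mean_k 2 p_k (1-p_k) - Ho/(2 nt))
    Ht  = 2 pbar (1-pbar) + Hs/(r nt) - Ho/(2 r nt)
    Fst = 1 - Hs/Ht

with nt the harmonic mean of per-cluster sample sizes (after removing
missing calls), pbar the unweighted mean cluster frequency and r = 2
clusters. Fst can be slightly negative under no differentiation (the
correction is unbiased, not clipped) and is undefined when Ht = 0
(overall monomorphic), in which case the marker is flagged and excluded
from downstream thresholding.

A Weir–Cockerham theta variant is available behind ``estimator="wc"``
for comparison; the Nei convention is the default and the one the region
analysis uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CLUSTER_LABELS, GenotypeMatrix, MarkerMap, UNPLACED

EXCLUDE_NO_DATA = "no data in one cluster"
EXCLUDE_MONOMORPHIC = "monomorphic (Ht = 0)"


@dataclass(frozen=True)
class ClusterStats:
    """Per-cluster summary at one marker: sample size after missing
    removal, alternate-allele frequency, observed heterozygosity."""

    n: int
    p: float
    ho: float


@dataclass
class FstRecord:
    marker_id: str
    n_per_cluster: dict[str, int]
    p_per_cluster: dict[str, float]
    ho: float
    hs: float
    ht: float
    fst: float
    excluded: str = ""


@dataclass
class FstScanResult:
    """Genome-ordered per-marker scan with exclusion bookkeeping."""

    table: pd.DataFrame  # marker_id, chrom, pos_bp, n/p per cluster, Ho, Hs, Ht, Fst, excluded
    meta: dict = field(default_factory=dict)

    def defined_fst(self) -> pd.Series:
        ok = self.table["excluded"] == ""
        return self.table.loc[ok, "Fst"]


# ---------------------------------------------------------------------------
# per-cluster summaries
# ---------------------------------------------------------------------------

def _mask_stats(dosages: np.ndarray, mask: np.ndarray):
    """Vectorised (n, p, Ho) per marker for one cluster mask."""
    sub = dosages[mask]
    seen = ~np.isnan(sub)
    n = seen.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(sub, axis=0) / (2.0 * n)
        ho = np.where(seen, sub == 1.0, False).sum(axis=0) / n
    return n, p, ho


def cluster_allele_frequencies(geno: GenotypeMatrix, marker_id: str) -> dict[str, ClusterStats]:
    """(n, p, Ho) for each cluster at one marker; clusters with no
    non-missing call get n = 0 and NaN frequencies."""
    j = geno.marker_ids.index(marker_id)
    out: dict[str, ClusterStats] = {}
    for label in CLUSTER_LABELS:
        n, p, ho = _mask_stats(geno.dosages[:, [j]], geno.cluster_mask(label))
        out[label] = ClusterStats(int(n[0]), float(p[0]), float(ho[0]))
    return out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _nei_arrays(n1, p1, h1, n2, p2, h2):
    """Vectorised Nei–Chesser Ho/Hs/Ht/Fst for two clusters."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nt = 2.0 / (1.0 / n1 + 1.0 / n2)                  # harmonic mean size
        ho = (h1 + h2) / 2.0
        within = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
        hs = nt / (nt - 1.0) * (within - ho / (2.0 * nt))
        pbar = (p1 + p2) / 2.0
        ht = 2.0 * pbar * (1.0 - pbar) + hs / (2.0 * nt) - ho / (4.0 * nt)
        fst = np.where(ht != 0.0, 1.0 - hs / ht, np.nan)
    return ho, hs, ht, fst


def _wc_arrays(n1, p1, h1, n2, p2, h2):
    """Weir–Cockerham theta for two populations (biallelic)."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = nbar / (nbar - 1.0) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / denom, np.nan)
    # keep the Nei-style components for reporting; theta replaces Fst
    ho, hs, ht, _ = _nei_arrays(n1, p1, h1, n2, p2, h2)
    return ho, hs, ht, theta


_ESTIMATORS = {"nei": _nei_arrays, "wc": _wc_arrays}


def nei_fst(stats: dict[str, ClusterStats], marker_id: str = "") -> FstRecord:
    """Nei–Chesser record from per-cluster summaries of both clusters."""
    if len(stats) < 2:
        raise ValueError("differentiation needs at least two clusters")
    (l1, s1), (l2, s2) = sorted(stats.items())
    if s1.n == 0 or s2.n == 0:
        return FstRecord(marker_id, {l1: s1.n, l2: s2.n},
                         {l1: s1.p, l2: s2.p}, np.nan, np.nan, np.nan, np.nan,
                         excluded=EXCLUDE_NO_DATA)
    ho, hs, ht, fst = _nei_arrays(s1.n, s1.p, s1.ho, s2.n, s2.p, s2.ho)
    excl = EXCLUDE_MONOMORPHIC if ht == 0.0 else ""
    return FstRecord(marker_id, {l1: s1.n, l2: s2.n}, {l1: s1.p, l2: s2.p},
                     float(ho), float(hs), float(ht),
                     float(fst) if not np.isnan(fst) else np.nan, excluded=excl)


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def scan_arrays(dosages: np.ndarray, mask_red: np.ndarray, mask_blue: np.ndarray,
                estimator: str = "nei"):
    """Vectorised scan core: (Ho, Hs, Ht, Fst, excluded-reason array)."""
    n1, p1, h1 = _mask_stats(dosages, mask_red)
    n2, p2, h2 = _mask_stats(dosages, mask_blue)
    ho, hs, ht, fst = _ESTIMATORS[estimator](n1, p1, h1, n2, p2, h2)
    excluded = np.full(dosages.shape[1], "", dtype=object)
    excluded[(n1 == 0) | (n2 == 0)] = EXCLUDE_NO_DATA
    mono = (excluded == "") & (ht == 0.0)
    excluded[mono] = EXCLUDE_MONOMORPHIC
    fst = np.where(excluded == "", fst, np.nan)
    return (n1, p1, h1), (n2, p2, h2), ho, hs, ht, fst, excluded


def fst_scan(geno: GenotypeMatrix, marker_map: MarkerMap | None = None,
             estimator: str = "nei") -> FstScanResult:
    """Per-marker differentiation scan in genome order.

    Markers absent from the map (or mapped to 'unplaced') are scanned but
    carry no usable coordinates for region calls; they sort last.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    labels = geno.cluster_labels.reindex(geno.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a cluster label before scanning")
    red, blue = geno.cluster_mask("red"), geno.cluster_mask("blue")
    if red.sum() == 0 or blue.sum() == 0:
        raise ValueError("the scan contrasts two clusters; one is empty")

    (n1, p1, _), (n2, p2, _), ho, hs, ht, fst, excluded = scan_arrays(
        geno.dosages, red, blue, estimator
    )
    table = pd.DataFrame({
        "marker_id": geno.marker_ids,
        "n_red": n1, "n_blue": n2,
        "p_red": p1, "p_blue": p2,
        "Ho": ho, "Hs": hs, "Ht": ht, "Fst": fst,
        "excluded": excluded,
    })
    n_unmapped = 0
    if marker_map is not None:
        coords = marker_map.table.set_index("marker_id")[["chrom", "pos_bp"]]
        if not set(geno.marker_ids) & set(coords.index):
            raise ValueError("genotype markers and marker map share no ids")
        table = table.join(coords, on="marker_id")
        table["chrom"] = table["chrom"].fillna(UNPLACED)
        n_unmapped = int((table["chrom"] == UNPLACED).sum())
        from .io_formats import _CHROM_ORDER
        key = table["chrom"].map(lambda c: _CHROM_ORDER.get(c, len(_CHROM_ORDER)))
        table = (table.assign(_k=key)
                 .sort_values(["_k", "chrom", "pos_bp", "marker_id"], kind="mergesort")
                 .drop(columns="_k").reset_index(drop=True))
    else:
        table["chrom"] = UNPLACED
        table["pos_bp"] = np.nan

    meta = {
        "estimator": estimator,
        "n_markers": len(table),
        "n_excluded_no_data": int((table["excluded"] == EXCLUDE_NO_DATA).sum()),
        "n_excluded_monomorphic": int((table["excluded"] == EXCLUDE_MONOMORPHIC).sum()),
        "n_unmapped": n_unmapped,
        "n_red_samples": int(red.sum()),
        "n_blue_samples": int(blue.sum()),
    }
    return FstScanResult(table=table, meta=meta)
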