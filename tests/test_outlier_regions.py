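"""Permutation null, percentile flagging, region merging, co-localization
and the Manhattan export."""

import numpy as np
import pandas as pd
import pytest

from solina.fst_scan import FstScanResult, fst_scan
from solina.io_formats import Gene, MarkerMap
from solina.outlier_regions import (
    NullDistribution, colocalize_genes, manhattan_export,
    merge_outlier_regions, percentile_threshold, permutation_null,
)
from solina.simulate import SimulationConfig, simulate_genotypes

from conftest import make_geno


def _scan_from_fst(fst_values, chrom="1A"):
    """Wrap bare Fst values into a scan result for threshold tests."""
    n = len(fst_values)
    table = pd.DataFrame({
        "marker_id": [f"M{i + 1:04d}" for i in range(n)],
        "chrom": chrom, "pos_bp": np.arange(1, n + 1) * 1_000_000,
        "Ho": 0.1, "Hs": 0.1, "Ht": 0.2,
        "Fst": np.asarray(fst_values, float), "excluded": "",
    })
    return FstScanResult(table=table, meta={})


def _map_from_positions(chrom_pos):
    return MarkerMap(pd.DataFrame(
        [{"marker_id": f"M{i + 1:04d}", "chrom": c, "pos_bp": int(p)}
         for i, (c, p) in enumerate(chrom_pos)]))


# -- permutation null -------------------------------------------------------

def test_null_stores_one_maximum_per_permutation(small_geno):
    null = permutation_null(small_geno, n_perm=100, seed=0)
    assert null.n_permutations == 100
    assert len(null.max_fst_values) == 100
    assert np.all(np.abs(null.max_fst_values) <= 1.0)


def test_null_is_reproducible_under_fixed_seed(small_geno):
    a = permutation_null(small_geno, n_perm=25, seed=3)
    b = permutation_null(small_geno, n_perm=25, seed=3)
    assert np.array_equal(a.max_fst_values, b.max_fst_values)


def test_degenerate_single_accession_per_cluster():
    """One accession of two identical seeds per cluster: every relabeling
    is the identity or the swap, so all null maxima equal the observed."""
    geno = make_geno([[2], [2]], [[0], [0]], seeds_per_accession=2)
    obs = fst_scan(geno).defined_fst().max()
    null = permutation_null(geno, n_perm=10, seed=1)
    assert np.allclose(null.max_fst_values, obs)


def test_p_value_uses_plus_one_correction(small_geno):
    null = NullDistribution(4, np.array([0.1, 0.2, 0.3, 0.4]))
    assert null.p_value(0.35) == pytest.approx(2 / 5)
    assert null.p_value(0.05) == pytest.approx(1.0)


def test_quantile_outside_resolution_warns():
    null = NullDistribution(5, np.array([0.1, 0.2, 0.3, 0.4, 0.5]))
    with pytest.warns(UserWarning, match="resolution"):
        assert null.quantile_threshold(0.99) == 0.5


# -- percentile threshold ---------------------------------------------------

def test_percentile_on_known_grid():
    """100 distinct values 0.00..0.99 at q=0.99: interpolated threshold
    0.9801 and exactly one marker flagged."""
    scan = _scan_from_fst(np.round(np.arange(100) * 0.01, 2))
    threshold, flagged = percentile_threshold(scan, q=0.99)
    assert threshold == pytest.approx(0.9801)
    assert flagged == ["M0100"]


def test_tie_saturation_flags_nothing():
    scan = _scan_from_fst([0.3] * 50)
    threshold, flagged = percentile_threshold(scan, q=0.99)
    assert threshold == pytest.approx(0.3)
    assert flagged == []


def test_flag_count_monotone_in_q():
    rng = np.random.default_rng(2)
    scan = _scan_from_fst(rng.uniform(-0.05, 0.9, 500))
    counts = [len(percentile_threshold(scan, q)[1])
              for q in (0.5, 0.8, 0.9, 0.95, 0.99)]
    assert counts == sorted(counts, reverse=True)


def test_excluded_markers_do_not_enter_threshold():
    scan = _scan_from_fst(np.linspace(0, 0.99, 100))
    scan.table.loc[99, "excluded"] = "monomorphic (Ht = 0)"
    threshold, flagged = percentile_threshold(scan, 0.99)
    # the top value is excluded, so the quantile comes from the remaining 99
    assert threshold < 0.98
    assert "M0100" not in flagged


# -- region merging ---------------------------------------------------------

def brute_force_merge(positions_mb, gap):
    """Transitive closure of the pairwise '<= gap apart' relation."""
    idx = list(range(len(positions_mb)))
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in idx:
        for j in idx:
            if abs(positions_mb[i] - positions_mb[j]) <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in idx:
        groups.setdefault(find(i), []).append(positions_mb[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


def test_printed_style_region():
    mm = _map_from_positions([("1B", 582.0e6), ("1B", 584.1e6), ("1B", 588.5e6)])
    regions = merge_outlier_regions(["M0001", "M0002", "M0003"], mm, max_gap_mb=10)
    assert len(regions) == 1
    r = regions[0]
    assert (r.chrom, r.start_mb, r.end_mb, r.n_snps) == ("1B", 582.0, 584.1 + 4.4, 3)


def test_singleton_is_zero_width():
    mm = _map_from_positions([("2A", 78.0e6)])
    (r,) = merge_outlier_regions(["M0001"], mm, max_gap_mb=15)
    assert r.start_mb == r.end_mb == 78.0
    assert r.n_snps == 1


def test_merge_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(9)
    for _ in range(200):
        n = rng.integers(1, 25)
        pos = np.sort(rng.uniform(0, 700, n))
        gap = float(rng.uniform(1, 60))
        mm = _map_from_positions([("3B", p * 1e6) for p in pos])
        pos_mb = (mm.table["pos_bp"] / 1e6).tolist()  # as the merger sees them
        regions = merge_outlier_regions(list(mm.table["marker_id"]), mm, gap)
        got = sorted(tuple(sorted(
            mm.table.set_index("marker_id").loc[r.member_marker_ids, "pos_bp"] / 1e6))
            for r in regions)
        assert got == brute_force_merge(pos_mb, gap)


def test_merge_is_idempotent_and_order_independent():
    rng = np.random.default_rng(10)
    pos = rng.uniform(0, 500, 30)
    mm = _map_from_positions([("5A", p * 1e6) for p in pos])
    ids = list(mm.table["marker_id"])
    a = merge_outlier_regions(ids, mm, 20.0)
    b = merge_outlier_regions(list(reversed(ids)), mm, 20.0)
    assert [(r.chrom, r.start_mb, r.end_mb, tuple(r.member_marker_ids))
            for r in a] == \
           [(r.chrom, r.start_mb, r.end_mb, tuple(r.member_marker_ids))
            for r in b]


def test_unplaced_markers_excluded_from_regions():
    mm = _map_from_positions([("1A", 1e6), ("unplaced", 2e6)])
    regions = merge_outlier_regions(["M0001", "M0002"], mm, 15.0)
    assert len(regions) == 1
    assert regions[0].chrom == "1A"


# -- gene co-localization ---------------------------------------------------

def test_gene_inside_region_reported_as_overlap():
    mm = _map_from_positions([("5A", 557.0e6), ("5A", 591.0e6)])
    regions = merge_outlier_regions(["M0001", "M0002"], mm, 40.0)
    genes = [Gene("VRN-A1", "5A", 575_000_001, 576_000_000)]
    (r,) = colocalize_genes(regions, genes, window_mb=0.0)
    assert r.overlapping_genes == ["VRN-A1"]
    assert r.proximal_genes == []


def test_proximity_distinguished_from_overlap():
    mm = _map_from_positions([("2A", 78.0e6), ("2A", 89.5e6)])
    regions = merge_outlier_regions(["M0001", "M0002"], mm, 15.0)
    genes = [Gene("TaCHLH", "2A", 92_000_001, 93_000_000)]
    (r,) = colocalize_genes(regions, genes, window_mb=5.0)
    assert r.overlapping_genes == []
    assert r.proximal_genes == ["TaCHLH"]


def test_empty_annotation_gives_empty_gene_lists():
    mm = _map_from_positions([("1A", 5e6)])
    regions = colocalize_genes(merge_outlier_regions(["M0001"], mm, 15.0), [])
    assert regions[0].overlapping_genes == []


def test_chromosome_mismatch_warns():
    mm = _map_from_positions([("1A", 5e6)])
    regions = merge_outlier_regions(["M0001"], mm, 15.0)
    with pytest.warns(UserWarning, match="no chromosome shared"):
        colocalize_genes(regions, [Gene("X", "7D", 1, 2)], 0.0)


def test_colocalization_matches_interval_oracle():
    rng = np.random.default_rng(12)
    for _ in range(300):
        start = rng.uniform(0, 600)
        end = start + rng.uniform(0, 60)
        g_start = rng.uniform(0, 600)
        g_end = g_start + rng.uniform(0.01, 30)
        window = float(rng.choice([0.0, 5.0]))
        mm = _map_from_positions([("4B", start * 1e6), ("4B", end * 1e6)])
        regions = merge_outlier_regions(["M0001", "M0002"], mm, 1e9)
        gene = Gene("G", "4B", int(g_start * 1e6) + 1, int(g_end * 1e6))
        (r,) = colocalize_genes(regions, [gene], window)
        gs, ge = gene.start_bp / 1e6, gene.end_bp / 1e6
        overlap = gs <= r.end_mb and ge >= r.start_mb
        padded = gs - window <= r.end_mb and ge + window >= r.start_mb
        assert (r.overlapping_genes == ["G"]) == overlap
        assert (r.proximal_genes == ["G"]) == (padded and not overlap)


# -- Manhattan export -------------------------------------------------------

def test_manhattan_coordinates_and_flags(tmp_path, small_geno):
    chrom_pos = [("1A", (i + 1) * 1e6) for i in range(30)] + \
                [("2B", (i + 1) * 1e6) for i in range(30)]
    mm = MarkerMap(pd.DataFrame(
        [{"marker_id": small_geno.marker_ids[i], "chrom": c, "pos_bp": int(p)}
         for i, (c, p) in enumerate(chrom_pos)]))
    scan = fst_scan(small_geno, mm)
    threshold, flagged = percentile_threshold(scan, 0.9)
    fig = tmp_path / "manhattan.png"
    table = manhattan_export(scan, flagged, threshold, str(fig))
    assert fig.exists()
    assert len(table) == 60
    assert (np.diff(table["x"]) > 0).all()
    assert set(table.loc[table["outlier_flag"], "marker_id"]) == set(flagged)
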