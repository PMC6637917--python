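"""TSS mapping, window scan, cluster calling, densest region — with oracles."""

import numpy as np
import pandas as pd
import pytest

from topoclust import clusters
from topoclust.io import GeneModel, ParameterError, TranscriptionUnit


def brute_force_scan(aff, tot, L, window, step):
    """Independent per-window recount."""
    rows = []
    w = 1
    while w <= L:
        end = min(w + window - 1, L)
        n_tot = sum(1 for p in tot if w <= p <= end)
        n_aff = sum(1 for p in aff if w <= p <= end)
        rows.append((w, end, n_tot, n_aff,
                     100.0 * n_aff / n_tot if n_tot else None))
        w += step
    return rows


def brute_force_densest(genes, flagged, width):
    best = None
    for g in genes:
        lo, hi = g.start, g.start + width - 1
        inside = [x for x in genes if lo <= x.start <= hi]
        n_aff = sum(1 for x in inside if x.locus_tag in flagged)
        n_tot = len(inside)
        key = (n_aff, n_aff / n_tot if n_tot else 0.0, -lo)
        if best is None or key > best[0]:
            best = (key, (lo, hi), n_aff, n_tot)
    return best[1:]


def uniform_genes(n, L, seed=0, length=200):
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.choice(np.arange(1, L - length, length + 10), size=n,
                                replace=False))
    return [GeneModel(f"g{i}", "c", int(s), int(s) + length - 1, "+")
            for i, s in enumerate(starts)]


# -------------------------------------------------------------------- map_tss


def test_map_tss_singleton_plus_strand():
    genes = [GeneModel("g1", "c", 100, 400, "+")]
    out = clusters.map_tss({"g1": "up"}, genes)
    assert out.iloc[0]["tss_position"] == 100


def test_map_tss_minus_strand_operon_last_member_affected():
    """An affected last member of a minus-strand operon maps to the operon's
    transcription start: the END of the rightmost (first transcribed) gene."""
    genes = [
        GeneModel("gA", "c", 1000, 1900, "-"),
        GeneModel("gB", "c", 2000, 2900, "-"),
        GeneModel("gC", "c", 3000, 4000, "-"),
    ]
    tus = [TranscriptionUnit("op", ("gC", "gB", "gA"), "-", 4000)]
    out = clusters.map_tss({"gA": "up"}, genes, tus)
    assert len(out) == 1
    assert out.iloc[0]["tss_position"] == 4000


def test_map_tss_deduplicates_within_tu():
    genes = [GeneModel("gA", "c", 100, 400, "+"), GeneModel("gB", "c", 500, 900, "+")]
    tus = [TranscriptionUnit("op", ("gA", "gB"), "+", 100)]
    out = clusters.map_tss({"gA": "up", "gB": "up"}, genes, tus)
    assert len(out) == 1


def test_map_tss_missing_gene_raises_with_tags():
    genes = [GeneModel("gA", "c", 100, 400, "+")]
    with pytest.raises(ParameterError, match="ghost"):
        clusters.map_tss({"ghost": "up"}, genes)


# ---------------------------------------------------------------- window scan


def test_window_scan_no_affected_gives_zero_percents():
    tot = np.arange(1000, 100_000, 1000)
    scan = clusters.window_scan([], tot, 100_000, 25_000, 12_500)
    assert (scan["percent"].dropna() == 0).all()


def test_window_scan_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for trial in range(30):
        L = int(rng.integers(50_000, 400_000))
        n = int(rng.integers(10, 200))
        tot = np.sort(rng.integers(1, L + 1, size=n))
        aff = np.sort(rng.choice(tot, size=int(rng.integers(0, n)), replace=False))
        window = int(rng.integers(5_000, 100_000))
        step = int(rng.integers(1_000, window + 1))
        scan = clusters.window_scan(aff, tot, L, window, step)
        oracle = brute_force_scan(aff, tot, L, window, step)
        assert len(scan) == len(oracle)
        for row, (w, e, n_tot, n_aff, pct) in zip(scan.itertuples(), oracle):
            assert (row.window_start, row.window_end) == (w, e)
            assert (row.n_total, row.n_affected) == (n_tot, n_aff)
            if pct is None:
                assert np.isnan(row.percent)
            else:
                assert row.percent == pytest.approx(pct)


def test_window_scan_tiling_partition_counts_each_position_once():
    tot = np.arange(500, 100_000, 777)
    aff = tot[::3]
    scan = clusters.window_scan(aff, tot, 100_000, 10_000, 10_000)
    assert scan["n_affected"].sum() == len(aff)
    assert scan["n_total"].sum() == len(tot)


def test_window_scan_localized_cluster_exceeds_threshold_only_nearby():
    """20 affected of 100 uniformly spread TUs, all within 300-400 kb, light
    up only windows overlapping that span."""
    tot = np.arange(5_000, 1_000_000, 10_000)  # 100 positions
    aff = tot[(tot >= 300_000) & (tot < 400_000)][:20]
    scan = clusters.window_scan(aff, tot, 1_000_000)
    hot = scan[scan["percent"] > 5]
    assert not hot.empty
    assert (hot["window_end"] >= 300_000).all() and (hot["window_start"] <= 400_000).all()
    far = scan[(scan["window_end"] < 300_000) | (scan["window_start"] > 400_000)]
    assert (far["percent"].dropna() == 0).all()


def test_window_scan_short_genome_single_clipped_window():
    scan = clusters.window_scan([10], [10, 20], 1_000, 250_000, 125_000)
    assert len(scan) == 1
    assert scan.iloc[0]["window_end"] == 1_000


def test_window_scan_rejects_bad_geometry():
    with pytest.raises(ParameterError):
        clusters.window_scan([], [], 1000, 100, 200)


# --------------------------------------------------------------- call_clusters


def test_call_clusters_empty_when_nothing_qualifies():
    tot = np.arange(1000, 200_000, 1000)
    scan = clusters.window_scan([], tot, 200_000, 50_000, 25_000)
    assert clusters.call_clusters(scan, [], tot, "up") == []


def test_call_clusters_merges_overlapping_windows():
    """Two qualifying half-overlapping windows become one merged call whose
    span is their union (interval-union oracle)."""
    tot = np.arange(1000, 500_001, 1000)
    aff = np.arange(100_000, 180_000, 2_000)  # dense patch
    scan = clusters.window_scan(aff, tot, 500_000, 250_000, 125_000)
    qual = scan[scan["percent"] > 5]
    assert len(qual) >= 2
    calls = clusters.call_clusters(scan, aff, tot, "up")
    assert len(calls) == 1
    assert calls[0].start == qual["window_start"].min()
    assert calls[0].end == qual["window_end"].max()
    assert calls[0].peak_window_percent == pytest.approx(qual["percent"].max())
    assert calls[0].n_affected == len(aff)


def test_call_clusters_threshold_is_strict():
    # 1 affected of 20 in one tiling window = exactly 5%: must not qualify
    tot = np.arange(1, 21).astype(np.int64) * 10
    aff = [10]
    scan = clusters.window_scan(aff, tot, 200, 200, 200)
    assert scan.iloc[0]["percent"] == pytest.approx(5.0)
    assert clusters.call_clusters(scan, aff, tot, "up") == []


def test_direction_separation():
    """Calls for one direction depend only on that direction's positions."""
    tot = np.arange(1000, 300_001, 1000)
    up = np.arange(50_000, 80_000, 1_500)
    down = np.arange(200_000, 230_000, 1_500)
    scan_up = clusters.window_scan(up, tot, 300_000, 50_000, 25_000)
    calls_up = clusters.call_clusters(scan_up, up, tot, "up")
    scan_up2 = clusters.window_scan(up, tot, 300_000, 50_000, 25_000)
    calls_up2 = clusters.call_clusters(scan_up2, up, tot, "up")
    assert calls_up == calls_up2
    assert all(c.direction == "up" for c in calls_up)
    assert calls_up and all(c.start < 100_000 for c in calls_up)


# -------------------------------------------------------------- densest region


def test_densest_region_single_affected_gene():
    genes = uniform_genes(30, 100_000, seed=1)
    (lo, hi), n_aff, n_tot = clusters.densest_region(genes, [genes[7].locus_tag],
                                                     width=5_000)
    assert n_aff == 1
    assert lo <= genes[7].start <= hi


def test_densest_region_mirrors_hypersensitive_cluster_counts():
    """34 genes tiled over 30 kb with 26 flagged: the scan returns that span
    with counts (26, 34) — checked against exhaustive anchor enumeration."""
    spacing = 30_000 // 34
    genes = [
        GeneModel(f"s{i}", "c", 200_000 + i * spacing,
                  200_000 + i * spacing + 400, "+")
        for i in range(34)
    ]
    # distant background genes, none affected
    genes += [GeneModel(f"b{i}", "c", 500_000 + i * 2_000,
                        500_000 + i * 2_000 + 400, "+") for i in range(50)]
    flagged = [f"s{i}" for i in range(26)]
    result = clusters.densest_region(genes, flagged, width=30_000)
    oracle = brute_force_densest(sorted(genes, key=lambda g: g.start),
                                 set(flagged), 30_000)
    assert result == oracle
    (lo, hi), n_aff, n_tot = result
    assert (n_aff, n_tot) == (26, 34)
    assert lo == 200_000


def test_densest_region_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(7)
    for trial in range(200):
        n = int(rng.integers(2, 60))
        genes = uniform_genes(n, 80_000, seed=trial)
        flags = {g.locus_tag for g in genes if rng.random() < 0.3}
        if not flags:
            flags = {genes[0].locus_tag}
        width = int(rng.integers(1_000, 40_000))
        assert clusters.densest_region(genes, flags, width) == \
            brute_force_densest(genes, flags, width)


def test_densest_region_requires_affected():
    genes = uniform_genes(5, 50_000)
    with pytest.raises(ParameterError):
        clusters.densest_region(genes, [])
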