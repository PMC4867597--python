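"""Unit tests for peak calling, densities, metagene profiles and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from riboclip import (
    Annotation,
    BinScheme,
    PeakCall,
    ReadSet,
    TranscriptModel,
    call_peaks,
    define_targets,
    metagene_profile,
    poisson_upper_tail,
    region_density,
    replicate_correlation,
)
from riboclip.clip_peaks import PEAK_COLUMNS

from conftest import make_tx_reads


def _long_tx(total=4000, utr5=200, utr3=300, tid="tL", gid="gL"):
    cds = total - utr5 - utr3
    return TranscriptModel(tid, gid, "chr1", "+", utr5, cds, utr3, ((0, total),))


# --- Poisson tail ------------------------------------------------------------


def test_poisson_tail_matches_partial_sum():
    # P(X >= 10 | lam = 2) by explicit complement of the lower partial sum
    lam, k = 2.0, 10
    import math

    lower = sum(math.exp(-lam) * lam**i / math.factorial(i) for i in range(k))
    assert poisson_upper_tail(10, 2.0) == pytest.approx(1 - lower, abs=1e-14)


def test_poisson_tail_edge_cases():
    assert poisson_upper_tail(0, 5.0) == pytest.approx(1.0)
    assert 0 < poisson_upper_tail(100, 1.0) < 1e-100


# --- peak calling ------------------------------------------------------------


def test_proportional_ip_and_control_yield_no_peaks():
    """IP = 10x uniform control is null by construction: zero significant peaks."""
    m = _long_tx()
    ann = Annotation([m])
    rng = np.random.default_rng(0)
    ctl_pos = rng.integers(0, m.total_len, size=2000)
    ip_pos = rng.integers(0, m.total_len, size=20_000)
    ip = make_tx_reads([("tL", int(p)) for p in ip_pos], "ip")
    ctl = make_tx_reads([("tL", int(p)) for p in ctl_pos], "ctl")
    pc = call_peaks(ip, ctl, ann)
    assert pc.n_peaks == 0
    tested = pc.windows[pc.windows.tested]
    assert (tested.q <= 0.05).mean() <= 0.05


def test_single_spike_gives_one_peak_with_summit_inside():
    """Uniform 0.1 reads/nt plus one 50-nt window at 20x -> exactly one peak."""
    m = _long_tx()
    ann = Annotation([m])
    rng = np.random.default_rng(1)
    bg = rng.integers(0, m.total_len, size=int(0.1 * m.total_len))
    spike_lo, spike_hi = 1000, 1050
    spike = rng.integers(spike_lo, spike_hi, size=int(0.1 * 50 * 20))
    ip = make_tx_reads([("tL", int(p)) for p in np.concatenate([bg, spike])], "ip")
    ctl = make_tx_reads(
        [("tL", int(p)) for p in rng.integers(0, m.total_len, size=500)], "ctl"
    )
    pc = call_peaks(ip, ctl, ann)
    assert pc.n_peaks == 1
    peak = pc.peaks.iloc[0]
    assert spike_lo <= peak.tsummit < spike_hi
    assert peak.gene_id == "gL"
    # genomic summit agrees with the transcript summit on this single-block tx
    assert peak.summit == peak.tsummit


def test_empty_ip_raises():
    ann = Annotation([_long_tx()])
    empty = make_tx_reads([], "ip")
    with pytest.raises(ValueError, match="empty"):
        call_peaks(empty, None, ann)


def test_missing_control_falls_back_to_gene_background(caplog):
    m = _long_tx()
    ann = Annotation([m])
    rng = np.random.default_rng(2)
    ip = make_tx_reads(
        [("tL", int(p)) for p in rng.integers(0, m.total_len, size=5000)], "ip"
    )
    import logging

    with caplog.at_level(logging.WARNING, logger="riboclip.clip_peaks"):
        pc = call_peaks(ip, None, ann)
    assert "control" in caplog.text.lower()
    assert pc.n_peaks == 0  # uniform reads: nothing enriched


def test_peak_call_write_bed(tmp_path):
    m = _long_tx()
    ann = Annotation([m])
    rng = np.random.default_rng(1)
    bg = rng.integers(0, m.total_len, size=400)
    spike = rng.integers(1000, 1050, size=120)
    ip = make_tx_reads([("tL", int(p)) for p in np.concatenate([bg, spike])], "ip")
    pc = call_peaks(ip, None, ann)
    out = tmp_path / "peaks.bed"
    pc.write_bed(str(out))
    df = pd.read_csv(out, sep="\t")
    assert len(df) == pc.n_peaks
    assert {"chrom", "start", "end", "strand", "summit", "q", "gene_id"} <= set(df.columns)


# --- densities and metagene --------------------------------------------------


def test_region_density_counts_read_anchor_classes(toy_annotation):
    reads = make_tx_reads([("tA", 5), ("tA", 15), ("tA", 45)], "r")
    df = region_density(reads, toy_annotation).set_index("region_class")
    assert df.loc["utr5", "count"] == 1
    assert df.loc["cds", "count"] == 1
    assert df.loc["utr3", "count"] == 1
    # density normalizes by class length in kb
    assert df.loc["cds", "density_per_kb"] == pytest.approx(
        1 / (df.loc["cds", "length_nt"] / 1000)
    )


def test_region_density_zero_length_class_is_nan(tx_plus):
    ann = Annotation([tx_plus], tts_length=10)
    df = region_density(make_tx_reads([("tA", 5)], "r"), ann).set_index("region_class")
    assert np.isnan(df.loc["pseudogene", "density_per_kb"])
    assert df.loc["pseudogene", "count"] == 0


def test_metagene_single_anchor_lands_in_first_utr5_bin():
    m = TranscriptModel("t1", "g1", "c", "+", 100, 300, 100, ((0, 500),))
    ann = Annotation([m])
    prof = metagene_profile(make_tx_reads([("t1", 1)], "r"), ann, scheme=BinScheme(50))
    assert prof.counts["utr5"][0] == 1
    assert prof.counts["utr5"][1:].sum() == 0
    assert prof.counts["cds"].sum() == 0
    assert prof.counts["utr3"].sum() == 0
    assert prof.extents["utr5"].sum() == 100


def test_metagene_gene_without_utr5_excluded_from_that_region_only():
    m1 = TranscriptModel("t1", "g1", "c", "+", 0, 300, 100, ((0, 400),))
    m2 = TranscriptModel("t2", "g2", "c", "+", 50, 300, 100, ((500, 950),))
    prof = metagene_profile(make_tx_reads([("t1", 10)], "r"), Annotation([m1, m2]))
    assert prof.n_genes["utr5"] == 1  # only g2 has a 5'-UTR
    assert prof.n_genes["cds"] == 2
    assert prof.extents["utr5"].sum() == 50


def test_metagene_gene_filter_restricts_counts_and_extents():
    m1 = TranscriptModel("t1", "g1", "c", "+", 100, 300, 100, ((0, 500),))
    m2 = TranscriptModel("t2", "g2", "c", "+", 100, 300, 100, ((600, 1100),))
    ann = Annotation([m1, m2])
    reads = make_tx_reads([("t1", 5), ("t2", 5)], "r")
    prof = metagene_profile(reads, ann, gene_filter={"g1"})
    assert prof.counts["utr5"].sum() == 1
    assert prof.extents["utr5"].sum() == 100
    with pytest.raises(ValueError):
        metagene_profile(reads, ann, gene_filter={"absent"})


# --- target definition -------------------------------------------------------


def _peakcall_from(gene_qs):
    rows = []
    for i, (gid, q) in enumerate(gene_qs):
        rows.append(
            dict.fromkeys(PEAK_COLUMNS, 0)
            | {"gene_id": gid, "q": q, "chrom": "c", "strand": "+"}
        )
    return PeakCall(peaks=pd.DataFrame(rows, columns=PEAK_COLUMNS), windows=pd.DataFrame())


def test_define_targets_trivial_cases():
    assert define_targets(_peakcall_from([])) == set()
    pc = _peakcall_from([("g1", 0.001), ("g1", 0.04), ("g1", 0.2), ("g2", 0.5)])
    assert define_targets(pc) == {"g1"}
    assert define_targets(pc, q_threshold=0.0005) == set()


# --- replicate correlation ---------------------------------------------------


def test_replicate_correlation_identical_is_one(toy_annotation):
    reads = make_tx_reads([("tA", 5), ("tA", 15), ("tB", 3), ("tB", 20)], "r")
    r = replicate_correlation(reads, reads, toy_annotation)
    assert r == pytest.approx(1.0)


def test_replicate_correlation_independent_noise_is_small():
    rng = np.random.default_rng(3)
    hits = 0
    for _ in range(20):
        x = rng.poisson(5.0, size=1000)
        y = rng.poisson(5.0, size=1000)
        if abs(replicate_correlation(x, y)) < 0.1:
            hits += 1
    assert hits >= 19  # |r| < 0.1 in at least 95% of draws


def test_replicate_correlation_zero_variance_raises():
    with pytest.raises(ValueError, match="variance"):
        replicate_correlation(np.ones(10), np.arange(10.0))


def test_replicate_correlation_shape_mismatch_raises():
    with pytest.raises(ValueError, match="grid"):
        replicate_correlation(np.ones(10), np.ones(9))


def test_replicate_correlation_window_unit(toy_annotation):
    reads = make_tx_reads([("tA", 5), ("tA", 55), ("tB", 3)], "r")
    r = replicate_correlation(reads, reads, toy_annotation, unit="window")
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError, match="unit"):
        replicate_correlation(reads, reads, toy_annotation, unit="exon")
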