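"""Unit tests for coordinates, binning, class partition and annotation I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riboclip import (
    Annotation,
    AnnotationError,
    CLASS_PRECEDENCE,
    REGIONS,
    TranscriptModel,
    bin_extents,
    bin_index,
    build_class_map,
    canonical_transcripts,
    classify_position,
    load_annotation,
    read_gtf,
    read_transcript_tsv,
    to_transcript_coords,
    write_gtf,
    write_transcript_tsv,
)


# --- binning -----------------------------------------------------------------


def test_bin_index_matches_floor_oracle_exhaustively():
    for L in range(1, 41):
        for n in range(1, 11):
            got = bin_index(np.arange(L), L, n)
            want = [min((off * n) // L, n - 1) for off in range(L)]
            assert got.tolist() == want


def test_bin_extents_match_bin_index_counts():
    for L in (1, 7, 49, 50, 51, 1000):
        for n in (1, 20, 50):
            ext = bin_extents(L, n)
            counts = np.bincount(bin_index(np.arange(L), L, n), minlength=n)
            assert ext.tolist() == counts.tolist()
            assert ext.sum() == L


def test_bin_extents_zero_length_region_is_all_zero():
    assert bin_extents(0, 20).tolist() == [0] * 20


def test_bin_index_rejects_nonpositive_region():
    with pytest.raises(ValueError):
        bin_index(np.array([0]), 0, 20)


@given(
    L=st.integers(min_value=1, max_value=10_000),
    n=st.integers(min_value=1, max_value=100),
    data=st.data(),
)
def test_bin_index_in_range_property(L, n, data):
    off = data.draw(st.integers(min_value=0, max_value=L - 1))
    b = int(bin_index(np.array([off]), L, n)[0])
    assert 0 <= b < n
    # floor rule: offset at a ceil-edge boundary starts the next bin
    assert b == min((off * n) // L, n - 1)


# --- transcript coordinates --------------------------------------------------


def test_region_of_boundaries(tx_plus):
    assert tx_plus.region_of(0) == ("utr5", 0)
    assert tx_plus.region_of(9) == ("utr5", 9)
    assert tx_plus.region_of(10) == ("cds", 0)
    assert tx_plus.region_of(39) == ("cds", 29)
    assert tx_plus.region_of(40) == ("utr3", 0)
    assert tx_plus.region_of(59) == ("utr3", 19)
    with pytest.raises(ValueError):
        tx_plus.region_of(60)


def test_genomic_roundtrip_plus_and_minus(tx_plus, tx_minus):
    for m in (tx_plus, tx_minus):
        for tpos in range(m.total_len):
            g = m.genomic_position(tpos)
            assert to_transcript_coords(m.chrom, g, m) == m.region_of(tpos)


def test_genomic_positions_vectorized_matches_scalar(tx_minus):
    tpos = np.arange(tx_minus.total_len)
    vec = tx_minus.genomic_positions(tpos)
    assert vec.tolist() == [tx_minus.genomic_position(int(t)) for t in tpos]


def test_minus_strand_five_prime_end_is_rightmost(tx_minus):
    assert tx_minus.genomic_position(0) == 331  # max end - 1


def test_strand_flip_preserves_region_sequence(tx_plus):
    """Mirroring a transcript onto the minus strand preserves region_of per tpos."""
    hi = 1000
    mirrored_blocks = tuple(
        (hi - e, hi - s) for s, e in tx_plus.blocks
    )
    flipped = TranscriptModel(
        transcript_id="tA_rc",
        gene_id="gA_rc",
        chrom="chr1",
        strand="-",
        utr5_len=tx_plus.utr5_len,
        cds_len=tx_plus.cds_len,
        utr3_len=tx_plus.utr3_len,
        blocks=tuple(sorted(mirrored_blocks, reverse=True)),
    )
    for tpos in range(tx_plus.total_len):
        assert flipped.region_of(tpos) == tx_plus.region_of(tpos)
        # genomic positions are mirrored: g' = hi - 1 - g
        assert flipped.genomic_position(tpos) == hi - 1 - tx_plus.genomic_position(tpos)


def test_region_genomic_intervals_cover_region(tx_minus):
    for region in REGIONS:
        ivals = tx_minus.region_genomic_intervals(region)
        assert sum(e - s for s, e in ivals) == tx_minus.region_len(region)


# --- validation --------------------------------------------------------------


def test_model_rejects_overlapping_blocks():
    with pytest.raises(AnnotationError):
        TranscriptModel("t", "g", "c", "+", 0, 3, 0, blocks=((0, 2), (1, 3)))


def test_model_rejects_bad_strand():
    with pytest.raises(AnnotationError):
        TranscriptModel("t", "g", "c", ".", 0, 3, 0, blocks=((0, 3),))


def test_model_rejects_region_span_mismatch():
    with pytest.raises(AnnotationError):
        TranscriptModel("t", "g", "c", "+", 5, 10, 5, blocks=((0, 10),))


def test_model_rejects_misordered_minus_blocks():
    with pytest.raises(AnnotationError):
        TranscriptModel("t", "g", "c", "-", 0, 20, 0, blocks=((0, 10), (15, 25)))


def test_annotation_rejects_duplicate_ids(tx_plus):
    with pytest.raises(AnnotationError):
        Annotation([tx_plus, tx_plus])


# --- genomic class partition -------------------------------------------------


def test_class_map_is_a_partition(toy_annotation):
    cmap = toy_annotation.class_map
    assert cmap.total_span == sum(cmap.class_lengths.values())
    # every single base gets exactly one class, consistent scalar vs vector
    pos = np.arange(0, 1900)
    codes = cmap.classify_many("chr1", pos)
    for p in (0, 99, 100, 150, 331, 500, 699, 700, 1800):
        assert CLASS_PRECEDENCE[codes[p]] == cmap.classify("chr1", int(p))


def test_class_map_known_labels(toy_annotation, tx_plus, tx_minus):
    cmap = toy_annotation.class_map
    assert cmap.classify("chr1", 100) == "utr5"  # tx_plus 5'-UTR start
    assert cmap.classify("chr1", 110) == "cds"
    assert cmap.classify("chr1", 159) == "utr3"
    assert cmap.classify("chr1", 160) == "tts"  # downstream of plus-strand 3' end
    # tx_minus's intron is overlapped by tx_plus's TTS window; TTS outranks intron
    assert cmap.classify("chr1", 315) == "tts"
    assert cmap.classify("chr1", 331) == "utr5"  # minus-strand 5' end
    assert cmap.classify("chr1", 299) == "tts"  # downstream of minus-strand 3' end
    assert cmap.classify("chr1", 600) == "ncRNA"
    assert cmap.classify("chr1", 50) == "tts"  # inside tx_minus's clipped TTS window
    assert cmap.classify("chr1", 2000) == "intergenic"  # beyond the annotated span
    assert cmap.classify("chrUnknown", 5) == "intergenic"


def test_intron_labeled_when_unshadowed(tx_minus):
    cmap = build_class_map([tx_minus], tts_length=10)
    assert cmap.classify("chr1", 315) == "intron"


def test_precedence_cds_beats_ncrna(tx_plus, tx_ncrna):
    overlap = TranscriptModel(
        transcript_id="tOv",
        gene_id="gOv",
        chrom="chr1",
        strand="+",
        utr5_len=0,
        cds_len=0,
        utr3_len=0,
        blocks=((90, 170),),
        biotype="ncRNA",
    )
    cmap = build_class_map([tx_plus, overlap])
    assert cmap.classify("chr1", 120) == "cds"
    assert cmap.classify("chr1", 95) == "ncRNA"
    assert classify_position("chr1", 120, "+", cmap) == "cds"


# --- canonical selection -----------------------------------------------------


def test_canonical_prefers_longest_cds_then_length_then_id():
    def mk(tid, u5, cds, u3, start):
        total = u5 + cds + u3
        return TranscriptModel(tid, "g1", "c", "+", u5, cds, u3, ((start, start + total),))

    a = mk("t1", 10, 30, 10, 0)
    b = mk("t2", 10, 60, 10, 100)  # longest CDS wins
    assert canonical_transcripts([a, b])[0].transcript_id == "t2"
    c = mk("t3", 50, 30, 10, 200)  # same CDS as a, longer transcript
    assert canonical_transcripts([a, c])[0].transcript_id == "t3"
    d = mk("t0", 10, 30, 10, 300)  # full tie with a: lexicographic id
    assert canonical_transcripts([a, d])[0].transcript_id == "t0"


# --- I/O ---------------------------------------------------------------------


def test_tsv_roundtrip(tmp_path, toy_annotation):
    path = str(tmp_path / "tx.tsv")
    write_transcript_tsv(toy_annotation.transcripts, path)
    back = read_transcript_tsv(path)
    assert sorted(m.transcript_id for m in back) == ["tA", "tB", "tC"]
    by_id = {m.transcript_id: m for m in back}
    for m in toy_annotation.transcripts:
        assert by_id[m.transcript_id] == m


def test_gtf_roundtrip(tmp_path, toy_annotation):
    path = str(tmp_path / "tx.gtf")
    write_gtf(toy_annotation.transcripts, path)
    back = {m.transcript_id: m for m in read_gtf(path)}
    for m in toy_annotation.transcripts:
        b = back[m.transcript_id]
        assert (b.utr5_len, b.cds_len, b.utr3_len) == (m.utr5_len, m.cds_len, m.utr3_len)
        assert tuple(sorted(b.blocks)) == tuple(sorted(m.blocks))
        assert b.strand == m.strand and b.gene_id == m.gene_id


def test_load_annotation_dispatches_by_extension(tmp_path, toy_annotation):
    gtf = str(tmp_path / "a.gtf")
    tsv = str(tmp_path / "a.tsv")
    write_gtf(toy_annotation.transcripts, gtf)
    write_transcript_tsv(toy_annotation.transcripts, tsv)
    from_gtf = load_annotation(gtf)
    from_tsv = load_annotation(tsv)
    assert [m.transcript_id for m in from_gtf.canonical] == [
        m.transcript_id for m in from_tsv.canonical
    ]


def test_read_tsv_reports_line_of_bad_record(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "transcript_id\tgene_id\tchrom\tstrand\tutr5_len\tcds_len\tutr3_len\tblocks\tbiotype\n"
        "t1\tg1\tc\t+\t5\t10\t5\t0-10\tprotein_coding\n"
    )
    with pytest.raises(AnnotationError, match="line 2"):
        read_transcript_tsv(str(path))
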