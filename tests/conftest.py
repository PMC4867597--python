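"""Shared fixtures: small handcrafted transcript models and read-set builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from riboclip import Annotation, ReadSet, TranscriptModel

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def tx_plus() -> TranscriptModel:
    """Single-exon plus-strand coding transcript: utr5=10, cds=30, utr3=20."""
    return TranscriptModel(
        transcript_id="tA",
        gene_id="gA",
        chrom="chr1",
        strand="+",
        utr5_len=10,
        cds_len=30,
        utr3_len=20,
        blocks=((100, 160),),
    )


@pytest.fixture
def tx_minus() -> TranscriptModel:
    """Two-exon minus-strand coding transcript: utr5=6, cds=12, utr3=6."""
    return TranscriptModel(
        transcript_id="tB",
        gene_id="gB",
        chrom="chr1",
        strand="-",
        utr5_len=6,
        cds_len=12,
        utr3_len=6,
        blocks=((320, 332), (300, 312)),
    )


@pytest.fixture
def tx_ncrna() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="tC",
        gene_id="gC",
        chrom="chr1",
        strand="+",
        utr5_len=0,
        cds_len=0,
        utr3_len=0,
        blocks=((500, 700),),
        biotype="ncRNA",
    )


@pytest.fixture
def toy_annotation(tx_plus, tx_minus, tx_ncrna) -> Annotation:
    return Annotation([tx_plus, tx_minus, tx_ncrna])


def make_tx_reads(pairs, sample_id="test", length=1) -> ReadSet:
    """ReadSet in transcript coordinates from (transcript_id, pos5) pairs."""
    df = pd.DataFrame(
        {
            "transcript_id": [t for t, _ in pairs],
            "pos5": np.array([p for _, p in pairs], dtype=np.int64),
            "length": length,
            "strand": "+",
        }
    )
    return ReadSet(sample_id, df, coords="transcript")
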