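"""Strand-aware read interval sets in genomic or mature-transcript coordinates.

Reads carry no sequence: every downstream analysis anchors each read to a
single nucleotide (its 5' end plus an optional offset, e.g. a ribosome P-site
offset), so only intervals and strands are stored.  Two layouts are
supported:

* genomic: BED6-style (chrom, start, end, strand), 0-based half-open;
* transcript: (transcript_id, pos5, length, strand) where pos5 is the read's
  5'-end coordinate on the mature (exon-joined) transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation

logger = logging.getLogger(__name__)

GENOMIC_COLUMNS = ["chrom", "start", "end", "strand"]
TRANSCRIPT_COLUMNS = ["transcript_id", "pos5", "length", "strand"]


@dataclass
class ReadSet:
    """A labeled collection of aligned-read intervals."""

    sample_id: str
    records: pd.DataFrame
    coords: str = "genomic"  # "genomic" | "transcript"

    def __post_init__(self) -> None:
        if self.coords not in ("genomic", "transcript"):
            raise ValueError(f"coords must be 'genomic' or 'transcript', got {self.coords!r}")
        cols = GENOMIC_COLUMNS if self.coords == "genomic" else TRANSCRIPT_COLUMNS
        missing = [c for c in cols if c not in self.records.columns]
        if missing:
            raise ValueError(f"ReadSet {self.sample_id}: missing columns {missing}")
        if self.coords == "genomic":
            if len(self.records) and not (self.records.start < self.records.end).all():
                raise ValueError(f"ReadSet {self.sample_id}: start must be < end")
        elif len(self.records) and not (self.records.length > 0).all():
            raise ValueError(f"ReadSet {self.sample_id}: read length must be positive")

    @property
    def total_mapped(self) -> int:
        return len(self.records)

    # -- anchoring ---------------------------------------------------------

    def transcript_anchors(
        self, annotation: Annotation, offset: int = 0
    ) -> tuple[np.ndarray, np.ndarray, int]:
        """Anchor each read at 5' end + ``offset`` on a canonical transcript.

        Returns (transcript index into annotation.canonical, transcript
        position, n_skipped).  Reads whose anchor misses every canonical exon
        (or runs off the transcript end) are skipped and counted.
        """
        if self.coords == "transcript":
            tid_to_idx = {m.transcript_id: i for i, m in enumerate(annotation.canonical)}
            txi = self.records.transcript_id.map(tid_to_idx).fillna(-1).to_numpy(np.int64)
            tpos = self.records.pos5.to_numpy(np.int64) + offset
            lens = np.array([m.total_len for m in annotation.canonical] + [0], dtype=np.int64)
            ok = (txi >= 0) & (tpos >= 0) & (tpos < lens[txi])
            skipped = int((~ok).sum())
            if skipped:
                logger.info(
                    "%s: %d reads skipped (anchor outside canonical transcripts)",
                    self.sample_id,
                    skipped,
                )
            return txi[ok], tpos[ok], skipped

        txi_all = np.full(len(self.records), -1, dtype=np.int64)
        tpos_all = np.zeros(len(self.records), dtype=np.int64)
        for chrom, grp in self.records.groupby("chrom", sort=False):
            plus = grp.strand.to_numpy() == "+"
            gpos = np.where(
                plus,
                grp.start.to_numpy(np.int64) + offset,
                grp.end.to_numpy(np.int64) - 1 - offset,
            )
            txi, tpos = annotation.map_genomic_positions(
                str(chrom), gpos, strands=grp.strand.to_numpy()
            )
            txi_all[grp.index.to_numpy()] = txi
            tpos_all[grp.index.to_numpy()] = tpos
        ok = txi_all >= 0
        skipped = int((~ok).sum())
        if skipped:
            logger.info(
                "%s: %d reads skipped (anchor outside canonical exons)",
                self.sample_id,
                skipped,
            )
        return txi_all[ok], tpos_all[ok], skipped

    def genomic_anchors(
        self, annotation: Annotation | None = None, offset: int = 0
    ) -> pd.DataFrame:
        """Genomic anchor position per read: 5' end + offset in read orientation.

        Returns a frame (chrom, pos).  Transcript-space reads require an
        ``annotation`` to project anchors back to the genome; anchors beyond
        the transcript end are dropped.
        """
        if self.coords == "genomic":
            plus = self.records.strand.to_numpy() == "+"
            pos = np.where(
                plus,
                self.records.start.to_numpy(np.int64) + offset,
                self.records.end.to_numpy(np.int64) - 1 - offset,
            )
            return pd.DataFrame({"chrom": self.records.chrom.to_numpy(), "pos": pos})
        if annotation is None:
            raise ValueError("annotation required to project transcript reads to the genome")
        chroms: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        for tid, grp in self.records.groupby("transcript_id", sort=False):
            model = annotation.by_id.get(str(tid))
            if model is None:
                logger.warning("%s: unknown transcript %r skipped", self.sample_id, tid)
                continue
            tpos = grp.pos5.to_numpy(np.int64) + offset
            ok = (tpos >= 0) & (tpos < model.total_len)
            if (~ok).any():
                logger.info(
                    "%s: %d reads on %s skipped (anchor off transcript)",
                    self.sample_id,
                    int((~ok).sum()),
                    tid,
                )
            g = model.genomic_positions(tpos[ok])
            chroms.append(np.full(g.shape, model.chrom, dtype=object))
            positions.append(g)
        if not chroms:
            return pd.DataFrame({"chrom": [], "pos": []})
        return pd.DataFrame(
            {"chrom": np.concatenate(chroms), "pos": np.concatenate(positions)}
        )


# ---------------------------------------------------------------------------
# I/O


def write_bed6(rs: ReadSet, path: str) -> None:
    if rs.coords != "genomic":
        raise ValueError("write_bed6 requires genomic coordinates")
    df = rs.records
    out = pd.DataFrame(
        {
            "chrom": df.chrom,
            "start": df.start,
            "end": df.end,
            "name": [f"{rs.sample_id}.{i}" for i in range(len(df))],
            "score": 0,
            "strand": df.strand,
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed6(path: str, sample_id: str | None = None) -> ReadSet:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "strand": str},
    )
    return ReadSet(sample_id or str(path), df, coords="genomic")


def write_reads_tsv(rs: ReadSet, path: str) -> None:
    if rs.coords != "transcript":
        raise ValueError("write_reads_tsv requires transcript coordinates")
    rs.records[TRANSCRIPT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str, sample_id: str | None = None) -> ReadSet:
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "strand": str})
    return ReadSet(sample_id or str(path), df, coords="transcript")


def load_reads(path: str, sample_id: str | None = None) -> ReadSet:
    """Load BED6 (.bed) or per-transcript TSV reads by extension."""
    if str(path).lower().endswith(".bed"):
        return read_bed6(path, sample_id)
    return read_reads_tsv(path, sample_id)
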