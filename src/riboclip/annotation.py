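"""Transcriptome region model: coordinate classification and region-normalized binning.

All coordinates are 0-based, half-open, matching BED conventions; GTF input
(1-based, closed) is converted on read.  Each spliced transcript is decomposed
into 5'-UTR, CDS and 3'-UTR segments measured along the mature (exon-joined)
transcript, and the genome is partitioned into disjoint annotation classes
(CDS, 5'-UTR, 3'-UTR, ncRNA, pseudogene, TTS, intron, intergenic) with a fixed
precedence so every base receives exactly one label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mRNA regions in 5'->3' order along the mature transcript.
REGIONS = ("utr5", "cds", "utr3")

#: Genomic annotation classes, highest precedence first.  A base covered by
#: several features is credited to the first matching class, so exonic coding
#: signal is never diluted into introns of overlapping genes.
CLASS_PRECEDENCE = (
    "cds",
    "utr5",
    "utr3",
    "ncRNA",
    "pseudogene",
    "tts",
    "intron",
    "intergenic",
)

_CLASS_CODE = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}

CODING = "protein_coding"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with its 5'-UTR/CDS/3'-UTR decomposition.

    ``blocks`` are genomic exon intervals (start, end), 0-based half-open,
    ordered 5'->3' in transcript orientation (descending genomic coordinate
    for minus-strand transcripts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    blocks: tuple[tuple[int, int], ...]
    biotype: str = CODING

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise AnnotationError(f"{self.transcript_id}: negative region length")
        if not self.blocks:
            raise AnnotationError(f"{self.transcript_id}: no exon blocks")
        for s, e in self.blocks:
            if s >= e:
                raise AnnotationError(f"{self.transcript_id}: empty block ({s},{e})")
        asc = sorted(self.blocks)
        for (s1, e1), (s2, e2) in zip(asc, asc[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping blocks")
        expect = asc if self.strand == "+" else asc[::-1]
        if tuple(expect) != self.blocks:
            raise AnnotationError(
                f"{self.transcript_id}: blocks not ordered 5'->3' in transcript orientation"
            )
        span = sum(e - s for s, e in self.blocks)
        if self.is_coding:
            if self.cds_len <= 0:
                raise AnnotationError(f"{self.transcript_id}: coding transcript needs cds_len > 0")
            if self.utr5_len + self.cds_len + self.utr3_len != span:
                raise AnnotationError(
                    f"{self.transcript_id}: region lengths "
                    f"{self.utr5_len}+{self.cds_len}+{self.utr3_len} != exon span {span}"
                )

    @property
    def is_coding(self) -> bool:
        return self.biotype == CODING

    @property
    def total_len(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def tx_start(self) -> int:
        """Leftmost genomic coordinate."""
        return min(s for s, _ in self.blocks)

    @property
    def tx_end(self) -> int:
        """Rightmost genomic coordinate (exclusive)."""
        return max(e for _, e in self.blocks)

    def region_len(self, region: str) -> int:
        return {"utr5": self.utr5_len, "cds": self.cds_len, "utr3": self.utr3_len}[region]

    def region_of(self, tpos: int) -> tuple[str, int]:
        """Map a mature-transcript coordinate to (region, offset-in-region)."""
        if not 0 <= tpos < self.total_len:
            raise ValueError(f"transcript position {tpos} outside [0,{self.total_len})")
        if tpos < self.utr5_len:
            return "utr5", tpos
        if tpos < self.utr5_len + self.cds_len:
            return "cds", tpos - self.utr5_len
        return "utr3", tpos - self.utr5_len - self.cds_len

    def genomic_position(self, tpos: int) -> int:
        """Genomic coordinate of mature-transcript position ``tpos``."""
        if not 0 <= tpos < self.total_len:
            raise ValueError(f"transcript position {tpos} outside [0,{self.total_len})")
        c = 0
        for s, e in self.blocks:
            w = e - s
            if tpos < c + w:
                off = tpos - c
                return s + off if self.strand == "+" else e - 1 - off
            c += w
        raise AssertionError("unreachable")

    def genomic_positions(self, tpos: np.ndarray) -> np.ndarray:
        """Vectorized genomic coordinates for mature-transcript positions."""
        tpos = np.asarray(tpos, dtype=np.int64)
        if tpos.size and (tpos.min() < 0 or tpos.max() >= self.total_len):
            raise ValueError("transcript positions outside transcript bounds")
        widths = np.array([e - s for s, e in self.blocks], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(widths)])
        idx = np.searchsorted(cum, tpos, side="right") - 1
        off = tpos - cum[idx]
        starts = np.array([s for s, _ in self.blocks], dtype=np.int64)
        ends = np.array([e for _, e in self.blocks], dtype=np.int64)
        if self.strand == "+":
            return starts[idx] + off
        return ends[idx] - 1 - off

    def region_genomic_intervals(self, region: str) -> list[tuple[int, int]]:
        """Genomic half-open intervals covered by ``region`` of this transcript."""
        lo = {"utr5": 0, "cds": self.utr5_len, "utr3": self.utr5_len + self.cds_len}[region]
        hi = lo + self.region_len(region)
        out: list[tuple[int, int]] = []
        c = 0
        for s, e in self.blocks:
            w = e - s
            a, b = max(lo, c), min(hi, c + w)
            if a < b:
                if self.strand == "+":
                    out.append((s + (a - c), s + (b - c)))
                else:
                    out.append((e - (b - c), e - (a - c)))
            c += w
        return out


def to_transcript_coords(
    chrom: str, pos: int, model: TranscriptModel
) -> tuple[str, int] | None:
    """Map a genomic position to (region, offset-in-region) on ``model``.

    Returns None when ``pos`` does not fall in any exon block.  Offsets are
    0-based from the region's 5' end in transcript orientation.
    """
    if chrom != model.chrom:
        return None
    c = 0
    for s, e in model.blocks:
        if s <= pos < e:
            off = (pos - s) if model.strand == "+" else (e - 1 - pos)
            return model.region_of(c + off)
        c += e - s
    return None


@dataclass(frozen=True)
class BinScheme:
    """Fixed-bin region normalization: offset -> floor(offset*n/len), clamped."""

    n_bins: int = 50

    def __post_init__(self) -> None:
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")


def bin_index(offset, region_len: int, n_bins: int):
    """Bin of an in-region offset under the floor rule (vectorized).

    Every offset in [0, region_len) maps to exactly one bin in [0, n_bins-1];
    offsets are clamped into the last bin so region_len < n_bins never
    produces an out-of-range index.
    """
    if region_len <= 0:
        raise ValueError("region_len must be positive; zero-length regions are skipped upstream")
    idx = (np.asarray(offset, dtype=np.int64) * n_bins) // region_len
    return np.minimum(idx, n_bins - 1)


def bin_extents(region_len: int, n_bins: int) -> np.ndarray:
    """Nucleotides of a region falling into each bin under the floor rule."""
    if region_len <= 0:
        return np.zeros(n_bins, dtype=np.int64)
    b = np.arange(n_bins + 1, dtype=np.int64)
    edges = -(-b * region_len // n_bins)  # ceil(b*L/n)
    edges[-1] = region_len
    return np.diff(edges)


class RegionClassMap:
    """Disjoint partition of the annotated genome into precedence-resolved classes."""

    def __init__(self, partitions: dict[str, tuple[np.ndarray, np.ndarray]]):
        # partitions: chrom -> (breakpoints[n+1], codes[n]); segments are
        # [bp[i], bp[i+1]) with class code codes[i]; together they tile
        # [0, span) on each chrom.
        self._partitions = partitions
        lengths = np.zeros(len(CLASS_PRECEDENCE), dtype=np.int64)
        for bp, codes in partitions.values():
            seg = np.diff(bp)
            lengths += np.bincount(codes, weights=seg, minlength=len(CLASS_PRECEDENCE)).astype(
                np.int64
            )
        self.class_lengths = {c: int(lengths[i]) for i, c in enumerate(CLASS_PRECEDENCE)}

    @property
    def total_span(self) -> int:
        return int(sum(self.class_lengths.values()))

    def classify(self, chrom: str, pos: int, strand: str | None = None) -> str:
        """Annotation class of a single genomic position.

        Positions on unknown chromosomes or beyond the annotated span are
        intergenic.  ``strand`` is accepted for interface symmetry; classes
        are defined strand-agnostically.
        """
        part = self._partitions.get(chrom)
        if part is None:
            logger.warning("classify: unknown chromosome %r -> intergenic", chrom)
            return "intergenic"
        bp, codes = part
        if pos < bp[0] or pos >= bp[-1]:
            return "intergenic"
        i = int(np.searchsorted(bp, pos, side="right")) - 1
        return CLASS_PRECEDENCE[codes[i]]

    def classify_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Class codes (indices into CLASS_PRECEDENCE) for an array of positions."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, _CLASS_CODE["intergenic"], dtype=np.int64)
        part = self._partitions.get(chrom)
        if part is None:
            if positions.size:
                logger.warning("classify: unknown chromosome %r -> intergenic", chrom)
            return out
        bp, codes = part
        inside = (positions >= bp[0]) & (positions < bp[-1])
        idx = np.searchsorted(bp, positions[inside], side="right") - 1
        out[inside] = codes[idx]
        return out


def build_class_map(
    transcripts: list[TranscriptModel], tts_length: int = 1000
) -> RegionClassMap:
    """Partition the genome spanned by ``transcripts`` into annotation classes.

    The TTS class is the ``tts_length`` nt immediately downstream of each
    transcript's 3' end.  Overlaps are resolved by CLASS_PRECEDENCE.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}

    def add(chrom: str, s: int, e: int, cls: str) -> None:
        s = max(0, s)
        if s < e:
            by_chrom.setdefault(chrom, []).append((s, e, _CLASS_CODE[cls]))

    for m in transcripts:
        if m.is_coding:
            for region in REGIONS:
                for s, e in m.region_genomic_intervals(region):
                    add(m.chrom, s, e, region)
        else:
            cls = m.biotype if m.biotype in ("ncRNA", "pseudogene") else "ncRNA"
            for s, e in m.blocks:
                add(m.chrom, s, e, cls)
        asc = sorted(m.blocks)
        for (s1, e1), (s2, _) in zip(asc, asc[1:]):
            add(m.chrom, e1, s2, "intron")
        if m.strand == "+":
            add(m.chrom, m.tx_end, m.tx_end + tts_length, "tts")
        else:
            add(m.chrom, m.tx_start - tts_length, m.tx_start, "tts")

    partitions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in by_chrom.items():
        span_end = max(e for _, e, _ in ivals)
        bp = np.unique(
            np.concatenate(
                [[0, span_end], [s for s, _, _ in ivals], [e for _, e, _ in ivals]]
            )
        )
        codes = np.full(len(bp) - 1, _CLASS_CODE["intergenic"], dtype=np.int64)
        # paint lowest precedence first so higher precedence overwrites
        for s, e, code in sorted(ivals, key=lambda t: -t[2]):
            i0 = np.searchsorted(bp, s, side="left")
            i1 = np.searchsorted(bp, e, side="left")
            codes[i0:i1] = code
        partitions[chrom] = (bp, codes)
    return RegionClassMap(partitions)


def classify_position(
    chrom: str, pos: int, strand: str, class_map: RegionClassMap
) -> str:
    """Annotation class of one genomic position (see RegionClassMap.classify)."""
    return class_map.classify(chrom, pos, strand)


def canonical_transcripts(transcripts: list[TranscriptModel]) -> list[TranscriptModel]:
    """One transcript per gene: longest CDS, then longest transcript, then id."""
    best: dict[str, TranscriptModel] = {}
    for m in transcripts:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        key_new = (-m.cds_len, -m.total_len, m.transcript_id)
        key_cur = (-cur.cds_len, -cur.total_len, cur.transcript_id)
        if key_new < key_cur:
            best[m.gene_id] = m
    return sorted(best.values(), key=lambda m: m.transcript_id)


class Annotation:
    """Bundle of transcript models and the derived genomic class partition.

    ``canonical`` holds one transcript per gene (metagene analyses require a
    single region decomposition per gene); the class map is built from all
    transcripts.
    """

    def __init__(self, transcripts: list[TranscriptModel], tts_length: int = 1000):
        if not transcripts:
            raise AnnotationError("no transcripts")
        self.transcripts = list(transcripts)
        self.by_id = {m.transcript_id: m for m in self.transcripts}
        if len(self.by_id) != len(self.transcripts):
            raise AnnotationError("duplicate transcript ids")
        self.canonical = canonical_transcripts(self.transcripts)
        self.canonical_by_gene = {m.gene_id: m for m in self.canonical}
        self.class_map = build_class_map(self.transcripts, tts_length=tts_length)
        self._tx_index = {m.transcript_id: i for i, m in enumerate(self.canonical)}
        self._exon_index: dict[str, tuple[np.ndarray, ...]] | None = None

    @property
    def coding_canonical(self) -> list[TranscriptModel]:
        return [m for m in self.canonical if m.is_coding]

    def _build_exon_index(self) -> dict[str, tuple[np.ndarray, ...]]:
        rows: dict[str, list[tuple[int, int, int, int, int]]] = {}
        for m in self.canonical:
            txi = self._tx_index[m.transcript_id]
            c = 0
            for s, e in m.blocks:
                rows.setdefault(m.chrom, []).append(
                    (s, e, txi, c, 1 if m.strand == "+" else 0)
                )
                c += e - s
        out = {}
        for chrom, lst in rows.items():
            lst.sort()
            arr = np.array(lst, dtype=np.int64)
            out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])
        return out

    def map_genomic_positions(
        self, chrom: str, positions: np.ndarray, strands: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map genomic positions to (canonical transcript index, transcript pos).

        Unmapped positions (intronic/intergenic, or strand mismatch when
        ``strands`` is given) get transcript index -1.  Canonical transcripts
        of distinct genes are assumed non-overlapping; with overlapping genes
        the leftmost-starting exon block wins.
        """
        if self._exon_index is None:
            self._exon_index = self._build_exon_index()
        positions = np.asarray(positions, dtype=np.int64)
        txi = np.full(positions.shape, -1, dtype=np.int64)
        tpos = np.zeros(positions.shape, dtype=np.int64)
        idx = self._exon_index.get(chrom)
        if idx is None:
            return txi, tpos
        starts, ends, txs, toffs, is_plus = idx
        j = np.searchsorted(starts, positions, side="right") - 1
        ok = (j >= 0) & (positions < ends[np.maximum(j, 0)])
        jj = j[ok]
        within_plus = positions[ok] - starts[jj]
        within_minus = ends[jj] - 1 - positions[ok]
        tpos_ok = toffs[jj] + np.where(is_plus[jj] == 1, within_plus, within_minus)
        txi_ok = txs[jj]
        if strands is not None:
            strands = np.asarray(strands)
            tx_strand = np.where(is_plus[jj] == 1, "+", "-")
            keep = strands[ok] == tx_strand
            txi_ok = np.where(keep, txi_ok, -1)
        txi[ok] = txi_ok
        tpos[ok] = tpos_ok
        return txi, tpos


# ---------------------------------------------------------------------------
# I/O

TSV_COLUMNS = [
    "transcript_id",
    "gene_id",
    "chrom",
    "strand",
    "utr5_len",
    "cds_len",
    "utr3_len",
    "blocks",
    "biotype",
]


def _blocks_to_str(blocks: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{s}-{e}" for s, e in sorted(blocks))


def _blocks_from_str(text: str, strand: str) -> tuple[tuple[int, int], ...]:
    asc = []
    for part in text.split(";"):
        s, e = part.split("-")
        asc.append((int(s), int(e)))
    asc.sort()
    return tuple(asc) if strand == "+" else tuple(asc[::-1])


def write_transcript_tsv(transcripts: list[TranscriptModel], path: str) -> None:
    rows = [
        {
            "transcript_id": m.transcript_id,
            "gene_id": m.gene_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "utr5_len": m.utr5_len,
            "cds_len": m.cds_len,
            "utr3_len": m.utr3_len,
            "blocks": _blocks_to_str(m.blocks),
            "biotype": m.biotype,
        }
        for m in transcripts
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_transcript_tsv(path: str) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    models = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            models.append(
                TranscriptModel(
                    transcript_id=str(row.transcript_id),
                    gene_id=str(row.gene_id),
                    chrom=str(row.chrom),
                    strand=str(row.strand),
                    utr5_len=int(row.utr5_len),
                    cds_len=int(row.cds_len),
                    utr3_len=int(row.utr3_len),
                    blocks=_blocks_from_str(str(row.blocks), str(row.strand)),
                    biotype=str(getattr(row, "biotype", CODING)),
                )
            )
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"{path} line {i}: {exc}") from exc
    return models


def write_gtf(transcripts: list[TranscriptModel], path: str, source: str = "riboclip") -> None:
    """Write exon and CDS features (1-based closed coordinates, GTF dialect).

    The CDS feature span includes the stop codon, mirroring how cds_len is
    defined on TranscriptModel.
    """
    lines = []
    for m in transcripts:
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'gene_biotype "{m.biotype}";'
        )
        for s, e in sorted(m.blocks):
            lines.append(
                f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}"
            )
        if m.is_coding:
            for s, e in sorted(m.region_genomic_intervals("cds")):
                lines.append(
                    f"{m.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_gtf(path: str) -> list[TranscriptModel]:
    """Build transcript models from a GTF (exon + CDS features).

    Region lengths are derived from exon/CDS geometry; the CDS feature span
    is taken as-is (include the stop codon in the CDS features if cds_len
    should count it).
    """
    import pyranges as pr

    try:
        df = pr.read_gtf(path).df
    except Exception as exc:  # pragma: no cover - library-specific messages
        raise AnnotationError(f"failed to parse GTF {path}: {exc}") from exc
    if df.empty:
        return []
    for col in ("gene_id", "transcript_id"):
        if col not in df.columns:
            raise AnnotationError(f"{path}: GTF attributes must include {col}")
    models = []
    for tid, grp in df.groupby("transcript_id", sort=True):
        exons = grp[grp.Feature == "exon"]
        cds = grp[grp.Feature == "CDS"]
        if exons.empty:
            raise AnnotationError(f"{path}: transcript {tid} has no exon features")
        strand = str(exons.Strand.iloc[0])
        chrom = str(exons.Chromosome.iloc[0])
        gene_id = str(exons.gene_id.iloc[0])
        biotype = (
            str(exons.gene_biotype.iloc[0]) if "gene_biotype" in exons.columns else None
        )
        asc = sorted(zip(exons.Start.astype(int), exons.End.astype(int)))
        blocks = tuple(asc) if strand == "+" else tuple(asc[::-1])
        total = sum(e - s for s, e in asc)
        if cds.empty:
            models.append(
                TranscriptModel(
                    transcript_id=str(tid),
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    utr5_len=0,
                    cds_len=0,
                    utr3_len=0,
                    blocks=blocks,
                    biotype=biotype or "ncRNA",
                )
            )
            continue
        cds_iv = sorted(zip(cds.Start.astype(int), cds.End.astype(int)))
        cds_len = sum(e - s for s, e in cds_iv)
        for s, e in cds_iv:
            if not any(bs <= s and e <= be for bs, be in asc):
                raise AnnotationError(
                    f"{path}: transcript {tid} CDS [{s},{e}) outside exon bounds"
                )
        cds_gstart, cds_gend = cds_iv[0][0], cds_iv[-1][1]
        if strand == "+":
            utr5 = sum(min(e, cds_gstart) - s for s, e in asc if s < cds_gstart)
        else:
            utr5 = sum(e - max(s, cds_gend) for s, e in asc if e > cds_gend)
        utr3 = total - utr5 - cds_len
        models.append(
            TranscriptModel(
                transcript_id=str(tid),
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                utr5_len=int(utr5),
                cds_len=int(cds_len),
                utr3_len=int(utr3),
                blocks=blocks,
                biotype=biotype or CODING,
            )
        )
    return models


def load_annotation(path: str, tts_length: int = 1000) -> Annotation:
    """Load a GTF/GFF or simplified transcript TSV into an Annotation.

    Format is chosen by extension (.gtf/.gff/.gff3 vs anything else = TSV).
    The result is deterministic and independent of record order.
    """
    lower = str(path).lower()
    if lower.endswith((".gtf", ".gff", ".gff3")):
        models = read_gtf(path)
    else:
        models = read_transcript_tsv(path)
    models.sort(key=lambda m: m.transcript_id)
    return Annotation(models, tts_length=tts_length)
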