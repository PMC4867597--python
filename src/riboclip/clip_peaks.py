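"""CLIP peak calling against a matched control, peak densities, and metagene profiles.

The peak caller scans sliding windows along mature-transcript coordinates and
scores each window's IP read count against a Poisson expectation taken as the
largest of (i) the control count scaled by the library-size ratio, (ii) the
transcript-level IP background rate times the window width, and (iii) a
pseudocount.  Window p-values are Benjamini-Hochberg corrected, significant
windows are merged into peaks, and each peak is anchored at its summit (the
position of maximal per-base anchor coverage, ties broken 5'-most).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import (
    Annotation,
    BinScheme,
    CLASS_PRECEDENCE,
    REGIONS,
    bin_extents,
    bin_index,
)
from .reads import ReadSet

logger = logging.getLogger(__name__)

PEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "summit",
    "ip_count",
    "expected",
    "enrichment",
    "p",
    "q",
    "gene_id",
    "transcript_id",
    "tstart",
    "tend",
    "tsummit",
]


def poisson_upper_tail(count, lam):
    """P(X >= count) for X ~ Poisson(lam); the window enrichment p-value."""
    count = np.asarray(count)
    lam = np.asarray(lam, dtype=float)
    return stats.poisson.sf(count - 1, lam)


@dataclass
class PeakCall:
    """Merged enriched windows with scores, plus the full tested-window table."""

    peaks: pd.DataFrame
    windows: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def write_bed(self, path: str) -> None:
        """BED6+ output: name=peak index, score=-10*log10(q)."""
        df = self.peaks
        score = np.minimum(1000, np.round(-10 * np.log10(np.maximum(df.q, 1e-100)))).astype(int)
        out = pd.DataFrame(
            {
                "chrom": df.chrom,
                "start": df.start,
                "end": df.end,
                "name": [f"peak_{i}" for i in range(len(df))],
                "score": score,
                "strand": df.strand,
                "summit": df.summit,
                "ip_count": df.ip_count,
                "expected": df.expected.round(4),
                "enrichment": df.enrichment.round(4),
                "p": df.p,
                "q": df.q,
                "gene_id": df.gene_id,
            }
        )
        out.to_csv(path, sep="\t", index=False)


def _anchor_axis(annotation: Annotation):
    """Concatenate canonical transcripts onto one integer axis."""
    lens = np.array([m.total_len for m in annotation.canonical], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    return lens, offsets


def call_peaks(
    ip: ReadSet,
    control: ReadSet | None,
    annotation: Annotation,
    window: int = 50,
    step: int = 25,
    fdr: float = 0.05,
    pseudocount: float = 1.0,
    min_count: int = 2,
    anchor_offset: int = 0,
) -> PeakCall:
    """Call enriched peaks from IP reads against a matched control.

    Reads are anchored at their 5' ends (+``anchor_offset``) on canonical
    transcripts; windows of ``window`` nt advance by ``step`` nt along each
    transcript.  An empty/absent control triggers transcript-background-only
    mode with a logged warning.
    """
    if ip.total_mapped == 0:
        raise ValueError("IP read set is empty")
    models = annotation.canonical
    lens, offsets = _anchor_axis(annotation)

    ip_txi, ip_tpos, _ = ip.transcript_anchors(annotation, offset=anchor_offset)
    ip_g = np.sort(offsets[ip_txi] + ip_tpos)

    use_control = control is not None and control.total_mapped > 0
    if not use_control:
        logger.warning(
            "empty control: peak expectations use transcript background only"
        )
        ctl_g = np.empty(0, dtype=np.int64)
        lib_ratio = 0.0
    else:
        c_txi, c_tpos, _ = control.transcript_anchors(annotation, offset=anchor_offset)
        ctl_g = np.sort(offsets[c_txi] + c_tpos)
        lib_ratio = ip.total_mapped / control.total_mapped

    # window grid over every canonical transcript
    w_tx, w_start = [], []
    for i, L in enumerate(lens):
        starts = np.arange(0, L, step, dtype=np.int64)
        w_tx.append(np.full(starts.shape, i, dtype=np.int64))
        w_start.append(starts)
    w_tx = np.concatenate(w_tx)
    w_start = np.concatenate(w_start)
    w_end = np.minimum(w_start + window, lens[w_tx])
    gs = offsets[w_tx] + w_start
    ge = offsets[w_tx] + w_end

    ip_count = np.searchsorted(ip_g, ge) - np.searchsorted(ip_g, gs)
    per_tx_ip = np.searchsorted(ip_g, offsets[1:]) - np.searchsorted(ip_g, offsets[:-1])
    gene_bg = per_tx_ip[w_tx] / lens[w_tx] * (w_end - w_start)
    expected = np.maximum(gene_bg, pseudocount)
    if use_control:
        ctl_count = np.searchsorted(ctl_g, ge) - np.searchsorted(ctl_g, gs)
        expected = np.maximum(expected, ctl_count * lib_ratio)

    pvals = poisson_upper_tail(ip_count, expected)
    tested = ip_count >= min_count
    qvals = np.full(pvals.shape, np.nan)
    if tested.any():
        qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    windows_df = pd.DataFrame(
        {
            "transcript_id": [models[i].transcript_id for i in w_tx],
            "tstart": w_start,
            "tend": w_end,
            "ip_count": ip_count,
            "expected": expected,
            "p": pvals,
            "q": qvals,
            "tested": tested,
        }
    )

    sig = tested & (qvals <= fdr)
    peak_rows = []
    for txi in np.unique(w_tx[sig]):
        m = models[txi]
        sel = sig & (w_tx == txi)
        starts, ends = w_start[sel], w_end[sel]
        wq = qvals[sel]
        order = np.argsort(starts)
        starts, ends, wq = starts[order], ends[order], wq[order]
        tx_anchors = ip_g[np.searchsorted(ip_g, offsets[txi]) : np.searchsorted(ip_g, offsets[txi + 1])] - offsets[txi]
        cs, ce, cq = starts[0], ends[0], wq[0]
        merged = []
        for s, e, q in zip(starts[1:], ends[1:], wq[1:]):
            if s <= ce:
                ce = max(ce, e)
                cq = min(cq, q)
            else:
                merged.append((cs, ce, cq))
                cs, ce, cq = s, e, q
        merged.append((cs, ce, cq))
        for s, e, q in merged:
            in_peak = tx_anchors[(tx_anchors >= s) & (tx_anchors < e)]
            n = len(in_peak)
            cover = np.bincount(in_peak - s, minlength=e - s)
            tsummit = int(s + np.argmax(cover))  # argmax ties -> 5'-most
            exp = max(per_tx_ip[txi] / lens[txi] * (e - s), pseudocount)
            if use_control:
                cc = np.searchsorted(ctl_g, offsets[txi] + e) - np.searchsorted(
                    ctl_g, offsets[txi] + s
                )
                exp = max(exp, cc * lib_ratio)
            g_span = m.genomic_positions(np.array([s, e - 1]))
            peak_rows.append(
                {
                    "chrom": m.chrom,
                    "start": int(g_span.min()),
                    "end": int(g_span.max()) + 1,
                    "strand": m.strand,
                    "summit": int(m.genomic_positions(np.array([tsummit]))[0]),
                    "ip_count": n,
                    "expected": exp,
                    "enrichment": n / exp,
                    "p": float(poisson_upper_tail(n, exp)),
                    "q": q,
                    "gene_id": m.gene_id,
                    "transcript_id": m.transcript_id,
                    "tstart": int(s),
                    "tend": int(e),
                    "tsummit": tsummit,
                }
            )
    peaks = pd.DataFrame(peak_rows, columns=PEAK_COLUMNS)
    peaks = peaks.sort_values(["transcript_id", "tstart"], ignore_index=True)
    params = {
        "window": window,
        "step": step,
        "fdr": fdr,
        "pseudocount": pseudocount,
        "min_count": min_count,
        "library_ratio": lib_ratio,
    }
    return PeakCall(peaks=peaks, windows=windows_df, params=params)


def region_density(
    features: "PeakCall | ReadSet",
    annotation: Annotation,
    anchor_offset: int = 0,
) -> pd.DataFrame:
    """Feature density (per kb) across genomic annotation classes.

    Peaks are anchored at their summit; reads at their 5' end plus
    ``anchor_offset``.  Classes with zero annotated length get a null (NaN)
    density, never 0.
    """
    cmap = annotation.class_map
    if isinstance(features, PeakCall):
        anchors = features.peaks[["chrom", "summit"]].rename(columns={"summit": "pos"})
    else:
        anchors = features.genomic_anchors(annotation, offset=anchor_offset)
    counts = np.zeros(len(CLASS_PRECEDENCE), dtype=np.int64)
    for chrom, grp in anchors.groupby("chrom", sort=False):
        codes = cmap.classify_many(str(chrom), grp.pos.to_numpy(np.int64))
        counts += np.bincount(codes, minlength=len(CLASS_PRECEDENCE))
    rows = []
    for i, cls in enumerate(CLASS_PRECEDENCE):
        ln = cmap.class_lengths[cls]
        rows.append(
            {
                "region_class": cls,
                "count": int(counts[i]),
                "length_nt": ln,
                "density_per_kb": counts[i] / (ln / 1000) if ln > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MetageneProfile:
    """Per-bin feature counts and densities over 5'-UTR, CDS and 3'-UTR."""

    scheme: BinScheme
    counts: dict[str, np.ndarray]
    extents: dict[str, np.ndarray]  # total nt per bin, summed over genes
    n_genes: dict[str, int]

    @property
    def density(self) -> dict[str, np.ndarray]:
        """Features per kb in each bin (NaN where no nucleotides contribute)."""
        out = {}
        for r in REGIONS:
            with np.errstate(invalid="ignore", divide="ignore"):
                out[r] = np.where(
                    self.extents[r] > 0, self.counts[r] / (self.extents[r] / 1000), np.nan
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        dens = self.density
        rows = []
        for r in REGIONS:
            for b in range(self.scheme.n_bins):
                rows.append(
                    {
                        "region": r,
                        "bin": b,
                        "count": int(self.counts[r][b]),
                        "extent_nt": int(self.extents[r][b]),
                        "density_per_kb": dens[r][b],
                    }
                )
        return pd.DataFrame(rows)


def _feature_anchors_tx(
    features: "PeakCall | ReadSet", annotation: Annotation, anchor_offset: int
) -> tuple[np.ndarray, np.ndarray]:
    """(canonical transcript index, transcript position) anchors for features."""
    if isinstance(features, PeakCall):
        tid_to_idx = {m.transcript_id: i for i, m in enumerate(annotation.canonical)}
        txi = features.peaks.transcript_id.map(tid_to_idx).to_numpy(np.int64)
        tpos = features.peaks.tsummit.to_numpy(np.int64)
        return txi, tpos
    txi, tpos, _ = features.transcript_anchors(annotation, offset=anchor_offset)
    return txi, tpos


def metagene_profile(
    features: "PeakCall | ReadSet",
    annotation: Annotation,
    scheme: BinScheme = BinScheme(50),
    anchor_offset: int = 0,
    gene_filter: set[str] | None = None,
) -> MetageneProfile:
    """Region-normalized metagene profile of feature anchors.

    Each coding gene's 5'-UTR, CDS and 3'-UTR are divided into
    ``scheme.n_bins`` bins; anchors are assigned by the floor rule and bin
    densities are counts per kb of the summed bin extents.  Genes lacking a
    region (length 0) are excluded from that region only.  ``gene_filter``
    restricts both anchors and extents to the given gene ids.
    """
    models = annotation.canonical

    def included(m) -> bool:
        return m.is_coding and (gene_filter is None or m.gene_id in gene_filter)

    if not any(included(m) for m in models):
        raise ValueError("metagene requires at least one coding transcript after filtering")
    n = scheme.n_bins
    txi, tpos = _feature_anchors_tx(features, annotation, anchor_offset)

    counts = {r: np.zeros(n, dtype=np.int64) for r in REGIONS}
    extents = {r: np.zeros(n, dtype=np.int64) for r in REGIONS}
    n_genes = {r: 0 for r in REGIONS}
    for m in models:
        if not included(m):
            continue
        for r in REGIONS:
            L = m.region_len(r)
            if L > 0:
                extents[r] += bin_extents(L, n)
                n_genes[r] += 1

    bounds = {}
    for i, m in enumerate(models):
        u5, cds = m.utr5_len, m.cds_len
        bounds[i] = (u5, u5 + cds, m.total_len)
    for i in np.unique(txi):
        m = models[i]
        if not included(m):
            continue
        pos = tpos[txi == i]
        u5, u5c, total = bounds[i]
        for r, lo, hi in (("utr5", 0, u5), ("cds", u5, u5c), ("utr3", u5c, total)):
            L = hi - lo
            if L <= 0:
                continue
            sel = pos[(pos >= lo) & (pos < hi)]
            if sel.size:
                b = bin_index(sel - lo, L, n)
                counts[r] += np.bincount(b, minlength=n)
    return MetageneProfile(scheme=scheme, counts=counts, extents=extents, n_genes=n_genes)


def define_targets(peaks: PeakCall, q_threshold: float = 0.05) -> set[str]:
    """Genes with at least one merged peak at q <= threshold."""
    df = peaks.peaks
    return set(df.loc[df.q <= q_threshold, "gene_id"].astype(str))


def replicate_correlation(
    rep1,
    rep2,
    annotation: Annotation | None = None,
    unit: str = "gene",
    window: int = 50,
    anchor_offset: int = 0,
) -> float:
    """Pearson correlation of log2(count+1) between two replicates.

    Accepts two ReadSets (requires ``annotation``) or two equal-length count
    vectors on a common grid.  For ReadSets, ``unit`` chooses the
    reproducibility grid: per-gene anchor counts ("gene", the usual CLIP
    replicate-agreement unit) or fixed non-overlapping ``window``-nt windows
    along canonical transcripts ("window").
    """
    if isinstance(rep1, ReadSet) and isinstance(rep2, ReadSet):
        if annotation is None:
            raise ValueError("annotation required to bin ReadSets")
        if unit not in ("gene", "window"):
            raise ValueError("unit must be 'gene' or 'window'")
        lens, offsets = _anchor_axis(annotation)
        if unit == "gene":
            edges = [offsets]
        else:
            edges = []
            for i, L in enumerate(lens):
                e = np.arange(0, L + window, window, dtype=np.int64)
                e[-1] = min(e[-1], L)
                edges.append(offsets[i] + np.unique(e))
        vecs = []
        for rs in (rep1, rep2):
            txi, tpos, _ = rs.transcript_anchors(annotation, offset=anchor_offset)
            g = np.sort(offsets[txi] + tpos)
            v = np.concatenate(
                [np.diff(np.searchsorted(g, e)) for e in edges]
            )
            vecs.append(v)
        x, y = vecs
    else:
        x = np.asarray(rep1, dtype=float)
        y = np.asarray(rep2, dtype=float)
        if x.shape != y.shape:
            raise ValueError("replicate vectors must share a common grid")
    lx, ly = np.log2(x + 1.0), np.log2(y + 1.0)
    if np.std(lx) == 0 or np.std(ly) == 0:
        raise ValueError("zero variance in a replicate vector: correlation undefined")
    r, _ = stats.pearsonr(lx, ly)
    return float(r)
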