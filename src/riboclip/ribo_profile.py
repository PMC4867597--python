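"""Ribosome-footprint densities, occupancy metagene curves, and occupancy-shift tests.

Footprints are anchored at an estimated ribosomal P-site (a fixed offset from
the read 5' end, 12 nt by default).  Occupancy curves are region-normalized
metagene profiles rescaled so the whole 5'-UTR/CDS/3'-UTR curve sums to one,
making conditions comparable regardless of sequencing depth.  Redistribution
of ribosomes between conditions is tested with a two-sample Kolmogorov-
Smirnov test on per-anchor positions normalized within a region, so the test
keeps a well-defined sample size (the anchor count) rather than being applied
to a handful of aggregated bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation, BinScheme, REGIONS
from .clip_peaks import metagene_profile, region_density
from .reads import ReadSet

GENE_CLASSES = ("all", "target", "non-target")


def footprint_density(
    reads: ReadSet, annotation: Annotation, psite_offset: int = 12
) -> pd.DataFrame:
    """Footprint density per thousand nt across genomic annotation classes.

    Each read is anchored at its 5' end + ``psite_offset`` in transcript
    orientation; anchors beyond the transcript end are skipped (logged).
    """
    return region_density(reads, annotation, anchor_offset=psite_offset)


def _gene_class_filter(
    annotation: Annotation, gene_class: str, targets: set[str] | None
) -> set[str] | None:
    if gene_class == "all":
        return None
    if targets is None:
        raise ValueError("target set required for gene_class filtering")
    genes = {m.gene_id for m in annotation.coding_canonical}
    return genes & targets if gene_class == "target" else genes - targets


@dataclass
class OccupancyCurve:
    """Relative ribosome density per region bin for one condition/gene class."""

    condition: str
    gene_class: str
    scheme: BinScheme
    raw_density: dict[str, np.ndarray]  # anchors per kb of bin extent
    rel_density: dict[str, np.ndarray]  # whole 3-region curve sums to 1
    n_footprints: int

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.rel_density[r] for r in REGIONS])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in REGIONS:
            for b in range(self.scheme.n_bins):
                rows.append(
                    {
                        "condition": self.condition,
                        "gene_class": self.gene_class,
                        "region": r,
                        "bin": b,
                        "raw_density": self.raw_density[r][b],
                        "rel_density": self.rel_density[r][b],
                    }
                )
        return pd.DataFrame(rows)


def occupancy_curve(
    reads: ReadSet,
    annotation: Annotation,
    scheme: BinScheme = BinScheme(20),
    gene_class: str = "all",
    targets: set[str] | None = None,
    psite_offset: int = 12,
    condition: str = "",
) -> OccupancyCurve:
    """Region-binned relative ribosome occupancy for one condition.

    Raw per-bin densities (anchors per kb of summed bin extent) are computed
    over the selected gene class, then the whole three-region curve is divided
    by its sum so it integrates to one.
    """
    if gene_class not in GENE_CLASSES:
        raise ValueError(f"gene_class must be one of {GENE_CLASSES}")
    gene_filter = _gene_class_filter(annotation, gene_class, targets)
    prof = metagene_profile(
        reads, annotation, scheme=scheme, anchor_offset=psite_offset, gene_filter=gene_filter
    )
    n_fp = int(sum(prof.counts[r].sum() for r in REGIONS))
    if n_fp == 0:
        raise ValueError(
            f"no footprints after filtering (condition={condition!r}, "
            f"gene_class={gene_class!r})"
        )
    raw = {}
    for r in REGIONS:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(prof.extents[r] > 0, prof.counts[r] / (prof.extents[r] / 1000), 0.0)
        raw[r] = d
    total = sum(raw[r].sum() for r in REGIONS)
    rel = {r: raw[r] / total for r in REGIONS}
    return OccupancyCurve(
        condition=condition,
        gene_class=gene_class,
        scheme=scheme,
        raw_density=raw,
        rel_density=rel,
        n_footprints=n_fp,
    )


@dataclass
class ShiftTestResult:
    """Two-sample KS comparison of within-region anchor positions."""

    region: str
    comparison: tuple[str, str]
    D: float
    p: float
    n_a: int
    n_b: int


def shift_test(
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    region: str,
    comparison: tuple[str, str] = ("A", "B"),
    min_n: int = 30,
) -> ShiftTestResult:
    """KS test on normalized within-region anchor positions (each in [0,1)).

    Requires at least ``min_n`` anchors per side for the asymptotic p-value
    to be meaningful; smaller inputs raise instead of silently degrading.
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(
            f"shift_test in {region}: need >= {min_n} anchors per side, "
            f"got {len(a)} vs {len(b)}"
        )
    res = stats.ks_2samp(a, b, method="asymp")
    return ShiftTestResult(
        region=region,
        comparison=comparison,
        D=float(res.statistic),
        p=float(min(res.pvalue, 1.0)) if res.pvalue > 0 else float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def region_anchor_table(
    reads: ReadSet, annotation: Annotation, psite_offset: int = 12
) -> pd.DataFrame:
    """Per-anchor (gene_id, region, normalized position) on coding canonical genes."""
    models = annotation.canonical
    txi, tpos, _ = reads.transcript_anchors(annotation, offset=psite_offset)
    u5 = np.array([m.utr5_len for m in models], dtype=np.int64)
    cds = np.array([m.cds_len for m in models], dtype=np.int64)
    tot = np.array([m.total_len for m in models], dtype=np.int64)
    coding = np.array([m.is_coding for m in models])
    genes = np.array([m.gene_id for m in models], dtype=object)

    keep = coding[txi]
    txi, tpos = txi[keep], tpos[keep]
    in_u5 = tpos < u5[txi]
    in_cds = (~in_u5) & (tpos < (u5 + cds)[txi])
    region = np.where(in_u5, "utr5", np.where(in_cds, "cds", "utr3"))
    offset = np.where(
        in_u5, tpos, np.where(in_cds, tpos - u5[txi], tpos - (u5 + cds)[txi])
    )
    rlen = np.where(
        in_u5, u5[txi], np.where(in_cds, cds[txi], (tot - u5 - cds)[txi])
    )
    return pd.DataFrame(
        {
            "gene_id": genes[txi],
            "region": region,
            "relpos": offset / rlen,
        }
    )


def _region_lengths_by_class(
    annotation: Annotation, targets: set[str] | None
) -> dict[tuple[str, str], int]:
    out: dict[tuple[str, str], int] = {}
    for m in annotation.coding_canonical:
        classes = ["all"]
        if targets is not None:
            classes.append("target" if m.gene_id in targets else "non-target")
        for c in classes:
            for r in REGIONS:
                out[(c, r)] = out.get((c, r), 0) + m.region_len(r)
    return out


def compare_conditions(
    reads_by_condition: dict[str, ReadSet],
    annotation: Annotation,
    targets: set[str],
    psite_offset: int = 12,
    regions: tuple[str, ...] = ("utr5", "cds"),
    min_n: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupancy-shift KS tests and 5'-UTR/CDS density ratios across conditions.

    For every condition pair and gene class (target / non-target) the
    within-region KS test is run for each requested region; the summary ratio
    (5'-UTR anchors per kb) / (CDS anchors per kb) is reported per condition
    and gene class.  Deterministic given its inputs.
    """
    if len(reads_by_condition) < 2:
        raise ValueError("need at least two conditions")
    lengths = _region_lengths_by_class(annotation, targets)
    tables = {}
    for cond, rs in reads_by_condition.items():
        if rs is None:
            raise ValueError(f"missing reads for condition {cond!r}")
        tab = region_anchor_table(rs, annotation, psite_offset=psite_offset)
        tab["gene_class"] = np.where(tab.gene_id.isin(targets), "target", "non-target")
        tables[cond] = tab

    ratio_rows = []
    for cond, tab in tables.items():
        for gc in ("target", "non-target", "all"):
            sub = tab if gc == "all" else tab[tab.gene_class == gc]
            dens = {}
            for r in ("utr5", "cds"):
                ln = lengths.get((gc, r), 0)
                dens[r] = (sub.region == r).sum() / (ln / 1000) if ln > 0 else np.nan
            ratio_rows.append(
                {
                    "condition": cond,
                    "gene_class": gc,
                    "utr5_density_per_kb": dens["utr5"],
                    "cds_density_per_kb": dens["cds"],
                    "utr5_cds_ratio": dens["utr5"] / dens["cds"]
                    if dens["cds"] and not np.isnan(dens["cds"])
                    else np.nan,
                    "n_anchors": len(sub),
                }
            )

    test_rows = []
    for cond_a, cond_b in combinations(tables.keys(), 2):
        for gc in ("target", "non-target"):
            for r in regions:
                pa = tables[cond_a].query("gene_class == @gc and region == @r").relpos.to_numpy()
                pb = tables[cond_b].query("gene_class == @gc and region == @r").relpos.to_numpy()
                res = shift_test(pa, pb, r, comparison=(cond_a, cond_b), min_n=min_n)
                test_rows.append(
                    {
                        "condition_a": cond_a,
                        "condition_b": cond_b,
                        "gene_class": gc,
                        "region": r,
                        "D": res.D,
                        "p": res.p,
                        "n_a": res.n_a,
                        "n_b": res.n_b,
                    }
                )
    return pd.DataFrame(test_rows), pd.DataFrame(ratio_rows)
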