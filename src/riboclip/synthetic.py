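"""Synthetic transcriptome, CLIP, ribosome-profiling, expression and transit data.

The generator produces data with the statistical structure the downstream
analyses assume, together with ground-truth tables, so every pipeline stage
can be exercised and benchmarked without any sequencing download:

* an annotation of coding genes (log-normal region lengths, a fraction with
  one intron) plus a few non-coding and pseudogene loci on one chromosome;
* CLIP IP replicates with a uniform mature-mRNA background modulated by a
  per-gene abundance factor, AUG-proximal 5'-UTR enrichment on target genes,
  and a shallow IgG-like control (~1% of IP depth);
* ribosome footprints from a piecewise-constant occupancy model: low 5'-UTR
  occupancy, a CDS plateau with initiation/termination pile-ups, and strong
  post-stop drop-off; a mutant condition raises 5'-UTR and lowers CDS
  occupancy on targets and non-targets alike (the initiation pile-up scales
  with initiation attempts, not with the reduced elongating flux);
* negative-binomial expression tables with equal means across conditions
  unless a fold change is injected, and PMS/PRS labeling time courses whose
  PRS line lags by the configured half-transit time.

Every output is a deterministic function of the mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, TranscriptModel, write_gtf, write_transcript_tsv
from .expression_compare import ExpressionTable
from .reads import ReadSet, write_reads_tsv

_STREAM = {"annotation": 0, "clip": 1, "ribo": 2, "expression": 3, "transit": 4}


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions emulated.

    Length scales follow typical human mRNAs (median 5'-UTR ~150 nt, CDS
    ~1.2 kb, 3'-UTR ~500 nt).  CLIP depth and the IP:control ratio echo the
    large observed depth asymmetry at desk scale.  The mutant condition
    triples 5'-UTR ribosome occupancy and reduces CDS occupancy to 60% on all
    genes, leaving mRNA abundance and the half-transit time unchanged.
    """

    seed: int

    # annotation
    n_genes: int = 300
    target_fraction: float = 0.1
    utr5_meanlog: float = math.log(150.0)
    utr5_sdlog: float = 0.6
    utr5_min: int = 30
    cds_meanlog: float = math.log(1200.0)
    cds_sdlog: float = 0.5
    cds_min: int = 120
    utr3_meanlog: float = math.log(500.0)
    utr3_sdlog: float = 0.7
    utr3_min: int = 30
    intron_fraction: float = 0.3
    intron_meanlog: float = math.log(1000.0)
    intron_sdlog: float = 0.5
    n_ncrna: int = 8
    n_pseudogene: int = 5
    chrom: str = "chrSim"
    expr_sdlog: float = 1.0  # per-gene abundance factor, log-normal

    # CLIP
    clip_bg_rate: float = 0.2  # background reads per nt of mature transcript
    clip_aug_fold: float = 10.0  # enrichment over background in the AUG window
    clip_aug_window: int = 50  # last w nt of the 5'-UTR
    clip_control_ratio: float = 0.01  # control depth relative to IP
    clip_read_len: int = 40
    clip_n_reps: int = 2

    # ribosome profiling
    ribo_footprints: int = 100_000  # per condition
    ribo_read_len: int = 30
    psite_offset: int = 12
    ribo_utr5_rel: float = 0.15  # baseline 5'-UTR rate relative to CDS plateau
    ribo_init_ramp: float = 3.0  # start-codon pile-up, x plateau baseline
    ribo_term_ramp: float = 2.0  # stop-codon pile-up, x elongating plateau
    ribo_ramp_frac: float = 0.05  # fraction of CDS in each ramp
    ribo_drop: float = 0.05  # 3'-UTR rate relative to CDS plateau
    # (utr5 multiplier, cds multiplier) per condition
    condition_multipliers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "vector": (1.0, 1.0),
            "WT": (1.0, 1.0),
            "mutant": (3.0, 0.6),
        }
    )

    # expression (counts)
    expr_base_mean: float = 200.0
    nb_dispersion: float = 0.02  # alpha in var = mu + alpha*mu^2
    expr_n_reps: int = 3

    # transit time
    transit_times: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    transit_slope: float = 5.0  # cpm per minute
    transit_half: dict[str, float] = field(
        default_factory=lambda: {"vector": 1.5, "WT": 1.5, "mutant": 1.5}
    )
    transit_cv: float = 0.05
    transit_n_reps: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("clip_bg_rate", "clip_control_ratio", "ribo_utr5_rel", "ribo_drop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for cond, (u, c) in self.condition_multipliers.items():
            if u <= 0 or c <= 0:
                raise ValueError(f"{cond}: condition multipliers must be > 0")
        for name in ("utr5_sdlog", "cds_sdlog", "utr3_sdlog"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be a finite non-negative number")

    def rng(self, stream: str, extra: int = 0) -> np.random.Generator:
        """Independent deterministic RNG per component (PCG64)."""
        return np.random.default_rng([self.seed % (2**31), _STREAM[stream], extra])


def _lognormal_int(rng, meanlog, sdlog, minimum, size) -> np.ndarray:
    x = np.round(rng.lognormal(meanlog, sdlog, size=size)).astype(np.int64)
    return np.maximum(x, minimum)


def simulate_annotation(cfg: SimConfig) -> tuple[Annotation, pd.DataFrame]:
    """Generate transcript models and the per-gene truth table.

    Returns the Annotation plus a frame (gene_id, transcript_id, is_target,
    expr_mult).  Genes are laid out on one chromosome with intergenic gaps
    wide enough to keep each gene's TTS window clear of its neighbors.
    """
    rng = cfg.rng("annotation")
    n = cfg.n_genes
    u5 = _lognormal_int(rng, cfg.utr5_meanlog, cfg.utr5_sdlog, cfg.utr5_min, n)
    cds = _lognormal_int(rng, cfg.cds_meanlog, cfg.cds_sdlog, cfg.cds_min, n)
    cds = (cds // 3) * 3
    u3 = _lognormal_int(rng, cfg.utr3_meanlog, cfg.utr3_sdlog, cfg.utr3_min, n)
    has_intron = rng.random(n) < cfg.intron_fraction
    intron_len = _lognormal_int(rng, cfg.intron_meanlog, cfg.intron_sdlog, 80, n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    expr_mult = rng.lognormal(0.0, cfg.expr_sdlog, size=n)
    n_targets = int(round(cfg.target_fraction * n))
    target_idx = set(rng.choice(n, size=n_targets, replace=False).tolist())

    models: list[TranscriptModel] = []
    rows = []
    cursor = 2000
    width = max(4, len(str(n + cfg.n_ncrna + cfg.n_pseudogene)))
    for i in range(n):
        gid = f"g{i:0{width}d}"
        tid = f"t{i:0{width}d}"
        total = int(u5[i] + cds[i] + u3[i])
        strand = str(strands[i])
        if has_intron[i] and cds[i] >= 60:
            # intron inserted at a uniform position inside the CDS
            brk = int(u5[i]) + int(rng.integers(30, cds[i] - 29))
            g0 = cursor
            asc = [(g0, g0 + brk), (g0 + brk + int(intron_len[i]), g0 + total + int(intron_len[i]))]
            span = total + int(intron_len[i])
        else:
            g0 = cursor
            asc = [(g0, g0 + total)]
            span = total
        blocks = tuple(asc) if strand == "+" else tuple(asc[::-1])
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=cfg.chrom,
                strand=strand,
                utr5_len=int(u5[i]),
                cds_len=int(cds[i]),
                utr3_len=int(u3[i]),
                blocks=blocks,
            )
        )
        rows.append(
            {
                "gene_id": gid,
                "transcript_id": tid,
                "is_target": i in target_idx,
                "expr_mult": float(expr_mult[i]),
            }
        )
        cursor += span + int(rng.integers(1500, 4000)) + 1000  # gap clears the TTS window

    for j in range(cfg.n_ncrna + cfg.n_pseudogene):
        biotype = "ncRNA" if j < cfg.n_ncrna else "pseudogene"
        k = n + j
        ln = int(_lognormal_int(rng, math.log(800.0), 0.6, 200, 1)[0])
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            TranscriptModel(
                transcript_id=f"t{k:0{width}d}",
                gene_id=f"g{k:0{width}d}",
                chrom=cfg.chrom,
                strand=strand,
                utr5_len=0,
                cds_len=0,
                utr3_len=0,
                blocks=((cursor, cursor + ln),),
                biotype=biotype,
            )
        )
        cursor += ln + int(rng.integers(1500, 4000)) + 1000

    gene_table = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "is_target", "expr_mult"])
    if not models:
        raise ValueError("empty annotation: n_genes, n_ncrna and n_pseudogene are all 0")
    return Annotation(models), gene_table


def simulate_clip(
    cfg: SimConfig, annotation: Annotation, gene_table: pd.DataFrame
) -> tuple[list[ReadSet], ReadSet, pd.DataFrame]:
    """CLIP IP replicates, IgG-like control, and the bound-gene truth table.

    IP reads fall uniformly on each mature transcript at a rate proportional
    to gene abundance, plus an enrichment component confined to the last
    ``clip_aug_window`` nt of target 5'-UTRs at ``clip_aug_fold`` x
    background.  The control is uniform at ``clip_control_ratio`` of IP depth.
    """
    rng = cfg.rng("clip")
    info = gene_table.set_index("transcript_id")
    reps: list[list[tuple[str, np.ndarray]]] = [[] for _ in range(cfg.clip_n_reps)]
    control: list[tuple[str, np.ndarray]] = []
    for m in sorted(annotation.coding_canonical, key=lambda m: m.transcript_id):
        row = info.loc[m.transcript_id]
        rate = cfg.clip_bg_rate * float(row.expr_mult)
        L = m.total_len
        w = min(cfg.clip_aug_window, m.utr5_len)
        for r in range(cfg.clip_n_reps):
            n_bg = rng.poisson(rate * L)
            pos = rng.integers(0, L, size=n_bg)
            if bool(row.is_target) and w > 0 and cfg.clip_aug_fold > 1:
                n_enr = rng.poisson(rate * (cfg.clip_aug_fold - 1.0) * w)
                pos = np.concatenate(
                    [pos, rng.integers(m.utr5_len - w, m.utr5_len, size=n_enr)]
                )
            reps[r].append((m.transcript_id, np.sort(pos)))
        n_ctl = rng.poisson(rate * cfg.clip_control_ratio * L)
        control.append((m.transcript_id, np.sort(rng.integers(0, L, size=n_ctl))))

    def _to_readset(chunks, sample_id):
        tids = np.concatenate(
            [np.full(len(p), t, dtype=object) for t, p in chunks]
        ) if chunks else np.array([], dtype=object)
        pos = np.concatenate([p for _, p in chunks]) if chunks else np.array([], dtype=np.int64)
        lens = {t: annotation.by_id[t].total_len for t, _ in chunks}
        length = np.minimum(
            cfg.clip_read_len,
            np.array([lens[t] for t in tids], dtype=np.int64) - pos,
        ) if len(pos) else np.array([], dtype=np.int64)
        df = pd.DataFrame(
            {"transcript_id": tids, "pos5": pos, "length": length, "strand": "+"}
        )
        return ReadSet(sample_id, df, coords="transcript")

    ip_sets = [_to_readset(reps[r], f"clip_ip_rep{r + 1}") for r in range(cfg.clip_n_reps)]
    ctl_set = _to_readset(control, "clip_control")
    truth = gene_table[["gene_id", "is_target"]].copy()
    return ip_sets, ctl_set, truth


def pool_readsets(readsets: list[ReadSet], sample_id: str = "pooled") -> ReadSet:
    """Concatenate replicates (the paper pools replicates before peak calling)."""
    if not readsets:
        raise ValueError("nothing to pool")
    coords = readsets[0].coords
    if any(rs.coords != coords for rs in readsets):
        raise ValueError("cannot pool read sets in different coordinate systems")
    df = pd.concat([rs.records for rs in readsets], ignore_index=True)
    return ReadSet(sample_id, df, coords=coords)


def _ribo_segments(cfg: SimConfig, m: TranscriptModel, utr5_mult: float, cds_mult: float):
    """(start, length, rate) segments of the piecewise-constant occupancy model.

    The initiation pile-up keeps its baseline amplitude under all conditions
    (stalled initiation events do not shrink with elongating flux), whereas
    the plateau, termination pile-up and 3'-UTR read-through scale with the
    CDS multiplier.  5'-UTR anchors start at the P-site offset: a footprint's
    P-site cannot sit closer to the cap than the offset itself.
    """
    u5, cds, u3 = m.utr5_len, m.cds_len, m.utr3_len
    ramp = max(1, int(round(cfg.ribo_ramp_frac * cds)))
    ramp = min(ramp, cds // 2)
    segs = []
    a0 = min(cfg.psite_offset, u5)
    if u5 - a0 > 0:
        segs.append((a0, u5 - a0, cfg.ribo_utr5_rel * utr5_mult))
    segs.append((u5, ramp, cfg.ribo_init_ramp))
    mid = cds - 2 * ramp
    if mid > 0:
        segs.append((u5 + ramp, mid, 1.0 * cds_mult))
    segs.append((u5 + cds - ramp, ramp, cfg.ribo_term_ramp * cds_mult))
    if u3 > 0:
        segs.append((u5 + cds, u3, cfg.ribo_drop * cds_mult))
    return segs


def simulate_ribo(
    cfg: SimConfig, annotation: Annotation, gene_table: pd.DataFrame, condition: str
) -> ReadSet:
    """Ribosome footprints for one condition (transcript coordinates).

    Exactly ``ribo_footprints`` P-site anchors are distributed across genes
    proportionally to abundance times the occupancy model's transcript mass,
    then placed uniformly within each constant-rate segment.  Condition
    multipliers apply to targets and non-targets alike.
    """
    if condition not in cfg.condition_multipliers:
        raise ValueError(
            f"unknown condition {condition!r}; configured: {sorted(cfg.condition_multipliers)}"
        )
    utr5_mult, cds_mult = cfg.condition_multipliers[condition]
    rng = cfg.rng("ribo", extra=sorted(cfg.condition_multipliers).index(condition))
    info = gene_table.set_index("transcript_id")
    models = sorted(annotation.coding_canonical, key=lambda m: m.transcript_id)
    seg_list = [_ribo_segments(cfg, m, utr5_mult, cds_mult) for m in models]
    mass = np.array(
        [
            float(info.loc[m.transcript_id].expr_mult) * sum(L * r for _, L, r in segs)
            for m, segs in zip(models, seg_list)
        ]
    )
    if mass.sum() <= 0:
        raise ValueError("occupancy model has zero total mass")
    counts = rng.multinomial(cfg.ribo_footprints, mass / mass.sum())
    tids, anchors = [], []
    for m, segs, n in zip(models, seg_list, counts):
        if n == 0:
            continue
        w = np.array([L * r for _, L, r in segs], dtype=float)
        per_seg = rng.multinomial(n, w / w.sum())
        pos_chunks = []
        for (s0, L, _), k in zip(segs, per_seg):
            if k:
                pos_chunks.append(rng.integers(s0, s0 + L, size=k))
        pos = np.sort(np.concatenate(pos_chunks)) if pos_chunks else np.array([], np.int64)
        anchors.append(pos)
        tids.append(np.full(len(pos), m.transcript_id, dtype=object))
    tid_arr = np.concatenate(tids) if tids else np.array([], dtype=object)
    anc = np.concatenate(anchors) if anchors else np.array([], dtype=np.int64)
    pos5 = anc - cfg.psite_offset
    keep = pos5 >= 0
    tid_arr, anc, pos5 = tid_arr[keep], anc[keep], pos5[keep]
    lens = np.array([annotation.by_id[t].total_len for t in tid_arr], dtype=np.int64)
    length = np.minimum(cfg.ribo_read_len, lens - pos5)
    df = pd.DataFrame(
        {"transcript_id": tid_arr, "pos5": pos5, "length": length, "strand": "+"}
    )
    return ReadSet(f"ribo_{condition}", df, coords="transcript")


def simulate_expression(
    cfg: SimConfig,
    gene_table: pd.DataFrame,
    conditions: tuple[str, ...] = ("control", "perturbed"),
    injected_log2fc: dict[str, float] | None = None,
) -> ExpressionTable:
    """Negative-binomial count tables, equal in mean across conditions.

    ``injected_log2fc`` applies a true log2 fold change to the named genes in
    every condition after the first (emulating a perturbation-responsive
    mRNA); everything else is null by construction.
    """
    rng = cfg.rng("expression")
    injected_log2fc = injected_log2fc or {}
    genes = gene_table.gene_id.to_numpy()
    mu0 = cfg.expr_base_mean * gene_table.expr_mult.to_numpy()
    alpha = cfg.nb_dispersion
    cols, design_rows = {}, []
    for ci, cond in enumerate(conditions):
        mu = mu0.copy()
        if ci > 0:
            for g, fc in injected_log2fc.items():
                mu[genes == g] *= 2.0**fc
        for rep in range(1, cfg.expr_n_reps + 1):
            name = f"{cond}_rep{rep}"
            if alpha > 0:
                size = 1.0 / alpha
                counts = rng.negative_binomial(size, size / (size + mu))
            else:
                counts = rng.poisson(mu)
            cols[name] = counts
            design_rows.append({"sample": name, "condition": cond, "replicate": str(rep)})
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    return ExpressionTable(values=values, design=pd.DataFrame(design_rows))


def simulate_transit(cfg: SimConfig) -> pd.DataFrame:
    """PMS/PRS labeling time courses per condition and replicate.

    pms(t) = s*t*(1+e) and prs(t) = s*max(0, t - half)*(1+e') with
    multiplicative Gaussian noise of coefficient of variation ``transit_cv``.
    """
    rng = cfg.rng("transit")
    t = np.asarray(cfg.transit_times, dtype=float)
    rows = []
    for cond in sorted(cfg.transit_half):
        half = cfg.transit_half[cond]
        for rep in range(1, cfg.transit_n_reps + 1):
            pms = cfg.transit_slope * t * (1 + rng.normal(0, cfg.transit_cv, len(t)))
            prs = cfg.transit_slope * np.maximum(0.0, t - half) * (
                1 + rng.normal(0, cfg.transit_cv, len(t))
            )
            for ti, a, b in zip(t, pms, prs):
                rows.append(
                    {
                        "condition": cond,
                        "replicate": str(rep),
                        "time_min": ti,
                        "pms_cpm": max(0.0, a),
                        "prs_cpm": max(0.0, b),
                    }
                )
    return pd.DataFrame(rows)


def simulate_all(cfg: SimConfig, outdir: str) -> dict[str, str]:
    """Run every generator and write all artifacts to ``outdir`` (TSV/GTF/BED-like).

    Returns a name -> path map of the files written.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    annotation, gene_table = simulate_annotation(cfg)
    write_gtf(annotation.transcripts, p("annotation.gtf"))
    write_transcript_tsv(annotation.transcripts, p("transcripts.tsv"))
    gene_table.to_csv(p("gene_truth.tsv"), sep="\t", index=False)

    ip_reps, ctl, truth = simulate_clip(cfg, annotation, gene_table)
    for i, rs in enumerate(ip_reps, start=1):
        write_reads_tsv(rs, p(f"clip_ip_rep{i}.tsv"))
    write_reads_tsv(ctl, p("clip_control.tsv"))
    truth.to_csv(p("clip_truth.tsv"), sep="\t", index=False)

    for cond in sorted(cfg.condition_multipliers):
        rs = simulate_ribo(cfg, annotation, gene_table, cond)
        write_reads_tsv(rs, p(f"ribo_{cond}.tsv"))

    expr = simulate_expression(cfg, gene_table)
    expr.values.to_csv(p("expression.tsv"), sep="\t")
    expr.design.to_csv(p("expression_design.tsv"), sep="\t", index=False)

    simulate_transit(cfg).to_csv(p("transit.tsv"), sep="\t", index=False)
    return paths
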