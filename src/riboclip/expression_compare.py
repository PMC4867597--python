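"""MA-style expression comparison and target/non-target mRNA stability testing.

The question these routines answer: does a perturbation (knockdown or mutant
over-expression) change the *abundance* of the bound target mRNAs, or only
their translation?  Genes are placed on an MA plot (M = log2 fold change,
A = mean log2 abundance, both with a pseudo-abundance to keep zeros defined);
individual genes are flagged when the fold change is both large (|M| above a
threshold) and statistically supported across replicates; and the target and
non-target M distributions are compared as groups with a two-sample KS test.

The replicate-based per-gene test models counts as negative binomial with a
common dispersion estimated from all genes by the method of moments, then
compares per-condition count sums with a normal approximation -- adequate for
the modest replicate numbers of a typical RNA-seq design and far more
powerful than a per-gene t-test at n=3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionTable:
    """Gene x sample abundance matrix with a condition/replicate design.

    ``values``: DataFrame indexed by gene_id, one column per sample.
    ``design``: DataFrame with columns (sample, condition, replicate).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("sample", "condition", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design must have a {col!r} column")
        missing = set(self.design["sample"]) - set(self.values.columns)
        if missing:
            raise ValueError(f"design samples absent from value columns: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design.condition))

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design.loc[self.design.condition == condition, "sample"]
        if sel.empty:
            raise ValueError(f"condition {condition!r} not in design")
        return list(sel)

    def condition_mean(self, condition: str) -> pd.Series:
        return self.values[self.samples_for(condition)].mean(axis=1)


def counts_to_fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series
) -> pd.DataFrame:
    """fragments * 1e9 / (gene length * total fragments), per sample."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"missing gene lengths for {missing[:5]}...")
    totals = counts.sum(axis=0)
    return counts.mul(1e9).div(totals, axis=1).div(lengths, axis=0)


def ma_transform(
    tbl: ExpressionTable, cond_a: str, cond_b: str, eps: float = 1.0
) -> pd.DataFrame:
    """Per-gene MA values between two conditions.

    M = log2((b+eps)/(a+eps)) and A = 0.5*log2((a+eps)*(b+eps)), computed on
    replicate-mean abundances; M is antisymmetric and A symmetric under
    swapping the conditions.
    """
    a = tbl.condition_mean(cond_a)
    b = tbl.condition_mean(cond_b)
    bad = a.index[a.isna() | b.isna()]
    if len(bad):
        raise ValueError(f"genes missing in one condition: {list(bad)}")
    M = np.log2((b + eps) / (a + eps))
    A = 0.5 * np.log2((a + eps) * (b + eps))
    return pd.DataFrame({"gene_id": a.index, "A": A.to_numpy(), "M": M.to_numpy()})


def estimate_common_dispersion(tbl: ExpressionTable) -> float:
    """Method-of-moments NB dispersion pooled over genes and conditions.

    For NB counts, var = mu + alpha*mu^2, so alpha = (var-mu)/mu^2 per gene;
    the median across genes (clipped at 0) is robust to outliers.
    """
    alphas = []
    for cond in tbl.conditions:
        cols = tbl.samples_for(cond)
        if len(cols) < 2:
            continue
        x = tbl.values[cols].to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        ok = m > 0
        alphas.append(np.clip((v[ok] - m[ok]) / m[ok] ** 2, 0, None))
    if not alphas:
        return 0.0
    return float(np.median(np.concatenate(alphas)))


def _nb_sum_test(
    ta: np.ndarray, tb: np.ndarray, na: int, nb: int, alpha: float
) -> np.ndarray:
    """Two-sided p-values for equal per-replicate means given count sums.

    Under H0 with shared mean mu, Var(sum over n reps) = n*mu + alpha*n*mu^2;
    a normal approximation to the difference of sums gives the z statistic.
    """
    mu = (ta + tb) / (na + nb)
    diff = ta / na - tb / nb
    var_diff = (mu + alpha * mu**2) * (1 / na + 1 / nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = diff / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(np.abs(z))
    return np.where(np.isfinite(p), p, 1.0)


@dataclass
class StabilityResult:
    """Per-gene fold-change flags plus the target/non-target group comparison."""

    per_gene: pd.DataFrame
    group_D: float
    group_p: float
    n_flagged: int
    n_targets: int
    n_nontargets: int
    dispersion: float


def target_stability_test(
    tbl: ExpressionTable,
    cond_a: str,
    cond_b: str,
    targets: set[str],
    m_threshold: float = 1.0,
    alpha_flag: float = 0.05,
    eps: float = 1.0,
    min_group: int = 10,
) -> StabilityResult:
    """Assess whether target mRNA abundance changes between two conditions.

    A gene is flagged when |M| > ``m_threshold`` and (when both conditions
    have >= 2 replicates) its BH-adjusted replicate-based p-value is <=
    ``alpha_flag``; without replicates the |M| rule alone applies.  The group
    test is a two-sample KS on M of targets versus non-targets.
    """
    if not targets:
        raise ValueError("empty target set")
    ma = ma_transform(tbl, cond_a, cond_b, eps=eps)
    is_target = ma.gene_id.isin(targets).to_numpy()
    n_t, n_nt = int(is_target.sum()), int((~is_target).sum())
    if n_t < min_group or n_nt < min_group:
        raise ValueError(
            f"need >= {min_group} targets and non-targets, got {n_t}/{n_nt}"
        )

    cols_a = tbl.samples_for(cond_a)
    cols_b = tbl.samples_for(cond_b)
    have_reps = len(cols_a) >= 2 and len(cols_b) >= 2
    disp = estimate_common_dispersion(tbl) if have_reps else np.nan
    big_m = np.abs(ma.M.to_numpy()) > m_threshold
    if have_reps:
        ta = tbl.values.loc[ma.gene_id, cols_a].sum(axis=1).to_numpy(dtype=float)
        tb_ = tbl.values.loc[ma.gene_id, cols_b].sum(axis=1).to_numpy(dtype=float)
        p = _nb_sum_test(ta, tb_, len(cols_a), len(cols_b), disp)
        q = multipletests(p, method="fdr_bh")[1]
        flagged = big_m & (q <= alpha_flag)
    else:
        p = np.full(len(ma), np.nan)
        q = np.full(len(ma), np.nan)
        flagged = big_m

    per_gene = ma.assign(is_target=is_target, p=p, q=q, flagged=flagged)
    ks = stats.ks_2samp(
        ma.M.to_numpy()[is_target], ma.M.to_numpy()[~is_target], method="asymp"
    )
    return StabilityResult(
        per_gene=per_gene,
        group_D=float(ks.statistic),
        group_p=float(ks.pvalue),
        n_flagged=int(flagged.sum()),
        n_targets=n_t,
        n_nontargets=n_nt,
        dispersion=float(disp) if have_reps else np.nan,
    )


def read_expression_tsv(path: str, design_path: str | None = None) -> ExpressionTable:
    """Read a gene x sample TSV (first column gene_id) plus an optional design TSV.

    Without a design file, sample columns named ``<condition>_rep<k>`` (or
    ``<condition>``) are parsed into the design.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t")
    else:
        rows = []
        for col in values.columns:
            cond, _, rep = col.rpartition("_rep")
            rows.append(
                {
                    "sample": col,
                    "condition": cond if cond else col,
                    "replicate": rep if rep else "1",
                }
            )
        design = pd.DataFrame(rows)
    return ExpressionTable(values=values, design=design)
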