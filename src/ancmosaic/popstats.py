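"""Allele-frequency population statistics: Hudson FST, balanced pairwise
FST, the relative-difference statistic, and outgroup f3 with block jackknife.

Genome-wide FST is the ratio-of-sums form of Hudson's estimator.  Per-site
numerators may be negative (finite-sample correction); they are retained in
the sums, and only the reported genome-wide value is clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def hudson_components(pA, nA, pB, nB):
    """Per-site Hudson numerator and denominator.

    num = (pA-pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    den = pA(1-pB) + pB(1-pA)

    Sites with fewer than two called alleles on either side are returned as
    NaN and must be excluded from any sum.
    """
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    ok = (nA >= 2) & (nB >= 2) & ~np.isnan(pA) & ~np.isnan(pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (pA - pB) ** 2 - pA * (1 - pA) / (nA - 1) - pB * (1 - pB) / (nB - 1)
        den = pA * (1 - pB) + pB * (1 - pA)
    num = np.where(ok, num, np.nan)
    den = np.where(ok, den, np.nan)
    return num, den


def site_fst(pA, nA, pB, nB):
    """Per-site Hudson FST (NaN where undefined or monomorphic in both)."""
    num, den = hudson_components(pA, nA, pB, nB)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def genomewide_fst(pA, nA, pB, nB, clamp: bool = True) -> float:
    """Genome-wide Hudson FST as a ratio of sums over usable sites."""
    num, den = hudson_components(pA, nA, pB, nB)
    ok = ~np.isnan(num) & ~np.isnan(den) & (den > 0)
    if not ok.any():
        raise ValueError("no usable sites for FST")
    fst = float(num[ok].sum() / den[ok].sum())
    return max(fst, 0.0) if clamp else fst


@dataclass
class FstPairResult:
    """Balanced-subsample pairwise FST between two populations."""

    pop_a: str
    pop_b: str
    replicates: np.ndarray  # genome-wide FST per subsample replicate
    subset: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if self.replicates.size > 1 else 0.0


def pairwise_fst_balanced(
    panel: HaplotypePanel,
    pop_a: str,
    pop_b: str,
    subset: int = 9,
    reps: int = 100,
    seed: int = 0,
) -> FstPairResult:
    """Pairwise FST with sample-size balancing by repeated subsampling.

    Each replicate draws ``subset`` diploid samples per population without
    replacement (sorted sample IDs, so the draw is invariant to column
    order) and computes the genome-wide Hudson FST; the distribution over
    ``reps`` replicates is returned.
    """
    rng = np.random.default_rng(seed)
    idx_a = panel.sample_indices(pop_a)
    idx_b = panel.sample_indices(pop_b)
    for pop, idx in ((pop_a, idx_a), (pop_b, idx_b)):
        if idx.size < subset:
            raise ValueError(
                f"population {pop!r} has {idx.size} samples, fewer than subset={subset}"
            )
    # draw by sorted sample name for column-order invariance
    order_a = idx_a[np.argsort([panel.samples[i] for i in idx_a])]
    order_b = idx_b[np.argsort([panel.samples[i] for i in idx_b])]

    values = np.empty(reps)
    for r in range(reps):
        sub_a = order_a[rng.choice(order_a.size, size=subset, replace=False)]
        sub_b = order_b[rng.choice(order_b.size, size=subset, replace=False)]
        ha = np.concatenate([2 * sub_a, 2 * sub_a + 1])
        hb = np.concatenate([2 * sub_b, 2 * sub_b + 1])
        pA, nA = panel.allele_freqs(hap_idx=ha)
        pB, nB = panel.allele_freqs(hap_idx=hb)
        values[r] = genomewide_fst(pA, nA, pB, nB)
    return FstPairResult(pop_a=pop_a, pop_b=pop_b, replicates=values, subset=subset)


# ---------------------------------------------------------------------------
# Relative difference
# ---------------------------------------------------------------------------

def relative_difference(fst_ax: float, fst_bx: float) -> float:
    """RD = (FST(A,X) - FST(B,X)) / (FST(A,X) + FST(B,X)).

    Positive values mean the tested population X is genetically closer to B
    (more recent exchange with B); negative means closer to A.  Returns NaN
    when the denominator is not positive (RD undefined).
    """
    denom = fst_ax + fst_bx
    if denom <= 0:
        return float("nan")
    return (fst_ax - fst_bx) / denom


# ---------------------------------------------------------------------------
# Outgroup f3
# ---------------------------------------------------------------------------

@dataclass
class F3Result:
    f3: float
    se: float
    n_sites: int
    n_blocks: int

    @property
    def z(self) -> float:
        return self.f3 / self.se if self.se > 0 else float("inf")


def f3_outgroup(
    p_out, p_a, p_b, positions=None, block_size: int = 5_000_000
) -> F3Result:
    """Outgroup f3 = mean over sites of (pO - pA)(pO - pB).

    Larger values mean more drift shared between A and B relative to the
    outgroup.  The standard error is a leave-one-block-out jackknife over
    physical blocks (default 5 Mb); block weights follow the usual weighted
    jackknife for unequal block sizes.
    """
    p_out = np.asarray(p_out, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    ok = ~(np.isnan(p_out) | np.isnan(p_a) | np.isnan(p_b))
    if not ok.any():
        raise ValueError("no usable sites for f3")
    prod = (p_out[ok] - p_a[ok]) * (p_out[ok] - p_b[ok])
    n = prod.size
    f3 = float(prod.mean())

    if positions is None:
        blocks = np.zeros(n, dtype=np.intp)
    else:
        blocks = (np.asarray(positions)[ok] // block_size).astype(np.intp)
    uniq = np.unique(blocks)
    if uniq.size < 2:
        return F3Result(f3=f3, se=float("nan"), n_sites=n, n_blocks=int(uniq.size))

    total = prod.sum()
    g = uniq.size
    theta_del = np.empty(g)
    weights = np.empty(g)
    for j, b in enumerate(uniq):
        sel = blocks == b
        mj = sel.sum()
        theta_del[j] = (total - prod[sel].sum()) / (n - mj)
        weights[j] = mj / n
    # weighted delete-one jackknife variance
    h = 1.0 / weights
    pseudo = h * f3 - (h - 1.0) * theta_del
    theta_j = float(np.sum(weights * pseudo))
    var = float(np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / g)
    return F3Result(f3=f3, se=float(np.sqrt(var)), n_sites=n, n_blocks=g)


def rank_by_drift(
    p_query,
    n_query,
    p_out,
    references: dict[str, np.ndarray],
    positions=None,
    min_sites: int = 100,
    block_size: int = 5_000_000,
):
    """Rank reference populations by shared drift with a query (outgroup f3).

    ``p_query``/``n_query`` are the query's per-site frequencies and called
    allele counts (a single pseudo-haploid sample works: frequencies 0/1
    with missing sites NaN).  References with fewer than ``min_sites``
    jointly called sites are flagged and ranked last with f3 = NaN.  Ties
    break lexicographically on the reference name.
    """
    import pandas as pd

    p_query = np.asarray(p_query, dtype=float)
    n_query = np.asarray(n_query)
    rows = []
    for name in sorted(references):
        p_ref = np.asarray(references[name], dtype=float)
        usable = (~np.isnan(p_query)) & (n_query > 0) & ~np.isnan(p_ref) & ~np.isnan(
            np.asarray(p_out, dtype=float)
        )
        n_use = int(usable.sum())
        if n_use < min_sites:
            rows.append((name, float("nan"), float("nan"), n_use, True))
            continue
        res = f3_outgroup(
            np.asarray(p_out)[usable], p_query[usable], p_ref[usable],
            positions=None if positions is None else np.asarray(positions)[usable],
            block_size=block_size,
        )
        rows.append((name, res.f3, res.se, n_use, False))
    df = pd.DataFrame(rows, columns=["reference", "f3", "se", "n_sites", "insufficient"])
    df = df.sort_values(
        by=["insufficient", "f3", "reference"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
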