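"""Differentiation-based selection screens.

Three screens anchored on allele-frequency differentiation against a
reference population (by default the Han-like majority group):

* top-quantile per-site FST (default top 0.1%);
* "extra" variants — in the top 0.1% of the reconstructed-ancestor-vs-
  reference FST but outside the top 1% of the present-day-vs-reference FST,
  i.e. differentiation signals unmasked by removing recent gene flow;
* a three-criterion gradient screen requiring fixation in the reference,
  a frequency difference of at least ``min_diff`` to the reconstructed
  ancestor, and a monotone frequency gradient ancestor -> present-day ->
  reference, oriented to the allele absent (or fixed) in the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypePanel


@dataclass
class ScreenConfig:
    missing_rate_max: float = 0.10
    top_quantile_primary: float = 0.001
    top_quantile_relaxed: float = 0.01
    min_freq_diff: float = 0.3
    fixed_tolerance: float = 0.0
    groups: dict[str, list[str]] = field(default_factory=dict)  # group -> samples

    def __post_init__(self) -> None:
        for q in (self.top_quantile_primary, self.top_quantile_relaxed):
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")
        if not 0.0 <= self.min_freq_diff <= 1.0:
            raise ValueError("min_freq_diff must lie in [0, 1]")


def filter_by_missingness(
    panel: HaplotypePanel,
    groups: dict[str, list[str]],
    max_rate: float = 0.10,
) -> np.ndarray:
    """Boolean site mask: True where the per-group genotype missing rate is
    <= ``max_rate`` in every group.

    ``groups`` maps group names to diploid sample names; a site is dropped
    as soon as any single group exceeds the cap.
    """
    keep = np.ones(panel.n_sites, dtype=bool)
    name_to_idx = {s: i for i, s in enumerate(panel.samples)}
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} is empty")
        idx = np.asarray([name_to_idx[s] for s in members], dtype=np.intp)
        keep &= panel.genotype_missing_rate(idx) <= max_rate
    return keep


def top_fst_screen(fst: np.ndarray, quantile: float = 0.001) -> np.ndarray:
    """Flag sites in the top ``quantile`` of the FST distribution.

    The threshold is the k-th largest finite value with
    ``k = floor(n * quantile)``; all ties at the threshold are included.
    If fewer than ``1/quantile`` usable sites exist a warning is issued and
    nothing is flagged.
    """
    fst = np.asarray(fst, dtype=float)
    valid = ~np.isnan(fst)
    n = int(valid.sum())
    k = int(np.floor(n * quantile))
    if k < 1:
        warnings.warn(
            f"only {n} usable sites; top-{quantile:g} screen selects nothing",
            stacklevel=2,
        )
        return np.zeros(fst.size, dtype=bool)
    thr = np.sort(fst[valid])[-k]
    return valid & (fst >= thr)


def extra_snvs(
    fst_ancestor_ref: np.ndarray,
    fst_present_ref: np.ndarray,
    q_primary: float = 0.001,
    q_relaxed: float = 0.01,
) -> np.ndarray:
    """Variants in the top ``q_primary`` of the ancestor-vs-reference FST
    but outside the top ``q_relaxed`` of the present-day-vs-reference FST.

    Both tracks must cover the same site universe (equal length; a NaN in
    one track does not disqualify the site in the other).
    """
    a = np.asarray(fst_ancestor_ref, dtype=float)
    b = np.asarray(fst_present_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError("FST tracks cover different site universes")
    return top_fst_screen(a, q_primary) & ~top_fst_screen(b, q_relaxed)


def gradient_screen(
    p_ref: np.ndarray,
    p_present: np.ndarray,
    p_ancestor: np.ndarray,
    min_diff: float = 0.3,
    fixed_tolerance: float = 0.0,
) -> tuple[np.ndarray, int]:
    """Three-criterion gradient screen.

    A site is flagged iff (i) the reference frequency is fixed
    (within ``fixed_tolerance`` of 0 or 1); (ii) the ancestor-reference
    frequency difference is at least ``min_diff``; (iii) frequencies are
    monotone (non-strict) along ancestor -> present-day -> reference,
    oriented toward the allele missing from the reference.  Sites with a
    missing frequency in any panel are excluded; their count is returned
    alongside the flag vector.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    p_present = np.asarray(p_present, dtype=float)
    p_ancestor = np.asarray(p_ancestor, dtype=float)
    usable = ~(np.isnan(p_ref) | np.isnan(p_present) | np.isnan(p_ancestor))
    n_excluded = int((~usable).sum())

    fixed_lo = p_ref <= fixed_tolerance
    fixed_hi = p_ref >= 1.0 - fixed_tolerance
    diff_ok = np.abs(p_ancestor - p_ref) >= min_diff
    grad_up = (p_ancestor >= p_present) & (p_present >= p_ref)    # allele absent in ref
    grad_down = (p_ancestor <= p_present) & (p_present <= p_ref)  # allele fixed in ref
    flags = usable & diff_ok & ((fixed_lo & grad_up) | (fixed_hi & grad_down))
    return flags, n_excluded
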