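"""Rare strong-effect derived-variant gene screen and familial aggregation.

Derived alleles are polarized against a reference ("East Asian") panel: the
lower-frequency allele there is treated as recently derived.  The gene
screen keeps genes carrying multiple dispersed rare derived alleles of
strong predicted effect; the familial-aggregation test asks whether related
sample pairs share such variants more often than unrelated pairs (two-sided
Fisher exact test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MISSING, HaplotypePanel

STRONG_EFFECTS = frozenset({"moderate", "high"})


def polarize(
    p_panel: np.ndarray,
    effect_class: np.ndarray,
    maf_max: float = 0.20,
) -> pd.DataFrame:
    """Select candidate sites and label their derived allele.

    ``p_panel`` is the ALT frequency in the polarizing panel (NaN where
    uncalled); ``effect_class`` the per-site predicted consequence severity
    (strings).  Sites with MAF <= ``maf_max`` and a moderate/high effect are
    retained; the minor allele is called derived.  Sites at exactly MAF 0.5
    are ambiguous and dropped with a warning.

    Returns a frame with columns ``site, derived_is_alt, panel_maf, effect``.
    """
    p_panel = np.asarray(p_panel, dtype=float)
    effect_class = np.asarray(effect_class, dtype=object)
    maf = np.minimum(p_panel, 1.0 - p_panel)
    strong = np.isin(effect_class, list(STRONG_EFFECTS))
    tie = maf == 0.5
    if np.any(tie & strong):
        warnings.warn(
            f"{int((tie & strong).sum())} site(s) at MAF exactly 0.5 excluded "
            "(derived allele ambiguous)",
            stacklevel=2,
        )
    keep = strong & ~np.isnan(maf) & (maf <= maf_max) & ~tie
    sites = np.flatnonzero(keep)
    return pd.DataFrame(
        {
            "site": sites,
            "derived_is_alt": p_panel[sites] < 0.5,
            "panel_maf": maf[sites],
            "effect": effect_class[sites],
        }
    )


def _derived_dosage(panel: HaplotypePanel, sites: np.ndarray, derived_is_alt: np.ndarray):
    """Per-individual derived-allele dosage matrix (-1 where genotype missing)."""
    H = panel.haplotypes[:, sites]
    derived = np.where(derived_is_alt[None, :], H == 1, H == 0).astype(np.int8)
    miss = H == MISSING
    a, b = derived[0::2], derived[1::2]
    dose = a + b
    dose[miss[0::2] | miss[1::2]] = -1
    return dose


def derived_freq(panel: HaplotypePanel, pop: str, sites, derived_is_alt) -> np.ndarray:
    """Derived-allele frequency per selected site in one population."""
    sites = np.asarray(sites, dtype=np.intp)
    p, n = panel.allele_freqs(pop=pop)
    p, n = p[sites], n[sites]
    return np.where(np.asarray(derived_is_alt), p, 1.0 - p)


def carrying_rate(
    panel: HaplotypePanel,
    sites,
    derived_is_alt,
    sample_idx: np.ndarray | None = None,
) -> float:
    """Fraction of individuals carrying >= 1 derived allele across the sites.

    Individuals with every genotype missing at the sites still count in the
    denominator; duplicated site rows do not change the result.
    """
    sites = np.asarray(sites, dtype=np.intp)
    dose = _derived_dosage(panel, sites, np.asarray(derived_is_alt))
    if sample_idx is not None:
        dose = dose[np.asarray(sample_idx, dtype=np.intp)]
    if dose.shape[0] == 0:
        raise ValueError("no individuals")
    carries = (dose > 0).any(axis=1)
    return float(carries.mean())


@dataclass
class GeneScreenResult:
    gene: str
    n_snvs: int
    han_derived_count: int
    carrier_fraction: float
    max_derived_freq: float
    pass_no_ref_derived: bool
    pass_carrier_fraction: bool
    pass_max_freq: bool
    pass_min_snvs: bool

    @property
    def passes(self) -> bool:
        return (
            self.pass_no_ref_derived
            and self.pass_carrier_fraction
            and self.pass_max_freq
            and self.pass_min_snvs
        )


def gene_screen(
    panel: HaplotypePanel,
    derived_calls: pd.DataFrame,
    gene_map: dict[str, list[int]],
    target_pop: str,
    ref_pop: str,
    carrier_min: float = 0.10,
    max_freq: float = 0.05,
    min_snvs: int = 2,
) -> list[GeneScreenResult]:
    """Four-criterion gene screen over polarized strong-effect sites.

    Per gene: (1) zero derived alleles in the reference population;
    (2) more than ``carrier_min`` of target individuals carry >= 1 derived
    allele; (3) the highest per-site derived frequency in the target stays
    below ``max_freq``; (4) at least ``min_snvs`` qualifying variants.
    Genes whose interval contains no polarized site are omitted.
    """
    call_by_site = derived_calls.set_index("site")["derived_is_alt"]
    target_idx = panel.sample_indices(target_pop)
    results = []
    for gene in sorted(gene_map):
        sites = np.asarray(
            [s for s in gene_map[gene] if s in call_by_site.index], dtype=np.intp
        )
        if sites.size == 0:
            continue
        derived_is_alt = call_by_site.loc[sites].to_numpy(dtype=bool)

        p_ref = derived_freq(panel, ref_pop, sites, derived_is_alt)
        _, n_ref = panel.allele_freqs(pop=ref_pop)
        ref_count = int(np.nansum(p_ref * n_ref[sites]).round())

        p_tgt = derived_freq(panel, target_pop, sites, derived_is_alt)
        max_p = float(np.nanmax(p_tgt))
        cf = carrying_rate(panel, sites, derived_is_alt, sample_idx=target_idx)

        results.append(
            GeneScreenResult(
                gene=gene,
                n_snvs=int(sites.size),
                han_derived_count=ref_count,
                carrier_fraction=cf,
                max_derived_freq=max_p,
                pass_no_ref_derived=ref_count == 0,
                pass_carrier_fraction=cf > carrier_min,
                pass_max_freq=max_p < max_freq,
                pass_min_snvs=sites.size >= min_snvs,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Familial aggregation
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """Counts: rows = (related, unrelated), cols = (shares, does not share)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def pairs_to_table(pairs: pd.DataFrame) -> ContingencyTable2x2:
    """Collapse a ``related/shares`` pair frame into the 2x2 sharing table."""
    rel = pairs["related"].astype(bool)
    sh = pairs["shares"].astype(bool)
    return ContingencyTable2x2(
        a=int((rel & sh).sum()),
        b=int((rel & ~sh).sum()),
        c=int((~rel & sh).sum()),
        d=int((~rel & ~sh).sum()),
    )


def familial_aggregation(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on the pair-sharing table.

    Returns ``(p, odds_ratio)`` where the p-value follows the
    minimum-likelihood summation convention (sum of hypergeometric
    probabilities <= that of the observed table) and the odds ratio is the
    conditional maximum-likelihood estimate (inf/NaN on degenerate
    margins).  Degenerate margins give p = 1.
    """
    arr = table.as_array()
    res = stats.fisher_exact(arr, alternative="two-sided")
    try:
        orr = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    except Exception:
        orr = float("nan")
    return float(res.pvalue), orr
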