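"""Synthetic phased panels with known population structure and ancestry tracts.

The generative model is deliberately simple and fully controlled:

* a shared ancestral ALT-allele frequency per site, Uniform(0.05, 0.95);
* per-population drift via the Balding–Nichols model — population
  frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral p;
* admixed haplotypes follow a single-pulse Markov tract process: ancestry
  breakpoints are Poisson with rate ``recomb_rate * generations`` per bp,
  and the ancestry at each breakpoint is target with probability ``m``
  (so realized switches occur at a 2·m(1-m)-thinned rate and tract lengths
  are exponential on the kb–Mb scale);
* alleles are drawn i.i.d. per site from the tract's source-population
  frequency; missingness is i.i.d. per diploid genotype.

Every downstream stage therefore has exact ground truth (``TruthTracts``),
which is what the pipeline's verification rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel, TractSet, merge_adjacent

ADMIXED_POP = "Admixed"


@dataclass
class PopSpec:
    """One source population: diploid sample count and Balding–Nichols F."""

    n_samples: int
    drift_F: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.drift_F < 1.0:
            raise ValueError("drift_F must lie in [0, 1)")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic panel.

    ``target_pop`` contributes the ancestry tracts of interest to the admixed
    individuals; ``other_pop`` is the second admixture source.  Defaults
    emulate a small multi-population panel with one drifted target ancestry,
    recent single-pulse admixture and tract lengths well above the 6 kb
    re-chunking scale.
    """

    pops: dict[str, PopSpec] = field(
        default_factory=lambda: {
            "Target": PopSpec(30, 0.2),
            "Other": PopSpec(30, 0.2),
            "Outgroup": PopSpec(10, 0.6),
        }
    )
    target_pop: str = "Target"
    other_pop: str = "Other"
    n_admixed: int = 30
    admixture_proportion: float = 0.5
    admixture_generations: int = 10
    n_sites: int = 2000
    chrom_length_bp: int = 2_000_000
    recomb_rate: float = 1e-8
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.admixture_proportion <= 1.0:
            raise ValueError("admixture_proportion m must lie in [0, 1]")
        if self.admixture_generations < 1:
            raise ValueError("admixture_generations must be a positive integer")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.chrom_length_bp < self.n_sites:
            raise ValueError("chrom_length_bp must be >= n_sites")
        for name in (self.target_pop, self.other_pop):
            if name not in self.pops:
                raise ValueError(f"admixture source {name!r} not among pops")


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, F: float) -> np.ndarray:
    if F == 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    return rng.beta(a, b)


def _admixed_tracts(
    rng: np.random.Generator, length: int, m: float, rate_per_bp: float,
    target: str, other: str,
) -> list[tuple[int, int, str]]:
    """Single-pulse tract process: Poisson breakpoints, ancestry ~ Bernoulli(m)."""

    def draw() -> str:
        return target if rng.random() < m else other

    breaks = [0]
    pos = 0.0
    if rate_per_bp > 0:
        while True:
            pos += rng.exponential(1.0 / rate_per_bp)
            if pos >= length:
                break
            breaks.append(int(pos))
    breaks.append(length)
    tracts = [(breaks[i], breaks[i + 1], draw()) for i in range(len(breaks) - 1)]
    tracts = [(s, e, lab) for s, e, lab in tracts if e > s]
    return merge_adjacent(tracts)


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, TractSet]:
    """Simulate a phased panel plus ground-truth ancestry tracts.

    Returns the panel (source populations followed by the admixed samples,
    population label ``"Admixed"``) and the ``TruthTracts`` of every admixed
    haplotype.  Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    L, S = config.chrom_length_bp, config.n_sites

    positions = np.sort(rng.choice(L, size=S, replace=False)).astype(np.int64)
    p_anc = rng.uniform(0.05, 0.95, size=S)
    pop_freqs = {
        name: _balding_nichols(rng, p_anc, spec.drift_F)
        for name, spec in config.pops.items()
    }

    samples: list[str] = []
    populations: list[str] = []
    hap_rows: list[np.ndarray] = []

    for name, spec in config.pops.items():
        p = pop_freqs[name]
        for k in range(spec.n_samples):
            samples.append(f"{name}_{k:03d}")
            populations.append(name)
            hap_rows.append((rng.random(S) < p).astype(np.int8))
            hap_rows.append((rng.random(S) < p).astype(np.int8))

    m = config.admixture_proportion
    rate = config.recomb_rate * config.admixture_generations
    truth: dict[str, list[tuple[int, int, str]]] = {}
    for k in range(config.n_admixed):
        sample = f"{ADMIXED_POP}_{k:03d}"
        samples.append(sample)
        populations.append(ADMIXED_POP)
        for h in (0, 1):
            tracts = _admixed_tracts(
                rng, L, m, rate, config.target_pop, config.other_pop
            )
            truth[f"{sample}.hap{h}"] = tracts
            hap = np.empty(S, dtype=np.int8)
            for s, e, lab in tracts:
                lo = np.searchsorted(positions, s, side="left")
                hi = np.searchsorted(positions, e, side="left")
                if hi > lo:
                    hap[lo:hi] = rng.random(hi - lo) < pop_freqs[lab][lo:hi]
            hap_rows.append(hap)

    H = np.vstack(hap_rows)
    if config.missing_rate > 0:
        n_samples = len(samples)
        miss = rng.random((n_samples, S)) < config.missing_rate
        for i in range(n_samples):
            H[2 * i, miss[i]] = MISSING
            H[2 * i + 1, miss[i]] = MISSING

    panel = HaplotypePanel(
        haplotypes=H, positions=positions, samples=samples,
        populations=populations, chrom="1", chrom_length=L,
    )
    tractset = TractSet(tracts=truth, chrom_length=L, chrom="1")
    tractset.validate()
    return panel, tractset


def target_fraction(truth: TractSet, target_pop: str) -> float:
    """Genome fraction of the admixed haplotypes assigned to the target ancestry."""
    tot = covered = 0
    for ivs in truth.tracts.values():
        for s, e, lab in ivs:
            tot += e - s
            if lab == target_pop:
                covered += e - s
    return covered / tot if tot else 0.0


# ---------------------------------------------------------------------------
# Ne trajectories (fixture for the divergence-dating rule)
# ---------------------------------------------------------------------------

def simulate_ne_trajectories(
    pops: list[str],
    time_bins: list[tuple[float, float]],
    true_split_time: float,
    seed: int = 0,
    query_pop: str = "Query",
    base_ne: float = 10_000.0,
    noise_sd: float = 0.0,
    effect_sd: float = 10.0,
) -> pd.DataFrame:
    """Construct Ne-by-time tables with a known divergence time.

    ``pops`` share a common trajectory (plus Gaussian noise of absolute SD
    ``noise_sd``).  The query population equals the group in bins older than
    ``true_split_time`` and is shifted by ``effect_sd`` group-SD units in
    bins overlapping the younger epoch (a bin is "younger" when its left
    boundary is below the split).  With ``noise_sd == 0`` the shift unit
    falls back to 1% of ``base_ne`` so the constructed signal is nonzero.

    Returns a tidy frame with columns ``pop, left_years, right_years, ne``;
    ``time_bins`` must be sorted ascending in age.
    """
    rng = np.random.default_rng(seed)
    lefts = [l for l, _ in time_bins]
    overlapping = any(
        time_bins[i + 1][0] < time_bins[i][1] for i in range(len(time_bins) - 1)
    )
    if any(b[1] <= b[0] for b in time_bins) or lefts != sorted(lefts) or overlapping:
        raise ValueError("time_bins must be ascending, non-overlapping intervals")

    unit = noise_sd if noise_sd > 0 else 0.01 * base_ne
    rows = []
    for left, right in time_bins:
        young = left < true_split_time
        for pop in pops:
            ne = base_ne + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((pop, left, right, ne))
        q = base_ne + (effect_sd * unit if young else 0.0)
        if noise_sd > 0:
            q += rng.normal(0.0, noise_sd)
        rows.append((query_pop, left, right, q))
    return pd.DataFrame(rows, columns=["pop", "left_years", "right_years", "ne"])


# ---------------------------------------------------------------------------
# Related/unrelated pair sharing (fixture for the familial-aggregation test)
# ---------------------------------------------------------------------------

def simulate_related_pairs(
    n_related: int,
    n_unrelated: int,
    sharing_prob_related: float,
    sharing_prob_unrelated: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Bernoulli per-pair shared-rare-variant indicators.

    Returns a frame with columns ``pair_id, related, shares`` (0/1 flags),
    suitable for :func:`ancmosaic.rarevar.pairs_to_table`.
    """
    for p in (sharing_prob_related, sharing_prob_unrelated):
        if not 0.0 <= p <= 1.0:
            raise ValueError("sharing probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    related = np.concatenate([np.ones(n_related, int), np.zeros(n_unrelated, int)])
    probs = np.where(related == 1, sharing_prob_related, sharing_prob_unrelated)
    shares = (rng.random(related.size) < probs).astype(int)
    return pd.DataFrame(
        {"pair_id": np.arange(related.size), "related": related, "shares": shares}
    )
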