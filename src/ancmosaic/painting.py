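"""Replicate local-ancestry painting and consensus candidate segments.

The painter is a collapsed population-frequency hidden Markov model: the
hidden state at each variant site is the donor population the query
haplotype is copying from, emissions are the donor population's smoothed
allele frequencies, and transitions scale with physical distance.  Replicate
paintings differ only in their posterior path sample (forward-filtering,
backward-sampling), which reproduces the contract of running an external
painter several times with different stochastic seeds.  Externally produced
tract files can be substituted anywhere a :class:`PaintingReplicate` is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import MISSING, HaplotypePanel, LabeledInterval, TractSet, merge_adjacent

DEFAULT_LAMBDA = 1e-6  # per-bp switch rate; ~1 expected switch per Mb
SWITCH_CAP = 0.49      # total per-interval switch probability stays below 0.5


@dataclass
class PaintingReplicate:
    """One painting of a set of query haplotypes over donor populations."""

    replicate_id: int
    tracts: TractSet
    donor_pops: list[str]


def _donor_emissions(panel: HaplotypePanel, donor_pops, donor_exclusion, query_pop):
    """Add-one-smoothed P(ALT | donor pop) per site; NaN where a pop has no calls."""
    em = {}
    for pop in donor_pops:
        hap_idx = panel.hap_indices(pop)
        excl = (donor_exclusion or {}).get(query_pop, {}).get(pop)
        if excl is not None:
            keep = [
                i for i in hap_idx
                if panel.samples[i // 2] not in excl
            ]
            hap_idx = np.asarray(keep, dtype=np.intp)
        alt, n = panel.allele_counts(hap_idx=hap_idx)
        with np.errstate(invalid="ignore"):
            p = (alt + 1.0) / (n + 2.0)
        p = np.where(n > 0, p, np.nan)
        em[pop] = p
    return em


def paint(
    panel: HaplotypePanel,
    query_pop: str,
    donor_pops: list[str],
    lam: float = DEFAULT_LAMBDA,
    seed: int = 0,
    replicate_id: int = 1,
    donor_exclusion: dict | None = None,
    query_haps: list[str] | None = None,
) -> PaintingReplicate:
    """Sample one ancestry painting of every query haplotype.

    Transition probability of switching away from the current donor
    population over a physical gap of ``d`` bp is ``min(lam * d, 0.49)``,
    split evenly over the other populations.  Sites where any donor
    population has no called alleles are skipped (uniform emission, so the
    state is inherited from the flanks).  ``donor_exclusion`` maps
    ``query_pop -> {donor_pop: set(sample names to drop)}`` so that, e.g.,
    self-copying designs can exclude the query's own close relatives.
    """
    for pop in donor_pops:
        panel.hap_indices(pop)  # raises if empty
    em = _donor_emissions(panel, donor_pops, donor_exclusion, query_pop)
    K = len(donor_pops)
    S = panel.n_sites
    pos = panel.positions
    rng = np.random.default_rng(seed)

    # emission likelihood matrix per state: L[k, s] = P(obs allele | pop k)
    p_alt = np.vstack([em[pop] for pop in donor_pops])  # (K, S)

    if query_haps is None:
        q_idx = panel.hap_indices(query_pop)
        names = [f"{panel.samples[i // 2]}.hap{i % 2}" for i in q_idx]
    else:
        all_names = panel.hap_names
        q_idx = np.asarray([all_names.index(h) for h in query_haps], dtype=np.intp)
        names = list(query_haps)

    gaps = np.diff(pos).astype(float)
    switch = np.minimum(lam * gaps, SWITCH_CAP)  # total switch prob per gap

    # vectorized across query haplotypes: lik has shape (H, K, S)
    obs = panel.haplotypes[q_idx]                          # (H, S)
    lik = np.where(obs[:, None, :] == 1, p_alt[None], 1.0 - p_alt[None])
    lik = np.where(np.isnan(lik) | (obs[:, None, :] == MISSING), 1.0, lik)
    H = len(names)

    # forward filtering with per-site normalization
    alpha = np.empty((S, H, K))
    a = lik[:, :, 0] / K
    alpha[0] = a / a.sum(axis=1, keepdims=True)
    for s in range(1, S):
        sw = switch[s - 1]
        prev = alpha[s - 1]
        if K > 1:
            prior = (1.0 - sw) * prev + (sw / (K - 1)) * (
                prev.sum(axis=1, keepdims=True) - prev
            )
        else:
            prior = prev
        a = prior * lik[:, :, s]
        tot = a.sum(axis=1, keepdims=True)
        np.divide(a, tot, out=a, where=tot > 0)
        a[np.squeeze(tot <= 0, axis=1)] = 1.0 / K
        alpha[s] = a

    def _sample_rows(w: np.ndarray) -> np.ndarray:
        tot = w.sum(axis=1, keepdims=True)
        w = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 1.0 / K)
        u = rng.random((w.shape[0], 1))
        return (w.cumsum(axis=1) < u).sum(axis=1).clip(max=K - 1)

    # backward sampling
    states = np.empty((S, H), dtype=np.intp)
    states[-1] = _sample_rows(alpha[-1])
    rows = np.arange(H)
    for s in range(S - 2, -1, -1):
        sw = switch[s]
        if K > 1:
            trans_col = np.full((H, K), sw / (K - 1))
            trans_col[rows, states[s + 1]] = 1.0 - sw
        else:
            trans_col = np.ones((H, K))
        states[s] = _sample_rows(alpha[s] * trans_col)

    tracts: dict[str, list[LabeledInterval]] = {}
    for h, name in enumerate(names):
        tracts[name] = _states_to_tracts(states[:, h], pos, panel.chrom_length, donor_pops)

    ts = TractSet(tracts=tracts, chrom_length=panel.chrom_length, chrom=panel.chrom)
    ts.validate()
    return PaintingReplicate(replicate_id=replicate_id, tracts=ts, donor_pops=list(donor_pops))


def _states_to_tracts(states, pos, chrom_length, labels) -> list[LabeledInterval]:
    """State-per-site -> bp intervals; boundaries at midpoints between sites."""
    out: list[LabeledInterval] = []
    start = 0
    for s in range(1, len(states)):
        if states[s] != states[s - 1]:
            cut = int((pos[s - 1] + pos[s]) // 2) + 1
            out.append((start, cut, labels[states[s - 1]]))
            start = cut
    out.append((start, chrom_length, labels[states[-1]]))
    return merge_adjacent(out)


def posterior_decode(
    panel: HaplotypePanel,
    query_hap: str,
    donor_pops: list[str],
    lam: float = DEFAULT_LAMBDA,
) -> np.ndarray:
    """Exact forward–backward posterior P(state | data) per site, (S, K).

    Used for marginal checks of the sampled replicates; shares the emission
    and transition model with :func:`paint`.
    """
    em = _donor_emissions(panel, donor_pops, None, None)
    K = len(donor_pops)
    S = panel.n_sites
    pos = panel.positions
    p_alt = np.vstack([em[pop] for pop in donor_pops])
    idx = panel.hap_names.index(query_hap)
    obs = panel.haplotypes[idx]
    lik = np.where(obs == 1, p_alt, 1.0 - p_alt)
    lik = np.where(np.isnan(lik) | (obs == MISSING), 1.0, lik)
    gaps = np.diff(pos).astype(float)
    switch = np.minimum(lam * gaps, SWITCH_CAP)

    alpha = np.empty((S, K))
    a = np.full(K, 1.0 / K) * lik[:, 0]
    alpha[0] = a / a.sum()
    for s in range(1, S):
        sw = switch[s - 1]
        prior = (1 - sw) * alpha[s - 1] + (sw / (K - 1)) * (
            alpha[s - 1].sum() - alpha[s - 1]
        ) if K > 1 else alpha[s - 1]
        a = prior * lik[:, s]
        alpha[s] = a / a.sum()

    beta = np.ones((S, K))
    for s in range(S - 2, -1, -1):
        sw = switch[s]
        msg = beta[s + 1] * lik[:, s + 1]
        beta[s] = (1 - sw) * msg + (sw / (K - 1)) * (msg.sum() - msg) if K > 1 else msg
        beta[s] /= beta[s].sum()

    post = alpha * beta
    return post / post.sum(axis=1, keepdims=True)


def paint_replicates(
    panel: HaplotypePanel,
    query_pop: str,
    donor_pops: list[str],
    n_replicates: int = 10,
    lam: float = DEFAULT_LAMBDA,
    seed: int = 0,
    donor_exclusion: dict | None = None,
    query_haps: list[str] | None = None,
) -> list[PaintingReplicate]:
    """Paint every query haplotype ``n_replicates`` times with child seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    return [
        paint(
            panel, query_pop, donor_pops, lam=lam, seed=int(s) % (2**31),
            replicate_id=r + 1, donor_exclusion=donor_exclusion,
            query_haps=query_haps,
        )
        for r, s in enumerate(seeds)
    ]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusSegments:
    """Target-ancestry intervals supported by >= min_support of R replicates."""

    segments: dict[str, list[tuple[int, int]]]
    chrom_length: int
    target_label: str
    min_support: int
    n_replicates: int
    chrom: str = "1"

    def total_covered(self, hap: str) -> int:
        return sum(e - s for s, e in self.segments[hap])


def consensus(
    replicates: list[PaintingReplicate],
    target_label: str,
    min_support: int = 5,
) -> ConsensusSegments:
    """Position-level consensus of replicate paintings.

    A position belongs to a consensus segment iff at least ``min_support``
    replicates label it ``target_label``; maximal runs of qualifying
    positions become half-open intervals.  All replicates must cover the
    same haplotypes over the same region.
    """
    if not replicates:
        raise ValueError("no replicates given")
    haps = set(replicates[0].tracts.tracts)
    length = replicates[0].tracts.chrom_length
    for rep in replicates[1:]:
        if set(rep.tracts.tracts) != haps:
            raise ValueError("replicates cover different haplotype sets")
        if rep.tracts.chrom_length != length:
            raise ValueError("replicates cover different regions")

    segments: dict[str, list[tuple[int, int]]] = {}
    for hap in sorted(haps):
        # elementary intervals from the union of all replicate breakpoints
        cuts = {0, length}
        for rep in replicates:
            for s, e, _ in rep.tracts.tracts[hap]:
                cuts.add(s)
                cuts.add(e)
        bounds = sorted(cuts)
        starts = np.asarray(bounds[:-1])
        support = np.zeros(starts.size, dtype=np.intp)
        for rep in replicates:
            for s, e, lab in rep.tracts.tracts[hap]:
                if lab == target_label:
                    lo = np.searchsorted(starts, s, side="left")
                    hi = np.searchsorted(starts, e, side="left")
                    support[lo:hi] += 1
        qual = support >= min_support
        ivs: list[tuple[int, int]] = []
        for i, q in enumerate(qual):
            if not q:
                continue
            s, e = bounds[i], bounds[i + 1]
            if ivs and ivs[-1][1] == s:
                ivs[-1] = (ivs[-1][0], e)
            else:
                ivs.append((s, e))
        segments[hap] = ivs

    return ConsensusSegments(
        segments=segments, chrom_length=length, target_label=target_label,
        min_support=min_support, n_replicates=len(replicates),
        chrom=replicates[0].tracts.chrom,
    )
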