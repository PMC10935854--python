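"""Mosaic assembly of ancestral haplotypes from a consensus candidate library.

The candidate library is a balanced set of donor haplotypes carrying their
consensus target-ancestry segments.  Reconstruction walks each region whose
candidate coverage passes the threshold (by default 20% of the library),
repeatedly choosing a covering candidate uniformly at random and copying at
most ``max_chunk`` (default 6000) bp from it; the short chunks break up the
donors' recent linkage disequilibrium so the assembled genomes behave as
draws from the ancestral gene pool rather than copies of any present-day
individual.  Regions below the coverage threshold are emitted as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .painting import ConsensusSegments
from .panel import MISSING, HaplotypePanel, Interval

DEFAULT_MAX_CHUNK = 6000
LIBRARY_COVERAGE_FRACTION = 0.20  # min_coverage = ceil(0.20 * library size)


@dataclass
class CoverageTrack:
    """Step function c(x): number of candidate haplotypes covering x."""

    bounds: np.ndarray  # breakpoints, length n+1, bounds[0]=0, bounds[-1]=L
    counts: np.ndarray  # per elementary interval, length n

    def at(self, pos: int) -> int:
        i = int(np.searchsorted(self.bounds, pos, side="right")) - 1
        i = min(max(i, 0), self.counts.size - 1)
        return int(self.counts[i])

    def regions_at_least(self, min_coverage: int) -> list[Interval]:
        out: list[Interval] = []
        for i, c in enumerate(self.counts):
            if c < min_coverage:
                continue
            s, e = int(self.bounds[i]), int(self.bounds[i + 1])
            if out and out[-1][1] == s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
        return out


@dataclass
class CandidateLibrary:
    """Balanced donor haplotypes with consensus segments and allele source."""

    panel: HaplotypePanel                     # allele source for the donors
    segments: dict[str, list[Interval]]       # hap name -> consensus intervals
    hap_index: dict[str, int]                 # hap name -> row in panel
    subpop_of: dict[str, str]                 # donor sample -> subpopulation
    coverage: CoverageTrack = field(repr=False, default=None)
    chrom_length: int = 0

    @property
    def n_haplotypes(self) -> int:
        return len(self.segments)

    def default_min_coverage(self) -> int:
        return max(1, math.ceil(LIBRARY_COVERAGE_FRACTION * self.n_haplotypes))

    def covering(self, pos: int) -> list[str]:
        """Library haplotypes whose consensus segment contains ``pos``."""
        hit = []
        for hap, ivs in self.segments.items():
            for s, e in ivs:
                if s <= pos < e:
                    hit.append(hap)
                    break
        return hit

    def segment_end(self, hap: str, pos: int) -> int:
        for s, e in self.segments[hap]:
            if s <= pos < e:
                return e
        raise KeyError(f"{hap} has no consensus segment covering {pos}")


def _coverage_track(segments: dict[str, list[Interval]], length: int) -> CoverageTrack:
    cuts = {0, length}
    for ivs in segments.values():
        for s, e in ivs:
            cuts.add(s)
            cuts.add(e)
    bounds = np.asarray(sorted(cuts), dtype=np.int64)
    counts = np.zeros(bounds.size - 1, dtype=np.int64)
    starts = bounds[:-1]
    for ivs in segments.values():
        for s, e in ivs:
            lo = np.searchsorted(starts, s, side="left")
            hi = np.searchsorted(starts, e, side="left")
            counts[lo:hi] += 1
    return CoverageTrack(bounds=bounds, counts=counts)


def build_library(
    consensus: ConsensusSegments,
    panel: HaplotypePanel,
    subpop_of: dict[str, str],
    quota_per_subpop: int = 10,
    selection_order: list[str] | None = None,
) -> CandidateLibrary:
    """Restrict the consensus donors to a balanced candidate library.

    ``subpop_of`` maps donor sample names to their subpopulation; exactly
    ``quota_per_subpop`` samples (both haplotypes each) are kept per
    subpopulation, taken in ``selection_order`` if given, else in
    lexicographic sample order.  Raises if a subpopulation cannot fill its
    quota.
    """
    by_subpop: dict[str, list[str]] = {}
    cons_samples = {h.rsplit(".hap", 1)[0] for h in consensus.segments}
    for sample in sorted(cons_samples):
        if sample not in subpop_of:
            continue
        by_subpop.setdefault(subpop_of[sample], []).append(sample)

    chosen: list[str] = []
    for subpop in sorted(by_subpop):
        pool = by_subpop[subpop]
        if selection_order:
            ordered = [s for s in selection_order if s in pool]
            ordered += [s for s in pool if s not in ordered]
        else:
            ordered = pool
        if len(ordered) < quota_per_subpop:
            raise ValueError(
                f"subpopulation {subpop!r} has {len(ordered)} donors, "
                f"fewer than quota {quota_per_subpop}"
            )
        chosen.extend(ordered[:quota_per_subpop])

    hap_names = panel.hap_names
    segments: dict[str, list[Interval]] = {}
    hap_index: dict[str, int] = {}
    for sample in chosen:
        for h in (0, 1):
            hap = f"{sample}.hap{h}"
            segments[hap] = list(consensus.segments.get(hap, []))
            hap_index[hap] = hap_names.index(hap)

    cov = _coverage_track(segments, consensus.chrom_length)
    return CandidateLibrary(
        panel=panel, segments=segments, hap_index=hap_index,
        subpop_of={s: subpop_of[s] for s in chosen},
        coverage=cov, chrom_length=consensus.chrom_length,
    )


def coverage_mask(library: CandidateLibrary, min_coverage: int | None = None) -> list[Interval]:
    """Reconstructable regions: maximal intervals with c(x) >= min_coverage."""
    if min_coverage is None:
        min_coverage = library.default_min_coverage()
    return library.coverage.regions_at_least(min_coverage)


ProvenanceChunk = tuple[str, int, int]  # (source haplotype, start, end)


def assemble_haplotype(
    library: CandidateLibrary,
    mask: list[Interval],
    max_chunk: int = DEFAULT_MAX_CHUNK,
    rng: np.random.Generator | None = None,
) -> list[ProvenanceChunk]:
    """Assemble one mosaic haplotype; returns its provenance chunks.

    Within each reconstructable region, assembly starts at the left edge; at
    every junction a candidate whose consensus segment covers the junction is
    drawn uniformly at random, excluding the immediately preceding source
    when an alternative exists, and copied until the chunk cap, the end of
    that candidate's segment, or the end of the region.
    """
    if library.n_haplotypes == 0:
        raise ValueError("empty candidate library")
    if not mask:
        raise ValueError("mask has no reconstructable region")
    rng = rng or np.random.default_rng()
    chunks: list[ProvenanceChunk] = []
    for region_start, region_end in mask:
        pos = region_start
        prev: str | None = None
        while pos < region_end:
            candidates = library.covering(pos)
            if not candidates:  # cannot occur when min_coverage >= 1
                raise RuntimeError(f"no candidate covers position {pos}")
            pool = [h for h in candidates if h != prev] or candidates
            hap = pool[rng.integers(len(pool))]
            end = min(pos + max_chunk, library.segment_end(hap, pos), region_end)
            chunks.append((hap, pos, end))
            prev = hap
            pos = end
    return chunks


@dataclass
class ReconstructedPanel:
    """Assembled mosaic genomes with mask and per-chunk provenance."""

    panel: HaplotypePanel
    provenance: dict[str, list[ProvenanceChunk]]
    mask_regions: list[Interval]
    min_coverage: int
    max_chunk: int

    def covered_fraction(self) -> float:
        covered = sum(e - s for s, e in self.mask_regions)
        return covered / self.panel.chrom_length

    def max_chunk_length(self) -> int:
        return max(
            (e - s for chunks in self.provenance.values() for _, s, e in chunks),
            default=0,
        )


def assemble_panel(
    library: CandidateLibrary,
    n_genomes: int = 30,
    max_chunk: int = DEFAULT_MAX_CHUNK,
    min_coverage: int | None = None,
    seed: int = 0,
    pop_label: str = "Reconstructed",
) -> ReconstructedPanel:
    """Assemble ``2 * n_genomes`` mosaic haplotypes, paired into diploids.

    The library is reused across genomes (sampling with replacement across
    genomes); each haplotype gets an independent child seed from the master
    seed, so assembly is reproducible and order-independent.  Haplotype
    pairing into diploids is sequential — the genomes are population-level
    proxies, not individuals.
    """
    if min_coverage is None:
        min_coverage = library.default_min_coverage()
    mask = coverage_mask(library, min_coverage)
    src = library.panel
    positions = src.positions

    in_mask = np.zeros(positions.size, dtype=bool)
    for s, e in mask:
        lo = np.searchsorted(positions, s, side="left")
        hi = np.searchsorted(positions, e, side="left")
        in_mask[lo:hi] = True

    child = np.random.SeedSequence(seed).spawn(2 * n_genomes)
    provenance: dict[str, list[ProvenanceChunk]] = {}
    rows = np.full((2 * n_genomes, positions.size), MISSING, dtype=np.int8)
    samples = [f"{pop_label}_{g:03d}" for g in range(n_genomes)]

    for k in range(2 * n_genomes):
        rng = np.random.default_rng(child[k])
        chunks = assemble_haplotype(library, mask, max_chunk=max_chunk, rng=rng)
        provenance[f"{samples[k // 2]}.hap{k % 2}"] = chunks
        for hap, s, e in chunks:
            lo = np.searchsorted(positions, s, side="left")
            hi = np.searchsorted(positions, e, side="left")
            rows[k, lo:hi] = src.haplotypes[library.hap_index[hap], lo:hi]
    rows[:, ~in_mask] = MISSING

    out = HaplotypePanel(
        haplotypes=rows, positions=positions.copy(), samples=samples,
        populations=[pop_label] * n_genomes, chrom=src.chrom,
        chrom_length=src.chrom_length,
    )
    return ReconstructedPanel(
        panel=out, provenance=provenance, mask_regions=mask,
        min_coverage=min_coverage, max_chunk=max_chunk,
    )


# ---------------------------------------------------------------------------
# Kinship QC on reconstructed genomes
# ---------------------------------------------------------------------------

def kinship_matrix(panel: HaplotypePanel) -> np.ndarray:
    """Pairwise kinship coefficients on jointly called sites.

    A simple genotype-correlation kinship (KING-robust style within-pair
    heterozygosity form): phi = (N_Aa,Aa - 2 * N_AA,aa) / (N_Aa(i) + N_Aa(j))
    computed over sites called in both individuals.  Third-degree pairs sit
    around phi ~ 0.0442; unrelated pairs near or below zero.
    """
    n = len(panel.samples)
    G = np.where(
        (panel.haplotypes[0::2] == MISSING) | (panel.haplotypes[1::2] == MISSING),
        -1,
        panel.haplotypes[0::2] + panel.haplotypes[1::2],
    )
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (G[i] >= 0) & (G[j] >= 0)
            gi, gj = G[i][ok], G[j][ok]
            het_i = int(((gi == 1)).sum())
            het_j = int(((gj == 1)).sum())
            het_het = int(((gi == 1) & (gj == 1)).sum())
            opp_hom = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
            denom = het_i + het_j
            phi[i, j] = phi[j, i] = (
                (het_het - 2.0 * opp_hom) / denom if denom > 0 else 0.0
            )
    return phi
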