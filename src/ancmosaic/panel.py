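"""Core in-memory containers for phased genotype panels and ancestry tracts.

Coordinates are 0-based half-open everywhere in memory; VCF/BED writers and
readers convert at the boundary.  Haplotype ``i`` belongs to diploid sample
``i // 2`` and is named ``"<sample>.hap<i % 2>"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class HaplotypePanel:
    """Phased biallelic genotype matrix with population labels.

    Attributes
    ----------
    haplotypes : (n_haplotypes, n_sites) int8 array
        Allele codes 0 (REF), 1 (ALT); ``MISSING`` (-1) for no-calls.
    positions : (n_sites,) int64 array
        Physical positions, 0-based, strictly increasing.
    samples : list of str
        Diploid sample names; ``len(samples) * 2 == haplotypes.shape[0]``.
    populations : list of str
        Population label per sample.
    chrom : str
        Chromosome name (single-chromosome panels only).
    chrom_length : int
        Physical span of the analyzed region in bp.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    samples: list[str]
    populations: list[str]
    chrom: str = "1"
    chrom_length: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (n_haplotypes, n_sites)")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("expected two haplotypes per sample")
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("positions do not match site dimension")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.chrom_length <= 0:
            self.chrom_length = int(self.positions[-1]) + 1 if self.positions.size else 1

    # ---- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def hap_names(self) -> list[str]:
        return [f"{s}.hap{h}" for s in self.samples for h in (0, 1)]

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, p in enumerate(self.populations) if p == pop]
        if not idx:
            raise KeyError(f"no samples labeled population {pop!r}")
        return np.asarray(idx, dtype=np.intp)

    def hap_indices(self, pop: str) -> np.ndarray:
        s = self.sample_indices(pop)
        return np.sort(np.concatenate([2 * s, 2 * s + 1]))

    def subset_samples(self, sample_idx: np.ndarray) -> "HaplotypePanel":
        sample_idx = np.asarray(sample_idx, dtype=np.intp)
        # keep row order aligned with the sample list
        hap_idx = np.stack([2 * sample_idx, 2 * sample_idx + 1], axis=1).ravel()
        return HaplotypePanel(
            haplotypes=self.haplotypes[hap_idx].copy(),
            positions=self.positions.copy(),
            samples=[self.samples[i] for i in sample_idx],
            populations=[self.populations[i] for i in sample_idx],
            chrom=self.chrom,
            chrom_length=self.chrom_length,
        )

    # ---- frequencies -----------------------------------------------------

    def allele_counts(self, pop: str | None = None, hap_idx: np.ndarray | None = None):
        """Return ``(alt_count, called_allele_count)`` per site.

        ``pop`` selects a population; ``hap_idx`` selects explicit haplotype
        rows; both ``None`` means the whole panel.
        """
        if hap_idx is None:
            H = self.haplotypes if pop is None else self.haplotypes[self.hap_indices(pop)]
        else:
            H = self.haplotypes[np.asarray(hap_idx, dtype=np.intp)]
        called = H != MISSING
        alt = np.where(called, H, 0).sum(axis=0)
        return alt.astype(np.int64), called.sum(axis=0).astype(np.int64)

    def allele_freqs(self, pop: str | None = None, hap_idx: np.ndarray | None = None):
        """ALT-allele frequency and called-allele count per site (NaN if no calls)."""
        alt, n = self.allele_counts(pop=pop, hap_idx=hap_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return p, n

    def genotype_missing_rate(self, sample_idx: np.ndarray) -> np.ndarray:
        """Per-site fraction of the given diploid samples with a missing genotype.

        A genotype is missing when either of its two haplotype alleles is
        a no-call.
        """
        sample_idx = np.asarray(sample_idx, dtype=np.intp)
        a = self.haplotypes[2 * sample_idx] == MISSING
        b = self.haplotypes[2 * sample_idx + 1] == MISSING
        return (a | b).mean(axis=0)


Interval = tuple[int, int]
LabeledInterval = tuple[int, int, str]


@dataclass
class TractSet:
    """Per-haplotype ancestry intervals, half-open, tiling ``[0, chrom_length)``."""

    tracts: dict[str, list[LabeledInterval]]
    chrom_length: int
    chrom: str = "1"

    def validate(self) -> None:
        for hap, ivs in self.tracts.items():
            if not ivs:
                raise ValueError(f"haplotype {hap}: empty tract list")
            prev_end = 0
            for s, e, _lab in ivs:
                if s != prev_end or e <= s:
                    raise ValueError(f"haplotype {hap}: tracts must tile the region")
                prev_end = e
            if prev_end != self.chrom_length:
                raise ValueError(f"haplotype {hap}: tracts do not reach chrom_length")

    def label_at(self, hap: str, pos: int) -> str:
        for s, e, lab in self.tracts[hap]:
            if s <= pos < e:
                return lab
        raise KeyError(f"position {pos} outside tracts of {hap}")

    def labels_at_positions(self, hap: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized tract lookup for sorted positions."""
        ivs = self.tracts[hap]
        starts = np.array([s for s, _, _ in ivs])
        labs = np.array([lab for _, _, lab in ivs])
        idx = np.searchsorted(starts, positions, side="right") - 1
        return labs[idx]


def merge_adjacent(intervals: list[LabeledInterval]) -> list[LabeledInterval]:
    """Merge touching intervals with identical labels."""
    out: list[LabeledInterval] = []
    for s, e, lab in intervals:
        if out and out[-1][2] == lab and out[-1][1] == s:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    return out
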