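"""Readers and writers for the pipeline's file formats.

VCF 4.2 (phased GT, biallelic SNVs), BED tract files with a
haplotype-qualified name column, MSMC-style Ne tables (TSV), similarity
matrices (CSV), sample-group tables (TSV), and YAML configs.  VCF positions
are 1-based on disk and converted to the internal 0-based convention at the
boundary; BED stays 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import MISSING, HaplotypePanel, TractSet

_ALLELES = ("A", "C", "G", "T")


def write_vcf(panel: HaplotypePanel, path, ref_alt: list[tuple[str, str]] | None = None):
    """Write a phased VCF 4.2; missing genotypes become ``./.``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={panel.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        H = panel.haplotypes
        for j in range(panel.n_sites):
            ref, alt = ref_alt[j] if ref_alt else ("A", "G")
            cells = []
            for i in range(len(panel.samples)):
                a, b = H[2 * i, j], H[2 * i + 1, j]
                if a == MISSING or b == MISSING:
                    cells.append("./.")
                else:
                    cells.append(f"{a}|{b}")
            fh.write(
                f"{panel.chrom}\t{panel.positions[j] + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path, groups: dict[str, str] | None = None, require_phased: bool = True) -> HaplotypePanel:
    """Read a biallelic-SNV VCF into a :class:`HaplotypePanel`.

    ``groups`` maps sample name -> population label (samples absent from the
    map get population ``"NA"``).  Multiallelic records are rejected.
    Unphased genotypes raise (with the first offending record named) unless
    ``require_phased=False``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    chrom = None
    chrom_length = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; split it first"
            )
        chrom = rec.CHROM
        gt = np.asarray(rec.genotype.array())  # (n_samples, 3): a, b, phased
        if require_phased:
            unphased = (gt[:, 2] == 0) & (gt[:, 0] >= 0) & (gt[:, 1] >= 0)
            if unphased.any():
                bad = samples[int(np.flatnonzero(unphased)[0])]
                raise ValueError(
                    f"unphased genotype for sample {bad} at {rec.CHROM}:{rec.POS}"
                )
        a = gt[:, 0].astype(np.int8)
        b = gt[:, 1].astype(np.int8)
        a[a < 0] = MISSING
        b[b < 0] = MISSING
        # missing is per-genotype: one missing allele masks the genotype
        miss = (a == MISSING) | (b == MISSING)
        a[miss] = MISSING
        b[miss] = MISSING
        row = np.empty(2 * len(samples), dtype=np.int8)
        row[0::2] = a
        row[1::2] = b
        rows.append(row)
        positions.append(rec.POS - 1)
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig") and chrom and f"ID={chrom}" in line and "length=" in line:
            chrom_length = int(line.split("length=")[1].rstrip(">").split(",")[0])
    pops = [groups.get(s, "NA") if groups else "NA" for s in samples]
    return HaplotypePanel(
        haplotypes=np.asarray(rows, dtype=np.int8).T,
        positions=np.asarray(positions, dtype=np.int64),
        samples=samples,
        populations=pops,
        chrom=chrom or "1",
        chrom_length=chrom_length or (positions[-1] + 1 if positions else 1),
    )


# ---------------------------------------------------------------------------
# Tracts / BED
# ---------------------------------------------------------------------------

def write_tracts_bed(tracts: TractSet, path, replicate: int | None = None):
    """BED: chrom, start, end, label, haplotype name [, replicate]."""
    with Path(path).open("w") as fh:
        for hap in sorted(tracts.tracts):
            for s, e, lab in tracts.tracts[hap]:
                cols = [tracts.chrom, str(s), str(e), lab, hap]
                if replicate is not None:
                    cols.append(str(replicate))
                fh.write("\t".join(cols) + "\n")


def read_tracts_bed(path, chrom_length: int) -> TractSet:
    tracts: dict[str, list[tuple[int, int, str]]] = {}
    chrom = "1"
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, s, e, lab, hap = parts[0], int(parts[1]), int(parts[2]), parts[3], parts[4]
            tracts.setdefault(hap, []).append((s, e, lab))
    for hap in tracts:
        tracts[hap].sort()
    ts = TractSet(tracts=tracts, chrom_length=chrom_length, chrom=chrom)
    ts.validate()
    return ts


def write_intervals_bed(intervals, path, chrom="1", name=None):
    with Path(path).open("w") as fh:
        for iv in intervals:
            cols = [chrom, str(iv[0]), str(iv[1])]
            if name is not None:
                cols.append(name)
            elif len(iv) > 2:
                cols.append(str(iv[2]))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_groups_tsv(path) -> dict[str, str]:
    """Two-column TSV (sample, group) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], comment="#")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def read_ne_table(path, mutation_rate: float | None = None, generation_years: float = 29.0) -> pd.DataFrame:
    """Read an Ne table as tidy TSV (pop, left_years, right_years, ne).

    Also accepts MSMC-style per-population files via :func:`read_msmc`, which
    converts scaled times/lambdas using ``mutation_rate`` and
    ``generation_years``.
    """
    return pd.read_csv(path, sep="\t")


def read_msmc(path, pop: str, mutation_rate: float = 1.25e-8, generation_years: float = 29.0) -> pd.DataFrame:
    """Convert MSMC output (time_index, left/right scaled time, lambda).

    Real times are scaled/mu * generation years; Ne = 1 / (2 * lambda * mu)
    in units of diploids.
    """
    df = pd.read_csv(path, sep="\t")
    out = pd.DataFrame(
        {
            "pop": pop,
            "left_years": df["left_time_boundary"] / mutation_rate * generation_years,
            "right_years": df["right_time_boundary"] / mutation_rate * generation_years,
            "ne": 1.0 / (2.0 * df["lambda"] * mutation_rate),
        }
    )
    return out


def write_ne_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_similarity_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df


def load_config(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path):
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
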