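"""End-to-end orchestration of the reconstruction-and-screens pipeline.

The full chain on one panel: replicate ancestry painting of the admixed
samples -> consensus candidate segments -> balanced candidate library ->
mosaic reconstruction -> frequency/FST screens.  Works on synthetic panels
out of the box (ground-truth tracts available) and on any externally loaded
panel with the same labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import painting, popstats, reconstruct, selscreen, simdata
from .panel import HaplotypePanel, TractSet


@dataclass
class PipelineConfig:
    """Stage parameters with the pipeline's canonical defaults."""

    n_replicates: int = 10
    min_support: int = 5
    lam: float = painting.DEFAULT_LAMBDA
    quota_per_subpop: int = 10
    n_subpops: int = 3
    max_chunk: int = 6000
    min_coverage: int | None = None        # None -> 20%-of-library rule
    n_genomes: int = 30
    fst_subset: int = 9
    fst_reps: int = 100
    top_quantile_primary: float = 0.001
    top_quantile_relaxed: float = 0.01
    min_freq_diff: float = 0.3
    missing_rate_max: float = 0.10
    seed: int = 0
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)


@dataclass
class PipelineResult:
    panel: HaplotypePanel
    truth: TractSet | None
    consensus: painting.ConsensusSegments
    library: reconstruct.CandidateLibrary
    reconstructed: reconstruct.ReconstructedPanel
    report: dict


def run_pipeline(config: PipelineConfig, panel=None, truth=None, outdir=None) -> PipelineResult:
    """Run every stage in dependency order and collect a summary report.

    With ``panel=None`` a synthetic panel is simulated from ``config.sim``
    (seeded from ``config.seed``); outputs are written under ``outdir`` when
    given.  Reruns with the same config are byte-identical.
    """
    rep: dict = {}
    if panel is None:
        sim_cfg = config.sim
        sim_cfg.seed = config.seed
        panel, truth = simdata.simulate_panel(sim_cfg)
        rep["sim_target_fraction"] = simdata.target_fraction(truth, sim_cfg.target_pop)
    target_pop = config.sim.target_pop
    other_pop = config.sim.other_pop
    admixed = simdata.ADMIXED_POP
    donor_pops = [p for p in dict.fromkeys(panel.populations) if p != admixed]

    reps = painting.paint_replicates(
        panel, admixed, donor_pops, n_replicates=config.n_replicates,
        lam=config.lam, seed=config.seed + 1,
    )
    cons = painting.consensus(reps, target_pop, min_support=config.min_support)
    rep["consensus_bp_per_hap"] = float(
        np.mean([cons.total_covered(h) for h in cons.segments])
    )

    admixed_samples = sorted(
        {h.rsplit(".hap", 1)[0] for h in cons.segments}
    )
    # round-robin pseudo-subpopulations keep the library balanced
    subpop_of = {
        s: f"sub{j % config.n_subpops}" for j, s in enumerate(admixed_samples)
    }
    library = reconstruct.build_library(
        cons, panel, subpop_of, quota_per_subpop=config.quota_per_subpop
    )
    recon = reconstruct.assemble_panel(
        library, n_genomes=config.n_genomes, max_chunk=config.max_chunk,
        min_coverage=config.min_coverage, seed=config.seed + 2,
    )
    rep["library_haplotypes"] = library.n_haplotypes
    rep["min_coverage"] = recon.min_coverage
    rep["covered_fraction"] = recon.covered_fraction()
    rep["max_chunk_bp"] = recon.max_chunk_length()

    # frequency tracks and screens against the non-target source ("reference")
    p_ref, n_ref = panel.allele_freqs(pop=other_pop)
    p_present, n_present = panel.allele_freqs(pop=admixed)
    p_anc, n_anc = recon.panel.allele_freqs()
    fst_anc = popstats.site_fst(p_anc, n_anc, p_ref, n_ref)
    fst_present = popstats.site_fst(p_present, n_present, p_ref, n_ref)
    extra = selscreen.extra_snvs(
        fst_anc, fst_present, config.top_quantile_primary, config.top_quantile_relaxed
    )
    grad, n_excl = selscreen.gradient_screen(
        p_ref, p_present, p_anc, min_diff=config.min_freq_diff
    )
    rep["n_extra_snvs"] = int(extra.sum())
    rep["n_gradient_hits"] = int(grad.sum())
    rep["n_gradient_excluded"] = n_excl

    pair = popstats.pairwise_fst_balanced(
        panel, target_pop, other_pop, subset=config.fst_subset,
        reps=config.fst_reps, seed=config.seed + 3,
    )
    rep["fst_target_other_mean"] = pair.mean
    rep["fst_target_other_sd"] = pair.sd

    if truth is not None:
        rep["reconstructed_target_base_fraction"] = provenance_target_fraction(
            recon, truth, target_pop
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from . import vcfio

        vcfio.write_vcf(recon.panel, outdir / "reconstructed.vcf")
        vcfio.write_intervals_bed(recon.mask_regions, outdir / "mask.bed", chrom=panel.chrom)
        prov = [
            (s, e, hap)
            for hap_chunks in recon.provenance.values()
            for hap, s, e in hap_chunks
        ]
        vcfio.write_intervals_bed(prov, outdir / "provenance.bed", chrom=panel.chrom)
        cfg = asdict(config)
        cfg["sim"]["pops"] = {
            k: asdict(v) if not isinstance(v, dict) else v
            for k, v in cfg["sim"]["pops"].items()
        }
        (outdir / "run_log.json").write_text(json.dumps(rep, indent=2, sort_keys=True))
        vcfio.save_config(cfg, outdir / "config.yaml")

    return PipelineResult(
        panel=panel, truth=truth, consensus=cons, library=library,
        reconstructed=recon, report=rep,
    )


def provenance_target_fraction(
    recon: reconstruct.ReconstructedPanel, truth: TractSet, target_pop: str
) -> float:
    """Fraction of reconstructed bases copied from true target-ancestry tracts."""
    total = on_target = 0
    for chunks in recon.provenance.values():
        for hap, s, e in chunks:
            total += e - s
            for ts, te, lab in truth.tracts[hap]:
                ov = min(e, te) - max(s, ts)
                if ov > 0 and lab == target_pop:
                    on_target += ov
    return on_target / total if total else 0.0
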