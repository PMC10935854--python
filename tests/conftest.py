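import numpy as np
import pytest

from ancmosaic import painting, reconstruct, simdata
from ancmosaic.panel import HaplotypePanel


@pytest.fixture(scope="session")
def dense_recon_run():
    """Shared end-to-end run on a dense 50 kb / 5000-site region.

    Admixture proportion 0.3 with short tracts, so that candidate coverage
    genuinely varies along the region and the coverage mask is non-trivial.
    """
    cfg = simdata.SimConfig(
        n_sites=5000,
        chrom_length_bp=50_000,
        admixture_proportion=0.2,  # candidate coverage fluctuates around 12/60
        recomb_rate=2e-6,  # mean tract 50 kb per ancestry-switch opportunity
        seed=11,
    )
    panel, truth = simdata.simulate_panel(cfg)
    reps = painting.paint_replicates(
        panel, simdata.ADMIXED_POP, ["Target", "Other", "Outgroup"],
        n_replicates=10, seed=11,
    )
    cons = painting.consensus(reps, "Target", min_support=5)
    samples = sorted({h.rsplit(".hap", 1)[0] for h in cons.segments})
    subpop_of = {s: f"sub{j % 3}" for j, s in enumerate(samples)}
    library = reconstruct.build_library(cons, panel, subpop_of, quota_per_subpop=10)
    recon = reconstruct.assemble_panel(library, n_genomes=30, min_coverage=12, seed=11)
    return {
        "config": cfg,
        "panel": panel,
        "truth": truth,
        "consensus": cons,
        "library": library,
        "recon": recon,
    }


@pytest.fixture
def two_pop_fixed_panel():
    """Tiny handcrafted panel: pops A and B fixed for opposite alleles, one
    query sample identical to A."""
    n_sites = 40
    positions = np.arange(n_sites) * 1000
    hapA = np.ones(n_sites, dtype=np.int8)
    hapB = np.zeros(n_sites, dtype=np.int8)
    rows = [hapA, hapA, hapA, hapA, hapB, hapB, hapB, hapB, hapA, hapA]
    return HaplotypePanel(
        haplotypes=np.vstack(rows),
        positions=positions,
        samples=["A_0", "A_1", "B_0", "B_1", "Q_0"],
        populations=["A", "A", "B", "B", "Q"],
        chrom="1",
        chrom_length=n_sites * 1000,
    )
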