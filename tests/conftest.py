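import numpy as np
import pytest

from admixkit import (
    GenotypeMatrix,
    ReferencePanel,
    SimulationSpec,
    VariantRecord,
    simulate_admixed_targets,
    simulate_frequencies,
    simulate_reference_panel,
)


def make_matrix(G, chrom="1", samples=None, alleles=None):
    """GenotypeMatrix from a plain array with auto-generated metadata."""
    G = np.asarray(G, dtype=np.int16)
    n, J = G.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    variants = []
    for j in range(J):
        ref, alt = alleles[j] if alleles else ("A", "G")
        variants.append(VariantRecord(chrom, j * 100 + 1, f"v{j + 1}", ref, alt))
    return GenotypeMatrix(samples, variants, G)


@pytest.fixture(scope="session")
def small_panel_sim():
    """Two well-differentiated populations, 40/pop, 800 SNPs, plus 30
    half-and-half admixed targets with known truth."""
    spec = SimulationSpec(
        populations=["PopA", "PopB"],
        fst=[0.2, 0.2],
        J=800,
        n_ref=40,
        targets=[(30, [0.5, 0.5])],
        seed=7,
    )
    F = simulate_frequencies(spec)
    panel = simulate_reference_panel(spec, F)
    targets, Qtrue = simulate_admixed_targets(spec, F)
    return spec, F, panel, targets, Qtrue


@pytest.fixture(scope="session")
def six_pop_panel():
    """Six-population synthetic panel at the default continental drift
    ladder, small enough for fast unit tests."""
    spec = SimulationSpec(J=1500, n_ref=30, seed=21)
    F = simulate_frequencies(spec)
    return spec, F, simulate_reference_panel(spec, F)
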