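"""Synthetic genotype data for admixture studies.

Population allele frequencies follow the Balding–Nichols model: for a
SNP with ancestral frequency p_j ~ Uniform(0.05, 0.95), population k
draws

    f_kj ~ Beta( p_j (1 - F_k) / F_k,  (1 - p_j)(1 - F_k) / F_k ),

where F_k is that population's drift/differentiation parameter; the
expected Hudson Fst between populations a and b is approximately
(F_a + F_b) / 2 under this star-shaped model.  Genotypes of an
individual with admixture vector q are Binomial(2, sum_k q_k f_kj),
independently across (unlinked) sites.

The default six-population scenario mimics a continental reference
panel: drift parameters are a least-squares star-model fit to observed
continental pairwise Fst values (range ~0.03-0.35, Europe-America pair
at 0.17), J = 16,443 markers spread over 22 chromosomes, and 50
reference individuals per population.  All generators are
bit-reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .admixture_core import EPS, AlleleFreqMatrix
from .errors import ParameterError
from .io import MISSING, GenotypeMatrix, ReferencePanel, VariantRecord

DEFAULT_POPULATIONS = [
    "Europe",
    "Africa",
    "America",
    "EastAsia",
    "Oceania",
    "CentralAsia",
]

# star-model drift ladder fitted to continental pairwise Fst (see module docs)
DEFAULT_FST = {
    "Europe": 0.09,
    "Africa": 0.25,
    "America": 0.25,
    "EastAsia": 0.09,
    "Oceania": 0.34,
    "CentralAsia": 0.03,
}

DEFAULT_J = 16_443
N_CHROMOSOMES = 22


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    ``targets`` lists (count, q-vector) groups of admixed individuals to
    draw in addition to the per-population reference individuals.
    """

    populations: list[str] = field(default_factory=lambda: list(DEFAULT_POPULATIONS))
    fst: list[float] | None = None
    J: int = DEFAULT_J
    n_ref: int | list[int] = 50
    targets: list[tuple[int, list[float]]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fst is None:
            self.fst = [DEFAULT_FST.get(p, 0.15) for p in self.populations]
        if len(self.fst) != len(self.populations):
            raise ParameterError("one drift parameter per population required")
        for f in self.fst:
            if not 0.0 < f < 1.0:
                raise ParameterError(f"drift parameters must lie in (0, 1), got {f}")
        if self.J < 1:
            raise ParameterError("J must be >= 1")
        if isinstance(self.n_ref, int):
            self.n_ref = [self.n_ref] * len(self.populations)
        else:
            self.n_ref = list(self.n_ref)
        if len(self.n_ref) != len(self.populations):
            raise ParameterError("one reference size per population required")
        if min(self.n_ref) < 1:
            raise ParameterError("n_ref must be >= 1")
        for count, q in self.targets:
            q = np.asarray(q, dtype=float)
            if count < 1 or len(q) != len(self.populations):
                raise ParameterError("each target group needs a count and a full q vector")
            if (q < 0).any() or abs(q.sum() - 1.0) > 1e-9:
                raise ParameterError("target q vectors must lie on the simplex")

    @property
    def K(self) -> int:
        return len(self.populations)


def _variant_list(J: int) -> list[VariantRecord]:
    per = -(-J // N_CHROMOSOMES)
    out = []
    for j in range(J):
        chrom = str(j // per + 1)
        out.append(VariantRecord(chrom, (j % per) * 1000 + 1, f"snp{j + 1}", "A", "G"))
    return out


def simulate_frequencies(spec: SimulationSpec) -> AlleleFreqMatrix:
    """Draw ancestral and population allele frequencies under Balding–Nichols."""
    rng = np.random.default_rng(spec.seed)
    p = rng.uniform(0.05, 0.95, size=spec.J)
    F = np.empty((spec.K, spec.J))
    for k, fk in enumerate(spec.fst):
        a = p * (1.0 - fk) / fk
        b = (1.0 - p) * (1.0 - fk) / fk
        F[k] = np.clip(rng.beta(a, b), EPS, 1.0 - EPS)
    return AlleleFreqMatrix(list(spec.populations), F)


def simulate_genotypes(
    Q: np.ndarray,
    F: AlleleFreqMatrix,
    seed: int = 0,
    sample_prefix: str = "sim",
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Binomial(2, Q F) genotypes for each row of Q."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != F.K:
        raise ParameterError(f"Q must be n x K={F.K}")
    rng = np.random.default_rng(seed)
    P = Q @ F.F
    G = rng.binomial(2, P).astype(np.int16)
    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = MISSING
    samples = [f"{sample_prefix}{i + 1}" for i in range(Q.shape[0])]
    return GenotypeMatrix(samples, _variant_list(F.J), G)


def simulate_reference_panel(
    spec: SimulationSpec, F: AlleleFreqMatrix | None = None
) -> ReferencePanel:
    """n_ref unadmixed individuals per population (indicator q vectors)."""
    if F is None:
        F = simulate_frequencies(spec)
    rows = []
    labels = []
    for k, pop in enumerate(spec.populations):
        q = np.zeros(spec.K)
        q[k] = 1.0
        rows.append(np.tile(q, (spec.n_ref[k], 1)))
        labels += [pop] * spec.n_ref[k]
    Q = np.vstack(rows)
    G = simulate_genotypes(Q, F, seed=spec.seed + 1, sample_prefix="ref")
    return ReferencePanel(G, labels, list(spec.populations))


def simulate_admixed_targets(
    spec: SimulationSpec, F: AlleleFreqMatrix | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Admixed individuals per the spec's target groups; returns (G, true Q)."""
    if not spec.targets:
        raise ParameterError("spec.targets is empty")
    if F is None:
        F = simulate_frequencies(spec)
    Q = np.vstack([np.tile(np.asarray(q, float), (count, 1)) for count, q in spec.targets])
    G = simulate_genotypes(Q, F, seed=spec.seed + 2, sample_prefix="tgt")
    return G, Q


def simulate_offspring(
    g_father: np.ndarray, g_mother: np.ndarray, seed: int = 0
) -> np.ndarray:
    """One child genotype vector by Mendelian transmission at unlinked sites.

    Per site one allele is drawn uniformly from each parent's two
    alleles; a missing parental genotype makes the child missing there.
    """
    g_father = np.asarray(g_father)
    g_mother = np.asarray(g_mother)
    if g_father.shape != g_mother.shape:
        raise ParameterError("parental genotype vectors must have equal length")
    rng = np.random.default_rng(seed)
    J = g_father.shape[0]
    # P(transmit alt) = g/2 for each parent independently
    a1 = rng.random(J) < g_father / 2.0
    a2 = rng.random(J) < g_mother / 2.0
    child = a1.astype(np.int16) + a2.astype(np.int16)
    child[(g_father == MISSING) | (g_mother == MISSING)] = MISSING
    return child


def write_truth_table(Q: np.ndarray, samples: list[str], populations: list[str], path) -> None:
    """TSV of true admixture vectors for downstream scoring."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(populations) + "\n")
        for s, row in zip(samples, Q):
            fh.write(s + "\t" + "\t".join(f"{q:.6f}" for q in row) + "\n")
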