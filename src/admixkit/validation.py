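"""Panel and estimate validation: IBS/PCoA, Fst, permutation variance
testing, leave-one-out resampling, SE-vs-marker-count curves, and trio
consistency.

These are the checks a reference panel must pass before it is trusted
for supervised ancestry inference: labeled groups should separate in
IBS distance space, grouping should explain a significant share of
distance variance, each member's documented ancestry should be
recapitulated when it is held out, and standard errors should shrink
with marker count roughly as 1/sqrt(J).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .admixture_core import (
    AdmixtureEstimate,
    AlleleFreqMatrix,
    FitOptions,
    fit_with_frequencies,
)
from .errors import DataError, ParameterError
from .io import MISSING, GenotypeMatrix, ReferencePanel
from .uncertainty import bootstrap_se

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "ibs_distance_matrix",
    "pcoa",
    "pairwise_fst",
    "distance_variance_test",
    "leave_one_out",
    "se_vs_marker_count",
    "trio_deviation",
]


@dataclass
class DistanceMatrix:
    samples: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.samples)
        if self.D.shape != (n, n):
            raise DataError("distance matrix must be n x n")
        if np.abs(self.D - self.D.T).max() > 1e-12:
            raise DataError("distance matrix must be symmetric")
        if np.abs(np.diag(self.D)).max() > 0:
            raise DataError("distance matrix must have a zero diagonal")
        if (self.D < 0).any():
            raise DataError("distances must be non-negative")


@dataclass
class PCoAResult:
    coords: np.ndarray
    varexp: np.ndarray


def ibs_distance_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean identity-by-state allele sharing over jointly observed SNPs.

    Per pair (i, l): D_il = 1 - (1/J_il) * sum_j (2 - |g_ij - g_lj|) / 2,
    which is 0 for identical genotype vectors and 1 for opposite
    homozygotes everywhere.
    """
    obs = G.observed_mask()
    # one-hot by genotype value; |a-b| decomposes into mismatch-class counts
    X = [(np.where(obs, G.G, -9) == v).astype(float) for v in (0, 1, 2)]
    c01 = X[0] @ X[1].T
    c12 = X[1] @ X[2].T
    c02 = X[0] @ X[2].T
    absdiff = c01 + c01.T + c12 + c12.T + 2.0 * (c02 + c02.T)
    shared = obs.astype(float) @ obs.astype(float).T
    no_overlap = (shared == 0) & ~np.eye(G.n, dtype=bool)
    if no_overlap.any():
        i, l = np.argwhere(no_overlap)[0]
        raise DataError(
            f"samples {G.samples[i]!r} and {G.samples[l]!r} share no observed SNPs"
        )
    D = absdiff / (2.0 * np.maximum(shared, 1.0))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(list(G.samples), D)


def pcoa(D: DistanceMatrix, m: int = 2) -> PCoAResult:
    """Classical scaling (principal coordinate analysis) of a distance matrix.

    Double-centers -1/2 * D^2, eigendecomposes, and returns coordinates
    eigvec * sqrt(eigval) on the top ``m`` positive eigenvalues.
    ``varexp`` is each axis's share of the total positive-eigenvalue
    variance.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    n = len(D.samples)
    D2 = D.D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigval, eigvec = scipy.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12 * abs(eigval[0]), 1e-12) if eigval[0] > 0 else eigval > 0
    if not pos.any():
        raise DataError("no positive eigenvalues; input is not a distance structure")
    m_eff = min(m, int(pos.sum()))
    lam = eigval[:m_eff]
    coords = eigvec[:, :m_eff] * np.sqrt(lam)[None, :]
    varexp = lam / eigval[pos].sum()
    return PCoAResult(coords=coords, varexp=varexp)


def pairwise_fst(panel: ReferencePanel) -> np.ndarray:
    """Hudson-style Fst between every pair of panel populations.

    Per SNP the numerator is (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    and the denominator p1(1-p2) + p2(1-p1); per pair these are combined
    as a ratio of sums across SNPs (sample-size robust).  Allele counts
    n1, n2 are counted in alleles (2 x observed genotypes).
    """
    K = panel.K
    lab = panel.label_indices()
    G = panel.genotypes.G
    obs = G != MISSING
    Gf = np.where(obs, G, 0).astype(float)
    p = np.zeros((K, panel.genotypes.J))
    nall = np.zeros((K, panel.genotypes.J))
    for k in range(K):
        rows = lab == k
        if rows.sum() < 2:
            raise DataError(
                f"population {panel.populations[k]!r} needs >= 2 members for Fst"
            )
        nall[k] = 2.0 * obs[rows].sum(0)
        with np.errstate(invalid="ignore"):
            p[k] = np.where(nall[k] > 0, Gf[rows].sum(0) / np.maximum(nall[k], 1), np.nan)
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            ok = (nall[a] > 2) & (nall[b] > 2) & ~np.isnan(p[a]) & ~np.isnan(p[b])
            pa, pb = p[a, ok], p[b, ok]
            na, nb = nall[a, ok], nall[b, ok]
            num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
            den = pa * (1 - pb) + pb * (1 - pa)
            den_sum = den.sum()
            if den_sum <= 0:
                raise DataError(
                    f"Fst undefined for monomorphic pair "
                    f"({panel.populations[a]}, {panel.populations[b]})"
                )
            out[a, b] = out[b, a] = num.sum() / den_sum
    return out


def distance_variance_test(
    D: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation pseudo-F test of a grouping on a distance matrix.

    Returns (R2, p): R2 = 1 - SS_within/SS_total computed from squared
    distances, and p the one-sided permutation p-value of the pseudo-F
    statistic under label shuffling, p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    labels = list(labels)
    if len(labels) != len(D.samples):
        raise DataError("one label per sample required")
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    n = len(labels)
    k = len(groups)
    D2 = D.D ** 2
    sst = D2[np.triu_indices(n, 1)].sum() / n
    lab_idx = np.array([groups.index(l) for l in labels])

    def ssw(perm_idx: np.ndarray) -> float:
        total = 0.0
        for g in range(k):
            rows = np.flatnonzero(perm_idx == g)
            if rows.size < 1:
                continue
            sub = D2[np.ix_(rows, rows)]
            total += sub[np.triu_indices(rows.size, 1)].sum() / rows.size
        return total

    def pseudo_f(perm_idx: np.ndarray) -> float:
        w = ssw(perm_idx)
        b = sst - w
        return (b / (k - 1)) / (w / (n - k)) if w > 0 else np.inf

    f_obs = pseudo_f(lab_idx)
    r2 = 1.0 - ssw(lab_idx) / sst
    rng = np.random.default_rng(seed)
    count = sum(
        1 for _ in range(n_perm) if pseudo_f(rng.permutation(lab_idx)) >= f_obs
    )
    p = (1 + count) / (n_perm + 1)
    return float(r2), float(p)


def leave_one_out(
    panel: ReferencePanel, opts: FitOptions | None = None
) -> AdmixtureEstimate:
    """Re-estimate each panel member's ancestry with that member held out.

    Frequencies for each fit are the held-out panel's per-population
    count frequencies (+0.5 pseudocount); the held-out individual is
    scored against them as a supervised target.  Requires >= 2 members
    per population.
    """
    opts = opts or FitOptions()
    lab = panel.label_indices()
    counts = np.bincount(lab, minlength=panel.K)
    for k, c in enumerate(counts):
        if c < 2:
            raise DataError(
                f"population {panel.populations[k]!r} has a single member; "
                "cannot hold it out"
            )
    G = panel.genotypes.G
    obs = G != MISSING
    Gf = np.where(obs, G, 0).astype(float)
    K, J = panel.K, panel.genotypes.J
    alt = np.zeros((K, J))
    tot = np.zeros((K, J))
    for k in range(K):
        rows = lab == k
        alt[k] = Gf[rows].sum(0)
        tot[k] = 2.0 * obs[rows].sum(0)
    Q = np.zeros((panel.genotypes.n, K))
    lls = 0.0
    for i in range(panel.genotypes.n):
        k = lab[i]
        alt_i, tot_i = alt.copy(), tot.copy()
        alt_i[k] -= Gf[i]
        tot_i[k] -= 2.0 * obs[i]
        F = (alt_i + 0.5) / (tot_i + 1.0)
        freqs = AlleleFreqMatrix(list(panel.populations), F)
        one = panel.genotypes.take_samples([i])
        est = fit_with_frequencies(one, freqs, opts)
        Q[i] = est.Q[0]
        lls += est.loglik
    return AdmixtureEstimate(
        list(panel.genotypes.samples), list(panel.populations), Q, lls,
        n_iter=0, converged=True,
    )


def se_vs_marker_count(
    panel: ReferencePanel,
    targets: GenotypeMatrix,
    marker_counts: Sequence[int],
    opts: FitOptions | None = None,
    n_reps: int = 200,
    block_len: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean bootstrap SE per population at each marker subsample size.

    For each count, markers are subsampled without replacement (seeded)
    and the bootstrap is re-run; rows are counts, columns populations.
    ``count == J`` uses all markers.
    """
    J = panel.genotypes.J
    rng = np.random.default_rng(seed)
    rows = []
    for count in marker_counts:
        if count > J:
            raise ParameterError(f"marker count {count} exceeds J={J}")
        idx = np.sort(rng.choice(J, size=count, replace=False))
        sub_panel = ReferencePanel(
            panel.genotypes.take_variants(idx), list(panel.labels), list(panel.populations)
        )
        sub_targets = targets.take_variants(idx)
        boot = bootstrap_se(
            sub_panel, sub_targets, opts, n_reps=n_reps, block_len=block_len,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(boot.SE.mean(axis=0))
    return pd.DataFrame(rows, index=list(marker_counts), columns=list(panel.populations))


def trio_deviation(
    q_child: np.ndarray, q_father: np.ndarray, q_mother: np.ndarray
) -> np.ndarray:
    """|q_child - (q_father + q_mother) / 2| per population.

    Under Mendelian transmission a child's admixture proportions equal
    the parental average in expectation; the deviation reflects
    estimation error.
    """
    q_child, q_father, q_mother = (
        np.asarray(x, dtype=float) for x in (q_child, q_father, q_mother)
    )
    if not (q_child.shape == q_father.shape == q_mother.shape):
        raise ParameterError("trio vectors must have equal length")
    return np.abs(q_child - (q_father + q_mother) / 2.0)
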