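"""Maximum-likelihood admixture estimation by EM.

Model
-----
For individual i with ancestry proportions q_i on the K-simplex, and
population alt-allele frequencies f_kj, the genotype at unlinked SNP j
is Binomial(2, p_ij) with p_ij = sum_k q_ik f_kj.  Dropping the binomial
constant, the log-likelihood over observed genotypes is

    L = sum_{ij} [ g_ij ln p_ij + (2 - g_ij) ln (1 - p_ij) ].

The EM updates (the same block updates used by the classic model-based
clustering programs, without quasi-Newton acceleration) are

    q'_ik = q_ik / (2 J_i) * sum_j [ g_ij f_kj / p_ij
                                     + (2 - g_ij)(1 - f_kj) / (1 - p_ij) ]
    f'_kj = A_kj / (A_kj + B_kj),
      A_kj = sum_i g_ij q_ik f_kj / p_ij,
      B_kj = sum_i (2 - g_ij) q_ik (1 - f_kj) / (1 - p_ij),

with J_i the number of observed SNPs for individual i; missing
genotypes contribute nothing to either sum.  Both updates are computed
from the same (Q, F), so each iteration is a genuine EM step and the
log-likelihood never decreases.

Supervised estimation fixes reference individuals' q rows at the
indicator vector of their documented population and iterates target
rows and (by default) F jointly to convergence.  A ``fixed_F`` mode
instead freezes F at reference-panel count frequencies (with a +0.5
pseudocount) and estimates only the target rows, which decouples the
fit across targets.

Frequencies are clamped to [EPS, 1 - EPS] to guard the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .io import MISSING, GenotypeMatrix, ReferencePanel

EPS = 1e-6
SIMPLEX_TOL = 1e-9


@dataclass
class AlleleFreqMatrix:
    """K populations x J variants of alt-allele frequencies, clamped to (0, 1)."""

    populations: list[str]
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.clip(np.asarray(self.F, dtype=float), EPS, 1.0 - EPS)
        if self.F.shape[0] != len(self.populations):
            raise DataError("one frequency row per population required")

    @property
    def K(self) -> int:
        return len(self.populations)

    @property
    def J(self) -> int:
        return self.F.shape[1]


@dataclass
class AdmixtureEstimate:
    """Per-sample ancestry proportions plus the fit's convergence record."""

    samples: list[str]
    populations: list[str]
    Q: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (len(self.samples), len(self.populations)):
            raise DataError("Q shape does not match samples x populations")
        if (self.Q < -SIMPLEX_TOL).any():
            raise DataError("admixture proportions must be non-negative")
        if np.abs(self.Q.sum(axis=1) - 1.0).max() > 1e-6:
            raise DataError("admixture proportions must sum to 1 per sample")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.Q, index=self.samples, columns=self.populations)


@dataclass
class FitOptions:
    """EM control knobs.

    ``tol`` is the absolute log-likelihood change below which iteration
    stops; ``None`` scales it as 1e-8 per observed genotype (floored at
    1e-8), so convergence stringency tracks problem size without
    becoming loose enough to leave near-boundary components undrained.
    """

    tol: float | None = None
    max_iter: int = 2000
    seed: int = 0
    fixed_F: bool = False
    accelerate: bool = True

    def __post_init__(self) -> None:
        if self.tol is not None and self.tol <= 0:
            raise ParameterError("tol must be positive")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")

    def resolve_tol(self, n_observed: int) -> float:
        if self.tol is not None:
            return self.tol
        return max(1e-8 * n_observed, 1e-8)


# ---------------------------------------------------------------------------
# dense internals: Garr float64 with NaN for missing is avoided; instead we
# carry (Gm, Hm) = (g, 2-g) with missing entries zeroed, which makes missing
# genotypes contribute exactly nothing to every sum.
# ---------------------------------------------------------------------------

def _split_observed(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    obs = G != MISSING
    Gf = np.where(obs, G, 0).astype(float)
    return Gf, np.where(obs, 2.0 - Gf, 0.0), obs


def _loglik_arrays(Gm: np.ndarray, Hm: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    P = Q @ F
    np.clip(P, EPS, 1.0 - EPS, out=P)
    return float(np.sum(Gm * np.log(P)) + np.sum(Hm * np.log1p(-P)))


def loglikelihood(G: GenotypeMatrix, Q: np.ndarray, F: AlleleFreqMatrix) -> float:
    """Binomial admixture log-likelihood (binomial constant omitted)."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (G.n, F.K):
        raise DataError(
            f"Q shape {Q.shape} does not match {G.n} samples x {F.K} populations"
        )
    if F.J != G.J:
        raise DataError(f"F has {F.J} variants, genotypes have {G.J}")
    Gm, Hm, _ = _split_observed(G.G)
    return _loglik_arrays(Gm, Hm, Q, F.F)


def em_step(
    G: GenotypeMatrix,
    Q: np.ndarray,
    F: AlleleFreqMatrix,
    fixed_q_rows: np.ndarray | list[int] = (),
    fixed_F: bool = False,
) -> tuple[np.ndarray, AlleleFreqMatrix]:
    """One EM iteration; returns (Q', F') without mutating the inputs."""
    Gm, Hm, obs = _split_observed(G.G)
    Qn, Fn = _em_update(Gm, Hm, obs.sum(1), np.asarray(Q, float), F.F,
                        np.asarray(fixed_q_rows, dtype=int), not fixed_F)
    return Qn, AlleleFreqMatrix(F.populations, Fn)


def _em_update(
    Gm: np.ndarray,
    Hm: np.ndarray,
    J_obs: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    fixed_rows: np.ndarray,
    update_F: bool,
) -> tuple[np.ndarray, np.ndarray]:
    P = Q @ F
    np.clip(P, EPS, 1.0 - EPS, out=P)
    R = Gm / P
    S = Hm / (1.0 - P)
    Qn = Q * (R @ F.T + S @ (1.0 - F.T))
    Qn /= np.maximum(2.0 * J_obs, 1.0)[:, None]
    Qn /= Qn.sum(axis=1, keepdims=True)  # guard float drift on the simplex
    if len(fixed_rows):
        Qn[fixed_rows] = Q[fixed_rows]
    if update_F:
        A = F * (Q.T @ R)
        B = (1.0 - F) * (Q.T @ S)
        Fn = np.clip(A / np.maximum(A + B, 1e-300), EPS, 1.0 - EPS)
    else:
        Fn = F
    return Qn, Fn


try:  # fused single-pass kernel; the numpy path below is the reference
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _em_sums(G, Q, F):  # pragma: no cover - exercised via _em_step_ll
        n, J = G.shape
        K = Q.shape[1]
        Qnum = np.zeros((n, K))
        A = np.zeros((K, J))
        B = np.zeros((K, J))
        Jobs = np.zeros(n)
        ll = 0.0
        lo = EPS
        hi = 1.0 - EPS
        for i in range(n):
            for j in range(J):
                g = G[i, j]
                if g < 0:
                    continue
                p = 0.0
                for k in range(K):
                    p += Q[i, k] * F[k, j]
                if p < lo:
                    p = lo
                elif p > hi:
                    p = hi
                gg = float(g)
                hh = 2.0 - gg
                ll += gg * np.log(p) + hh * np.log(1.0 - p)
                r = gg / p
                s = hh / (1.0 - p)
                for k in range(K):
                    fk = F[k, j]
                    q = Q[i, k]
                    Qnum[i, k] += q * (r * fk + s * (1.0 - fk))
                    A[k, j] += q * r * fk
                    B[k, j] += q * s * (1.0 - fk)
                Jobs[i] += 1.0
        return Qnum, A, B, Jobs, ll

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _em_step_ll(
    G: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    fixed_rows: np.ndarray,
    update_F: bool,
    ref_alt: np.ndarray | None = None,
    ref_other: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One EM step plus the log-likelihood *at the input* (Q, F).

    ``ref_alt``/``ref_other`` are optional K x J alt- and
    reference-allele count matrices of fixed-membership reference
    individuals.  Because a reference individual of population k has
    p_ij = f_kj exactly, its EM contribution to the frequency update
    reduces to its constant allele counts, and its log-likelihood to
    sum_j [alt ln f + other ln(1 - f)]; passing counts instead of rows
    makes the joint supervised fit cost scale with the targets only.
    """
    if _HAVE_NUMBA:
        Qnum, A, B, Jobs, ll = _em_sums(np.ascontiguousarray(G, dtype=np.int16),
                                        Q, np.ascontiguousarray(F))
        Qn = Qnum / np.maximum(2.0 * Jobs, 1.0)[:, None]  # q_ik folded in by the kernel
        rowsum = Qn.sum(axis=1, keepdims=True)
        Qn = np.where(rowsum > 0, Qn / np.maximum(rowsum, 1e-300), Q)
        if len(fixed_rows):
            Qn[fixed_rows] = Q[fixed_rows]
    else:
        Gm, Hm, obs = _split_observed(G)
        ll = _loglik_arrays(Gm, Hm, Q, F)
        P = Q @ F
        np.clip(P, EPS, 1.0 - EPS, out=P)
        R = Gm / P
        S = Hm / (1.0 - P)
        Qn = Q * (R @ F.T + S @ (1.0 - F.T))
        Qn /= np.maximum(2.0 * obs.sum(1), 1.0)[:, None]
        Qn /= Qn.sum(axis=1, keepdims=True)
        if len(fixed_rows):
            Qn[fixed_rows] = Q[fixed_rows]
        A = F * (Q.T @ R)
        B = (1.0 - F) * (Q.T @ S)
    if ref_alt is not None:
        ll += float(np.sum(ref_alt * np.log(F)) + np.sum(ref_other * np.log1p(-F)))
    if update_F:
        num = A if ref_alt is None else A + ref_alt
        den = A + B if ref_alt is None else A + B + ref_alt + ref_other
        Fn = np.clip(num / np.maximum(den, 1e-300), EPS, 1.0 - EPS)
    else:
        Fn = F
    return Qn, Fn, ll


def _project(Q: np.ndarray, F: np.ndarray, fixed_rows: np.ndarray,
             Q_ref: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    # floor at a small positive value, NOT zero: the multiplicative EM update
    # can never regrow an exactly-zero proportion, so a zero introduced by an
    # extrapolation overshoot would be absorbing and bias the fit
    Q = np.clip(Q, 1e-9, None)
    Q /= Q.sum(axis=1, keepdims=True)
    if len(fixed_rows) and Q_ref is not None:
        Q[fixed_rows] = Q_ref
    return Q, np.clip(F, EPS, 1.0 - EPS)


def _run_em(
    Garr: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    fixed_rows: np.ndarray,
    update_F: bool,
    opts: FitOptions,
    ref_alt: np.ndarray | None = None,
    ref_other: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Iterate EM to convergence; ``it`` counts EM-equivalent steps.

    With ``opts.accelerate`` a SQUAREM extrapolation is wrapped around
    pairs of plain EM steps; the extrapolated point (after one
    stabilizing EM step) is accepted only when it does not decrease the
    log-likelihood, so the iteration stays exactly monotone.
    """
    Garr = np.ascontiguousarray(Garr, dtype=np.int16)
    # tol scales with the genotypes the iteration actually moves on; the
    # reference count term is a constant-structure offset and would only
    # loosen the stopping rule if counted
    tol = opts.resolve_tol(int((Garr != MISSING).sum()))
    converged = False
    it = 0
    Q_ref = Q[fixed_rows].copy() if len(fixed_rows) else None

    def step(Q, F):
        return _em_step_ll(Garr, Q, F, fixed_rows, update_F, ref_alt, ref_other)

    def final_ll(Q, F):
        Gm, Hm, _ = _split_observed(Garr)
        ll = _loglik_arrays(Gm, Hm, Q, F)
        if ref_alt is not None:
            ll += float(np.sum(ref_alt * np.log(F)) + np.sum(ref_other * np.log1p(-F)))
        return ll

    if not opts.accelerate:
        ll_prev = -np.inf
        while it < opts.max_iter:
            Q, F, ll_in = step(Q, F)  # ll_in is the loglik at the pre-step point
            it += 1
            if abs(ll_in - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll_in
        return Q, F, final_ll(Q, F), it, converged

    # SQUAREM-style extrapolation around pairs of EM steps.  Each kernel call
    # returns the log-likelihood at its input point, so monotonicity can be
    # guarded without extra likelihood passes: the extrapolated point is kept
    # only if its own likelihood has not dropped below the pre-extrapolation
    # one (EM's ascent property then covers the stabilization step).
    ll0 = None
    while it < opts.max_iter:
        Q1, F1, ll_at_Q = step(Q, F)
        Q2, F2, ll_at_Q1 = step(Q1, F1)
        it += 2
        if ll0 is not None and abs(ll_at_Q - ll0) < tol:
            Q, F = Q1, F1
            converged = True
            break
        if abs(ll_at_Q1 - ll_at_Q) < tol:
            Q, F = Q2, F2
            converged = True
            break
        rQ, rF = Q1 - Q, F1 - F
        vQ, vF = (Q2 - Q1) - rQ, (F2 - F1) - rF
        vnorm2 = float((vQ * vQ).sum() + ((vF * vF).sum() if update_F else 0.0))
        rnorm2 = float((rQ * rQ).sum() + ((rF * rF).sum() if update_F else 0.0))
        if vnorm2 <= 1e-300:
            Q, F, ll0 = Q2, F2, ll_at_Q1
            continue
        alpha = -min(max(np.sqrt(rnorm2 / vnorm2), 1.0), 64.0)
        Qp = Q - 2.0 * alpha * rQ + alpha * alpha * vQ
        Fp = F - 2.0 * alpha * rF + alpha * alpha * vF if update_F else F
        Qp, Fp = _project(Qp, Fp, fixed_rows, Q_ref)
        Qn, Fn, ll_at_Qp = step(Qp, Fp)
        it += 1
        if np.isfinite(ll_at_Qp) and ll_at_Qp >= ll_at_Q1:
            Q, F, ll0 = Qn, Fn, None  # accepted; ll at Qn arrives next cycle
        else:
            Q, F, ll0 = Q2, F2, ll_at_Q1  # safeguard: keep the double EM step
    return Q, F, final_ll(Q, F), it, converged


def panel_allele_counts(panel: ReferencePanel) -> tuple[np.ndarray, np.ndarray]:
    """K x J matrices of (alt-allele count, total observed alleles) per population."""
    lab = panel.label_indices()
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
    return alt, tot


def _panel_frequencies_from_counts(
    alt: np.ndarray, tot: np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    return np.clip((alt + pseudocount) / (tot + 2.0 * pseudocount), EPS, 1.0 - EPS)


def _panel_frequencies(panel: ReferencePanel, pseudocount: float = 0.5) -> np.ndarray:
    """Per-population alt-allele count frequencies with a +pseudocount prior."""
    alt, tot = panel_allele_counts(panel)
    return _panel_frequencies_from_counts(alt, tot, pseudocount)


def _check_variants_match(a: GenotypeMatrix, b: GenotypeMatrix) -> None:
    if len(a.variants) != len(b.variants) or any(
        (u.chrom, u.pos, u.ref, u.alt) != (v.chrom, v.pos, v.ref, v.alt)
        for u, v in zip(a.variants, b.variants)
    ):
        raise DataError(
            "reference panel and targets must share an identical, allele-aligned "
            "variant list (use merge_intersect first)"
        )


def fit_supervised(
    panel: ReferencePanel,
    targets: GenotypeMatrix,
    opts: FitOptions | None = None,
    init_Q: np.ndarray | None = None,
    init_F: np.ndarray | None = None,
    _ref_counts: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[AdmixtureEstimate, AlleleFreqMatrix]:
    """Supervised admixture fit of ``targets`` against a labeled panel.

    Reference individuals' proportions are fixed at the indicator vector
    of their documented population; target rows (and, unless
    ``opts.fixed_F``, the allele frequencies, estimated jointly over
    panel + targets) are iterated to convergence.  Returns the target
    rows only, plus the fitted frequencies.

    Because reference memberships are fixed, the joint fit is computed
    exactly as an EM over the targets with the panel folded in as
    per-population allele-count matrices (see ``_em_step_ll``); the cost
    per iteration therefore scales with the number of targets, not the
    panel size.

    ``init_Q``/``init_F`` warm-start the target rows and frequencies
    (used by the bootstrap); the default start is the uniform simplex
    point and panel count frequencies.  ``_ref_counts`` lets callers that
    resample markers pass pre-sliced panel count matrices directly, in
    which case the panel genotypes are not touched and the variant-list
    check is the caller's responsibility.
    """
    opts = opts or FitOptions()
    if panel.K == 0:
        raise DataError("reference panel has no populations")
    if _ref_counts is None:
        _check_variants_match(panel.genotypes, targets)
        alt, tot = panel_allele_counts(panel)
    else:
        alt, tot = _ref_counts
    K = panel.K
    n_tgt = targets.n
    F0 = (
        _panel_frequencies_from_counts(alt, tot)
        if init_F is None
        else np.clip(init_F, EPS, 1 - EPS)
    )
    Q_tgt = np.full((n_tgt, K), 1.0 / K) if init_Q is None else np.array(init_Q, float)
    no_fixed = np.array([], dtype=int)

    if opts.fixed_F:
        # decoupled per-target problem against panel count frequencies
        Q, F, ll, it, conv = _run_em(
            targets.G, Q_tgt, F0, no_fixed, update_F=False, opts=opts
        )
    else:
        Q, F, ll_all, it, conv = _run_em(
            targets.G, Q_tgt, F0, no_fixed, update_F=True, opts=opts,
            ref_alt=alt, ref_other=tot - alt,
        )
        Gm, Hm, _ = _split_observed(targets.G)
        ll = _loglik_arrays(Gm, Hm, Q, F)
    freqs = AlleleFreqMatrix(list(panel.populations), F)
    est = AdmixtureEstimate(list(targets.samples), list(panel.populations),
                            Q, ll, it, conv)
    return est, freqs


def fit_with_frequencies(
    targets: GenotypeMatrix,
    freqs: AlleleFreqMatrix,
    opts: FitOptions | None = None,
    init_Q: np.ndarray | None = None,
) -> AdmixtureEstimate:
    """Supervised fit against known population frequencies (F held fixed).

    The problem decouples across targets; this is the estimator used by
    the fast leave-one-out path and by known-frequency oracles.
    """
    opts = opts or FitOptions()
    if freqs.J != targets.J:
        raise DataError(f"F has {freqs.J} variants, targets have {targets.J}")
    K = freqs.K
    Q0 = np.full((targets.n, K), 1.0 / K) if init_Q is None else np.array(init_Q, float)
    Q, _, ll, it, conv = _run_em(
        targets.G, Q0, freqs.F.copy(), np.array([], dtype=int), update_F=False, opts=opts
    )
    return AdmixtureEstimate(list(targets.samples), list(freqs.populations),
                             Q, ll, it, conv)


def fit_unsupervised(
    G: GenotypeMatrix, K: int, opts: FitOptions | None = None
) -> tuple[AdmixtureEstimate, AlleleFreqMatrix]:
    """Unsupervised K-cluster admixture fit (no fixed rows).

    Q rows are initialized from seeded flat-Dirichlet draws and F from
    pooled frequencies perturbed with seeded noise; cluster identity is
    therefore arbitrary up to label permutation, as usual.
    """
    opts = opts or FitOptions()
    if K < 1:
        raise ParameterError("K must be >= 1")
    if G.n < K:
        raise DataError(f"need at least K={K} samples, got {G.n}")
    rng = np.random.default_rng(opts.seed)
    Q0 = rng.dirichlet(np.ones(K), size=G.n)
    pooled = np.nan_to_num(G.allele_freq(), nan=0.5)
    F0 = np.clip(
        pooled[None, :] + rng.normal(0.0, 0.05, size=(K, G.J)), EPS, 1.0 - EPS
    )
    Q, F, ll, it, conv = _run_em(
        G.G, Q0, F0, np.array([], dtype=int), update_F=True, opts=opts
    )
    pops = [f"Cluster{k + 1}" for k in range(K)]
    return (
        AdmixtureEstimate(list(G.samples), pops, Q, ll, it, conv),
        AlleleFreqMatrix(pops, F),
    )


# ---------------------------------------------------------------------------
# TSV output mirroring the .Q / .P layouts
# ---------------------------------------------------------------------------

def write_q_matrix(est: AdmixtureEstimate, path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("sample\t" + "\t".join(est.populations) + "\n")
        for s, row in zip(est.samples, est.Q):
            fh.write(s + "\t" + "\t".join(f"{q:.6f}" for q in row) + "\n")


def write_freq_matrix(freqs: AlleleFreqMatrix, path, header: bool = True) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(freqs.populations) + "\n")
        for j in range(freqs.J):
            fh.write("\t".join(f"{f:.6f}" for f in freqs.F[:, j]) + "\n")
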