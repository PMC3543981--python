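"""Marker and sample quality control.

The canonical filter order, applied by :func:`apply_qc`, is:

1. per-SNP missingness (< ``max_snp_missing`` retained),
2. per-individual missingness (< ``max_ind_missing`` retained, computed
   on the SNPs surviving step 1),
3. minor allele frequency (> ``min_maf`` retained, pooled over samples),
4. greedy windowed LD pruning at squared Pearson correlation
   ``ld_r2``.

All filters are deterministic and idempotent.  ``ld_pair_fraction``
reports the fraction of marker pairs below an r² threshold — the
property a low-LD panel is expected to satisfy for ~99% of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import GenotypeMatrix


@dataclass
class QCThresholds:
    min_maf: float = 0.01
    max_snp_missing: float = 0.05
    max_ind_missing: float = 0.01
    ld_r2: float = 0.1
    ld_window: int = 50

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_snp_missing", "max_ind_missing", "ld_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.min_maf > 0.5:
            raise ParameterError("min_maf must lie in [0, 0.5]")
        if self.ld_window < 2:
            raise ParameterError("ld_window must be >= 2")


def filter_maf(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain SNPs with minor allele frequency strictly above ``min_maf``."""
    if not 0.0 <= min_maf <= 0.5:
        raise ParameterError(f"min_maf must lie in [0, 0.5], got {min_maf}")
    freq = G.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=0.0) > min_maf)
    return G.take_variants(keep)


def filter_missingness(
    G: GenotypeMatrix, max_snp_missing: float, max_ind_missing: float
) -> GenotypeMatrix:
    """Drop high-missingness SNPs first, then high-missingness individuals.

    Both thresholds are strict: a SNP (individual) is retained when its
    missing fraction is < the threshold, the individual rate being
    computed on the SNPs that survived the first pass.
    """
    for name, v in (("max_snp_missing", max_snp_missing), ("max_ind_missing", max_ind_missing)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {v}")
    G = G.take_variants(np.flatnonzero(G.snp_missing_rate() < max_snp_missing))
    return G.take_samples(np.flatnonzero(G.sample_missing_rate() < max_ind_missing))


def _imputed_columns(G: GenotypeMatrix) -> np.ndarray:
    """Genotypes as float with missing entries replaced by the column mean."""
    X = G.G.astype(float)
    obs = G.observed_mask()
    with np.errstate(invalid="ignore"):
        col_mean = np.where(obs, X, 0.0).sum(0) / np.maximum(obs.sum(0), 1)
    return np.where(obs, X, col_mean[None, :])


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(G: GenotypeMatrix, r2_threshold: float, window: int) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within a sliding marker window.

    Within each chromosome, each marker is compared with the retained
    markers among the preceding ``window - 1`` positions; if any pair
    exceeds ``r2_threshold`` the later marker is removed (the earlier
    one is kept on ties).
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ParameterError(f"r2_threshold must lie in (0, 1], got {r2_threshold}")
    if window < 2:
        raise ParameterError(f"window must be >= 2, got {window}")
    X = _imputed_columns(G)
    keep: list[int] = []
    by_chrom: dict[str, list[int]] = {}
    for j, v in enumerate(G.variants):
        by_chrom.setdefault(v.chrom, []).append(j)
    for cols in by_chrom.values():
        retained: list[int] = []  # positions within this chromosome's column list
        for pos, j in enumerate(cols):
            ok = True
            for prev_pos, pj in retained:
                if pos - prev_pos < window and _r2(X[:, pj], X[:, j]) > r2_threshold:
                    ok = False
                    break
            if ok:
                retained.append((pos, j))
        keep.extend(j for _, j in retained)
    return G.take_variants(sorted(keep))


def ld_pair_fraction(
    G: GenotypeMatrix,
    r2_threshold: float,
    max_pairs: int = 200_000,
    seed: int = 0,
) -> float:
    """Fraction of SNP pairs with squared correlation strictly below threshold.

    When the number of pairs exceeds ``max_pairs`` a seeded random
    subsample of pairs is scored instead.
    """
    if G.J < 2:
        raise ParameterError("need at least 2 SNPs")
    X = _imputed_columns(G)
    n_pairs = G.J * (G.J - 1) // 2
    if n_pairs <= max_pairs:
        pairs = [(a, b) for a in range(G.J) for b in range(a + 1, G.J)]
    else:
        rng = np.random.default_rng(seed)
        a = rng.integers(0, G.J, size=max_pairs)
        b = rng.integers(0, G.J - 1, size=max_pairs)
        b = np.where(b >= a, b + 1, b)
        pairs = list(zip(a.tolist(), b.tolist()))
    below = sum(1 for a, b in pairs if _r2(X[:, a], X[:, b]) < r2_threshold)
    return below / len(pairs)


def apply_qc(
    G: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Run the full filter cascade; return the filtered matrix and a report.

    The report is a tidy table with columns (item, kind, reason) listing
    every removed marker or sample and the filter that removed it.
    """
    t = thresholds or QCThresholds()
    rows: list[tuple[str, str, str]] = []

    step = G.take_variants(np.flatnonzero(G.snp_missing_rate() < t.max_snp_missing))
    removed = set(v.id for v in G.variants) - set(v.id for v in step.variants)
    rows += [(vid, "marker", "snp_missingness") for vid in sorted(removed)]

    step2 = step.take_samples(np.flatnonzero(step.sample_missing_rate() < t.max_ind_missing))
    rows += [
        (s, "sample", "individual_missingness")
        for s in step.samples
        if s not in set(step2.samples)
    ]

    step3 = filter_maf(step2, t.min_maf)
    removed = set(v.id for v in step2.variants) - set(v.id for v in step3.variants)
    rows += [(vid, "marker", "maf") for vid in sorted(removed)]

    step4 = ld_prune(step3, t.ld_r2, t.ld_window)
    removed = set(v.id for v in step3.variants) - set(v.id for v in step4.variants)
    rows += [(vid, "marker", "ld_prune") for vid in sorted(removed)]

    report = pd.DataFrame(rows, columns=["item", "kind", "reason"])
    return step4, report
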