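"""Bootstrap standard errors of admixture proportions.

Markers are resampled with replacement in contiguous blocks (a
moving-block bootstrap over the marker order within each chromosome) to
the original marker count, the supervised fit is re-run per replicate,
and SE_ik is the across-replicate sample standard deviation of each
proportion.  Because panel markers are LD-pruned the default block
length is 1 (ordinary marker resampling); longer blocks preserve
residual local dependence on linked data.

Replicate fits warm-start from the point estimate, which shortens EM
convergence without changing the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admixture_core import (
    AdmixtureEstimate,
    AlleleFreqMatrix,
    FitOptions,
    fit_supervised,
    panel_allele_counts,
)
from .errors import ParameterError
from .io import GenotypeMatrix, ReferencePanel


@dataclass
class BootstrapResult:
    SE: np.ndarray
    n_reps: int
    block_len: int
    seed: int

    def __post_init__(self) -> None:
        self.SE = np.asarray(self.SE, dtype=float)
        if (self.SE < 0).any():
            raise ParameterError("standard errors must be non-negative")


def block_resample_indices(
    chroms: list[str], block_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Moving-block resample of marker indices, per chromosome, to length J.

    Within each chromosome of Jc markers, blocks of ``block_len``
    consecutive markers (all Jc - block_len + 1 start positions) are
    drawn with replacement and concatenated, then trimmed to Jc.
    """
    J = len(chroms)
    if block_len < 1:
        raise ParameterError("block_len must be >= 1")
    if block_len >= J:
        raise ParameterError(
            f"block_len {block_len} must be smaller than the marker count {J}"
        )
    out: list[np.ndarray] = []
    start = 0
    order = {}
    groups: list[tuple[int, int]] = []  # (start, length) runs of equal chromosome
    for j, c in enumerate(chroms):
        if j == 0 or c != chroms[j - 1]:
            groups.append((j, 1))
        else:
            s, ln = groups[-1]
            groups[-1] = (s, ln + 1)
    for s, Jc in groups:
        if block_len > Jc:
            raise ParameterError(
                f"block_len {block_len} exceeds chromosome size {Jc}"
            )
        n_blocks = -(-Jc // block_len)
        starts = rng.integers(0, Jc - block_len + 1, size=n_blocks)
        idx = (starts[:, None] + np.arange(block_len)[None, :]).ravel()[:Jc]
        out.append(idx + s)
    return np.concatenate(out)


def bootstrap_se(
    panel: ReferencePanel,
    targets: GenotypeMatrix,
    opts: FitOptions | None = None,
    n_reps: int = 200,
    block_len: int = 1,
    seed: int = 0,
    point: AdmixtureEstimate | None = None,
    point_freqs: AlleleFreqMatrix | None = None,
) -> BootstrapResult:
    """Block-bootstrap SEs of the supervised admixture estimates.

    ``point``/``point_freqs`` may pass in an already-computed point
    estimate to warm-start replicates; otherwise it is computed here.
    """
    if n_reps < 2:
        raise ParameterError("n_reps must be >= 2")
    opts = opts or FitOptions()
    if point is None or point_freqs is None:
        point, point_freqs = fit_supervised(panel, targets, opts)
    rng = np.random.default_rng(seed)
    chroms = [v.chrom for v in panel.genotypes.variants]
    alt, tot = panel_allele_counts(panel)
    reps = np.empty((n_reps, targets.n, panel.K))
    for b in range(n_reps):
        idx = block_resample_indices(chroms, block_len, rng)
        targets_b = targets.take_variants(idx)
        est_b, _ = fit_supervised(
            panel,
            targets_b,
            opts,
            init_Q=point.Q,
            init_F=point_freqs.F[:, idx],
            _ref_counts=(alt[:, idx], tot[:, idx]),
        )
        reps[b] = est_b.Q
    SE = reps.std(axis=0, ddof=1)
    return BootstrapResult(SE=SE, n_reps=n_reps, block_len=block_len, seed=seed)
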