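"""Second-stage denoising of admixture estimates.

For each target, a source population is retained only when its
first-pass proportion minus twice its bootstrap standard error is
strictly positive — i.e. when the lower bound of the ~95% confidence
interval excludes zero.  Populations without such evidence are removed
from the reference panel, and proportions are re-estimated over the
retained set; removed populations receive exact zeros.

If the rule would retain nothing (possible only for degenerate inputs;
large SEs on every component), the single largest first-pass component
is retained as a guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admixture_core import AdmixtureEstimate, FitOptions, fit_supervised
from .errors import DataError, ParameterError
from .io import GenotypeMatrix, ReferencePanel
from .uncertainty import BootstrapResult


@dataclass
class DenoisedEstimate:
    """Refined proportions over the full population set, with exact zeros
    on populations excluded per individual, plus the first-pass
    estimates and SEs that drove retention."""

    samples: list[str]
    populations: list[str]
    Q: np.ndarray
    retained: list[tuple[str, ...]]
    q_initial: np.ndarray
    se_initial: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if np.abs(self.Q.sum(axis=1) - 1.0).max() > 1e-6:
            raise DataError("refined proportions must sum to 1 per sample")
        for i, kept in enumerate(self.retained):
            if not kept:
                raise DataError("retained set must be non-empty")
            excluded = [
                k for k, p in enumerate(self.populations) if p not in kept
            ]
            if excluded and self.Q[i, excluded].any():
                raise DataError("excluded populations must have exactly zero weight")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.Q, index=self.samples, columns=self.populations)


def retain_populations(q: np.ndarray, se: np.ndarray) -> list[int]:
    """Indices k with q_k - 2*se_k > 0; argmax fallback if that set is empty."""
    q = np.asarray(q, dtype=float)
    se = np.asarray(se, dtype=float)
    if q.shape != se.shape:
        raise ParameterError("q and se must have equal length")
    if (se < 0).any():
        raise ParameterError("standard errors must be non-negative")
    kept = np.flatnonzero(q - 2.0 * se > 0)
    if kept.size == 0:
        return [int(np.argmax(q))]
    return kept.tolist()


def denoise_estimates(
    panel: ReferencePanel,
    targets: GenotypeMatrix,
    first_pass: AdmixtureEstimate,
    ses: BootstrapResult,
    opts: FitOptions | None = None,
    group: bool = True,
) -> DenoisedEstimate:
    """Apply the retention rule and re-fit over each retained set.

    Targets with identical retained sets are refit in one supervised run
    against the panel restricted to those populations (an exact
    equivalence under fixed F and a near-equivalence when F is
    re-estimated); ``group=False`` forces one run per individual.
    """
    if first_pass.Q.shape != ses.SE.shape:
        raise DataError("first-pass estimate and SE matrices are misaligned")
    if first_pass.populations != list(panel.populations):
        raise DataError("first-pass populations do not match the panel")
    opts = opts or FitOptions()
    pops = list(panel.populations)
    n, K = first_pass.Q.shape

    retained_sets: list[tuple[str, ...]] = []
    for i in range(n):
        kept_idx = retain_populations(first_pass.Q[i], ses.SE[i])
        retained_sets.append(tuple(pops[k] for k in kept_idx))

    Q_out = np.zeros((n, K))
    by_set: dict[tuple[str, ...], list[int]] = {}
    if group:
        for i, kept in enumerate(retained_sets):
            by_set.setdefault(kept, []).append(i)
    else:
        for i, kept in enumerate(retained_sets):
            by_set[(i,) + kept] = [i]  # unique key per individual

    for key, rows in by_set.items():
        kept = retained_sets[rows[0]]
        if set(kept) == set(pops):
            # no exclusion: the first pass already is the full-panel fit
            Q_out[rows] = first_pass.Q[rows]
            continue
        sub_panel = panel.subset_populations(kept)
        sub_targets = targets.take_samples(rows)
        est, _ = fit_supervised(sub_panel, sub_targets, opts)
        col_of = {p: k for k, p in enumerate(pops)}
        for r, row_idx in enumerate(rows):
            for p, q in zip(sub_panel.populations, est.Q[r]):
                Q_out[row_idx, col_of[p]] = q
    # exact zeros elsewhere by construction; renormalize float drift
    Q_out /= Q_out.sum(axis=1, keepdims=True)
    return DenoisedEstimate(
        samples=list(first_pass.samples),
        populations=pops,
        Q=Q_out,
        retained=retained_sets,
        q_initial=first_pass.Q.copy(),
        se_initial=ses.SE.copy(),
    )


def write_denoised(result: DenoisedEstimate, path) -> None:
    """TSV: sample, K refined proportions, K first-pass SEs, retained set."""
    with open(path, "w") as fh:
        cols = (
            ["sample"]
            + result.populations
            + [f"se_{p}" for p in result.populations]
            + ["retained"]
        )
        fh.write("\t".join(cols) + "\n")
        for i, s in enumerate(result.samples):
            fields = (
                [s]
                + [f"{q:.6f}" for q in result.Q[i]]
                + [f"{se:.6f}" for se in result.se_initial[i]]
                + [",".join(result.retained[i])]
            )
            fh.write("\t".join(fields) + "\n")
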