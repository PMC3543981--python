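"""High-level workflows: the two-step estimation procedure and the
synthetic continental study it is validated on.

``two_step_estimate`` chains the supervised fit, the block-bootstrap
standard errors and the denoising pass — the complete procedure a user
runs on a cohort of unknown-ancestry individuals.

``continental_study`` builds the synthetic analogue of a continental
reference panel (six populations at the default drift ladder, with the
per-population sizes of a realistic public-data panel) plus admixed
target cohorts, and scores the two-step procedure against the known
truth.  This is the package's quantitative validation surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admixture_core import (
    EPS,
    AdmixtureEstimate,
    AlleleFreqMatrix,
    FitOptions,
    fit_supervised,
    panel_allele_counts,
)
from .denoise import DenoisedEstimate, denoise_estimates
from .io import GenotypeMatrix, ReferencePanel
from .simulate import (
    DEFAULT_J,
    SimulationSpec,
    simulate_admixed_targets,
    simulate_frequencies,
    simulate_reference_panel,
)
from .uncertainty import BootstrapResult, bootstrap_se

# per-population reference sizes of a realistic public-data continental
# panel (individuals with documented, unadmixed ancestry)
CONTINENTAL_PANEL_SIZES = {
    "Europe": 1335,
    "Africa": 366,
    "America": 47,
    "EastAsia": 453,
    "Oceania": 16,
    "CentralAsia": 296,
}


@dataclass
class TwoStepResult:
    first_pass: AdmixtureEstimate
    freqs: AlleleFreqMatrix
    bootstrap: BootstrapResult
    denoised: DenoisedEstimate


def two_step_estimate(
    panel: ReferencePanel,
    targets: GenotypeMatrix,
    opts: FitOptions | None = None,
    n_reps: int = 200,
    block_len: int = 1,
    seed: int = 0,
) -> TwoStepResult:
    """Supervised fit + bootstrap SEs + denoising, in one call."""
    opts = opts or FitOptions(seed=seed)
    est, freqs = fit_supervised(panel, targets, opts)
    boot = bootstrap_se(
        panel, targets, opts, n_reps=n_reps, block_len=block_len, seed=seed,
        point=est, point_freqs=freqs,
    )
    den = denoise_estimates(panel, targets, est, boot, opts)
    return TwoStepResult(est, freqs, boot, den)


@dataclass
class StudyResult:
    spec: SimulationSpec
    panel: ReferencePanel
    targets: GenotypeMatrix
    q_true: np.ndarray
    result: TwoStepResult

    def mean_estimates(self) -> dict[str, float]:
        """Mean denoised proportion per population across targets."""
        means = self.result.denoised.Q.mean(axis=0)
        return dict(zip(self.spec.populations, means.tolist()))


def continental_study(
    target_groups: list[tuple[int, dict[str, float]]],
    J: int = DEFAULT_J,
    seed: int = 0,
    n_reps: int = 40,
    panel_sizes: dict[str, int] | None = None,
) -> StudyResult:
    """Run the two-step procedure on a synthetic continental scenario.

    ``target_groups`` lists (count, {population: proportion}) admixture
    mixes; unmentioned populations contribute nothing.  The reference
    panel uses the continental composition above (at drift parameters
    fitted to observed continental pairwise Fst) unless ``panel_sizes``
    overrides it.

    Target genotypes are drawn from the *panel-estimated* allele
    frequencies, mirroring how such simulation studies are actually
    set up: source-population frequencies are taken from the reference
    panel itself, so the generative frequencies are the ones the
    estimator has access to, and target error reflects genotype
    sampling rather than panel-frequency mismatch.
    """
    sizes = panel_sizes or CONTINENTAL_PANEL_SIZES
    pops = list(sizes)
    groups = []
    for count, mix in target_groups:
        q = [float(mix.get(p, 0.0)) for p in pops]
        groups.append((count, q))
    spec = SimulationSpec(
        populations=pops,
        J=J,
        n_ref=[sizes[p] for p in pops],
        targets=groups,
        seed=seed,
    )
    F = simulate_frequencies(spec)
    panel = simulate_reference_panel(spec, F)
    alt, tot = panel_allele_counts(panel)
    F_panel = AlleleFreqMatrix(pops, np.clip(alt / np.maximum(tot, 1.0), EPS, 1 - EPS))
    targets, q_true = simulate_admixed_targets(spec, F_panel)
    result = two_step_estimate(panel, targets, n_reps=n_reps, seed=spec.seed + 3)
    return StudyResult(spec, panel, targets, q_true, result)
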