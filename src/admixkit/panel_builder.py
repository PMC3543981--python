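"""Stepwise construction of a labeled reference panel.

A panel is grown from candidate cohorts with documented (but not fully
trusted) ancestry in two kinds of stages:

* an *unsupervised seed* stage clusters well-differentiated cohorts into
  K groups, maps clusters to documented labels by optimal assignment on
  the mean-proportion matrix, and admits individuals whose proportion on
  their own mapped cluster reaches the admission threshold;
* an *anchored expansion* stage adds one new population at a time: a
  small set of anchor individuals is assigned fixed membership in the
  new population, a supervised fit scores the remaining candidates, and
  those whose proportion on the new population exceeds the threshold are
  admitted.

Admission boundaries differ on purpose: the seed stage retains at >= the
threshold, while expansion requires strictly > (both configurable).
Every candidate ends up either in the panel or in the exclusion report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .admixture_core import FitOptions, fit_supervised, fit_unsupervised
from .errors import DataError, ParameterError
from .io import GenotypeMatrix, ReferencePanel


@dataclass
class ExclusionRow:
    sample: str
    stage: str
    own_proportion: float
    reason: str


@dataclass
class ExclusionReport:
    rows: list[ExclusionRow] = field(default_factory=list)

    def extend(self, other: "ExclusionReport") -> None:
        self.rows.extend(other.rows)

    def samples(self) -> list[str]:
        return [r.sample for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample, r.stage, r.own_proportion, r.reason) for r in self.rows],
            columns=["sample", "stage", "own_proportion", "reason"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SeedStage:
    """Unsupervised seeding over the cohorts documented with ``labels``."""

    labels: list[str]
    kind: str = "unsupervised_seed"


@dataclass
class ExpansionStage:
    """Anchored admission of one new population."""

    new_population: str
    anchors: list[str]
    candidates: list[str]
    kind: str = "anchored_expansion"


@dataclass
class PanelRecipe:
    stages: list[SeedStage | ExpansionStage]
    threshold: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0 and self.threshold != 0.0:
            if not 0.0 <= self.threshold < 1.0:
                raise ParameterError("threshold must lie in [0, 1)")
        for st in self.stages:
            if isinstance(st, ExpansionStage) and not st.anchors:
                raise ParameterError(
                    f"expansion stage {st.new_population!r} needs anchors"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PanelRecipe":
        stages: list[SeedStage | ExpansionStage] = []
        for s in d["stages"]:
            if s["kind"] == "unsupervised_seed":
                stages.append(SeedStage(labels=list(s["labels"])))
            elif s["kind"] == "anchored_expansion":
                stages.append(
                    ExpansionStage(
                        new_population=s["new_population"],
                        anchors=list(s["anchors"]),
                        candidates=list(s["candidates"]),
                    )
                )
            else:
                raise ParameterError(f"unknown stage kind {s['kind']!r}")
        return cls(stages=stages, threshold=float(d.get("threshold", 0.9)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelRecipe":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def unsupervised_seed_stage(
    cohorts: GenotypeMatrix,
    labels: Sequence[str],
    K: int,
    threshold: float = 0.9,
    opts: FitOptions | None = None,
) -> tuple[ReferencePanel, ExclusionReport]:
    """Cluster cohorts into K groups and admit well-assigned individuals.

    Clusters are mapped to documented labels by maximizing the total
    own-label mean proportion over label-to-cluster permutations
    (Hungarian assignment on the K x K mean-Q matrix).  An individual is
    admitted iff its proportion on its label's mapped cluster is
    >= ``threshold``.
    """
    labels = list(labels)
    if len(labels) != cohorts.n:
        raise DataError("one documented label per sample required")
    label_names = sorted(set(labels))
    if len(label_names) != K:
        raise DataError(
            f"K={K} must equal the number of documented labels ({len(label_names)})"
        )
    est, _ = fit_unsupervised(cohorts, K, opts)
    lab_idx = np.array([label_names.index(l) for l in labels])
    meanQ = np.vstack([est.Q[lab_idx == a].mean(axis=0) for a in range(K)])
    row, col = linear_sum_assignment(-meanQ)
    mapping = dict(zip(row.tolist(), col.tolist()))  # label index -> cluster index
    # sanity: the mapped cluster must dominate its label's mean proportions,
    # otherwise the unsupervised clusters do not correspond to the cohorts
    for a in range(K):
        if meanQ[a, mapping[a]] < meanQ[a].max() - 1e-9 and meanQ[a, mapping[a]] < 0.5:
            raise DataError(
                "ambiguous cluster-to-label mapping; mean proportion matrix:\n"
                + str(np.round(meanQ, 3))
            )
    own = est.Q[np.arange(cohorts.n), np.array([mapping[a] for a in lab_idx])]
    admitted = own >= threshold
    report = ExclusionReport(
        [
            ExclusionRow(s, "unsupervised_seed", float(p), "own_cluster_below_threshold")
            for s, p, ok in zip(cohorts.samples, own, admitted)
            if not ok
        ]
    )
    idx = np.flatnonzero(admitted)
    if idx.size == 0:
        raise DataError("seed stage admitted no individuals")
    panel = ReferencePanel(
        cohorts.take_samples(idx),
        [labels[i] for i in idx],
        label_names,
    )
    return panel, report


def anchored_expansion(
    current: ReferencePanel,
    candidates: GenotypeMatrix,
    anchors: GenotypeMatrix,
    new_population: str,
    threshold: float = 0.9,
    opts: FitOptions | None = None,
) -> tuple[ReferencePanel, ExclusionReport]:
    """Add ``new_population`` anchored by a small set of fixed individuals.

    Anchors get fixed indicator ancestry on the new population; the
    remaining candidates are scored by a supervised fit against the
    current panel + anchors and admitted iff their estimated proportion
    on the new population is strictly > ``threshold``.
    """
    if new_population in current.populations:
        raise DataError(f"population {new_population!r} is already in the panel")
    anchor_panel = ReferencePanel(
        GenotypeMatrix(
            current.genotypes.samples + anchors.samples,
            current.genotypes.variants,
            np.vstack([current.genotypes.G, anchors.G]),
        ),
        current.labels + [new_population] * anchors.n,
        current.populations + [new_population],
    )
    est, _ = fit_supervised(anchor_panel, candidates, opts)
    new_col = est.populations.index(new_population)
    q_new = est.Q[:, new_col]
    admitted = q_new > threshold
    report = ExclusionReport(
        [
            ExclusionRow(s, f"expansion:{new_population}", float(p), "new_population_below_threshold")
            for s, p, ok in zip(candidates.samples, q_new, admitted)
            if not ok
        ]
    )
    idx = np.flatnonzero(admitted)
    admitted_G = candidates.take_samples(idx)
    expanded = ReferencePanel(
        GenotypeMatrix(
            anchor_panel.genotypes.samples + admitted_G.samples,
            anchor_panel.genotypes.variants,
            np.vstack([anchor_panel.genotypes.G, admitted_G.G]),
        ),
        anchor_panel.labels + [new_population] * admitted_G.n,
        anchor_panel.populations,
    )
    return expanded, report


def build_panel(
    recipe: PanelRecipe,
    data: GenotypeMatrix,
    labels: dict[str, str],
    opts: FitOptions | None = None,
) -> tuple[ReferencePanel, ExclusionReport]:
    """Run the recipe's stages in order, threading the growing panel.

    ``data`` holds all candidate individuals on a common variant list;
    ``labels`` documents their claimed ancestry.  The first stage must
    be an unsupervised seed.
    """
    report = ExclusionReport()
    panel: ReferencePanel | None = None
    sample_pos = {s: i for i, s in enumerate(data.samples)}
    for stage in recipe.stages:
        if isinstance(stage, SeedStage):
            if panel is not None:
                raise ParameterError("seed stage must come first")
            idx = [i for i, s in enumerate(data.samples) if labels[s] in set(stage.labels)]
            cohort = data.take_samples(idx)
            panel, rep = unsupervised_seed_stage(
                cohort,
                [labels[s] for s in cohort.samples],
                K=len(set(stage.labels)),
                threshold=recipe.threshold,
                opts=opts,
            )
            report.extend(rep)
        elif isinstance(stage, ExpansionStage):
            if panel is None:
                raise ParameterError("expansion stage requires a seeded panel")
            anchors = data.take_samples([sample_pos[s] for s in stage.anchors])
            cand_ids = [s for s in stage.candidates if s not in set(stage.anchors)]
            candidates = data.take_samples([sample_pos[s] for s in cand_ids])
            panel, rep = anchored_expansion(
                panel,
                candidates,
                anchors,
                stage.new_population,
                threshold=recipe.threshold,
                opts=opts,
            )
            report.extend(rep)
        else:  # pragma: no cover - recipe validation prevents this
            raise ParameterError(f"unknown stage {stage!r}")
    if panel is None:
        raise ParameterError("recipe contains no stages")
    return panel, report
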