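"""End-to-end study workflows on synthetic cohorts.

Bundles the stages into the study design the package models: a four-subtype
case series (14/5/2/7 subjects) against a large control pool, a shared
episignature carried by every subtype, subtype-specific blocks with partial
overlap, and planted multi-probe regions.  These helpers are what the
examples and the reproduction script drive; each stage remains available
individually from its own module.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import GroundTruth, MethylationCohort
from .consensus import ConsensusResult, consensus_cluster
from .discovery import build_design_matrix, discover_probes, select_signature_probes
from .preprocess import MatchedDesign, estimate_cell_composition, match_controls
from .synthetic import CellReferencePanel, CohortDesign, RegionBlock, \
    SignatureBlock, SignatureSpec, inject_signature, make_cell_reference_panel, \
    make_manifest, simulate_null_cohort

__all__ = ["StudyData", "default_signature_spec", "simulate_study",
           "run_discovery", "consensus_subtypes"]


@dataclass
class StudyData:
    """A complete simulated study: cohort with planted truth and its panel."""

    manifest: pd.DataFrame
    panel: CellReferencePanel
    cohort: MethylationCohort
    truth: GroundTruth
    design: CohortDesign

    @property
    def case_ids(self) -> list[str]:
        return list(self.cohort.samples.index[self.cohort.samples["group"] != "control"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.cohort.samples.index[self.cohort.samples["group"] == "control"])


def default_signature_spec(n_shared: int = 150, n_specific: int = 150,
                           effect_range: tuple[float, float] = (0.10, 0.20),
                           n_regions: int = 3) -> SignatureSpec:
    """The study's planted layout.

    A shared block carried by every subtype (the common episignature), a
    block shared by the two related subtypes B and D, a block specific to
    subtype A, and ``n_regions`` four-probe regions carried by all
    subtypes.  Consecutive blocks overlap by the default 15%.
    """
    blocks = [
        SignatureBlock("shared", n_shared, effect_range,
                       affected_groups=("A", "B", "C", "D")),
        SignatureBlock("BD", n_specific, effect_range, affected_groups=("B", "D")),
        SignatureBlock("A_specific", max(2, int(0.8 * n_specific)), effect_range,
                       affected_groups=("A",)),
    ]
    regions = [RegionBlock(f"region{i + 1}", n_probes=4, effect=0.15,
                           affected_groups=("A", "B", "C", "D"))
               for i in range(n_regions)]
    return SignatureSpec(blocks=blocks, region_blocks=regions)


def simulate_study(seed: int = 0, n_probes: int = 2000,
                   control_pool_size: int = 400,
                   spec: SignatureSpec | None = None,
                   noise_sd: float = 0.25) -> StudyData:
    """Simulate the full default study cohort with planted signatures."""
    manifest = make_manifest(n_probes, n_chromosomes=8, mean_spacing=1000.0,
                             seed=seed)
    panel = make_cell_reference_panel(
        manifest, n_cell_types=7,
        n_discriminating=max(50, n_probes // 20), seed=seed + 1)
    design = CohortDesign(control_pool_size=control_pool_size,
                          noise_sd=noise_sd, seed=seed + 2)
    cohort, truth = simulate_null_cohort(design, manifest, panel)
    if spec is None:
        spec = default_signature_spec()
    cohort, truth = inject_signature(cohort, truth, spec, seed=seed + 3)
    return StudyData(manifest, panel, cohort, truth, design)


def run_discovery(study: StudyData, case_groups=("A",), ratio: int = 6,
                  seed: int = 0, min_delta: float = 0.10, max_q: float = 0.05
                  ) -> tuple[MatchedDesign, pd.DataFrame, list[str]]:
    """Match controls, adjust for sex + cell composition, test every probe.

    Returns the matched design, the per-probe statistics table and the
    selected signature (q < ``max_q`` and |Δβ| > ``min_delta``).
    """
    samples = study.cohort.samples
    cases = samples[samples["group"].isin(case_groups)]
    pool = samples[samples["group"] == "control"]
    matched = match_controls(cases, pool, ratio=ratio, seed=seed)
    sub = study.cohort.subset_samples(matched.all_ids)
    cells = estimate_cell_composition(sub, study.panel)
    design = build_design_matrix(sub.samples, case_labels=case_groups,
                                 cell_proportions=cells.proportions)
    stats = discover_probes(sub, design, case_labels=case_groups)
    signature = select_signature_probes(stats, min_delta=min_delta, max_q=max_q)
    return matched, stats, signature


def consensus_subtypes(study: StudyData, probe_ids, groups=("A", "B", "D"),
                       k_range=range(2, 7), reps: int = 200,
                       seed: int = 0) -> ConsensusResult:
    """Consensus-cluster the case samples on the signature probes."""
    samples = study.cohort.samples
    case_ids = samples.index[samples["group"].isin(groups)]
    data = study.cohort.betas.loc[list(probe_ids), case_ids].T
    return consensus_cluster(data, k_range=k_range, reps=reps, seed=seed)
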