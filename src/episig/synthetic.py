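"""Synthetic methylation cohorts with known planted structure.

The generator emulates the data structure of a blood-based episignature
study: case subtypes of very different sizes against a large control pool,
bimodal beta baselines driven by CpG-island context, betas formed as blood
cell-type mixtures, age/sex/batch covariate effects, and planted probe
signatures (shared and subtype-specific, with partial overlap) plus planted
multi-probe regions.  Every cohort is returned together with a
:class:`~episig.cohort.GroundTruth` so downstream stages can be validated
without any external data.

Conventions: mixtures are formed on the beta scale (proportion-weighted
reference betas); covariate effects and noise are then added on the logit
scale, which keeps betas bounded while making effects additive for the
regression model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import GroundTruth, MethylationCohort

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")

__all__ = [
    "CellReferencePanel", "CohortDesign", "SignatureBlock", "RegionBlock",
    "SignatureSpec", "make_manifest", "make_cell_reference_panel",
    "simulate_null_cohort", "inject_signature",
]


@dataclass
class CellReferencePanel:
    """Reference beta profiles of purified blood cell populations.

    ``reference_betas`` is probe × cell-type, every entry in [0, 1].  The
    default study design uses seven populations, mirroring deconvolution
    panels built from seven isolated leukocyte fractions.
    """

    cell_types: list[str]
    reference_betas: pd.DataFrame
    discriminating_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ValueError("a reference panel needs at least 2 cell types")
        vals = self.reference_betas.to_numpy()
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("reference betas must lie in [0, 1]")


@dataclass
class CohortDesign:
    """Sizes, covariates and noise of a simulated study cohort.

    Defaults mirror the modelled study: four case groups of 14/5/2/7
    subjects against a large control pool, two array platforms, and
    group-specific age distributions.  ``noise_sd`` is the per-probe
    Gaussian noise on the logit (natural-log odds) scale.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"A": 14, "B": 5, "C": 2, "D": 7})
    control_pool_size: int = 400
    age_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (11.0, 8.0), "B": (12.0, 9.0),
                                 "C": (10.0, 6.0), "D": (13.0, 9.0),
                                 "control": (12.0, 8.0)})
    sex_ratio: float = 0.5
    n_batches: int = 3
    array_types: tuple[str, ...] = ("450k", "EPIC")
    cell_dirichlet: dict[str, np.ndarray] | None = None
    noise_sd: float = 0.25
    noise_dispersion: float = 0.5       # sd of per-probe log noise-scale
    beta_noise_sd: float = 0.015        # technical noise on the beta scale
    age_slope_sd: float = 0.002
    sex_effect_sd: float = 0.05
    batch_effect_sd: float = 0.05
    covariate_affected_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()) or self.control_pool_size < 0:
            raise ValueError("group sizes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SignatureBlock:
    """One planted probe set: which groups carry it and how strongly."""

    label: str
    n_probes: int
    effect_size_range: tuple[float, float] = (0.05, 0.20)
    direction_mix: float = 0.5          # fraction of probes hypermethylated
    affected_groups: tuple[str, ...] = ("A",)

    def __post_init__(self) -> None:
        lo, hi = self.effect_size_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("effect sizes must lie in (0, 0.5]")


@dataclass
class RegionBlock:
    """A planted differentially methylated region on consecutive probes."""

    label: str
    n_probes: int = 4
    max_gap: int = 1000
    effect: float = 0.15
    affected_groups: tuple[str, ...] = ("A", "B", "C", "D")

    def __post_init__(self) -> None:
        if self.n_probes < 3:
            raise ValueError("a region block needs at least 3 probes")
        if not (0 < self.effect <= 0.5):
            raise ValueError("region effect must lie in (0, 0.5]")


@dataclass
class SignatureSpec:
    """Planted signature layout: probe blocks, pairwise overlap, regions.

    ``overlap_fraction`` is the fraction of each block's probes shared with
    the previously placed block, emulating the partial (10–20%) overlap
    observed between subtype signatures.
    """

    blocks: list[SignatureBlock] = field(default_factory=list)
    overlap_fraction: float = 0.15
    region_blocks: list[RegionBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")


def make_manifest(n_probes: int, n_chromosomes: int = 22,
                  mean_spacing: float = 1500.0, seed: int = 0) -> pd.DataFrame:
    """Generate a sorted probe manifest with genes, island context and QC flags.

    Positions follow exponential inter-probe gaps (strictly increasing within
    each chromosome); about 5% of probes carry each QC flag
    (sex-chromosome, SNP overlap, cross-reactive); genes are assigned in
    genomic runs with right-skewed probes-per-gene counts (1–30).
    """
    if n_probes < 1 or n_chromosomes < 1 or mean_spacing <= 0:
        raise ValueError("n_probes, n_chromosomes and mean_spacing must be positive")
    rng = np.random.default_rng(seed)

    per_chrom = np.full(n_chromosomes, n_probes // n_chromosomes)
    per_chrom[: n_probes % n_chromosomes] += 1
    chroms, positions = [], []
    for c, n_c in enumerate(per_chrom):
        if n_c == 0:
            continue
        gaps = np.maximum(1, rng.exponential(mean_spacing, size=n_c)).astype(np.int64)
        pos = np.cumsum(gaps) + 1000
        chroms.extend([f"chr{c + 1}"] * int(n_c))
        positions.extend(pos.tolist())

    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    island = rng.choice(ISLAND_RELATIONS, size=n_probes, p=[0.30, 0.20, 0.10, 0.40])

    # genes in genomic runs; run lengths geometric-ish, right-skewed 1..30
    gene_sizes = np.minimum(30, 1 + rng.geometric(0.25, size=n_probes))
    genes = np.empty(n_probes, dtype=object)
    i, g = 0, 0
    while i < n_probes:
        size = int(gene_sizes[g % n_probes])
        if rng.random() < 0.15:                      # intergenic stretch
            genes[i:i + size] = ""
        else:
            genes[i:i + size] = f"GENE{g:05d}"
        i += size
        g += 1

    manifest = pd.DataFrame({
        "chrom": chroms,
        "pos": positions,
        "gene": genes,
        "island_relation": island,
        "sex_chromosome": rng.random(n_probes) < 0.05,
        "snp_overlap": rng.random(n_probes) < 0.05,
        "cross_reactive": rng.random(n_probes) < 0.05,
    }, index=pd.Index(probe_ids, name="probe_id"))
    manifest = manifest.sort_values(["chrom", "pos"], kind="mergesort")
    assert not manifest.index.duplicated().any()
    return manifest


def make_cell_reference_panel(manifest: pd.DataFrame, n_cell_types: int = 7,
                              n_discriminating: int = 600,
                              seed: int = 0) -> CellReferencePanel:
    """Build a reference panel of purified cell-type beta profiles.

    The shared baseline is bimodal — island/shore probes hypomethylated,
    open-sea/shelf probes hypermethylated — and a designated subset of
    probes discriminates the cell types with a between-type beta spread of
    at least 0.3 (these carry the deconvolution signal).
    """
    if n_cell_types < 2:
        raise ValueError("a reference panel needs at least 2 cell types")
    n_probes = len(manifest)
    if n_discriminating > n_probes:
        raise ValueError("more discriminating probes requested than probes exist")
    rng = np.random.default_rng(seed)

    low = manifest["island_relation"].isin(["Island", "Shore"]).to_numpy()
    baseline = np.where(low, rng.beta(2.0, 14.0, size=n_probes),
                        rng.beta(14.0, 2.0, size=n_probes))
    betas = np.tile(baseline[:, None], (1, n_cell_types))
    betas += rng.normal(0.0, 0.01, size=betas.shape)

    disc_idx = rng.choice(n_probes, size=n_discriminating, replace=False)
    if n_cell_types > 1:
        levels = np.linspace(0.15, 0.85, n_cell_types)     # spread 0.7 ≥ 0.3
        for i in disc_idx:
            betas[i] = rng.permutation(levels) + rng.normal(0, 0.02, n_cell_types)
    betas = np.clip(betas, 0.005, 0.995)

    cell_types = [f"cell{j + 1}" for j in range(n_cell_types)]
    ref = pd.DataFrame(betas, index=manifest.index, columns=cell_types)
    disc = list(manifest.index[np.sort(disc_idx)])
    return CellReferencePanel(cell_types, ref, disc)


def _make_sample_sheet(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    groups = list(design.group_sizes.items()) + [("control", design.control_pool_size)]
    i = 0
    for group, n in groups:
        mean, sd = design.age_distribution.get(group, (12.0, 8.0))
        for _ in range(n):
            age = -1.0
            while age < 0.5:                       # truncate at infancy
                age = rng.normal(mean, sd)
            rows.append({
                "sample_id": f"s{i:04d}",
                "group": group,
                "age": round(float(age), 1),
                "sex": "F" if rng.random() < design.sex_ratio else "M",
                "batch": f"batch{rng.integers(design.n_batches) + 1}",
                "array_type": design.array_types[rng.integers(len(design.array_types))],
            })
            i += 1
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_null_cohort(design: CohortDesign, manifest: pd.DataFrame,
                         panel: CellReferencePanel
                         ) -> tuple[MethylationCohort, GroundTruth]:
    """Simulate a cohort with no planted disease signature.

    Per sample: beta = expit( logit(cell-mixture expectation) + age·slope
    + sex offset + batch offset + noise ), where the cell mixture is the
    reference panel weighted by Dirichlet-drawn true proportions and the
    noise is Gaussian on the logit scale with a per-probe sd
    (``noise_sd`` times a lognormal probe-specific scale).
    Covariate effects touch only a small random probe subset
    (``covariate_affected_fraction``).  Returns the cohort and a ground
    truth carrying the true cell proportions and subtype labels.
    """
    if not manifest.index.equals(panel.reference_betas.index):
        raise ValueError("manifest and reference panel probe ids do not match")
    rng = np.random.default_rng(design.seed)
    samples = _make_sample_sheet(design, rng)
    n_probes, n_samples = len(manifest), len(samples)
    n_cells = len(panel.cell_types)

    conc = design.cell_dirichlet or {}
    default_conc = np.full(n_cells, 12.0)
    props = np.vstack([
        rng.dirichlet(np.asarray(conc.get(g, default_conc), dtype=float))
        for g in samples["group"]])
    proportions = pd.DataFrame(props, index=samples.index, columns=panel.cell_types)

    mixture = panel.reference_betas.to_numpy() @ props.T        # probe × sample
    m = logit(np.clip(mixture, 1e-9, 1 - 1e-9))

    n_affected = int(round(design.covariate_affected_fraction * n_probes))

    def affected(scale: float) -> np.ndarray:
        coef = np.zeros(n_probes)
        if scale > 0 and n_affected > 0:
            idx = rng.choice(n_probes, size=n_affected, replace=False)
            coef[idx] = rng.normal(0.0, scale, size=n_affected)
        return coef

    age_slope = affected(design.age_slope_sd)
    sex_off = affected(design.sex_effect_sd)
    age = samples["age"].to_numpy() - samples["age"].mean()
    is_f = (samples["sex"] == "F").to_numpy().astype(float)
    m = m + age_slope[:, None] * age[None, :] + sex_off[:, None] * is_f[None, :]
    for b in sorted(samples["batch"].unique()):
        off = affected(design.batch_effect_sd)
        in_b = (samples["batch"] == b).to_numpy().astype(float)
        m = m + off[:, None] * in_b[None, :]
    if design.noise_sd > 0:
        # probes differ widely in inter-individual variability: per-probe
        # lognormal scale on a common base sd (heteroscedastic across probes,
        # homoscedastic across samples); clipped below at the technical noise
        # floor and above at the plausible biological range
        scale = design.noise_sd * np.clip(np.exp(
            rng.normal(0.0, design.noise_dispersion, size=n_probes)), 0.6, 2.5)
        m = m + rng.normal(0.0, 1.0, size=(n_probes, n_samples)) * scale[:, None]

    betas = expit(m)
    if design.beta_noise_sd > 0:
        # array measurement error is roughly additive on the fraction scale,
        # which inflates M-value variance at extreme baselines
        betas = betas + rng.normal(0.0, design.beta_noise_sd,
                                   size=betas.shape)
    betas = np.clip(betas, 1e-6, 1 - 1e-6)
    cohort = MethylationCohort(
        betas=pd.DataFrame(betas, index=manifest.index, columns=samples.index),
        samples=samples, manifest=manifest)
    truth = GroundTruth(true_cell_proportions=proportions,
                        true_subtype=samples["group"].to_dict())
    return cohort, truth


def _calibrated_shift(m_affected: np.ndarray, target_beta: float) -> float:
    """Logit shift delta s.t. mean(expit(m + delta)) hits target_beta (bisection)."""
    lo, hi = -12.0, 12.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expit(m_affected + mid).mean() < target_beta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _find_region_window(manifest: pd.DataFrame, n_probes: int, max_gap: int,
                        exclude: set[str], base_beta: pd.Series, effect: float,
                        rng: np.random.Generator) -> tuple[pd.Index, float]:
    """A run of n consecutive manifest probes with gaps ≤ max_gap.

    A planted region must shift all its probes in the same direction (a
    coherent DMR), so only windows whose baseline betas leave room for a
    common shift of ``effect`` are eligible.  Windows whose flanking
    probes (within ``max_gap`` of either end) are already planted are
    skipped, keeping the region-level ground truth spatially unambiguous.
    Returns the window and the chosen sign.
    """
    candidates = []
    for _, sub in manifest.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        ok_gap = np.diff(pos) <= max_gap
        flagged = sub[["sex_chromosome", "snp_overlap",
                       "cross_reactive"]].any(axis=1).to_numpy()
        for start in range(len(sub) - n_probes + 1):
            if not ok_gap[start:start + n_probes - 1].all():
                continue
            ids = sub.index[start:start + n_probes]
            if exclude.intersection(ids) or flagged[start:start + n_probes].any():
                continue
            near = (pos >= pos[start] - max_gap) \
                & (pos <= pos[start + n_probes - 1] + max_gap)
            if exclude.intersection(sub.index[near]):
                continue
            base = base_beta.loc[ids]
            up_ok = (base + effect <= 0.98).all()
            down_ok = (base - effect >= 0.02).all()
            if up_ok or down_ok:
                candidates.append((ids, up_ok, down_ok))
    if not candidates:
        raise ValueError(
            f"no direction-coherent window of {n_probes} consecutive probes "
            f"with gaps ≤ {max_gap} bp")
    ids, up_ok, down_ok = candidates[int(rng.integers(len(candidates)))]
    if up_ok and down_ok:
        sign = 1.0 if rng.random() < 0.5 else -1.0
    else:
        sign = 1.0 if up_ok else -1.0
    return ids, sign


def inject_signature(cohort: MethylationCohort, truth: GroundTruth,
                     spec: SignatureSpec, seed: int = 0
                     ) -> tuple[MethylationCohort, GroundTruth]:
    """Plant probe-block and region signatures into a null cohort.

    For every affected sample the planted probes are shifted on the logit
    scale, with the shift calibrated by bisection so that the realized
    group-mean |Δβ| (affected group vs everyone else) matches the drawn
    effect size to within a small tolerance.  Consecutive blocks share
    ``spec.overlap_fraction`` of their probes; region blocks occupy
    manifest-consecutive probes with inter-probe gaps ≤ ``max_gap``.
    Returns a new cohort and an updated (copied) truth.
    """
    rng = np.random.default_rng(seed)
    if not spec.blocks and not spec.region_blocks:
        return cohort, truth

    flagged = (cohort.manifest["sex_chromosome"] | cohort.manifest["snp_overlap"]
               | cohort.manifest["cross_reactive"])
    eligible = list(cohort.manifest.index[~flagged])
    n_requested = sum(b.n_probes for b in spec.blocks)
    if n_requested > len(eligible):
        raise ValueError(
            f"signature requests {n_requested} probes, only {len(eligible)} unflagged")

    betas = cohort.betas.to_numpy().copy()
    probe_loc = {p: i for i, p in enumerate(cohort.betas.index)}
    group = cohort.samples["group"]

    new_truth = GroundTruth(
        planted_probe_ids={k: list(v) for k, v in truth.planted_probe_ids.items()},
        planted_effects={k: dict(v) for k, v in truth.planted_effects.items()},
        planted_regions=list(truth.planted_regions),
        true_cell_proportions=truth.true_cell_proportions,
        true_subtype=dict(truth.true_subtype),
    )

    def plant(probe_ids, effects, directions, groups):
        """Shift `probe_ids` in samples of `groups` to hit per-probe target Δβ."""
        affected_mask = group.isin(groups).to_numpy()
        if not affected_mask.any():
            raise ValueError(f"no samples in affected groups {groups}")
        for pid, eff, sign in zip(probe_ids, effects, directions):
            i = probe_loc[pid]
            ref = betas[i, ~affected_mask] if (~affected_mask).any() \
                else betas[i, affected_mask]
            base = ref.mean()
            if not 0.02 <= base + sign * eff <= 0.98:
                sign = -sign          # full effect must fit inside (0, 1)
            target = float(np.clip(base + sign * eff, 0.02, 0.98))
            with np.errstate(divide="ignore"):
                m_aff = logit(np.clip(betas[i, affected_mask], 1e-9, 1 - 1e-9))
            delta = _calibrated_shift(m_aff, target)
            betas[i, affected_mask] = np.clip(expit(m_aff + delta), 1e-9, 1 - 1e-9)
            rec = new_truth.planted_effects.setdefault(pid, {})
            for g in groups:
                rec[g] = float(sign * (target - base))

    available = [p for p in eligible]
    rng.shuffle(available)
    cursor = 0
    prev_block_ids: list[str] = []
    for block in spec.blocks:
        n_shared = int(round(spec.overlap_fraction * block.n_probes)) if prev_block_ids else 0
        n_shared = min(n_shared, len(prev_block_ids), block.n_probes)
        shared = list(rng.choice(prev_block_ids, size=n_shared, replace=False)) \
            if n_shared else []
        n_new = block.n_probes - n_shared
        if cursor + n_new > len(available):
            raise ValueError("not enough unflagged probes for signature blocks")
        fresh = available[cursor:cursor + n_new]
        cursor += n_new
        ids = shared + fresh
        lo, hi = block.effect_size_range
        effects = rng.uniform(lo, hi, size=len(ids))
        directions = np.where(rng.random(len(ids)) < block.direction_mix, 1.0, -1.0)
        plant(ids, effects, directions, block.affected_groups)
        new_truth.planted_probe_ids[block.label] = list(ids)
        prev_block_ids = list(ids)

    taken = set(new_truth.all_planted_probes())
    base_beta = pd.Series(betas.mean(axis=1), index=cohort.betas.index)
    for region in spec.region_blocks:
        window, sign = _find_region_window(cohort.manifest, region.n_probes,
                                           region.max_gap, taken, base_beta,
                                           region.effect, rng)
        taken.update(window)
        plant(list(window), [region.effect] * len(window),
              [sign] * len(window), region.affected_groups)
        sub = cohort.manifest.loc[window]
        new_truth.planted_probe_ids[region.label] = list(window)
        new_truth.planted_regions.append(
            (sub["chrom"].iloc[0], int(sub["pos"].min()), int(sub["pos"].max()),
             list(window)))

    out = MethylationCohort(
        betas=pd.DataFrame(betas, index=cohort.betas.index,
                           columns=cohort.betas.columns),
        samples=cohort.samples, manifest=cohort.manifest,
        detection_p=cohort.detection_p)
    return out, new_truth
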