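"""Quality control, value transforms, cell deconvolution, control matching.

Everything between a raw beta matrix and a discovery-ready design:

* probe filters (detection p-value, sex chromosomes, SNP/cross-reactive
  blacklist) and sample filters (failed-probe rate, genome-wide bimodality,
  PCA outliers);
* the beta ↔ M-value transform, M = log2(β/(1−β));
* reference-based blood cell-type deconvolution by constrained projection;
* greedy age-matched control selection at a fixed case:control ratio within
  exact array-type strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA

from .cohort import MethylationCohort

__all__ = [
    "QcReport", "CellComposition", "MatchedDesign", "filter_probes",
    "filter_samples", "beta_to_m", "m_to_beta", "estimate_cell_composition",
    "match_controls", "default_blacklist",
]


@dataclass
class QcReport:
    """Which probes/samples were removed and why."""

    removed_probes: dict[str, str] = field(default_factory=dict)   # id -> reason
    removed_samples: dict[str, str] = field(default_factory=dict)
    n_probes_retained: int = 0
    n_samples_retained: int = 0

    def reasons(self, reason: str) -> list[str]:
        return [k for k, v in {**self.removed_probes, **self.removed_samples}.items()
                if v == reason]


@dataclass
class CellComposition:
    """Estimated cell-type proportions per sample plus fit residuals."""

    proportions: pd.DataFrame           # sample × cell type
    residual_norm: pd.Series            # per sample, beta-scale L2 residual


@dataclass
class MatchedDesign:
    """A case set with its ratio-matched control set."""

    case_ids: list[str]
    control_ids: list[str]
    ratio: int
    covariates: list[str]
    exact: list[str]
    age_gaps: pd.Series                 # per matched control, |age - case age|

    @property
    def all_ids(self) -> list[str]:
        return self.case_ids + self.control_ids

    def labels(self) -> pd.Series:
        """1 for cases, 0 for controls, indexed by sample id."""
        return pd.Series([1] * len(self.case_ids) + [0] * len(self.control_ids),
                         index=self.all_ids, name="case")


def default_blacklist(manifest: pd.DataFrame) -> dict[str, str]:
    """SNP-overlap / cross-reactive probe ids from manifest flags, with reasons."""
    out: dict[str, str] = {}
    for pid in manifest.index[manifest["snp_overlap"]]:
        out[pid] = "snp_overlap"
    for pid in manifest.index[manifest["cross_reactive"]]:
        out.setdefault(pid, "cross_reactive")
    return out


def filter_probes(cohort: MethylationCohort, detection_threshold: float = 0.01,
                  drop_sex: bool = True, blacklist: dict[str, str] | None = None,
                  ) -> tuple[MethylationCohort, QcReport]:
    """Remove unreliable probes.

    A probe is removed if its detection p exceeds ``detection_threshold`` in
    ANY sample (strict scope, appropriate for small cohorts), if it is
    flagged sex-chromosomal (``drop_sex``), or if it appears in the
    blacklist (SNP overlap / cross-reactive; pass
    :func:`default_blacklist` or your own id→reason mapping).
    """
    if blacklist is None:
        blacklist = default_blacklist(cohort.manifest)
    removed: dict[str, str] = {}

    if cohort.detection_p is not None:
        failed = (cohort.detection_p > detection_threshold).any(axis=1)
        for pid in cohort.detection_p.index[failed]:
            removed[pid] = "detection_p"
    if drop_sex:
        sex = cohort.manifest["sex_chromosome"] | cohort.manifest["chrom"].isin(
            ["chrX", "chrY", "X", "Y"])
        for pid in cohort.manifest.index[sex]:
            removed.setdefault(pid, "sex_chromosome")
    for pid, reason in blacklist.items():
        if pid in cohort.betas.index:
            removed.setdefault(pid, reason)

    keep = cohort.betas.index.difference(pd.Index(removed), sort=False)
    if len(keep) == 0:
        raise ValueError("probe filtering removed every probe")
    filtered = cohort.subset_probes(keep)
    report = QcReport(removed_probes=removed, n_probes_retained=len(keep),
                      n_samples_retained=filtered.n_samples)
    return filtered, report


def _is_bimodal(betas: np.ndarray) -> bool:
    """Genome-wide beta density check: hypo/hyper modes with a real valley.

    Flags a sample when the central density (betas in 0.3–0.7) exceeds
    0.8× the lower of the two mode heights — i.e. the valley between the
    methylated and unmethylated modes has filled in.
    """
    kde = gaussian_kde(betas)
    grid = np.linspace(0.0, 1.0, 201)
    dens = kde(grid)
    low_peak = dens[grid <= 0.3].max()
    high_peak = dens[grid >= 0.7].max()
    valley = dens[(grid > 0.3) & (grid < 0.7)].min()
    return valley <= 0.8 * min(low_peak, high_peak)


def filter_samples(cohort: MethylationCohort, max_failed_fraction: float = 0.05,
                   detection_threshold: float = 0.01, bimodality_check: bool = True,
                   pca_outlier_sd: float = 3.0,
                   ) -> tuple[MethylationCohort, QcReport]:
    """Remove failed arrays, non-bimodal samples and PCA outliers.

    Order: failed-probe rate (> ``max_failed_fraction`` of probes with
    detection p above threshold), then the bimodality screen, then a PCA
    screen on the M-value matrix (samples with |score| beyond
    ``pca_outlier_sd`` standard deviations on PC1 or PC2).
    """
    if cohort.n_samples < 3:
        raise ValueError("sample QC needs at least 3 samples")
    removed: dict[str, str] = {}

    if cohort.detection_p is not None:
        failed_frac = (cohort.detection_p > detection_threshold).mean(axis=0)
        for sid in failed_frac.index[failed_frac > max_failed_fraction]:
            removed[sid] = "failed_probe_rate"
    if bimodality_check:
        for sid in cohort.betas.columns:
            if sid in removed:
                continue
            if not _is_bimodal(cohort.betas[sid].to_numpy()):
                removed[sid] = "density_not_bimodal"

    survivors = [s for s in cohort.betas.columns if s not in removed]
    if pca_outlier_sd and len(survivors) >= 3:
        m = beta_to_m(cohort.betas[survivors].to_numpy()).T    # samples × probes
        scores = PCA(n_components=2, svd_solver="full").fit_transform(
            m - m.mean(axis=0))
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z = np.abs(scores / sd)
        for sid, flag in zip(survivors, (z > pca_outlier_sd).any(axis=1)):
            if flag:
                removed[sid] = "pca_outlier"

    keep = [s for s in cohort.betas.columns if s not in removed]
    if not keep:
        raise ValueError("sample filtering removed every sample")
    filtered = cohort.subset_samples(keep)
    report = QcReport(removed_samples=removed, n_probes_retained=filtered.n_probes,
                      n_samples_retained=len(keep))
    return filtered, report


def beta_to_m(beta, epsilon: float = 1e-3):
    """M-value transform, M = log2(β/(1−β)), with β clamped to [ε, 1−ε]."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1 - epsilon)
    return np.log2(b / (1 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` on the clamped domain: β = 2^M/(1+2^M)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def estimate_cell_composition(cohort: MethylationCohort,
                              panel, probe_subset=None,
                              simplex: bool = True) -> CellComposition:
    """Estimate blood cell-type proportions by constrained projection.

    Per sample, solves non-negative least squares of the sample's betas on
    the reference panel over the discriminating probes; with ``simplex`` the
    sum-to-one constraint is imposed (via a heavily weighted augmentation
    row).  Deterministic.
    """
    if probe_subset is None:
        probe_subset = panel.discriminating_probes
    probe_subset = [p for p in probe_subset if p in cohort.betas.index]
    if not probe_subset:
        raise ValueError("probe subset empty or absent from cohort")
    ref = panel.reference_betas.loc[probe_subset].to_numpy()
    obs = cohort.betas.loc[probe_subset].to_numpy()

    if np.linalg.matrix_rank(ref) < ref.shape[1]:
        warnings.warn("reference panel is rank-deficient on this probe subset; "
                      "proportions are a best-effort solution")
    lam = 1000.0
    a = np.vstack([ref, lam * np.ones((1, ref.shape[1]))]) if simplex else ref
    props, resid = [], []
    for j in range(obs.shape[1]):
        b = np.concatenate([obs[:, j], [lam]]) if simplex else obs[:, j]
        x, _ = nnls(a, b)
        props.append(x)
        resid.append(float(np.linalg.norm(ref @ x - obs[:, j])))
    proportions = pd.DataFrame(props, index=cohort.betas.columns,
                               columns=panel.cell_types)
    return CellComposition(proportions, pd.Series(resid, index=cohort.betas.columns,
                                                  name="residual_norm"))


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 6,
                   covariates: list[str] | None = None,
                   exact: list[str] | None = None, seed: int = 0) -> MatchedDesign:
    """Select ``ratio`` controls per case, nearest on age within array strata.

    Greedy nearest-neighbour matching on the continuous covariates (default
    ``age``) inside exact strata (default ``array_type``), without
    replacement.  Cases are processed in a seeded random order; ties in
    distance break by pool order.  Raises a capacity error naming the
    stratum when the pool cannot supply ``ratio`` controls per case.
    """
    covariates = covariates or ["age"]
    exact = exact if exact is not None else ["array_type"]
    rng = np.random.default_rng(seed)

    def stratum_key(rec) -> tuple:
        return tuple(rec[c] for c in exact)

    for key, case_sub in (cases.groupby(exact) if exact else [((), cases)]):
        pool_sub = pool
        for col, val in zip(exact, key if isinstance(key, tuple) else (key,)):
            pool_sub = pool_sub[pool_sub[col] == val]
        need = ratio * len(case_sub)
        if len(pool_sub) < need:
            raise ValueError(
                f"control pool too small in stratum {key}: "
                f"need {need}, have {len(pool_sub)}")

    available = set(pool.index)
    case_order = list(cases.index)
    rng.shuffle(case_order)
    control_ids: list[str] = []
    gaps: dict[str, float] = {}
    for cid in case_order:
        case = cases.loc[cid]
        sub = pool.loc[[p for p in pool.index if p in available]]
        for col in exact:
            sub = sub[sub[col] == case[col]]
        if len(sub) < ratio:
            raise ValueError(
                f"control pool exhausted in stratum "
                f"{tuple(case[c] for c in exact)} while matching {cid}")
        dist = np.zeros(len(sub))
        for col in covariates:
            dist += (sub[col].to_numpy(dtype=float) - float(case[col])) ** 2
        picked = sub.index[np.argsort(dist, kind="stable")[:ratio]]
        for p in picked:
            available.discard(p)
            control_ids.append(p)
            gaps[p] = float(abs(pool.loc[p, "age"] - case["age"]))

    return MatchedDesign(
        case_ids=sorted(cases.index), control_ids=control_ids, ratio=ratio,
        covariates=covariates, exact=exact,
        age_gaps=pd.Series(gaps, name="age_gap"))
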