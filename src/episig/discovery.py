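"""Episignature discovery: moderated differential methylation and DMRs.

Per-probe ordinary least squares on M-values with covariate adjustment,
empirical-Bayes shrinkage of the residual variances (moderated t), BH
multiple-testing correction, the significance/effect-size probe filter,
Ward hierarchical clustering of the candidate signature, and region-level
detection by stitching runs of significant probes with a Stouffer-combined
region statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import digamma, polygamma

from .cohort import MethylationCohort
from .preprocess import beta_to_m

__all__ = [
    "build_design_matrix", "fit_moderated_model", "adjust_bh",
    "select_signature_probes", "hierarchical_cluster", "stouffer_combine",
    "detect_dmrs", "discover_probes",
]


def build_design_matrix(samples: pd.DataFrame, case_labels,
                        cell_proportions: pd.DataFrame | None = None,
                        covariates: tuple[str, ...] = ("sex",),
                        include_batch: bool = False) -> pd.DataFrame:
    """Design matrix: intercept, case indicator, factor dummies, cell covariates.

    ``case_labels`` is the set of ``group`` values treated as cases.  Factor
    covariates (sex, batch) are dummy-coded dropping one reference level;
    one cell-proportion column is dropped to avoid the sum-to-one
    collinearity.  Raises if the result is rank-deficient.
    """
    cols = {"intercept": np.ones(len(samples)),
            "case": samples["group"].isin(case_labels).astype(float).to_numpy()}
    factors = list(covariates) + (["batch"] if include_batch else [])
    for f in factors:
        levels = sorted(samples[f].unique())
        for lev in levels[1:]:
            cols[f"{f}_{lev}"] = (samples[f] == lev).astype(float).to_numpy()
    design = pd.DataFrame(cols, index=samples.index)
    if cell_proportions is not None:
        cp = cell_proportions.loc[samples.index]
        design = pd.concat([design, cp.iloc[:, 1:]], axis=1)  # drop first: simplex
    x = design.to_numpy()
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return design


def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0²) on log variances.

    With s² ~ s0² · F(df, d0): E[log s²] and Var[log s²] have closed forms in
    digamma/trigamma; matching the sample moments of log s² yields d0 and s0².
    Returns (inf, geometric-type mean) when the variances are under-dispersed
    relative to pure chi-squared sampling noise.
    """
    z = np.log(np.maximum(s2, 1e-300))
    zbar = z.mean()
    zvar = z.var(ddof=1) if len(z) > 1 else 0.0
    excess = zvar - polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        log_s0 = zbar - digamma(df / 2.0) + np.log(df / 2.0)
        return d0, float(np.exp(log_s0))
    d0 = 2.0 * _trigamma_inverse(excess)
    log_s0 = (zbar - digamma(df / 2.0) + np.log(df / 2.0)
              + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(np.exp(log_s0))


def fit_moderated_model(m_values: pd.DataFrame, design: pd.DataFrame,
                        coef: str = "case",
                        prior_df: float | None = None) -> pd.DataFrame:
    """Per-probe OLS with empirical-Bayes moderated t-statistics.

    Fits the same design to every probe (rows of ``m_values``), shrinks the
    residual variances toward a common prior fitted by method of moments,
    and returns a DataFrame indexed by probe with columns ``coefficient,
    df, s2, t, p`` plus the prior as attrs ``d0`` and ``s0_2``.  Posterior
    variance is (d0·s0² + df·s²)/(d0 + df); the moderated t uses d0 + df
    degrees of freedom.  ``prior_df`` overrides the fitted d0 (0 recovers
    ordinary per-probe OLS t exactly).
    """
    x = design.to_numpy(dtype=float)
    y = m_values.to_numpy(dtype=float)
    n, p = x.shape
    if y.shape[1] != n:
        raise ValueError("m_values columns must match design rows")
    if n < p + 1:
        raise ValueError("more design columns than samples allow")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank-deficient")
    xtx_inv = np.linalg.inv(x.T @ x)
    coefs = (xtx_inv @ x.T @ y.T)                     # p × probes
    resid = y.T - x @ coefs
    df = n - p
    s2 = (resid ** 2).sum(axis=0) / df
    j = design.columns.get_loc(coef)
    unscaled = xtx_inv[j, j]

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        total_df = 1e12
    else:
        post_var = (d0 * s0_2 + df * s2) / (d0 + df) if d0 > 0 else s2
        total_df = d0 + df
    t = coefs[j] / np.sqrt(post_var * unscaled)
    pvals = 2.0 * stats.t.sf(np.abs(t), total_df)

    out = pd.DataFrame({"coefficient": coefs[j], "df": df, "s2": s2,
                        "t": t, "p": pvals}, index=m_values.index)
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out.attrs["total_df"] = total_df
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_j ≥ p_i of m·p_j/rank_j, capped at 1;
    order-preserving and invariant to input permutation.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a nonempty 1-d vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def discover_probes(cohort: MethylationCohort, design: pd.DataFrame,
                    case_labels, coef: str = "case",
                    prior_df: float | None = None) -> pd.DataFrame:
    """Full per-probe discovery table: moderated stats + Δβ + BH q.

    Δβ is the difference of group-mean betas (cases − controls) on the beta
    scale — the interpretable "methylation difference" the 10% cutoff
    refers to — not a back-transformed regression coefficient.
    """
    sub = cohort.subset_samples(design.index)
    m = pd.DataFrame(beta_to_m(sub.betas.to_numpy()), index=sub.betas.index,
                     columns=sub.betas.columns)
    st = fit_moderated_model(m, design, coef=coef, prior_df=prior_df)
    is_case = sub.samples["group"].isin(case_labels).to_numpy()
    st["delta_beta"] = (sub.betas.to_numpy()[:, is_case].mean(axis=1)
                        - sub.betas.to_numpy()[:, ~is_case].mean(axis=1))
    st["q"] = adjust_bh(st["p"].to_numpy())
    return st


def select_signature_probes(stats_table: pd.DataFrame, min_delta: float = 0.10,
                            max_q: float = 0.05) -> list[str]:
    """Probes with q < max_q and |Δβ| > min_delta, sorted by p (ties by id)."""
    keep = stats_table[(stats_table["q"] < max_q)
                       & (stats_table["delta_beta"].abs() > min_delta)]
    order = np.lexsort((keep.index.to_numpy(), keep["p"].to_numpy()))
    return list(keep.index[order])


def hierarchical_cluster(betas: pd.DataFrame, n_clusters: int = 2
                         ) -> tuple[np.ndarray, pd.Series]:
    """Ward-linkage clustering of samples on Euclidean distance.

    ``betas`` is probe × sample (samples are clustered).  Returns the scipy
    linkage matrix and the ``n_clusters``-cut labels indexed by sample id.
    Deterministic; invariant to sample order up to label renaming.
    """
    if betas.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    z = linkage(betas.to_numpy().T, method="ward", metric="euclidean")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return z, pd.Series(labels, index=betas.columns, name="cluster")


def stouffer_combine(z, weights=None) -> float:
    """Stouffer-combined z: Σwᵢzᵢ/√Σwᵢ² (unweighted: Σzᵢ/√n)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("cannot combine an empty z vector")
    if not np.isfinite(z).all():
        raise ValueError("z values must be finite")
    if weights is None:
        return float(z.sum() / np.sqrt(z.size))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    return float((w * z).sum() / np.sqrt((w ** 2).sum()))


def _signed_z(stats_table: pd.DataFrame) -> pd.Series:
    """Signed normal quantile from the two-sided probe p, sign from t."""
    p = np.clip(stats_table["p"].to_numpy(), 1e-300, 1.0)
    z = stats.norm.isf(p / 2.0)
    return pd.Series(np.sign(stats_table["t"].to_numpy()) * z,
                     index=stats_table.index)


def detect_dmrs(stats_table: pd.DataFrame, manifest: pd.DataFrame,
                max_gap: int = 1000, min_probes: int = 3,
                min_mean_delta: float = 0.10, max_region_fdr: float = 0.05,
                probe_q: float = 0.05,
                smoothing_bandwidth: float | None = None) -> pd.DataFrame:
    """Differentially methylated regions by stitching significant probes.

    Per chromosome (manifest must be position-sorted): optionally smooth the
    signed probe z over genomic position with a Gaussian kernel, mark probes
    significant at probe-level q < ``probe_q``, stitch runs of significant
    probes whose inter-probe gaps are ≤ ``max_gap`` bp, keep runs with
    ≥ ``min_probes`` probes and |mean Δβ| > ``min_mean_delta``, compute the
    region Stouffer z over the member probes' signed z, convert to a
    two-sided region p, BH-adjust across regions, and keep regions with
    FDR < ``max_region_fdr``.  Coordinates are 1-based inclusive probe
    positions (first to last member probe).
    """
    shared = stats_table.index.intersection(manifest.index)
    if len(shared) < len(stats_table):
        raise ValueError("stats and manifest probe ids do not match")
    mani = manifest.loc[stats_table.index]
    for _, sub in mani.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
            raise ValueError("manifest positions must be sorted and strictly "
                             "increasing within chromosomes; sort it first")

    z_all = _signed_z(stats_table)
    records = []
    for chrom, sub in mani.groupby("chrom", sort=True):
        ids = sub.index
        pos = sub["pos"].to_numpy()
        z = z_all.loc[ids].to_numpy()
        if smoothing_bandwidth:
            w = np.exp(-0.5 * ((pos[:, None] - pos[None, :])
                               / smoothing_bandwidth) ** 2)
            z = (w @ z) / np.sqrt((w ** 2).sum(axis=1))
            p_loc = 2.0 * stats.norm.sf(np.abs(z))
            sig = adjust_bh(p_loc) < probe_q
        else:
            sig = stats_table.loc[ids, "q"].to_numpy() < probe_q

        sig_idx = np.flatnonzero(sig)
        if sig_idx.size == 0:
            continue
        run_start = 0
        runs = []
        for k in range(1, len(sig_idx) + 1):
            if k == len(sig_idx) or (pos[sig_idx[k]] - pos[sig_idx[k - 1]]) > max_gap:
                runs.append(sig_idx[run_start:k])
                run_start = k
        for run in runs:
            if len(run) < min_probes:
                continue
            member = ids[run]
            mean_delta = float(stats_table.loc[member, "delta_beta"].mean())
            if abs(mean_delta) <= min_mean_delta:
                continue
            region_z = stouffer_combine(z_all.loc[member].to_numpy())
            records.append({
                "chrom": chrom, "start": int(pos[run[0]]), "end": int(pos[run[-1]]),
                "n_probes": len(run), "probe_ids": list(member),
                "mean_delta_beta": mean_delta, "stouffer_z": region_z,
                "p": 2.0 * stats.norm.sf(abs(region_z)),
            })
    if not records:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_probes",
                                     "probe_ids", "mean_delta_beta",
                                     "stouffer_z", "p", "fdr"])
    regions = pd.DataFrame(records)
    regions["fdr"] = adjust_bh(regions["p"].to_numpy())
    regions = regions[regions["fdr"] < max_region_fdr]
    return regions.sort_values(["chrom", "start"]).reset_index(drop=True)


def dmrs_to_bed(regions: pd.DataFrame) -> str:
    """BED text (0-based half-open) for a region table from :func:`detect_dmrs`."""
    lines = [f"{r.chrom}\t{r.start - 1}\t{r.end}\tDMR_{i + 1}\t"
             f"{r.stouffer_z:.4f}\t{'+' if r.mean_delta_beta > 0 else '-'}"
             for i, r in enumerate(regions.itertuples())]
    return "\n".join(lines) + ("\n" if lines else "")
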