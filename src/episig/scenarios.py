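"""Study-scale validation scenarios run end to end on synthetic cohorts.

Each function simulates the relevant study condition with the generator's
default parameters, runs the pipeline stage under test, and returns the
measured quantities as a flat dict of numbers.  The test suite asserts on
these; the reproduction script reports them.  Problem sizes are desk-scale
analogues of the modelled study (2,000-probe universes for the powered
comparisons; a 20,000-probe universe for the rare-subtype power-failure
scan, where the multiple-testing burden is the phenomenon of interest).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.metrics import adjusted_rand_score

from .classifier import build_feature_panel, score_samples, train_classifier, \
    train_test_split_stratified
from .consensus import select_optimal_k
from .discovery import detect_dmrs, hierarchical_cluster
from .enrichment import biased_urn_tail, probe_bias_go_test
from .pipeline import StudyData, consensus_subtypes, run_discovery, simulate_study
from .preprocess import estimate_cell_composition, match_controls
from .synthetic import CohortDesign, SignatureBlock, SignatureSpec, \
    inject_signature, make_cell_reference_panel, make_manifest, \
    simulate_null_cohort

__all__ = ["matched_control_counts", "discovery_metrics",
           "small_group_power_failure", "clustering_metrics",
           "classifier_metrics", "enrichment_metrics"]


def _sample_sheet(n: int, prefix: str, rng: np.random.Generator,
                  group: str = "control") -> pd.DataFrame:
    return pd.DataFrame({
        "group": group,
        "age": rng.uniform(1, 30, n).round(1),
        "sex": rng.choice(["F", "M"], n),
        "batch": rng.choice(["b1", "b2", "b3"], n),
        "array_type": rng.choice(["450k", "EPIC"], n),
    }, index=[f"{prefix}{i:03d}" for i in range(n)])


def matched_control_counts(seed: int = 0) -> dict[str, float]:
    """6:1 matched-control cohort sizes for the study's group sizes."""
    rng = np.random.default_rng(seed)
    pool = _sample_sheet(400, "c", rng)
    out = {}
    for n_cases in (14, 5, 7, 21):
        cases = _sample_sheet(n_cases, f"p{n_cases}_", rng, group="case")
        design = match_controls(cases, pool, ratio=6, seed=seed)
        out[f"controls_for_{n_cases}_cases"] = float(len(design.control_ids))
    return out


def _region_recovery(regions: pd.DataFrame, truth) -> tuple[float, float]:
    """A planted region counts as recovered when a reported region shares at
    least three probes with it (the caller's own minimum region size)."""
    found_sets = [set(p) for p in regions["probe_ids"]] if len(regions) else []
    planted = truth.all_planted_probes()
    n_rec = sum(any(len(set(r[3]) & fs) >= 3 for fs in found_sets)
                for r in truth.planted_regions)
    n_spurious = sum(all(p not in planted for p in fs) for fs in found_sets)
    return n_rec / max(1, len(truth.planted_regions)), float(n_spurious)


def discovery_metrics(seed: int = 0, n_seeds: int = 5) -> dict[str, float]:
    """Signature discovery on the 14-vs-84 design over several seeds.

    Sensitivity is measured against planted probes whose effect in the case
    group is at least the 10% reporting threshold; the empirical FDR counts
    selected probes that were never planted.
    """
    sens, fdr, region_rec, region_spur = [], [], [], []
    for s in range(n_seeds):
        study = simulate_study(seed=seed + s)
        truth = study.truth
        _, stats, sig = run_discovery(study, case_groups=("A",), seed=seed + s)
        recoverable = [pid for pid, rec in truth.planted_effects.items()
                       if "A" in rec and abs(rec["A"]) >= 0.10]
        planted = truth.all_planted_probes()
        fp = len([p for p in sig if p not in planted])
        sens.append(len(set(sig) & set(recoverable)) / len(recoverable))
        fdr.append(fp / max(1, len(sig)))
        regions = detect_dmrs(stats, study.manifest)
        rec, spur = _region_recovery(regions, truth)
        region_rec.append(rec)
        region_spur.append(spur)
    return {
        "discovery_sensitivity_min": float(np.min(sens)),
        "discovery_sensitivity_mean": float(np.mean(sens)),
        "discovery_fdr_max": float(np.max(fdr)),
        "region_recovery_rate": float(np.mean(region_rec)),
        "spurious_unplanted_regions": float(np.sum(region_spur)),
        "n_seeds": float(n_seeds),
    }


def small_group_power_failure(seed: int = 0) -> dict[str, float]:
    """A 2-case subtype on a genome-scale universe yields no signature.

    40 subtype probes are planted at exactly the 10% reporting threshold in
    a 20,000-probe scan; with 2 cases against 12 matched controls the BH
    threshold is far below the attainable p, reproducing the empty outcome
    a rare subtype shows in practice.
    """
    manifest = make_manifest(20000, n_chromosomes=22, mean_spacing=1500.0,
                             seed=seed + 11)
    panel = make_cell_reference_panel(manifest, 7, 600, seed=seed + 12)
    design = CohortDesign(group_sizes={"C": 2}, control_pool_size=60,
                          seed=seed + 13)
    cohort, truth = simulate_null_cohort(design, manifest, panel)
    spec = SignatureSpec(blocks=[SignatureBlock(
        "C_block", 40, (0.10, 0.10), affected_groups=("C",))],
        region_blocks=[])
    cohort, truth = inject_signature(cohort, truth, spec, seed=seed + 14)
    study = StudyData(manifest, panel, cohort, truth, design)
    _, stats, sig = run_discovery(study, case_groups=("C",), seed=seed + 15)
    return {"two_case_signature_size": float(len(sig)),
            "two_case_min_q": float(stats["q"].min())}


def clustering_metrics(seed: int = 0, reps: int = 200) -> dict[str, float]:
    """Case/control separation and subtype consensus structure.

    Hierarchical clustering of cases plus matched controls on the
    discovered all-case signature, then consensus clustering of the A vs
    B/D cases on their subtype-specific planted blocks.
    """
    study = simulate_study(seed=seed)
    truth = study.truth
    matched, _, sig = run_discovery(study, case_groups=("A", "B", "C", "D"),
                                    seed=seed)
    ids = matched.all_ids
    _, labels = hierarchical_cluster(study.cohort.betas.loc[sig, ids])
    is_case = study.cohort.samples.loc[ids, "group"].ne("control").astype(int)
    rand = adjusted_rand_score(is_case.to_numpy(), labels.loc[ids].to_numpy())

    probes = truth.planted_probe_ids["A_specific"] + truth.planted_probe_ids["BD"]
    res = consensus_subtypes(study, probes, groups=("A", "B", "D"),
                             k_range=range(2, 7), reps=reps, seed=seed + 1)
    best_k = select_optimal_k(res)
    lab = res.labels[2]
    groups = study.cohort.samples.loc[lab.index, "group"]
    bd_together = float(
        groups[lab == lab[groups[groups == "B"].index[0]]].isin(["B", "D"]).all()
        and (lab[groups.isin(["B", "D"])].nunique() == 1)
        and (lab[groups == "A"].nunique() == 1)
        and lab[groups == "A"].iloc[0] != lab[groups == "B"].iloc[0])
    return {
        "hierarchical_rand_index": float(rand),
        "signature_size_all_cases": float(len(sig)),
        "consensus_optimal_k": float(best_k),
        "consensus_min_cluster_consensus_k2": float(res.cluster_consensus[2].min()),
        "consensus_pac_k2": float(res.pac[2]),
        "consensus_bd_vs_a_split": bd_together,
    }


def classifier_metrics(seed: int = 0) -> dict[str, float]:
    """Train/validate the diagnostic model, with the specificity harness.

    Trains on 21 cases / 126 matched controls (75% stratified split of the
    28 cases), scores the held-out cases and controls, an other-syndrome
    cohort carrying an unrelated planted signature, the controls sharing
    the training cases' batches, and per-individual pure cell-type
    reconstitutions of held-out controls.
    """
    study = simulate_study(seed=seed)
    co, truth = study.cohort, study.truth
    samples = co.samples
    cases = samples[samples["group"] != "control"]
    pool = samples[samples["group"] == "control"]
    train_cases, test_cases = train_test_split_stratified(cases, 0.75,
                                                          seed=seed + 4)
    matched = match_controls(cases.loc[train_cases], pool, ratio=6,
                             seed=seed + 4)
    train_ids = matched.all_ids
    sub = co.subset_samples(train_ids)
    cells = estimate_cell_composition(sub, study.panel)
    panel = build_feature_panel(sub, sub.samples,
                                case_labels=("A", "B", "C", "D"),
                                cell_proportions=cells.proportions)
    labels = pd.Series([1] * len(matched.case_ids)
                       + [0] * len(matched.control_ids), index=train_ids)
    model = train_classifier(sub.betas, labels, panel, seed=seed + 4)

    held_controls = [s for s in pool.index if s not in set(matched.control_ids)]
    rep = score_samples(model, co.betas[test_cases + held_controls])
    case_batches = set(samples.loc[train_cases, "batch"])
    batch_mates = [s for s in held_controls
                   if samples.loc[s, "batch"] in case_batches]

    # other-syndrome cohort: same array, unrelated planted signature
    other_design = CohortDesign(group_sizes={"other": 20}, control_pool_size=20,
                                seed=seed + 99)
    other_cohort, other_truth = simulate_null_cohort(other_design,
                                                     study.manifest,
                                                     study.panel)
    other_spec = SignatureSpec(blocks=[SignatureBlock(
        "other", 300, (0.10, 0.20), affected_groups=("other",))],
        region_blocks=[])
    other_cohort, _ = inject_signature(other_cohort, other_truth, other_spec,
                                       seed=seed + 100)
    other_ids = other_cohort.samples.index[
        other_cohort.samples["group"] == "other"]
    other_scores = score_samples(model, other_cohort.betas[list(other_ids)])

    # pure cell-type reconstitutions keep each individual's residual profile
    ref = study.panel.reference_betas
    recon_max, recon_spread = 0.0, 0.0
    for sid in held_controls[:10]:
        obs = co.betas[sid].to_numpy()
        props = truth.true_cell_proportions.loc[sid].to_numpy()
        mix = np.clip(ref.to_numpy() @ props, 1e-9, 1 - 1e-9)
        resid = logit(np.clip(obs, 1e-9, 1 - 1e-9)) - logit(mix)
        cols = {ct: expit(logit(np.clip(ref[ct].to_numpy(), 1e-9, 1 - 1e-9))
                          + resid) for ct in study.panel.cell_types}
        scores = score_samples(
            model, pd.DataFrame(cols, index=co.betas.index))["score"]
        recon_max = max(recon_max, float(scores.max()))
        recon_spread = max(recon_spread, float(scores.max() - scores.min()))

    return {
        "panel_size": float(len(panel.probe_ids)),
        "cv_accuracy": float(model.cv_accuracy),
        "held_out_case_score_min": float(rep.loc[test_cases, "score"].min()),
        "held_out_control_score_max": float(rep.loc[held_controls, "score"].max()),
        "batch_mate_score_max": float(rep.loc[batch_mates, "score"].max()),
        "other_syndrome_score_max": float(other_scores["score"].max()),
        "cell_reconstitution_score_max": recon_max,
        "cell_reconstitution_spread_max": recon_spread,
    }


def enrichment_metrics(seed: int = 0, n_draws: int = 1000) -> dict[str, float]:
    """Null calibration of the urn test plus planted-enrichment detection.

    Calibration uses a probe-count-homogeneous universe (2,000 genes × 3
    probes, 100 sets of 50 genes) with selected probes drawn uniformly, so
    the bias odds collapse to 1; the planted scenario concentrates 80% of
    the selection on one set's genes in a skewed universe.
    """
    rng = np.random.default_rng(seed)
    n_genes, probes_per_gene, n_sets, set_size, n_sel = 2000, 3, 100, 50, 400
    gene_idx = np.repeat(np.arange(n_genes), probes_per_gene)
    n_probes = len(gene_idx)
    set_masks = np.zeros((n_sets, n_genes), dtype=bool)
    for si in range(n_sets):
        set_masks[si, rng.choice(n_genes, set_size, replace=False)] = True

    hits, total = 0, 0
    for _ in range(n_draws):
        sel = rng.choice(n_probes, n_sel, replace=False)
        sel_genes = np.zeros(n_genes, dtype=bool)
        sel_genes[gene_idx[sel]] = True
        n_sel_genes = int(sel_genes.sum())
        for si in range(n_sets):
            k = int((set_masks[si] & sel_genes).sum())
            p = biased_urn_tail(k, set_size, n_sel_genes, n_genes, odds=1.0)
            hits += p < 0.05
            total += 1
    type_i = hits / total

    manifest = make_manifest(4000, n_chromosomes=8, mean_spacing=1000.0,
                             seed=seed + 3)
    genic = manifest[manifest["gene"] != ""]
    genes = genic["gene"].unique()
    target = set(rng.choice(genes, 30, replace=False))
    target_probes = list(genic.index[genic["gene"].isin(target)])
    universe = list(manifest.index)
    off_target = [p for p in universe if p not in set(target_probes)]
    selected = (list(rng.choice(target_probes, 120, replace=False))
                + list(rng.choice(off_target, 30, replace=False)))
    coll = {"TARGET": target}
    coll.update({f"R{j}": set(rng.choice(genes, 30, replace=False))
                 for j in range(49)})
    res = probe_bias_go_test(selected, universe, manifest, coll)
    return {
        "null_type_i_rate": float(type_i),
        "planted_set_fdr": float(res.loc["TARGET", "fdr"]),
        "planted_set_rank": float(list(res.index).index("TARGET") + 1),
        "n_null_draws": float(n_draws),
    }
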