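"""End-to-end study pipeline on a synthetic cohort.

Mirrors the full analysis: generate a cohort, preprocess, cross-validate the
convolutional age decoder subject-wise (training on non-pathological
recordings only), fit the quadratic bias model and biomarker thresholds on
cross-validation predictions, run the repeated final evaluation on held-out
subjects, and compute the gap, biomarker, longitudinal change-rate, and
transition statistics. Every recording enters the analysis with an
out-of-sample prediction (out-of-fold for training subjects, final
evaluation for held-out subjects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .biomarker import (ThresholdPair, age_threshold_proxy, bacc_of_rule,
                        change_rates, optimize_thresholds,
                        transition_rates_all)
from .derivatives import assign_all
from .metrics import apply_bias, compute_gaps, fit_bias, mae, r2, subject_average_gap
from .model import ModelConfig, TrainConfig, run_cv, run_final_evaluation
from .preproc import PreprocConfig, preprocess_recording
from .stats import (brunner_munzel, ks_test, paired_t, perm_test_bacc,
                    perm_test_mean_diff, wmw_test)
from .synthetic import CohortConfig, generate_cohort, recordings_to_manifest

__all__ = ["StudyConfig", "StudyResult", "run_study", "desk_preproc_config"]


def desk_preproc_config(cohort: CohortConfig) -> PreprocConfig:
    """Preprocessing settings matched to the desk-scale synthetic cohort.

    The chain is the clinical one; only the head-drop is shortened (10 s)
    because synthetic recordings are short and carry no settling artifacts.
    """
    return PreprocConfig(channels=tuple(cohort.channels),
                         target_sfreq=cohort.sfreq,
                         drop_head_s=10.0,
                         min_duration_s=cohort.duration_s / 2)


@dataclass
class StudyConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv_folds: int = 3
    fe_runs: int = 2
    eval_fraction: float = 0.25
    n_permutations: int = 2000
    seed: int = 0


@dataclass
class StudyResult:
    gaps: pd.DataFrame              # out-of-sample per-recording gap records
    bias_model: object
    thresholds: ThresholdPair
    findings: dict
    cv_artifacts: list
    fe_artifacts: list
    latents: list
    manifest: pd.DataFrame


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full desk-scale study; see the module docstring."""
    cohort_cfg = config.cohort
    recordings, latents = generate_cohort(cohort_cfg)
    manifest = recordings_to_manifest(recordings)
    pre_cfg = desk_preproc_config(cohort_cfg)
    preprocessed = [preprocess_recording(r, pre_cfg) for r in recordings]

    # subject-wise train / final-evaluation split
    rng = np.random.default_rng(config.seed)
    subjects = sorted({r.subject_id for r in recordings})
    perm = rng.permutation(len(subjects))
    n_eval = max(2, int(round(config.eval_fraction * len(subjects))))
    eval_set = {subjects[i] for i in perm[:n_eval]}
    tr_idx = [i for i, r in enumerate(recordings) if r.subject_id not in eval_set]
    ev_idx = [i for i, r in enumerate(recordings) if r.subject_id in eval_set]

    cv_pred, cv_art = run_cv(
        [recordings[i] for i in tr_idx], [preprocessed[i] for i in tr_idx],
        config.model, config.train, k=config.cv_folds, seed=config.seed)
    fe_pred, fe_art = run_final_evaluation(
        [recordings[i] for i in tr_idx], [preprocessed[i] for i in tr_idx],
        [recordings[i] for i in ev_idx], [preprocessed[i] for i in ev_idx],
        config.model, config.train, n_runs=config.fe_runs, seed=config.seed + 7)

    # bias model: pooled CV validation predictions of non-pathological recordings
    cv_gaps = compute_gaps(cv_pred)
    cv_np = cv_gaps[~cv_gaps["pathology"]]
    bias = fit_bias(cv_np["chronological_age"], cv_np["gap_raw"], source="cv")
    cv_gaps = apply_bias(bias, cv_gaps)
    fe_gaps = apply_bias(bias, compute_gaps(fe_pred))
    all_gaps = pd.concat([cv_gaps, fe_gaps], ignore_index=True)

    findings: dict = {}

    # decoding performance on held-out non-pathological recordings
    fe_np = fe_gaps[~fe_gaps["pathology"]]
    fe_p = fe_gaps[fe_gaps["pathology"]]
    train_np_ages = cv_np["chronological_age"].to_numpy()
    findings["fe_mae_np"] = mae(fe_np["chronological_age"], fe_np["brain_age"])
    findings["fe_r2_np"] = r2(fe_np["chronological_age"], fe_np["brain_age"])
    findings["fe_mae_p"] = (mae(fe_p["chronological_age"], fe_p["brain_age"])
                            if len(fe_p) else np.nan)
    findings["baseline_mae_np"] = mae(
        fe_np["chronological_age"],
        np.full(len(fe_np), train_np_ages.mean()))
    findings["cv_mae_np"] = mae(cv_np["chronological_age"],
                                apply_bias(bias, cv_np)["brain_age"])

    # BA vs CA (paired t) per pathology group, held-out recordings
    for name, grp in (("np", fe_np), ("p", fe_p)):
        if len(grp) >= 2:
            t, p = paired_t(grp["brain_age"], grp["chronological_age"])
            findings[f"mean_gap_{name}"] = float(grp["gap_corrected"].mean())
            findings[f"paired_t_{name}_p"] = p

    # subject-averaged gap difference NP vs P (all out-of-sample records)
    subj = subject_average_gap(all_gaps)
    gaps_np = subj.loc[~subj["pathology"], "mean_gap"].to_numpy()
    gaps_p = subj.loc[subj["pathology"], "mean_gap"].to_numpy()
    res = perm_test_mean_diff(gaps_np, gaps_p, config.n_permutations,
                              seed=config.seed + 11)
    findings["gap_diff_np_p"] = res.observed_stat
    findings["gap_diff_perm_p"] = res.p_value

    # biomarker thresholds: per CV fold, plus pooled pair for the fixed rule
    fold_pairs = []
    cv_baccs = []
    for art in cv_art:
        fold_df = cv_gaps[cv_gaps["split"] == f"cv_fold_{art['fold']}"]
        if fold_df["pathology"].nunique() == 2:
            pair_f, bacc_f = optimize_thresholds(fold_df["gap_corrected"],
                                                 fold_df["pathology"])
            fold_pairs.append(pair_f)
            cv_baccs.append(bacc_f)
    pair, cv_bacc_pooled = optimize_thresholds(cv_gaps["gap_corrected"],
                                               cv_gaps["pathology"])
    findings["cv_biomarker_bacc"] = float(np.mean(cv_baccs)) if cv_baccs else np.nan

    fe_sub = subject_average_gap(fe_gaps)
    fe_vals = fe_sub["mean_gap"].to_numpy()
    fe_labs = fe_sub["pathology"].to_numpy()
    if fe_labs.any() and (~fe_labs).any():
        fold_baccs = [bacc_of_rule(pf, fe_vals, fe_labs) for pf in fold_pairs]
        findings["fe_biomarker_bacc"] = (float(np.mean(fold_baccs))
                                         if fold_baccs else np.nan)
        res = perm_test_bacc(fe_vals, fe_labs, pair, config.n_permutations,
                             seed=config.seed + 13)
        findings["fe_biomarker_bacc_pooled"] = res.observed_stat
        findings["fe_biomarker_perm_p"] = res.p_value

        # chronological-age threshold baseline proxy
        age_cut, _ = age_threshold_proxy(cv_gaps["chronological_age"],
                                         cv_gaps["pathology"])
        age_pair = ThresholdPair(-np.inf, age_cut)
        fe_by_subj = (fe_gaps.groupby(["subject_id", "pathology"])
                      ["chronological_age"].mean().reset_index())
        findings["fe_age_proxy_bacc"] = bacc_of_rule(
            age_pair, fe_by_subj["chronological_age"], fe_by_subj["pathology"])

    # longitudinal derivatives on out-of-sample gaps
    multi = all_gaps.groupby("subject_id").filter(lambda g: len(g) >= 2)
    cats = assign_all(multi).set_index("subject_id")["category"]
    findings["derivative_counts"] = cats.value_counts().to_dict()

    rnp_rp = multi[multi["subject_id"].map(cats).isin(["RNP", "RP"])]
    rates = change_rates(rnp_rp)
    r_np = rates.loc[~rates["pathology"], "rate"].to_numpy()
    r_p = rates.loc[rates["pathology"], "rate"].to_numpy()
    if len(r_np) >= 2 and len(r_p) >= 2:
        findings["rate_ks_p"] = ks_test(r_np, r_p)[1]
        findings["rate_wmw_p"] = wmw_test(r_np, r_p)[1]
        findings["rate_bm_p"] = brunner_munzel(r_np, r_p)[1]
        findings["rate_mean_rnp"] = float(r_np.mean())
        findings["rate_mean_rp"] = float(r_p.mean())

    trans = multi[multi["subject_id"].map(cats).isin(["TNPP", "TPNP"])]
    trates = transition_rates_all(trans)
    t_np = trates.loc[trates["direction"] == "TNPP", "rate"].to_numpy()
    t_pn = trates.loc[trates["direction"] == "TPNP", "rate"].to_numpy()
    findings["n_tnpp"] = int(len(t_np))
    findings["n_tpnp"] = int(len(t_pn))
    if len(t_np) >= 2 and len(t_pn) >= 2:
        findings["transition_ks_p"] = ks_test(t_np, t_pn)[1]
        findings["transition_wmw_p"] = wmw_test(t_np, t_pn)[1]
        findings["transition_bm_p"] = brunner_munzel(t_np, t_pn)[1]
        findings["transition_mean_tnpp"] = float(t_np.mean())
        findings["transition_mean_tpnp"] = float(t_pn.mean())

    # trait structure: per-subject mean corrected gap vs planted trait offset
    trait_by_subject = {lat.subject_id: lat.trait_offset for lat in latents}
    subj_mean = all_gaps.groupby("subject_id")["gap_corrected"].mean()
    traits = np.array([trait_by_subject[s] for s in subj_mean.index])
    if np.std(traits) > 0:
        r_val, p_val = pearsonr(subj_mean.to_numpy(), traits)
        findings["trait_corr_r"] = float(r_val)
        findings["trait_corr_p"] = float(p_val)

    return StudyResult(gaps=all_gaps, bias_model=bias, thresholds=pair,
                       findings=findings, cv_artifacts=cv_art,
                       fe_artifacts=fe_art, latents=latents,
                       manifest=manifest)
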