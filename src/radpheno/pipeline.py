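"""End-to-end orchestration: phantom cohort -> features -> filtering ->
models -> three-class immunophenotype calls -> report.

Per patient, each of the four post-contrast phases is resampled to an
isotropic grid and two ROIs are
read off the shared tumor mask (whole tumor, inner 2-mm rim); a
wavelet-augmented 833-feature RFG is extracted per phase x ROI.  Features
unstable under re-segmentation (ICC(2,1) < 0.8 over the duplicate-mask
subset) are dropped per RFG, the top 50 by training-cohort AUC are kept,
and LASSO score models are fit per phase, then fused by score (SC) and by
feature (FC).  The two FC models, thresholded at their training Youden
cutoffs, drive the cascaded three-class caller evaluated on the held-out
validation cohort.

Validation patients influence nothing upstream of evaluation: ICC uses
only the duplicate-segmentation subset's features, and ranking,
standardization, penalty selection and cutoffs all see training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import extract_rfg
from .filtering import StabilityFilter, TopAucSelector
from .imaging import VolumeWithMask, crop_to_mask, peripheral_rim, resample_isotropic
from .modeling import (
    FeatureCombinedModel,
    LassoScoreModel,
    PhenotypeCaller,
    ScoreCombinedModel,
    evaluate,
    split_cohort,
)
from .stats import auc, delong_test, group_compare, holm_adjust, pearson_r
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort
from .wavelets import filter_bank

PHASES = (1, 2, 3, 4)
ROIS = ("whole", "peri")
#: margin (voxels) retained around the tumor before wavelet filtering; at
#: least the longest filter support so in-mask reconstructions are exact.
CROP_MARGIN = 8


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: cohort spec + analysis knobs."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_levels: int = 32
    target_spacing_mm: float = 1.0
    rim_mm: float = 2.0
    icc_threshold: float = 0.8
    top_k: int = 50
    cv_folds: int = 5
    split_ratio: tuple[int, int] = (3, 1)
    seed: int = 0


def extract_patient_rfgs(
    volumes: dict[str, VolumeWithMask],
    config: RunConfig,
    mask_override: np.ndarray | None = None,
) -> dict[tuple[str, int], pd.Series]:
    """All 8 RFGs (4 phases x 2 ROIs) for one patient.

    ``mask_override`` substitutes a second observer's mask (same grid as
    the stored volumes) for re-segmentation stability analysis.
    """
    out: dict[tuple[str, int], pd.Series] = {}
    for p in PHASES:
        v = volumes[f"dce{p}"]
        if mask_override is not None:
            v = v.with_mask(mask_override)
        v = resample_isotropic(v, config.target_spacing_mm)
        rim = peripheral_rim(v, config.rim_mm).mask
        vc, (rim_c,) = crop_to_mask(v, CROP_MARGIN, rim)
        bank = filter_bank(vc)
        out[("whole", p)] = extract_rfg(vc, config.n_levels, _bank=bank)
        out[("peri", p)] = extract_rfg(
            vc.with_mask(rim_c), config.n_levels, _bank=bank
        )
    return out


def extract_cohort_features(cohort: SyntheticCohort, config: RunConfig):
    """Feature tables for the whole cohort plus the duplicate-mask subset.

    Returns ``(features, repeat_features)``: dicts keyed by (roi, phase)
    holding DataFrames of 833 columns; ``repeat_features`` covers only the
    re-segmented patients, extracted with the second observer's mask.
    """
    rows: dict[tuple[str, int], dict] = {k: {} for k in _rfg_keys()}
    repeat_rows: dict[tuple[str, int], dict] = {k: {} for k in _rfg_keys()}
    for patient in cohort.iter_patients():
        rfgs = extract_patient_rfgs(patient.volumes, config)
        for k, s in rfgs.items():
            rows[k][patient.id] = s
        if patient.mask_repeat is not None:
            rfgs2 = extract_patient_rfgs(
                patient.volumes, config, mask_override=patient.mask_repeat
            )
            for k, s in rfgs2.items():
                repeat_rows[k][patient.id] = s
    features = {k: pd.DataFrame(v).T for k, v in rows.items()}
    repeat = {k: pd.DataFrame(v).T for k, v in repeat_rows.items()}
    return features, repeat


def _rfg_keys():
    return [(roi, p) for roi in ROIS for p in PHASES]


ENDPOINTS = {
    # endpoint -> (roi, positive-class rule, patient-subset rule)
    "whole": ("whole", lambda ph: ph == "inflamed", lambda ph: np.ones_like(ph, bool)),
    "peri": ("peri", lambda ph: ph == "excluded", lambda ph: ph != "inflamed"),
}


def fit_endpoint_models(
    endpoint: str,
    features: dict,
    repeat: dict,
    phenotypes: pd.Series,
    split,
    config: RunConfig,
) -> dict:
    """Fit the 6 models of one endpoint: 4 single-phase + SC + FC."""
    roi, positive, subset = ENDPOINTS[endpoint]
    ph = phenotypes
    train_ids = [i for i in split.training if subset(np.array([ph[i]]))[0]]
    y_train = positive(ph.loc[train_ids].to_numpy())
    phase_models: dict[int, LassoScoreModel] = {}
    selectors = {}
    train_tables = {}
    for p in PHASES:
        X = features[(roi, p)]
        stab = StabilityFilter(config.icc_threshold).fit(
            X.loc[repeat[(roi, p)].index], repeat[(roi, p)]
        )
        X_tr = stab.transform(X.loc[train_ids])
        sel = TopAucSelector(config.top_k).fit(X_tr, y_train)
        selectors[p] = (stab, sel)
        model = LassoScoreModel(
            cv=config.cv_folds, random_state=config.seed + p
        ).fit(sel.transform(X_tr), y_train)
        phase_models[p] = model
        train_tables[p] = features[(roi, p)].loc[train_ids]
    sc = ScoreCombinedModel(
        phase_models, cv=config.cv_folds, random_state=config.seed + 11
    ).fit(train_tables, y_train)
    fc = FeatureCombinedModel(
        phase_models, cv=config.cv_folds, random_state=config.seed + 13
    ).fit(train_tables, y_train)
    return {
        "roi": roi,
        "train_ids": train_ids,
        "phase": phase_models,
        "selectors": selectors,
        "sc": sc,
        "fc": fc,
    }


def _model_scores(endpoint_fit: dict, features: dict, ids) -> pd.DataFrame:
    """Scores of all 6 endpoint models for the given patients."""
    roi = endpoint_fit["roi"]
    tables = {p: features[(roi, p)].loc[ids] for p in PHASES}
    cols = {}
    for p, m in endpoint_fit["phase"].items():
        cols[f"RM_{p}"] = m.decision_function(tables[p])
    cols["RM_SC"] = endpoint_fit["sc"].decision_function(tables)
    cols["RM_FC"] = endpoint_fit["fc"].decision_function(tables)
    return pd.DataFrame(cols, index=list(ids))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow on a synthetic cohort; return the report.

    The report carries per-model training/validation AUCs for both
    endpoints, the validation confusion matrix / accuracy / macro-F1 of the
    cascaded caller, Holm-adjusted DeLong comparisons of each fused model
    against the single-phase models (entire cohort), score-CD8 density
    correlations, and every fitted model in serialized form.
    """
    cohort = generate_cohort(config.cohort)
    features, repeat = extract_cohort_features(cohort, config)
    ph = cohort.phenotypes
    split = split_cohort(
        cohort.ids, seed=config.seed, ratio=config.split_ratio, stratify=ph.to_numpy()
    )

    report: dict = {
        "n_patients": len(cohort),
        "training_n": len(split.training),
        "validation_n": len(split.validation),
        "class_counts": ph.value_counts().to_dict(),
        "endpoints": {},
    }
    fits = {}
    for endpoint in ("whole", "peri"):
        fit = fit_endpoint_models(endpoint, features, repeat, ph, split, config)
        fits[endpoint] = fit
        _, positive, subset = ENDPOINTS[endpoint]
        ep_report: dict = {"models": {}, "auc": {}}
        val_ids = [i for i in split.validation if subset(np.array([ph[i]]))[0]]
        all_ids = [i for i in cohort.ids if subset(np.array([ph[i]]))[0]]
        s_train = _model_scores(fit, features, fit["train_ids"])
        s_val = _model_scores(fit, features, val_ids)
        s_all = _model_scores(fit, features, all_ids)
        y_tr = positive(ph.loc[fit["train_ids"]].to_numpy())
        y_val = positive(ph.loc[val_ids].to_numpy())
        y_all = positive(ph.loc[all_ids].to_numpy())
        for col in s_train.columns:
            ep_report["auc"][col] = {
                "training": auc(s_train[col], y_tr),
                "validation": auc(s_val[col], y_val),
            }
        # fused-model vs single-phase comparisons, Holm-adjusted per family
        comparisons = []
        for fused in ("RM_SC", "RM_FC"):
            for p in PHASES:
                res = delong_test(s_all[fused], s_all[f"RM_{p}"], y_all)
                comparisons.append(
                    {
                        "a": fused,
                        "b": f"RM_{p}",
                        "auc_a": res.auc_a,
                        "auc_b": res.auc_b,
                        "z": res.z,
                        "p": res.p,
                    }
                )
        res = delong_test(s_all["RM_FC"], s_all["RM_SC"], y_all)
        comparisons.append(
            {
                "a": "RM_FC",
                "b": "RM_SC",
                "auc_a": res.auc_a,
                "auc_b": res.auc_b,
                "z": res.z,
                "p": res.p,
            }
        )
        adj = holm_adjust([c["p"] for c in comparisons])
        for c, q in zip(comparisons, adj):
            c["p_holm"] = float(q)
        ep_report["delong"] = comparisons
        for p, m in fit["phase"].items():
            ep_report["models"][f"RM_{p}"] = m.to_dict()
        ep_report["models"]["RM_SC"] = fit["sc"].to_dict()
        ep_report["models"]["RM_FC"] = fit["fc"].to_dict()
        ep_report["n_selected_per_phase"] = {
            p: len(m.selected_features_) for p, m in fit["phase"].items()
        }
        report["endpoints"][endpoint] = ep_report

    # cascaded three-class caller from the two FC models
    caller = PhenotypeCaller(fits["whole"]["fc"], fits["peri"]["fc"])
    whole_tables_tr = {
        p: features[("whole", p)].loc[fits["whole"]["train_ids"]] for p in PHASES
    }
    peri_tables_tr = {
        p: features[("peri", p)].loc[fits["whole"]["train_ids"]] for p in PHASES
    }
    caller.fit(whole_tables_tr, peri_tables_tr, ph.loc[fits["whole"]["train_ids"]])
    val_ids = split.validation
    calls = caller.predict(
        {p: features[("whole", p)].loc[val_ids] for p in PHASES},
        {p: features[("peri", p)].loc[val_ids] for p in PHASES},
    )
    ev = evaluate(calls, ph.loc[val_ids].to_numpy())
    report["caller"] = {
        "c_whole": caller.c_whole_,
        "c_peri": caller.c_peri_,
        "validation_accuracy": ev["accuracy"],
        "validation_macro_f1": ev["macro_f1"],
        "f1_per_class": ev["f1_per_class"],
        "confusion": ev["confusion"].to_numpy().tolist(),
        "confusion_labels": ev["labels"],
    }

    # score vs generated CD8 density, entire cohort; a degenerate
    # (constant-score) fused model has no association by definition
    whole_all = _model_scores(fits["whole"], features, cohort.ids)["RM_FC"]
    peri_all = _model_scores(fits["peri"], features, cohort.ids)["RM_FC"]

    def _safe_pearson(scores, dens):
        if np.var(np.asarray(scores, dtype=float)) == 0:
            return 0.0, 1.0
        return pearson_r(scores, dens)

    r_c, p_c = _safe_pearson(whole_all, cohort.table["cd8_central"])
    r_p, p_p = _safe_pearson(peri_all, cohort.table["cd8_peripheral"])
    report["cd8_correlation"] = {
        "whole_fc_vs_central": {"r": r_c, "p": p_c},
        "peri_fc_vs_peripheral": {"r": r_p, "p": p_p},
    }
    report["split"] = {
        "training": list(split.training),
        "validation": list(split.validation),
    }
    report["_fits"] = fits  # live model objects, stripped on serialization
    return report


def fused_auc_on_held_out(
    features: dict,
    repeat: dict,
    phenotypes: pd.Series,
    config: RunConfig,
    n_replicates: int = 12,
    subset_size: int = 90,
    seed: int = 0,
    permute_labels: bool = True,
) -> list[dict]:
    """Overfitting guard: fit the full modeling chain on random patient
    subsets and score the fused models on the held-out remainder.

    Each replicate draws a fresh subset, optionally permutes the phenotype
    labels (exchangeable on a null cohort), runs the standard 3:1 split +
    filtering + LASSO + fusion protocol inside the subset, and reports the
    feature-combined models' AUC on the patients the replicate never saw.
    On cohorts generated with zero phenotype effects these AUCs measure
    pure overfitting leakage and should hover around 0.5.
    """
    rng = np.random.default_rng(seed)
    ids = list(phenotypes.index)
    out = []
    for k in range(n_replicates):
        labels = phenotypes
        if permute_labels:
            labels = pd.Series(rng.permutation(phenotypes.to_numpy()), index=ids)
        subset = [ids[i] for i in rng.choice(len(ids), subset_size, replace=False)]
        split = split_cohort(
            subset, seed=seed * 100 + k, stratify=labels.loc[subset].to_numpy()
        )
        external = [i for i in ids if i not in set(subset)]
        rep_aucs = {}
        for endpoint in ("whole", "peri"):
            fit = fit_endpoint_models(endpoint, features, repeat, labels, split, config)
            roi, positive, subset_rule = ENDPOINTS[endpoint]
            ext = [i for i in external if subset_rule(np.array([labels[i]]))[0]]
            y_ext = positive(labels.loc[ext].to_numpy())
            tables = {p: features[(roi, p)].loc[ext] for p in PHASES}
            rep_aucs[endpoint] = auc(fit["fc"].decision_function(tables), y_ext)
        out.append(rep_aucs)
    return out


def apply_to_external_cohort(
    whole_fc: FeatureCombinedModel,
    peri_fc: FeatureCombinedModel,
    whole_tables: dict[int, pd.DataFrame],
    peri_tables: dict[int, pd.DataFrame],
    group=None,
) -> dict:
    """Score an external cohort's feature tables with the fused models.

    When a binary/categorical ``group`` (e.g. pathologic complete response)
    is supplied, each score is compared across groups.  Feature tables must
    contain every model feature; missing columns are reported by name.
    """
    for model, tables, label in (
        (whole_fc, whole_tables, "whole"),
        (peri_fc, peri_tables, "peri"),
    ):
        for p, feats in _required_features(model).items():
            missing = sorted(set(feats) - set(tables[p].columns))
            if missing:
                raise ValueError(
                    f"{label} tables for phase {p} are missing model features: "
                    f"{missing}"
                )
    index = whole_tables[1].index
    scores = pd.DataFrame(
        {
            "whole_fc_score": whole_fc.decision_function(whole_tables),
            "peri_fc_score": peri_fc.decision_function(peri_tables),
        },
        index=index,
    )
    out = {"scores": scores}
    if group is not None:
        out["group_comparison"] = {
            col: group_compare(scores[col].to_numpy(), np.asarray(group))
            for col in scores.columns
        }
    return out


def _required_features(model: FeatureCombinedModel) -> dict[int, set]:
    req: dict[int, set] = {}
    for k, f in model.pooled_features:
        req.setdefault(k, set()).add(f)
    for k, m in model.phase_models.items():
        req.setdefault(k, set()).update(m.feature_names_in_)
    return req
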