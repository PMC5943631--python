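"""End-to-end composition: synthesis -> protocol -> calibration -> agreement
-> classification, with all artifacts written under an output directory.

The run is a pure function of its configuration (which embeds the seed):
identical config and seed give identical artifacts.  Intermediate results
are returned as objects so each stage remains individually inspectable; the
``summary`` dict is the JSON-shaped machine output.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._version import __version__
from .agreement import AgreementReport, Improvement, bland_altman, improvement_metrics, validity_check
from .calibrate import CalibrationModel, JackknifeResult, apply_calibration, calibrate_pairs, pairs_to_arrays
from .classify import MethodThresholdReport, method_comparison
from .core import Arm, BPReading, Channel, Method, Site, Stage
from .io import (
    RunConfig,
    config_to_dict,
    write_cohort,
    write_method_report,
    write_models,
    write_pairs_table,
    write_readings,
    write_screen_report,
)
from .protocol import (
    EligibilityDecision,
    ScreenDecision,
    SimultaneousPair,
    assemble_day2_pairs,
    bilateral_equality_screen,
    eligibility_filter,
)
from .synth import StudyDataset, hypertension_prevalence, simulate_cohort, simulate_study, biased_method_readings

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    config: RunConfig
    dataset: StudyDataset
    eligibility: list[EligibilityDecision]
    screening: list[ScreenDecision]
    pairs: dict[Site, list[SimultaneousPair]]
    jackknife: dict[Site, dict[Channel, JackknifeResult]]
    agreement_pre: dict[Site, dict[Channel, AgreementReport]]
    agreement_post: dict[Site, dict[Channel, AgreementReport]]
    improvements: dict[Site, dict[Channel, Improvement]]
    independent_pre: dict[Channel, AgreementReport] = field(default_factory=dict)
    independent_post: dict[Channel, AgreementReport] = field(default_factory=dict)
    independent_improvements: dict[Channel, Improvement] = field(default_factory=dict)
    classification: list[MethodThresholdReport] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _report_dict(report: AgreementReport) -> dict:
    return {
        "n": report.n,
        "signed_mean_difference": report.signed_mean_difference,
        "absolute_mean_difference": report.absolute_mean_difference,
        "sd_signed": report.sd_signed,
        "sd_absolute": report.sd_absolute,
        "limits_of_agreement": list(report.limits_of_agreement),
        "paired_p": report.paired_p,
        "within_threshold_fraction": report.within_threshold_fraction,
        "threshold": report.threshold,
        "trend_slope": report.trend_slope,
        "valid": validity_check(report)
        if not math.isnan(report.within_threshold_fraction)
        else None,
    }


def _model_dict(m: CalibrationModel) -> dict:
    return {
        "channel": m.channel.value,
        "intercept": m.intercept,
        "slope": m.slope,
        "reference_site": None if m.reference_site is None else m.reference_site.value,
        "n_training": m.n_training,
        "family": m.family,
    }


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Execute the full calibration-and-validation analysis.

    Stages: simulate the cohort and the two-day study; apply eligibility and
    the bilateral equality screen; assemble simultaneous pairs (conditioning
    readings discarded); Bland-Altman before calibration; jackknife
    calibration against each intra-arterial site with held-out evaluation;
    Bland-Altman after; improvement metrics; the same pre/post comparison on
    the independent auscultatory set using the deployed central (aortic)
    model; and guideline-threshold classification with treatment gap and
    one-tailed Fisher exact against the direct aortic reference.
    """
    config = config or RunConfig()
    root = np.random.SeedSequence(config.seed)
    s_cohort, s_study, s_upper = root.spawn(3)

    # --- synthesis -------------------------------------------------------
    cohort = simulate_cohort(config.n_patients, config.cohort, seed=s_cohort)
    dataset = simulate_study(cohort, config.protocol, config.device, seed=s_study)

    # --- protocol --------------------------------------------------------
    eligibility = [eligibility_filter(p) for p in cohort]
    eligible_ids = {e.patient_id for e in eligibility if e.eligible}
    screening: list[ScreenDecision] = []
    passing_ids: list[str] = []
    for profile in cohort:
        if profile.patient_id not in eligible_ids:
            continue
        arms = dataset.day1_screen_readings(profile.patient_id)
        decision = bilateral_equality_screen(arms[Arm.LEFT], arms[Arm.RIGHT])
        screening.append(decision)
        if decision.passed:
            passing_ids.append(profile.patient_id)

    pairs: dict[Site, list[SimultaneousPair]] = {Site.RADIAL: [], Site.AORTA: []}
    for pid in passing_ids:
        radial, aortic = assemble_day2_pairs(
            dataset.day2_session(pid),
            n_pairs_per_site=config.protocol.n_pairs_per_site,
            n_conditioning=config.protocol.n_conditioning,
        )
        pairs[Site.RADIAL].extend(radial)
        pairs[Site.AORTA].extend(aortic)

    # --- calibration + agreement ----------------------------------------
    jackknife: dict[Site, dict[Channel, JackknifeResult]] = {}
    agreement_pre: dict[Site, dict[Channel, AgreementReport]] = {}
    agreement_post: dict[Site, dict[Channel, AgreementReport]] = {}
    improvements: dict[Site, dict[Channel, Improvement]] = {}
    for site in (Site.RADIAL, Site.AORTA):
        site_pairs = pairs[site]
        jackknife[site] = calibrate_pairs(site_pairs, family=config.calibration_family)
        agreement_pre[site] = {}
        agreement_post[site] = {}
        improvements[site] = {}
        for channel in Channel:
            dev, ref = pairs_to_arrays(site_pairs, channel)
            pre = bland_altman(dev, ref, channel, test=config.paired_test_kind)
            jk = jackknife[site][channel]
            post = bland_altman(
                jk.calibrated, jk.reference, channel, test=config.paired_test_kind
            )
            agreement_pre[site][channel] = pre
            agreement_post[site][channel] = post
            improvements[site][channel] = improvement_metrics(pre, post)

    # --- independent auscultatory set ------------------------------------
    independent_pre: dict[Channel, AgreementReport] = {}
    independent_post: dict[Channel, AgreementReport] = {}
    independent_improvements: dict[Channel, Improvement] = {}
    ind = dataset.independent_readings
    if ind:
        wrist = {(r.patient_id, r.order_index): r for r in ind if r.method is Method.WRIST_CUFF}
        ausc = {
            (r.patient_id, r.order_index): r
            for r in ind
            if r.method is Method.UPPER_ARM_AUSCULTATORY
        }
        keys = sorted(set(wrist) & set(ausc))
        sys_model = jackknife[Site.AORTA][Channel.SYSTOLIC].deployed
        dia_model = jackknife[Site.AORTA][Channel.DIASTOLIC].deployed
        calibrated = [apply_calibration(wrist[k], sys_model, dia_model) for k in keys]
        for channel in Channel:
            raw = np.array([wrist[k].pressure(channel) for k in keys])
            ref = np.array([ausc[k].pressure(channel) for k in keys])
            cal = np.array([r.pressure(channel) for r in calibrated])
            pre = bland_altman(raw, ref, channel, test=config.paired_test_kind)
            post = bland_altman(cal, ref, channel, test=config.paired_test_kind)
            independent_pre[channel] = pre
            independent_post[channel] = post
            independent_improvements[channel] = improvement_metrics(pre, post)

    # --- classification ---------------------------------------------------
    aortic_pairs = pairs[Site.AORTA]
    refs = [p.reference for p in aortic_pairs]
    wrist_raw = [p.wrist for p in aortic_pairs]
    sys_model = jackknife[Site.AORTA][Channel.SYSTOLIC].deployed
    dia_model = jackknife[Site.AORTA][Channel.DIASTOLIC].deployed
    wrist_cal = [apply_calibration(r, sys_model, dia_model) for r in wrist_raw]
    upper_arm = biased_method_readings(refs, config.upper_arm, seed=s_upper)
    classification = method_comparison(
        {
            "intra_aortic": refs,
            "wrist_raw": wrist_raw,
            "wrist_calibrated_central": wrist_cal,
            "upper_arm": upper_arm,
        },
        "intra_aortic",
        config.threshold_sets,
        by=config.classification_by,
    )

    # --- summary ----------------------------------------------------------
    n_intra = sum(len(v) for v in pairs.values())
    summary = {
        "package": "wristbp",
        "version": __version__,
        "seed": config.seed,
        "n_patients": len(cohort),
        "n_eligible": len(eligible_ids),
        "n_screen_passed": len(passing_ids),
        "hypertension_prevalence": hypertension_prevalence(cohort),
        # schedule bookkeeping: each patient contributes 4 intra-arterial
        # readings; counting systolic and diastolic channels separately
        # doubles the tally.
        "n_intra_arterial_readings": n_intra,
        "n_intra_arterial_channel_values": 2 * n_intra,
        "agreement": {
            site.value: {
                channel.value: {
                    "pre": _report_dict(agreement_pre[site][channel]),
                    "post": _report_dict(agreement_post[site][channel]),
                    "improvement": {
                        "accuracy_improvement": improvements[site][channel].accuracy_improvement,
                        "variability_reduction": improvements[site][channel].variability_reduction,
                        "accuracy_improvement_rounded": improvements[site][channel].accuracy_improvement_rounded,
                        "variability_reduction_rounded": improvements[site][channel].variability_reduction_rounded,
                    },
                    "deployed_model": _model_dict(jackknife[site][channel].deployed),
                }
                for channel in Channel
            }
            for site in (Site.RADIAL, Site.AORTA)
        },
        "independent": {
            channel.value: {
                "pre": _report_dict(independent_pre[channel]),
                "post": _report_dict(independent_post[channel]),
                "improvement": {
                    "accuracy_improvement": independent_improvements[channel].accuracy_improvement,
                    "variability_reduction": independent_improvements[channel].variability_reduction,
                    "accuracy_improvement_rounded": independent_improvements[channel].accuracy_improvement_rounded,
                    "variability_reduction_rounded": independent_improvements[channel].variability_reduction_rounded,
                },
            }
            for channel in independent_pre
        },
        "classification": [
            {
                "method": r.method,
                "threshold_set": r.threshold_set,
                "n": r.n,
                "positives_method": r.positives_method,
                "positives_reference": r.positives_reference,
                "sensitivity": r.sensitivity,
                "treatment_gap": r.treatment_gap,
                "fisher_p": r.fisher_p,
            }
            for r in classification
        ],
    }

    result = PipelineResult(
        config=config,
        dataset=dataset,
        eligibility=eligibility,
        screening=screening,
        pairs=pairs,
        jackknife=jackknife,
        agreement_pre=agreement_pre,
        agreement_post=agreement_post,
        improvements=improvements,
        independent_pre=independent_pre,
        independent_post=independent_post,
        independent_improvements=independent_improvements,
        classification=classification,
        summary=summary,
    )

    if config.output_dir is not None:
        _write_artifacts(result, Path(config.output_dir))
    return result


def _write_plot_data(report_pairs, path) -> None:
    """Per-pair (mean, difference) table for external Bland-Altman plotting."""
    import csv

    a, b = report_pairs
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mean", "difference"])
        for ai, bi in zip(a, b):
            w.writerow([f"{(ai + bi) / 2:.10g}", f"{ai - bi:.10g}"])


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(result.dataset.cohort, outdir / "cohort.csv")
    write_readings(result.dataset.readings, outdir / "readings.csv")
    if result.dataset.independent_readings:
        write_readings(result.dataset.independent_readings, outdir / "independent_readings.csv")
    write_screen_report(result.screening, outdir / "screening.csv")
    artifacts = ["cohort.csv", "readings.csv", "screening.csv"]
    for site, site_pairs in result.pairs.items():
        name = f"pairs_{site.value}.csv"
        write_pairs_table(site_pairs, outdir / name)
        artifacts.append(name)
        for channel in Channel:
            jk = result.jackknife[site][channel]
            pname = f"bland_altman_{site.value}_{channel.value}_post.csv"
            _write_plot_data((jk.calibrated, jk.reference), outdir / pname)
            artifacts.append(pname)
            dev, ref = pairs_to_arrays(site_pairs, channel)
            pname = f"bland_altman_{site.value}_{channel.value}_pre.csv"
            _write_plot_data((dev, ref), outdir / pname)
            artifacts.append(pname)
    models = [
        result.jackknife[site][channel].deployed
        for site in result.jackknife
        for channel in result.jackknife[site]
    ]
    write_models(models, outdir / "models.json")
    write_method_report(result.classification, outdir / "classification.csv")
    artifacts += ["models.json", "classification.csv", "summary.json"]
    (outdir / "summary.json").write_text(json.dumps(result.summary, indent=2) + "\n")
    manifest = {
        "package": "wristbp",
        "version": __version__,
        "seed": result.config.seed,
        "config": config_to_dict(result.config),
        "artifacts": sorted(artifacts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
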