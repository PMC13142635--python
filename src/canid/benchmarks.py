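"""Headline summary quantities for a fully scored battery dataset.

Given a merged measures + covariates table (the format produced by the
``canid score`` stage joined to sessions and dogs), this module runs the
standard analysis and collects the quantities usually reported when the
battery is evaluated on a real cohort: overall-component loadings and
variance share, the three ICC flavors for the overall score, the
timepoint (practice) coefficients of the aging model for the overall and
task scores, and the age likelihood-ratio test with its variance-explained
effect size.  It is the entry point for checking the package against a
deposited dataset, and is exercised on simulated cohorts everywhere else.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import aging as aging_mod
from . import repeatability as repeat_mod
from .composite import CanidScorer


def benchmark_report(merged: pd.DataFrame, seed: int = 0,
                     n_boot: int = 0) -> dict:
    """Fit the baseline scoring model, project all sessions, and summarize.

    Parameters
    ----------
    merged : DataFrame
        One row per (dog, timepoint) with the raw measures columns plus
        ``test_age_years``, ``sex``, ``location``.
    seed : int
        Seed for imputation draws and bootstrap intervals.
    n_boot : int
        Bootstrap replicates for ICC intervals (0 disables intervals).
    """
    baseline = merged[merged["timepoint"] == "baseline"]
    scorer = CanidScorer(random_state=seed).fit(baseline)
    scores = scorer.transform(merged)

    report = {
        "overall_loadings": {
            task: float(v) for task, v in
            zip(scorer.overall_pca_.input_names, scorer.overall_pca_.loadings)
        },
        "overall_pc1_var_share": scorer.overall_pca_.explained_var_ratio,
    }

    builder = lambda sub: aging_mod.build_design(sub)[0]  # noqa: E731
    sub = repeat_mod.usable_scores(scores, "overall_score")
    adj = repeat_mod.model_icc(scores, "overall_score",
                               covariates=builder(sub), seed=seed,
                               n_boot=n_boot)
    unadj = repeat_mod.model_icc(scores, "overall_score", seed=seed,
                                 n_boot=n_boot)
    report["icc_adjusted"] = adj.estimate
    report["icc_intercept_only"] = unadj.estimate
    for t1, t2 in (("baseline", "m6"), ("baseline", "m12"), ("m6", "m12")):
        try:
            r = repeat_mod.pairwise_icc(scores, t1, t2, "overall_score",
                                        seed=seed, n_boot=n_boot)
            report[f"icc_{t1}_{t2}"] = r.estimate
        except Exception:
            report[f"icc_{t1}_{t2}"] = float("nan")

    fit = aging_mod.fit_aging_model(scores, "overall_score")
    eff = aging_mod.age_effect_size(scores, "overall_score", fit=fit)
    report["overall_m6_b"] = float(fit.params.loc["tp_m6", "estimate"])
    report["overall_m12_b"] = float(fit.params.loc["tp_m12", "estimate"])
    report["age_lrt_chi2"] = eff.lrt_chi2
    report["age_partial_r2"] = eff.partial_r2
    report["age_cohens_f2"] = eff.cohens_f2
    for measure, key in (("sr_score", "sr"), ("ds_score", "ds"),
                         ("cyl_score", "cyl")):
        tfit = aging_mod.fit_aging_model(scores, measure)
        report[f"{key}_m6_b"] = float(tfit.params.loc["tp_m6", "estimate"])
        report[f"{key}_m12_b"] = float(tfit.params.loc["tp_m12", "estimate"])
    report["scores"] = scores
    return report
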