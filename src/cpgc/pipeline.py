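"""End-to-end orchestration: prep -> fit -> surrogate null -> Fisher ->
masked group contrast -> behavior and motion QC correlations.

These helpers wire the module-level operations together in the canonical
order for whole cohorts; the command-line interface and the analysis
scripts are thin layers over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defaults import DEFAULTS
from .group import (GroupDiffResult, behavior_correlations,
                    masked_group_difference, qc_motion_correlation)
from .mvar import cpgc_from_model, fit_mmvar
from .signal_prep import (bandpass_array, framewise_displacement, linear_drift,
                          regress_nuisance_array, standardize_array)
from .simulate import GROUPS, Cohort
from .surrogate import (PathInference, build_null, classify_paths,
                        empirical_p_matrix, fisher_combine_matrix)


STUDY_BAND = (DEFAULTS["band_low"], DEFAULTS["band_high"])


def prep_subject(data: np.ndarray, tr: float,
                 motion: np.ndarray | None = None,
                 nuisance: np.ndarray | None = None,
                 band: tuple[float, float] | None = STUDY_BAND,
                 global_signal: bool | None = None,
                 global_series: np.ndarray | None = None) -> np.ndarray:
    """Band-pass, regress nuisance columns, standardize — in that order.

    ``band=None`` skips temporal filtering entirely (appropriate for signals
    that are broadband by construction: an ideal narrow band-pass leaves an
    autoregressive design nearly collinear and is known to distort
    causality estimates).  Confounds are the 6 motion parameters, a linear
    drift term, any supplied tissue (WM/CSF) columns, and — only when
    ``global_signal`` is on — ``global_series`` (the measured whole-brain
    average) or, lacking one, the mean of the ROI columns.  The fallback is
    only a reasonable proxy when k is large; at small k the column mean is
    exactly collinear with the ROI set.  Global-signal regression is off by
    default, matching the primary analysis.
    """
    if global_signal is None:
        global_signal = DEFAULTS["global_signal_regression"]
    x = np.asarray(data, dtype=float)
    if band is not None:
        x = bandpass_array(x, tr, *band)
    conf = [linear_drift(x.shape[0])[:, None]]
    if motion is not None:
        conf.append(np.asarray(motion, dtype=float))
    if nuisance is not None:
        conf.append(np.asarray(nuisance, dtype=float))
    if global_signal:
        g = (np.asarray(global_series, dtype=float)[:, None]
             if global_series is not None else x.mean(axis=1, keepdims=True))
        conf.append(g)
    x = regress_nuisance_array(x, np.concatenate(conf, axis=1))
    return standardize_array(x)


@dataclass
class WithinGroupResult:
    """Observed CPGC, per-subject empirical p and combined inference."""

    cpgc: np.ndarray          # (n_subjects, k, k)
    subject_p: np.ndarray     # (n_subjects, k, k)
    fisher_stat: np.ndarray   # (k, k)
    fisher_p: np.ndarray      # (k, k)
    inference: PathInference


def within_group_inference(prepped: list[np.ndarray], order: int,
                           n_surrogates: int, rng: np.random.Generator,
                           alpha: float = 0.01,
                           zero_lag: bool = True) -> WithinGroupResult:
    """Subject-level surrogate testing combined across a group.

    Each subject's observed CPGC is ranked within that subject's own
    surrogate null (respecting subject-specific spectra); per-path p-values
    are combined across subjects with Fisher's method and thresholded.
    """
    cpgc_stack, p_stack = [], []
    for X in prepped:
        model = fit_mmvar(X, order, zero_lag=zero_lag)
        obs = cpgc_from_model(model)
        null = build_null(X, order, n_surrogates, rng, zero_lag=zero_lag)
        cpgc_stack.append(obs)
        p_stack.append(empirical_p_matrix(obs, null))
    cpgc_stack = np.stack(cpgc_stack)
    p_stack = np.stack(p_stack)
    stat, p = fisher_combine_matrix(p_stack)
    return WithinGroupResult(cpgc_stack, p_stack, stat, p,
                             classify_paths(p, alpha, stat))


@dataclass
class CohortAnalysis:
    within: dict                      # group -> WithinGroupResult
    diff: GroupDiffResult
    behavior: pd.DataFrame
    qc: dict                          # group -> motion-correlation table
    mean_fd: pd.DataFrame


def analyze_cohort(cohort: Cohort, order: int | None = None,
                   n_surrogates: int = 500,
                   alpha_within: float | None = None,
                   alpha_between: float | None = None,
                   band: tuple[float, float] | None = STUDY_BAND,
                   global_signal: bool | None = None,
                   seed: int = 0,
                   zero_lag: bool = True) -> CohortAnalysis:
    """Run the full within- and between-group analysis on a cohort.

    The atrophy covariate from the cohort metadata enters the per-path
    ANCOVA; behavior correlations are computed, within the patient group,
    only for paths surviving the masked contrast.
    """
    order = DEFAULTS["model_order"] if order is None else order
    alpha_within = DEFAULTS["alpha_within"] if alpha_within is None else alpha_within
    alpha_between = DEFAULTS["alpha_between"] if alpha_between is None else alpha_between
    rng = np.random.default_rng(np.random.SeedSequence([seed, cohort.seed]))

    within, fds = {}, []
    for g in GROUPS:
        prepped = []
        for sub in cohort.subjects[g]:
            prepped.append(prep_subject(sub.series.data, sub.series.tr,
                                        sub.motion, sub.nuisance, band,
                                        global_signal, sub.global_proxy))
            fds.append({"subject_id": sub.subject_id, "group": g,
                        "mean_fd": framewise_displacement(sub.motion).mean_fd})
        within[g] = within_group_inference(prepped, order, n_surrogates, rng,
                                           alpha_within, zero_lag)
    mean_fd = pd.DataFrame(fds)

    meta = cohort.meta
    cov = np.r_[meta.loc[meta.group == "patient", "atrophy"].to_numpy(float),
                meta.loc[meta.group == "control", "atrophy"].to_numpy(float)]
    diff = masked_group_difference(within["patient"].cpgc,
                                   within["control"].cpgc,
                                   within["patient"].inference,
                                   within["control"].inference,
                                   covariate=cov, alpha=alpha_between)

    score_cols = [c for c in ("MMSE", "CVLT_immediate", "CVLT_short",
                              "CVLT_long", "CDT") if c in meta.columns]
    paths = diff.increased + diff.decreased
    pat_scores = meta.loc[meta.group == "patient", score_cols].reset_index(drop=True)
    behavior = behavior_correlations(within["patient"].cpgc, paths, pat_scores) \
        if paths and score_cols else pd.DataFrame(
            columns=["target", "source", "measure", "r", "p", "n"])

    qc = {}
    for g in GROUPS:
        fd_g = mean_fd.loc[mean_fd.group == g, "mean_fd"].to_numpy(float)
        qc[g] = qc_motion_correlation(fd_g, within[g].cpgc)
    return CohortAnalysis(within, diff, behavior, qc, mean_fd)
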