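"""Between-group contrasts, behavior correlations and demographic tests.

The group contrast per directed path is a one-way ANOVA with a scalar
gray-matter atrophy covariate (i.e. an ANCOVA on a 0/1 group code, no
interaction term).  Paths significant between groups are intersected with
the within-group significance masks: "increased" paths must also be
significant within the patient group, "decreased" paths within the control
group.  Behavior correlations are plain Pearson r between path strength and
neuropsychological scores; motion QC correlates per-subject mean framewise
displacement with every path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .surrogate import PathInference


class GroupAnalysisError(ValueError):
    pass


_COVARIATE_VAR_TOL = 1e-12


def _group_lm(Y: np.ndarray, group: np.ndarray,
              covariate: np.ndarray | None):
    """Vectorized OLS of each column of Y on [1, group, covariate].

    Returns (coef, F, p) for the group effect, each of shape (n_paths,).
    A covariate with (near-)zero variance is dropped, which reduces the
    model to a plain one-way ANOVA.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T if Y.shape[1] > 1 else Y
    n = Y.shape[0]
    g = np.asarray(group, dtype=float)
    if g.shape[0] != n:
        raise GroupAnalysisError("group labels do not match number of subjects")
    if len(np.unique(g)) != 2:
        raise GroupAnalysisError("exactly two groups are required")
    cols = [np.ones(n), g]
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if not np.all(np.isfinite(c)):
            raise GroupAnalysisError("covariate contains non-finite values")
        if np.var(c) > _COVARIATE_VAR_TOL:
            cols.append(c)
    X = np.column_stack(cols)
    q = X.shape[1]
    dof = n - q
    if dof < 1:
        raise GroupAnalysisError("not enough subjects for the model")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y                       # (q, n_paths)
    resid = Y - X @ B
    sigma2 = (resid ** 2).sum(axis=0) / dof
    if np.any(sigma2 <= 0):
        raise GroupAnalysisError("degenerate model: zero residual variance "
                                 "(constant path values?)")
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    t = B[1] / se
    F = t ** 2
    p = stats.f.sf(F, 1, dof)
    return B[1], F, p


@dataclass
class AncovaResult:
    f: float
    p: float
    direction: int      # +1 patient > control, -1 control > patient
    coef: float


def ancova_path(values: np.ndarray, group: np.ndarray,
                covariate: np.ndarray | None = None) -> AncovaResult:
    """Group contrast for one path: value ~ intercept + group + covariate.

    ``group`` is 0/1 with 1 = patient; the reported F is the group effect
    (equivalently t^2) and ``direction`` the sign of the group coefficient.
    """
    coef, F, p = _group_lm(np.asarray(values, dtype=float)[:, None],
                           group, covariate)
    return AncovaResult(float(F[0]), float(p[0]),
                        int(np.sign(coef[0])) or 0, float(coef[0]))


@dataclass
class GroupDiffResult:
    """Masked between-group contrast over all directed paths.

    ``increased`` are paths with patient > control at ``alpha`` that are also
    within-patient significant; ``decreased`` are control > patient paths
    that are within-control significant.  Matrix convention throughout:
    entry (i, j) is the path j -> i.
    """

    f: np.ndarray
    p: np.ndarray
    coef: np.ndarray
    alpha: float
    increased: list[tuple[int, int]]
    decreased: list[tuple[int, int]]

    def to_edges(self, labels=None) -> pd.DataFrame:
        k = self.p.shape[0]
        labels = labels or [str(i) for i in range(k)]
        rows = []
        for sign, paths in (("increased", self.increased),
                            ("decreased", self.decreased)):
            for (i, j) in paths:
                rows.append({"source": labels[j], "target": labels[i],
                             "contrast": sign, "F": self.f[i, j],
                             "p": self.p[i, j]})
        return pd.DataFrame(rows, columns=["source", "target", "contrast", "F", "p"])


def masked_group_difference(cpgc_patient: np.ndarray,
                            cpgc_control: np.ndarray,
                            within_patient: PathInference,
                            within_control: PathInference,
                            covariate: np.ndarray | None = None,
                            alpha: float = 0.01) -> GroupDiffResult:
    """ANCOVA per path, masked by the within-group significant paths.

    ``cpgc_patient``/``cpgc_control`` are (n_subjects, k, k) stacks whose ROI
    order must agree; ``covariate`` is one scalar per subject, patients
    first then controls (or None).
    """
    P = np.asarray(cpgc_patient, dtype=float)
    C = np.asarray(cpgc_control, dtype=float)
    if P.ndim != 3 or C.ndim != 3 or P.shape[1:] != C.shape[1:]:
        raise GroupAnalysisError("misaligned CPGC stacks (check ROI order)")
    k = P.shape[1]
    if within_patient.p.shape != (k, k) or within_control.p.shape != (k, k):
        raise GroupAnalysisError("within-group inference does not match ROI count")
    n1, n2 = P.shape[0], C.shape[0]
    if min(n1, n2) < 2:
        raise GroupAnalysisError("each group needs at least 2 subjects")
    group = np.r_[np.ones(n1), np.zeros(n2)]
    Y = np.concatenate([P, C], axis=0).reshape(n1 + n2, k * k)
    off = ~np.eye(k, dtype=bool).ravel()
    coef = np.zeros(k * k)
    F = np.zeros(k * k)
    p = np.ones(k * k)
    coef[off], F[off], p[off] = _group_lm(Y[:, off], group, covariate)
    coef, F, p = (a.reshape(k, k) for a in (coef, F, p))

    sig = (p < alpha) & ~np.eye(k, dtype=bool)
    inc = sig & (coef > 0) & within_patient.significant
    dec = sig & (coef < 0) & within_control.significant
    increased = [tuple(ix) for ix in np.argwhere(inc)]
    decreased = [tuple(ix) for ix in np.argwhere(dec)]
    return GroupDiffResult(F, p, coef, float(alpha), increased, decreased)


# ---------------------------------------------------------------------------
# correlations

@dataclass
class BehaviorCorrelation:
    path: tuple[int, int]
    measure: str
    r: float
    p: float
    n: int


def behavior_correlation(values: np.ndarray, scores: np.ndarray,
                         path: tuple[int, int] = (-1, -1),
                         measure: str = "") -> BehaviorCorrelation:
    """Pearson r between per-subject path strength and a behavioral score.

    Two-sided p from the exact t transform with n - 2 degrees of freedom.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(scores, dtype=float)
    if v.shape != s.shape or v.ndim != 1:
        raise GroupAnalysisError("values and scores must be equal-length vectors")
    if v.size < 3:
        raise GroupAnalysisError("need at least 3 subjects")
    if not np.all(np.isfinite(s)):
        raise GroupAnalysisError("scores contain non-finite values")
    res = stats.pearsonr(v, s)
    return BehaviorCorrelation(tuple(path), measure,
                               float(res.statistic), float(res.pvalue), v.size)


def behavior_correlations(cpgc: np.ndarray, paths, scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations for each (path x score column) combination."""
    rows = []
    for (i, j) in paths:
        vals = cpgc[:, i, j]
        for col in scores.columns:
            bc = behavior_correlation(vals, scores[col].to_numpy(), (i, j), col)
            rows.append({"target": i, "source": j, "measure": col,
                         "r": bc.r, "p": bc.p, "n": bc.n})
    return pd.DataFrame(rows, columns=["target", "source", "measure", "r", "p", "n"])


def qc_motion_correlation(mean_fds: np.ndarray,
                          path_values: np.ndarray) -> pd.DataFrame:
    """Mean-FD vs CPGC Pearson correlation for every directed path.

    Constant FD across subjects makes r undefined: the whole table is
    returned flagged (``defined`` False) rather than raising.
    """
    fd = np.asarray(mean_fds, dtype=float)
    V = np.asarray(path_values, dtype=float)
    if V.ndim != 3 or V.shape[0] != fd.shape[0]:
        raise GroupAnalysisError("path_values must be (n_subjects, k, k)")
    k = V.shape[1]
    fd_defined = np.std(fd) > 0
    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if not fd_defined or np.std(V[:, i, j]) == 0:
                rows.append({"target": i, "source": j, "r": np.nan,
                             "p": np.nan, "defined": False})
                continue
            res = stats.pearsonr(fd, V[:, i, j])
            rows.append({"target": i, "source": j, "r": float(res.statistic),
                         "p": float(res.pvalue), "defined": True})
    return pd.DataFrame(rows, columns=["target", "source", "r", "p", "defined"])


# ---------------------------------------------------------------------------
# demographic summary tests

def summary_stat_ttest(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       equal_var: bool = True) -> tuple[float, float]:
    """Two-sample two-tailed t-test from summary statistics.

    Pooled-variance (Student) by default; Welch with ``equal_var=False``.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise GroupAnalysisError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise GroupAnalysisError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def contingency_chi2(table: np.ndarray,
                     continuity: bool | None = None) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, two-tailed.

    Yates continuity correction is applied automatically when any expected
    count is below 5 (pass ``continuity`` to force either behavior).  Tables
    with a zero margin have undefined expected counts and are rejected.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise GroupAnalysisError("expected a 2x2 table of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise GroupAnalysisError("zero margin: expected counts undefined")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if continuity is None:
        continuity = bool(np.any(expected < 5))
    chi2, p, _, _ = stats.chi2_contingency(t, correction=continuity)
    return float(chi2), float(p)


def demographics_table(meta: pd.DataFrame,
                       numeric_cols=("age", "MMSE", "CVLT_immediate",
                                     "CVLT_short", "CVLT_long", "CDT")) -> pd.DataFrame:
    """Group mean+-SD and test p per metadata column (t-test; chi2 for sex)."""
    pat = meta[meta["group"] == "patient"]
    con = meta[meta["group"] == "control"]
    rows = []
    if "sex" in meta.columns:
        tab = np.array([[np.sum(g["sex"] == "F"), np.sum(g["sex"] == "M")]
                        for g in (pat, con)])
        chi2, p = contingency_chi2(tab)
        rows.append({"measure": "sex F/M",
                     "patient": f"{tab[0, 0]}/{tab[0, 1]}",
                     "control": f"{tab[1, 0]}/{tab[1, 1]}",
                     "statistic": chi2, "p": p})
    for col in numeric_cols:
        if col not in meta.columns:
            continue
        a, b = pat[col].to_numpy(float), con[col].to_numpy(float)
        t, p = summary_stat_ttest(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b))
        rows.append({"measure": col,
                     "patient": f"{a.mean():.2f}±{a.std(ddof=1):.2f}",
                     "control": f"{b.mean():.2f}±{b.std(ddof=1):.2f}",
                     "statistic": t, "p": p})
    return pd.DataFrame(rows)
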