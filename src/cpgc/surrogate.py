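"""Phase-randomized surrogate inference for directed paths.

Significance of each directed path is assessed against an empirical null
built by phase randomization: each ROI series is given uniformly random
Fourier phases while its magnitude spectrum (hence power spectrum and
autocorrelation) is retained exactly.  Randomizing every column
independently destroys both lagged and zero-lag cross-structure, so the null
hypothesis is "no temporal relationship between series".  Each surrogate set
is standardized and refitted with the same model, and the observed CPGC of a
path is ranked within its surrogate distribution (add-one rule).  Per-subject
empirical p-values are combined across the subjects of a group with Fisher's
method, and significant pairs are classified as uni- or bi-directional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy import stats

from .mvar import cpgc_from_coefs, fit_mmvar_batched


class InferenceError(ValueError):
    pass


@dataclass
class NullEnsemble:
    """Surrogate CPGC values for one subject: (n_surrogates, k, k)."""

    values: np.ndarray
    order: int
    zero_lag: bool = True
    subject_id: str = ""
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def save(self, path_npy, path_json=None) -> None:
        np.save(path_npy, self.values)
        if path_json is not None:
            meta = {"order": self.order, "zero_lag": self.zero_lag,
                    "subject_id": self.subject_id, "seed": self.seed,
                    "n_surrogates": int(self.n)}
            with open(path_json, "w") as fh:
                json.dump(meta, fh, indent=2)


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One phase-randomized surrogate of a 1-D series.

    The output is real with exactly the input's magnitude spectrum; the DC
    bin and (for even length) the Nyquist bin are left untouched so their
    phases stay 0 or pi and the inverse transform is real.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    if T < 3:
        raise InferenceError("need at least 3 time points")
    return phase_randomize_batched(x[:, None], 1, rng)[0, :, 0]


def phase_randomize_batched(X: np.ndarray, n: int,
                            rng: np.random.Generator) -> np.ndarray:
    """n independent surrogates of every column of a T x k matrix: (n, T, k).

    Each column of each surrogate draws its own phases, so all cross-column
    structure is destroyed while each column's spectrum is preserved.
    """
    X = np.asarray(X, dtype=float)
    T, k = X.shape
    spec = np.fft.rfft(X, axis=0)                  # (nb, k)
    nb = spec.shape[0]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, nb, k))
    phases[:, 0, :] = 0.0
    if T % 2 == 0:
        phases[:, -1, :] = 0.0                     # Nyquist bin stays real
    surro_spec = spec[None, :, :] * np.exp(1j * phases)
    return np.fft.irfft(surro_spec, n=T, axis=1)


def build_null(X: np.ndarray, order: int, n_surrogates: int,
               rng: np.random.Generator, zero_lag: bool = True,
               subject_id: str = "", seed: int | None = None) -> NullEnsemble:
    """Surrogate CPGC ensemble for one subject's T x k series.

    Every surrogate is: independent phase randomization of each column,
    standardization, mMVAR fit at ``order``, CPGC.  Fully reproducible from
    the generator state.
    """
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    if n_surrogates == 0:
        return NullEnsemble(np.zeros((0, k, k)), order, zero_lag, subject_id, seed)
    Xs = phase_randomize_batched(X, n_surrogates, rng)
    Xs = Xs - Xs.mean(axis=1, keepdims=True)
    Xs = Xs / Xs.std(axis=1, ddof=1, keepdims=True)
    try:
        _, coefs = fit_mmvar_batched(Xs, order, zero_lag=zero_lag)
    except np.linalg.LinAlgError as err:
        raise InferenceError(f"surrogate fit failed: {err}") from err
    return NullEnsemble(cpgc_from_coefs(coefs), order, zero_lag, subject_id, seed)


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Add-one empirical p: (1 + #{null >= observed}) / (1 + n); never 0."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise InferenceError("empty null ensemble")
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def empirical_p_matrix(observed: np.ndarray, null: NullEnsemble) -> np.ndarray:
    """Per-path add-one empirical p-values; diagonal set to 1."""
    if null.n == 0:
        raise InferenceError("empty null ensemble")
    counts = np.sum(null.values >= observed[None, :, :], axis=0)
    p = (1.0 + counts) / (1.0 + null.n)
    np.fill_diagonal(p, 1.0)
    return p


def fisher_combine(pvalues: np.ndarray) -> tuple[float, float]:
    """Fisher's method: statistic -2 sum(log p), combined p from chi2(2m)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InferenceError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise InferenceError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(p).sum()
    return float(stat), float(stats.chi2.sf(stat, 2 * p.size))


def fisher_combine_matrix(subject_p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-subject p matrices (m, k, k) pathwise; diagonals -> p=1."""
    P = np.asarray(subject_p, dtype=float)
    if P.ndim != 3 or P.shape[0] < 1:
        raise InferenceError("expected (n_subjects, k, k) p-values")
    if np.any(P <= 0) or np.any(P > 1):
        raise InferenceError("p-values must lie in (0, 1]")
    stat = -2.0 * np.log(P).sum(axis=0)
    p = stats.chi2.sf(stat, 2 * P.shape[0])
    np.fill_diagonal(p, 1.0)
    return stat, p


@dataclass
class PathInference:
    """Group-level path significance and pairwise direction classes."""

    p: np.ndarray                       # (k, k) combined p, diag 1
    alpha: float
    fisher_stat: np.ndarray | None = None
    significant: np.ndarray = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        sig = p < self.alpha
        np.fill_diagonal(sig, False)
        self.significant = sig

    def pair_class(self, i: int, j: int) -> str:
        """'none', 'bidirectional', 'unidirectional i->j' or '... j->i'.

        Path (i, j) means influence of ROI j on ROI i (matrix convention).
        """
        ij = self.significant[j, i]     # i -> j: target j, source i
        ji = self.significant[i, j]
        if ij and ji:
            return "bidirectional"
        if ij:
            return f"unidirectional {i}->{j}"
        if ji:
            return f"unidirectional {j}->{i}"
        return "none"

    def to_edges(self, labels=None, cpgc: np.ndarray | None = None) -> pd.DataFrame:
        """Significant directed edges as a tidy table (source, target, p...)."""
        k = self.p.shape[0]
        labels = labels or [str(i) for i in range(k)]
        rows = []
        for i in range(k):
            for j in range(k):
                if i == j or not self.significant[i, j]:
                    continue
                rows.append({
                    "source": labels[j], "target": labels[i],
                    "p": self.p[i, j],
                    "cpgc": float(cpgc[i, j]) if cpgc is not None else np.nan,
                    "class": ("bidirectional" if self.significant[j, i]
                              else "unidirectional"),
                })
        return pd.DataFrame(rows, columns=["source", "target", "p", "cpgc", "class"])


def classify_paths(group_p: np.ndarray, alpha: float = 0.01,
                   fisher_stat: np.ndarray | None = None) -> PathInference:
    """Threshold a combined-p matrix at alpha and classify pair directions."""
    return PathInference(np.asarray(group_p, dtype=float), float(alpha), fisher_stat)
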