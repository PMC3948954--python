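"""Synthetic two-group cohorts with known causal ground truth.

The generator emulates the structure of a resting-state case-control study:
two groups of 16 subjects, 229 frames at TR 2 s, k ROI series per subject.
"Neural" signals follow a structural VAR whose lagged coefficients carry the
planted causal edges; instantaneous (zero-lag) correlation is induced by a
mixing matrix applied to the Gaussian innovations — not through the model's
A(0) — so "instantaneous correlation without causality" is unambiguous in
the ground truth.  Signals are optionally blurred with a canonical
double-gamma hemodynamic response, then nuisance components (linear drift,
optional global signal) are added.  Motion traces, white-matter/CSF nuisance
series, an atrophy covariate and behavior scores coupled to the planted path
strengths complete the bundle.

All randomness flows from a single master seed through named substreams
(ground truth, one per subject, scores), so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .defaults import DEFAULTS
from .signal_prep import RoiTimeSeriesSet

GROUPS = ("patient", "control")

# group mean/SD used to scale behavior score columns (patient, control)
SCORE_DISTS = {
    "MMSE": ((25.94, 1.65), (28.56, 0.63)),
    "CVLT_immediate": ((8.39, 1.23), (11.33, 1.86)),
    "CVLT_short": ((9.13, 1.23), (13.00, 1.86)),
    "CVLT_long": ((7.31, 1.43), (12.62, 1.36)),
    "CDT": ((5.75, 0.54), (8.62, 1.36)),
}
AGE_DISTS = {"patient": (68.50, 7.77), "control": (67.19, 8.38)}
EDU_DISTS = {"patient": (10.06, 3.91), "control": (9.06, 3.64)}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class DifferentialEdge:
    """A directed edge planted in one group only: x_source -> x_target."""

    target: int
    source: int
    group: str = "patient"
    delta: float = 0.5
    lag: int = 1


@dataclass
class GroundTruth:
    """Generative parameters: per-group lag tensors, mixing, couplings."""

    k: int
    order: int
    coefs: dict                      # group -> (p, k, k)
    mixing: np.ndarray               # (k, k), innovations e = M z
    innovation_sd: float = 1.0
    differential_edges: list = field(default_factory=list)
    behavior_coupling: dict = field(default_factory=dict)  # score -> (path, r)
    edge_jitter_sd: float = 0.1
    scenario: str = ""

    def __post_init__(self):
        for g, A in self.coefs.items():
            rho = companion_spectral_radius(np.asarray(A, dtype=float))
            if rho >= 1.0:
                raise SimulationError(
                    f"non-stationary VAR for group {g!r}: spectral radius "
                    f"{rho:.3f} >= 1 (reduce edge strengths)")
        for e in self.differential_edges:
            if not (0 <= e.target < self.k and 0 <= e.source < self.k
                    and e.target != e.source):
                raise SimulationError(f"differential edge {e} outside node set")

    def to_json(self, path) -> None:
        doc = {
            "scenario": self.scenario, "k": self.k, "order": self.order,
            "innovation_sd": self.innovation_sd,
            "edge_jitter_sd": self.edge_jitter_sd,
            "coefs": {g: np.asarray(A).tolist() for g, A in self.coefs.items()},
            "mixing": np.asarray(self.mixing).tolist(),
            "differential_edges": [vars(e) for e in self.differential_edges],
            "behavior_coupling": {m: {"path": list(p), "r": r}
                                  for m, (p, r) in self.behavior_coupling.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def companion_spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stationarity iff < 1)."""
    p, k, _ = A.shape
    comp = np.zeros((k * p, k * p))
    comp[:k] = A.reshape(p * k, k).reshape(p, k, k).transpose(1, 0, 2).reshape(k, p * k)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _mixing_matrix(k: int, corr: float, structure: str = "pair",
                   pair: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Innovation mixing matrix inducing zero-lag correlation ``corr``.

    ``structure='pair'`` correlates one channel pair (localized instantaneous
    correlation, the analogue of planting a single causal edge);
    ``'equicorrelated'`` correlates every pair at ``corr`` (a global shared
    component).
    """
    if not (0 <= corr < 1):
        raise SimulationError("mixing correlation must be in [0, 1)")
    if corr == 0:
        return np.eye(k)
    if structure == "equicorrelated":
        sigma = np.full((k, k), corr) + (1 - corr) * np.eye(k)
    elif structure == "pair":
        a, b = pair
        sigma = np.eye(k)
        sigma[a, b] = sigma[b, a] = corr
    else:
        raise SimulationError(f"unknown mixing structure {structure!r}")
    return np.linalg.cholesky(sigma)


def make_ground_truth(scenario: str, k: int = 6,
                      self_ar: float | None = None,
                      mixing_corr: float | None = None,
                      mixing_structure: str = "equicorrelated",
                      corr_pair: tuple[int, int] = (0, 1),
                      effect: float = 0.5, edge: tuple[int, int] = (1, 0),
                      behavior_r: float = -0.6,
                      edge_jitter_sd: float = 0.1) -> GroundTruth:
    """Construct the generative truth for a named scenario.

    Scenarios
    ---------
    ``null``
        No coefficients at all, identity mixing: independent white series.
        Observed data and surrogates are exchangeable here, so surrogate
        inference is exactly calibrated — the global-null reference.
    ``instantaneous-only``
        Zero lagged coefficients; a shared innovation component makes every
        channel pair instantaneously correlated at ``mixing_corr`` (default
        0.6; ``mixing_structure='pair'`` localizes the correlation to one
        channel pair instead).  The test bed for the purging property:
        instantaneous correlation with no causality.  Series are white by
        default (``self_ar`` 0) so the zero-lag structure is the only true
        structure.
    ``one-edge``
        Control group: diagonal self-autoregression ``self_ar`` (default
        0.3).  Patient group additionally has one lag-1 directed edge
        ``edge`` (source -> target) of strength ``effect``, jittered across
        subjects and coupled to the MMSE-like score at target correlation
        ``behavior_r``.
    """
    base = np.zeros((1, k, k))
    if scenario == "null":
        gt = GroundTruth(k, 1, {"patient": base.copy(), "control": base.copy()},
                         np.eye(k), scenario=scenario, edge_jitter_sd=0.0)
    elif scenario == "instantaneous-only":
        corr = 0.6 if mixing_corr is None else mixing_corr
        A = base.copy()
        A[0][np.diag_indices(k)] = 0.0 if self_ar is None else self_ar
        gt = GroundTruth(k, 1, {"patient": A.copy(), "control": A.copy()},
                         _mixing_matrix(k, corr, mixing_structure, corr_pair),
                         scenario=scenario, edge_jitter_sd=0.0)
    elif scenario == "one-edge":
        corr = 0.0 if mixing_corr is None else mixing_corr
        A = base.copy()
        A[0][np.diag_indices(k)] = 0.3 if self_ar is None else self_ar
        Apat = A.copy()
        ti, sj = edge
        Apat[0, ti, sj] = effect
        de = DifferentialEdge(ti, sj, "patient", effect, 1)
        gt = GroundTruth(k, 1, {"patient": Apat, "control": A.copy()},
                         _mixing_matrix(k, corr, mixing_structure, corr_pair),
                         differential_edges=[de],
                         behavior_coupling={"MMSE": ((ti, sj), behavior_r)},
                         edge_jitter_sd=edge_jitter_sd, scenario=scenario)
    else:
        raise SimulationError(f"unknown scenario {scenario!r}")
    return gt


@dataclass
class CohortConfig:
    """Cohort dimensions and signal/nuisance settings (study defaults)."""

    n_per_group: int = DEFAULTS["n_per_group"]
    n_frames: int = DEFAULTS["n_frames"]
    tr: float = DEFAULTS["tr"]
    hrf: bool = True
    drift_amplitude: float = 1.0
    global_amplitude: float = 0.0
    motion_step_mm: float = 0.02
    motion_step_deg: float = 0.02
    burn_in: int = 200
    atrophy_shift: float = -0.5      # patient-minus-control mean of covariate


def hrf_kernel(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR (peak 6 s, undershoot 16 s,
    undershoot ratio 6), normalized to unit peak."""
    t = np.arange(0, duration + tr / 2, tr)
    h = _stats.gamma.pdf(t, a=6, scale=1.0) - _stats.gamma.pdf(t, a=16, scale=1.0) / 6.0
    return h / np.max(np.abs(h))


@dataclass
class SubjectData:
    """One simulated subject: series, motion, tissue nuisance, true coefs."""

    subject_id: str
    group: str
    series: RoiTimeSeriesSet
    motion: np.ndarray               # (T, 6)
    nuisance: np.ndarray             # (T, 2): WM, CSF
    coefs: np.ndarray                # this subject's realized (p, k, k)
    edge_strengths: dict             # (target, source) -> realized coefficient
    global_proxy: np.ndarray = None  # (T,) measured whole-brain average


def _jittered_coefs(gt: GroundTruth, group: str,
                    rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    A = np.asarray(gt.coefs[group], dtype=float).copy()
    strengths = {}
    for e in gt.differential_edges:
        if e.group != group:
            strengths[(e.target, e.source)] = A[e.lag - 1, e.target, e.source]
            continue
        for _ in range(20):
            val = e.delta + rng.normal(0.0, gt.edge_jitter_sd)
            trial = A.copy()
            trial[e.lag - 1, e.target, e.source] = val
            if companion_spectral_radius(trial) < 1.0:
                A = trial
                break
        else:
            raise SimulationError("could not jitter edge while staying stationary")
        strengths[(e.target, e.source)] = A[e.lag - 1, e.target, e.source]
    return A, strengths


def simulate_subject(gt: GroundTruth, group: str, cfg: CohortConfig,
                     rng: np.random.Generator,
                     subject_id: str = "sub") -> SubjectData:
    """Iterate the structural VAR and dress it up as a BOLD-like recording.

    Burn-in samples are discarded before the HRF convolution window; the
    convolved signal is renormalized to unit variance per column before
    drift and global components are added.
    """
    if group not in gt.coefs:
        raise SimulationError(f"unknown group {group!r}")
    A, strengths = _jittered_coefs(gt, group, rng)
    p, k = gt.order, gt.k
    T = cfg.n_frames
    kern = hrf_kernel(cfg.tr) if cfg.hrf else np.array([1.0])
    Lh = len(kern)
    total = cfg.burn_in + T + Lh + p
    z = rng.normal(0.0, gt.innovation_sd, size=(total, k))
    e = z @ gt.mixing.T
    x = np.zeros((total, k))
    x[:p] = e[:p]
    for t in range(p, total):
        acc = e[t]
        for n in range(1, p + 1):
            acc = acc + A[n - 1] @ x[t - n]
        x[t] = acc
    x = x[cfg.burn_in:]
    if cfg.hrf:
        y = np.empty((T, k))
        for j in range(k):
            conv = np.convolve(x[:, j], kern, mode="full")
            y[:, j] = conv[Lh - 1:Lh - 1 + T]    # full-kernel-support segment
    else:
        y = x[:T].copy()
    y = y / y.std(axis=0, ddof=1, keepdims=True)

    if cfg.drift_amplitude:
        y = y + cfg.drift_amplitude * np.linspace(-1, 1, T)[:, None]
    g = _ar1(rng, T, phi=0.9)
    if cfg.global_amplitude:
        y = y + cfg.global_amplitude * g[:, None]
    # whole-brain average as a scanner would measure it: the shared global
    # component plus signal from voxels outside the modeled ROIs
    global_proxy = cfg.global_amplitude * g + 0.3 * _ar1(rng, T, phi=0.9)

    motion = np.cumsum(
        rng.normal(0.0, [cfg.motion_step_mm] * 3 + [cfg.motion_step_deg] * 3,
                   size=(T, 6)), axis=0)
    nuis = np.column_stack([_ar1(rng, T, phi=0.5), _ar1(rng, T, phi=0.5)])
    series = RoiTimeSeriesSet(subject_id, y, cfg.tr,
                              [f"roi{j}" for j in range(k)])
    return SubjectData(subject_id, group, series, motion, nuis, A, strengths,
                       global_proxy)


def _ar1(rng: np.random.Generator, T: int, phi: float) -> np.ndarray:
    z = rng.normal(size=T)
    out = np.empty(T)
    out[0] = z[0]
    for t in range(1, T):
        out[t] = phi * out[t - 1] + z[t]
    return out / out.std(ddof=1)


def behavior_scores(strengths: np.ndarray, target_r: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Standardized latent scores with population correlation ``target_r``
    to the given per-subject strengths (degenerate strengths -> pure noise)."""
    z = np.asarray(strengths, dtype=float)
    noise = rng.normal(size=z.size)
    if z.std() < 1e-12 or abs(target_r) < 1e-12:
        return noise
    z = (z - z.mean()) / z.std()
    return target_r * z + np.sqrt(1.0 - target_r ** 2) * noise


@dataclass
class Cohort:
    subjects: dict                   # group -> list[SubjectData]
    meta: pd.DataFrame
    ground_truth: GroundTruth
    seed: int

    def all_subjects(self):
        for g in GROUPS:
            yield from self.subjects[g]


def simulate_cohort(gt: GroundTruth, cfg: CohortConfig, seed: int) -> Cohort:
    """Simulate both groups plus metadata, covariate and behavior scores.

    Behavior columns are named after the study's instruments (MMSE, CVLT
    recall conditions, CDT) and scaled to group-typical means/SDs; coupled
    columns follow the ground truth's (path, target r) spec within the
    patient group.
    """
    ss = np.random.SeedSequence(seed)
    sub_seeds = ss.spawn(2 * cfg.n_per_group + 1)
    score_rng = np.random.default_rng(sub_seeds[-1])

    subjects = {g: [] for g in GROUPS}
    rows = []
    idx = 0
    for g in GROUPS:
        for s in range(cfg.n_per_group):
            rng = np.random.default_rng(sub_seeds[idx])
            sid = f"sub-{g[0]}{s + 1:02d}"
            subjects[g].append(simulate_subject(gt, g, cfg, rng, sid))
            sex = "F" if s < 10 else "M"       # 10/6 split as in the cohort
            age = rng.normal(*AGE_DISTS[g])
            edu = rng.normal(*EDU_DISTS[g])
            atrophy = rng.normal(0.0, 0.5) + (cfg.atrophy_shift if g == "patient" else 0.0)
            rows.append({"subject_id": sid, "group": g, "sex": sex,
                         "age": age, "education": edu, "atrophy": atrophy})
            idx += 1
    meta = pd.DataFrame(rows)

    for measure, (pat_ms, con_ms) in SCORE_DISTS.items():
        latent = {}
        for g in GROUPS:
            if g == "patient" and measure in gt.behavior_coupling:
                (ti, sj), r = gt.behavior_coupling[measure]
                strengths = np.array([sub.edge_strengths.get((ti, sj), 0.0)
                                      for sub in subjects[g]])
                latent[g] = behavior_scores(strengths, r, score_rng)
            else:
                latent[g] = score_rng.normal(size=cfg.n_per_group)
        mu_p, sd_p = pat_ms
        mu_c, sd_c = con_ms
        vals = np.r_[mu_p + sd_p * latent["patient"],
                     mu_c + sd_c * latent["control"]]
        meta[measure] = vals
    return Cohort(subjects, meta, gt, seed)
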