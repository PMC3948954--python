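"""Study-level default parameters, defined in exactly one place.

Every numeric default that mirrors the study design (acquisition timing,
filter band, model order, surrogate count, significance levels, ROI and
head-sphere geometry, group sizes) lives in :data:`DEFAULTS` and is surfaced
by ``cpgc --show-defaults``.
"""

from __future__ import annotations

DEFAULTS: dict = {
    # acquisition / volume accounting
    "tr": 2.0,                # seconds per frame
    "scan_seconds": 478.0,    # total functional scan duration
    "n_discard": 10,          # equilibration volumes dropped
    "n_frames": 229,          # analysis frames after discarding
    # temporal filtering
    "band_low": 0.01,         # Hz
    "band_high": 0.08,        # Hz
    # model / inference
    "model_order": 5,
    "n_surrogates": 10_000,
    "alpha_within": 0.01,
    "alpha_between": 0.01,
    "global_signal_regression": False,
    # geometry
    "roi_radius_mm": 12.0,
    "head_radius_mm": 50.0,
    # cohort
    "n_per_group": 16,
}


def n_analysis_frames(scan_seconds: float | None = None,
                      tr: float | None = None,
                      n_discard: int | None = None) -> int:
    """Number of frames entering analysis: acquired volumes minus discards.

    With the defaults (478 s scan, TR 2 s, 10 discarded volumes) this is 229.
    """
    scan_seconds = DEFAULTS["scan_seconds"] if scan_seconds is None else scan_seconds
    tr = DEFAULTS["tr"] if tr is None else tr
    n_discard = DEFAULTS["n_discard"] if n_discard is None else n_discard
    if tr <= 0:
        raise ValueError("TR must be positive")
    acquired = int(round(scan_seconds / tr))
    n = acquired - int(n_discard)
    if n <= 0:
        raise ValueError("no frames left after discarding equilibration volumes")
    return n
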