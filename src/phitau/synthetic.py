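"""Synthetic two-condition sweep data with known ground truth.

These generators produce tidy sweep tables of the same shape the Φ pipeline
emits — multiple subjects, multiple channel pairs per subject, a log Φ value
per timescale and condition — with a *planted* effect whose parameters are
known, so that the Δlog(Φ) + quadratic-fit stage can be validated end to end:

* :func:`two_condition_sweep` plants a multiplicative Φ bump at a chosen τ*
  in the "wake" condition relative to the "anaesthesia" condition (additive
  parabola in log Φ, vertex at log₂ τ*);
* :func:`multilevel_parabola` draws responses exactly from the quadratic
  mixed model (fixed quadratic in log₂ τ + subject and subject:pair random
  intercepts + residual noise) for coefficient-recovery checks.

Defaults emulate the scale of a small multi-subject electrophysiology study
(13 subjects, 10 channel pairs each) with effect sizes of the order seen in
Δlog(Φ) analyses (curvature ~1e-2 per (log₂ τ)², residual spread ~0.1-0.3).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .sweep import DEFAULT_TAU_GRID

__all__ = ["two_condition_sweep", "multilevel_parabola"]


def _units(n_subjects: int, n_pairs: int, tau_grid: Sequence[int]) -> pd.DataFrame:
    recs = [
        {"subject": f"s{s:02d}", "pair": f"p{p:02d}", "run": 0, "tau": int(t)}
        for s in range(n_subjects)
        for p in range(n_pairs)
        for t in tau_grid
    ]
    df = pd.DataFrame(recs)
    df["method"] = "synthetic"
    df["tau_ms"] = df["tau"].astype(float)
    return df


def two_condition_sweep(
    tau_star: float = 10.0,
    *,
    tau_grid: Sequence[int] = DEFAULT_TAU_GRID,
    n_subjects: int = 13,
    n_pairs: int = 10,
    bump_height: float = 0.4,
    bump_curvature: float = 0.02,
    baseline_slope: float = -0.15,
    subject_sd: float = 0.2,
    pair_sd: float = 0.2,
    condition_subject_sd: float = 0.1,
    condition_pair_sd: float = 0.1,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two matched sweep tables with a planted Φ-ratio bump at ``tau_star``.

    The anaesthesia condition is a linear-in-log₂τ baseline with subject and
    subject:pair random intercepts and iid noise; the wake condition adds a
    downward-opening parabola in x = log₂ τ peaking at x* = log₂ τ*:
    ``bump_height - bump_curvature * (x - x*)**2``.  Δlog(Φ) between the two
    conditions therefore follows the quadratic peak model exactly, with
    ground-truth turning point τ*.  Unit intercepts have a component shared
    between conditions (``subject_sd``, ``pair_sd``; cancelled by the Δ) and
    a condition-specific component (``condition_*_sd``; surviving in the Δ as
    genuine subject / subject:pair random effects).

    Returns ``(wake, anesthesia)`` DataFrames matching the sweep schema
    (log_phi column; phi = exp(log_phi)).
    """
    rng = np.random.default_rng(seed)
    base = _units(n_subjects, n_pairs, tau_grid)
    x = np.log2(base["tau"].astype(float).to_numpy())
    x_star = np.log2(float(tau_star))

    subjects = sorted(base["subject"].unique())
    pair_keys = sorted(set(zip(base["subject"], base["pair"])))

    def unit_offsets(s_sd: float, p_sd: float) -> np.ndarray:
        subj_fx = dict(zip(subjects, rng.normal(0, s_sd, n_subjects)))
        pair_fx = dict(zip(pair_keys, rng.normal(0, p_sd, len(pair_keys))))
        return base["subject"].map(subj_fx).to_numpy() + np.array(
            [pair_fx[k] for k in zip(base["subject"], base["pair"])]
        )

    shared = unit_offsets(subject_sd, pair_sd)
    baseline = -2.0 + baseline_slope * x + shared

    anesth = base.copy()
    anesth["condition"] = "anesthesia"
    anesth["log_phi"] = (
        baseline
        + unit_offsets(condition_subject_sd, condition_pair_sd)
        + rng.normal(0, noise_sd, len(base))
    )

    bump = bump_height - bump_curvature * (x - x_star) ** 2
    wake = base.copy()
    wake["condition"] = "wake"
    wake["log_phi"] = (
        baseline
        + bump
        + unit_offsets(condition_subject_sd, condition_pair_sd)
        + rng.normal(0, noise_sd, len(base))
    )

    for df in (wake, anesth):
        df["phi"] = np.exp(df["log_phi"])
        df["imputed_row_fraction"] = 0.0
    return wake, anesth


def multilevel_parabola(
    beta: tuple[float, float, float] = (0.4, 4.4e-2, -9.2e-3),
    *,
    tau_grid: Sequence[int] = DEFAULT_TAU_GRID,
    n_subjects: int = 13,
    n_pairs: int = 10,
    subject_sd: float = 0.2,
    pair_sd: float = 0.2,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Responses drawn exactly from the quadratic mixed model.

    ``y = beta0 + beta1*x + beta2*x**2 + u_subject + u_subject:pair + eps``
    with x = log₂ τ.  Returns a tidy DataFrame with a ``delta_log_phi``
    response column, for coefficient-recovery validation of the fitter.
    """
    rng = np.random.default_rng(seed)
    base = _units(n_subjects, n_pairs, tau_grid)
    x = np.log2(base["tau"].astype(float).to_numpy())
    subj_fx = dict(
        zip(sorted(base["subject"].unique()), rng.normal(0, subject_sd, n_subjects))
    )
    pair_keys = sorted(set(zip(base["subject"], base["pair"])))
    pair_fx = dict(zip(pair_keys, rng.normal(0, pair_sd, len(pair_keys))))
    b0, b1, b2 = beta
    base["delta_log_phi"] = (
        b0
        + b1 * x
        + b2 * x**2
        + base["subject"].map(subj_fx).to_numpy()
        + np.array([pair_fx[k] for k in zip(base["subject"], base["pair"])])
        + rng.normal(0, noise_sd, len(base))
    )
    return base
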