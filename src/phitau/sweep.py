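"""Timescale sweeps of Φ, Δlog(Φ), and the quadratic peak model.

The workflow mirrors the analysis this package exists for: Φ is computed over
a grid of timescales τ for every (subject, channel pair, run, condition);
because Φ is positively skewed it is log-transformed; the two-condition
contrast Δlog(Φ) = log Φ_wake − log Φ_anaesthesia (the log of the Φ ratio) is
regressed on a quadratic in x = log₂ τ with random intercepts for subject and
subject:pair; a likelihood-ratio test against the linear model assesses the
quadratic term, and the fitted parabola's turning point 2^(−β₁/2β₂) is a
candidate intermediate-timescale peak when β₂ < 0 and the vertex lies
strictly inside the τ grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding import binarize_median, build_tpm_downsampling, build_tpm_skipping, coarse_binaries, state_index, _tally, _finalise
from .phi import phi_timeseries
from .simulate import MultiChannelSeries

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TAU_GRID",
    "SWEEP_COLUMNS",
    "sweep",
    "mean_phi_curve",
    "argmax_tau",
    "delta_log_phi",
    "PeakFit",
    "fit_quadratic_peak",
    "turning_point",
    "is_intermediate_peak",
]

#: Approximately exponential τ grid (samples).  It deliberately contains
#: non-powers of two such as 10 and 360 so that integer interaction lags in
#: that range can be resolved exactly.
DEFAULT_TAU_GRID = (
    1, 2, 3, 4, 5, 6, 8, 10, 13, 16, 20, 25, 32, 40, 50, 64, 90, 128, 180,
    256, 360, 512,
)

SWEEP_COLUMNS = [
    "subject", "pair", "run", "condition", "method", "tau", "tau_ms",
    "phi", "log_phi", "imputed_row_fraction",
]


def _pair_label(pair: tuple[int, ...] | None) -> str:
    return "all" if pair is None else "-".join(str(p) for p in pair)


def _downsampling_pair_tpms(values: np.ndarray, tau: int, pairs):
    """Pooled-offset downsampling TPMs for several channel subsets at once.

    Coarse binarisation is per channel (medians per offset), so the offset
    series are computed once and tallied per subset.
    """
    per_offset = coarse_binaries(values, tau)
    out = {}
    for pair in pairs:
        chans = list(pair) if pair is not None else list(range(values.shape[0]))
        n_ch = len(chans)
        on = np.zeros((2**n_ch, n_ch), dtype=np.int64)
        counts = np.zeros(2**n_ch, dtype=np.int64)
        for bits, _med in per_offset:
            sub = bits[chans]
            idx = state_index(sub)
            o, c = _tally(idx[:-1], sub[:, 1:], n_ch)
            on += o
            counts += c
        out[pair] = _finalise(on, counts, tau, "downsampling", n_ch)
    return out


def sweep(
    series_by_condition: Mapping[str, Sequence[MultiChannelSeries]] | Sequence[MultiChannelSeries],
    method: str,
    tau_grid: Sequence[int] = DEFAULT_TAU_GRID,
    channel_pairs: str | Sequence[tuple[int, ...]] | None = None,
    *,
    subject: str = "sim",
    sampling_rate_hz: float | None = None,
) -> pd.DataFrame:
    """Φ across a τ grid for every (condition, run, channel subset).

    Parameters
    ----------
    series_by_condition
        Either a mapping ``condition label -> list of runs`` or a plain list
        of runs (labelled by each run's own ``condition_label``).
    method
        ``"skipping"`` or ``"downsampling"``.
    channel_pairs
        ``None`` — treat all channels as one system; ``"pairs"`` — every
        2-channel subset as its own system (partial observation); or an
        explicit list of channel-index tuples.

    Returns a tidy DataFrame with one row per (subject, pair, run, condition,
    method, τ); ``log_phi`` is the natural log, left missing (NaN) where
    Φ is zero.
    """
    if method not in ("skipping", "downsampling"):
        raise ValueError(f"unknown method {method!r}")
    tau_grid = sorted(int(t) for t in tau_grid)
    if len(tau_grid) != len(set(tau_grid)):
        raise ValueError("tau grid contains duplicates")
    if isinstance(series_by_condition, Mapping):
        items = [(cond, runs) for cond, runs in series_by_condition.items()]
    else:
        items = [(None, list(series_by_condition))]

    rows = []
    for cond, runs in items:
        for run in runs:
            condition = cond if cond is not None else run.condition_label
            if channel_pairs is None:
                pairs: list[tuple[int, ...] | None] = [None]
            elif channel_pairs == "pairs":
                pairs = list(combinations(range(run.n_channels), 2))
            else:
                pairs = [tuple(p) for p in channel_pairs]
            binary = binarize_median(run) if method == "skipping" else None
            for tau in tau_grid:
                if method == "downsampling":
                    tpms = _downsampling_pair_tpms(run.values, tau, pairs)
                for pair in pairs:
                    if method == "skipping":
                        sub = binary if pair is None else binary.subset(pair)
                        tpm = build_tpm_skipping(sub, tau)
                    else:
                        tpm = tpms[pair]
                    result = phi_timeseries(tpm)
                    phi = result.phi_aggregate
                    if phi > 0:
                        log_phi = float(np.log(phi))
                    else:
                        log_phi = np.nan
                        logger.info(
                            "Phi = 0 for %s run %s pair %s tau %d; log recorded as missing",
                            condition, run.run_id, _pair_label(pair), tau,
                        )
                    rows.append(
                        {
                            "subject": subject,
                            "pair": _pair_label(pair),
                            "run": run.run_id,
                            "condition": condition,
                            "method": method,
                            "tau": tau,
                            "tau_ms": 1000.0 * tau / sampling_rate_hz
                            if sampling_rate_hz
                            else np.nan,
                            "phi": phi,
                            "log_phi": log_phi,
                            "imputed_row_fraction": result.imputed_row_fraction,
                        }
                    )
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    dup = df.duplicated(subset=["subject", "pair", "run", "condition", "method", "tau"])
    if dup.any():
        raise ValueError("duplicate (unit, condition, method, tau) records in sweep")
    return df


def mean_phi_curve(df: pd.DataFrame) -> pd.Series:
    """Mean Φ per τ, averaged over runs (and pairs if present)."""
    return df.groupby("tau")["phi"].mean()


def argmax_tau(df: pd.DataFrame) -> int:
    """The τ at which the run-mean Φ curve is maximal."""
    curve = mean_phi_curve(df)
    return int(curve.idxmax())


def delta_log_phi(sweep_wake: pd.DataFrame, sweep_anesth: pd.DataFrame) -> pd.DataFrame:
    """Δlog(Φ) = log Φ_wake − log Φ_anaesthesia per matched record.

    Records are matched on (subject, pair, run, method, τ); unmatched or
    missing-log records are excluded (and logged).
    """
    keys = ["subject", "pair", "run", "method", "tau"]
    merged = pd.merge(
        sweep_wake[keys + ["tau_ms", "log_phi"]],
        sweep_anesth[keys + ["log_phi"]],
        on=keys,
        how="inner",
        suffixes=("_wake", "_anesth"),
    )
    n_dropped = len(sweep_wake) + len(sweep_anesth) - 2 * len(merged)
    if n_dropped:
        logger.info("delta_log_phi: %d unmatched records excluded", n_dropped)
    merged["delta_log_phi"] = merged["log_phi_wake"] - merged["log_phi_anesth"]
    before = len(merged)
    merged = merged.dropna(subset=["delta_log_phi"]).reset_index(drop=True)
    if len(merged) < before:
        logger.info(
            "delta_log_phi: %d records with undefined log Phi excluded",
            before - len(merged),
        )
    return merged


def turning_point(beta1: float, beta2: float) -> tuple[float, bool]:
    """Vertex of ``beta1*x + beta2*x**2`` on the x = log₂ τ axis.

    Returns (τ at the vertex, i.e. ``2**(-beta1/(2*beta2))``, is_local_max).
    """
    if beta2 == 0:
        raise ValueError("beta2 must be nonzero for a turning point")
    x_star = -beta1 / (2.0 * beta2)
    return float(2.0**x_star), bool(beta2 < 0)


@dataclass
class PeakFit:
    """Quadratic-in-log₂(τ) mixed-model fit with its turning point."""

    beta0: float
    beta1: float
    beta2: float
    chi2: float
    df: int
    p_value: float
    turning_point_tau: float
    is_local_max: bool
    random_effect_variances: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.is_local_max == (self.beta2 < 0)


def _fit_mixed(data: pd.DataFrame, formula: str, vc: dict | None):
    import statsmodels.formula.api as smf

    last_err: Exception | None = None
    for method in ("powell", "lbfgs", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    formula, data, groups=data["subject"], re_formula="1", vc_formula=vc
                )
                fit = model.fit(reml=False, method=method)
            if fit.converged and np.isfinite(fit.llf):
                return fit
            last_err = RuntimeError(f"{method}: not converged or non-finite llf")
        except Exception as err:  # keep trying the next optimiser
            last_err = err
    raise RuntimeError(f"mixed model fit failed: {last_err}")


def fit_quadratic_peak(
    data: pd.DataFrame,
    response: str = "delta_log_phi",
    *,
    tau_col: str = "tau",
) -> PeakFit:
    """Fit the quadratic peak model and test it against the linear model.

    Fits, by maximum likelihood, mixed models in x = log₂ τ with random
    intercepts for subject and subject:pair::

        response ~ 1 + x       (+ (1|subject) + (1|subject:pair))
        response ~ 1 + x + x²  (+ (1|subject) + (1|subject:pair))

    and reports the likelihood-ratio χ²(1) of the quadratic term, the fitted
    coefficients, and the turning point on the τ axis.  With a single subject
    (or a single pair per subject) the degenerate random terms are dropped,
    falling back to ordinary least squares when no grouping remains; this is
    flagged in ``notes``.  ``tau_col`` may point at τ in samples or in ms;
    the turning point is returned in the same units.
    """
    notes: list[str] = []
    data = data.dropna(subset=[response, tau_col]).copy()
    if data[tau_col].nunique() < 3:
        raise ValueError("need >= 3 distinct tau values for a quadratic fit")
    data["x"] = np.log2(data[tau_col].astype(float))
    f_lin = f"{response} ~ x"
    f_quad = f"{response} ~ x + I(x**2)"

    n_subjects = data["subject"].nunique()
    multi_pair = "pair" in data.columns and data.groupby("subject")["pair"].nunique().max() > 1
    vc = {"pair": "0 + C(pair)"} if multi_pair else None

    if n_subjects >= 2:
        try:
            lin = _fit_mixed(data, f_lin, vc)
            quad = _fit_mixed(data, f_quad, vc)
        except Exception as err:  # singular / non-converged: drop vc term
            notes.append(f"refit without subject:pair variance component ({err})")
            vc = None
            lin = _fit_mixed(data, f_lin, None)
            quad = _fit_mixed(data, f_quad, None)
        params = quad.params
        beta0, beta1, beta2 = params["Intercept"], params["x"], params["I(x ** 2)"]
        ll_lin, ll_quad = lin.llf, quad.llf
        re_var = {"subject": float(quad.cov_re.iloc[0, 0])}
        if vc is not None:
            re_var["subject:pair"] = float(np.asarray(quad.vcomp).ravel()[0])
        re_var["residual"] = float(quad.scale)
    else:
        notes.append("single subject: fixed-effects-only (OLS) fallback")
        import statsmodels.formula.api as smf

        lin = smf.ols(f_lin, data).fit()
        quad = smf.ols(f_quad, data).fit()
        beta0, beta1, beta2 = (
            quad.params["Intercept"], quad.params["x"], quad.params["I(x ** 2)"],
        )
        ll_lin, ll_quad = lin.llf, quad.llf
        re_var = {"residual": float(quad.mse_resid)}

    chi2 = max(0.0, 2.0 * (ll_quad - ll_lin))
    p_value = float(stats.chi2.sf(chi2, 1))
    tp_tau, is_max = turning_point(float(beta1), float(beta2))
    return PeakFit(
        beta0=float(beta0),
        beta1=float(beta1),
        beta2=float(beta2),
        chi2=float(chi2),
        df=1,
        p_value=p_value,
        turning_point_tau=tp_tau,
        is_local_max=is_max,
        random_effect_variances=re_var,
        notes=notes,
    )


def is_intermediate_peak(fit: PeakFit, tau_grid: Sequence[int | float]) -> bool:
    """Whether the fit indicates a peak at an intermediate timescale.

    True iff the turning point is a local maximum and lies strictly inside
    the range of the τ grid (same units as the fit's τ axis).
    """
    return bool(
        fit.is_local_max and min(tau_grid) < fit.turning_point_tau < max(tau_grid)
    )
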