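"""Parameter-sensitivity workflow for post-transient vessel-radius dynamics.

Metrics: the time-weighted mean radius Rbar over [T0, t_end] and the
post-transient amplitude A = max |R(t) - Rbar|, reported as the relative
change dA = 100 (A/A0 - 1) % against a baseline amplitude A0.

Designs: one-at-a-time sweeps (ten equally spaced factors over [0.7, 1.3]),
Latin hypercube sampling over +/-30% hyperrectangles with rank-based partial
correlations (PRCC), and symmetric +/-10% local elasticities.

A *model runner* is any callable ``runner(params: dict) -> (t, R)`` returning
a radius trace; the orchestrator supplies one for the NGVU wall model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

T0_DEFAULT = 5.0
T_END_DEFAULT = 60.0
OAT_FACTORS = np.linspace(0.7, 1.3, 10)
LHS_HALF_WIDTH = 0.30
LOCAL_FACTORS = (0.9, 1.1)


@dataclass
class RadiusTrace:
    times: np.ndarray
    radii: np.ndarray
    T0: float = T0_DEFAULT
    t_end: float = T_END_DEFAULT

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.radii.size:
            raise ValueError("times/radii must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.t_end <= self.T0:
            raise ValueError("t_end must exceed T0")


def post_transient_metrics(trace: RadiusTrace) -> tuple[float, float]:
    """(Rbar, A): trapezoid-weighted mean and max excursion on [T0, t_end]."""
    m = (trace.times >= trace.T0) & (trace.times <= trace.t_end)
    t, r = trace.times[m], trace.radii[m]
    if t.size < 2:
        raise ValueError("post-transient window contains < 2 samples")
    rbar = float(np.trapezoid(r, t) / (t[-1] - t[0]))
    amp = float(np.max(np.abs(r - rbar)))
    return rbar, amp


def delta_amplitude(a: float, a0: float) -> float:
    """Relative amplitude change dA = 100 (A/A0 - 1) [%]."""
    if a0 == 0:
        raise ValueError("baseline amplitude A0 is zero")
    return 100.0 * (a / a0 - 1.0)


@dataclass
class SensitivityDesign:
    param_names: list
    baseline: dict
    mode: str = "oat"
    n_samples: int = 200
    seed: int = 0
    factors: np.ndarray = field(default_factory=lambda: OAT_FACTORS.copy())
    T0: float = T0_DEFAULT
    t_end: float = T_END_DEFAULT

    def __post_init__(self):
        if self.mode not in {"oat", "lhs", "local"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        missing = set(self.param_names) - set(self.baseline)
        if missing:
            raise ValueError(f"baseline values missing for {sorted(missing)}")


def _amplitude(runner, params, T0, t_end) -> float:
    t, r = runner(params)
    return post_transient_metrics(RadiusTrace(t, r, T0=T0, t_end=t_end))[1]


def oat_sweep(runner, design: SensitivityDesign) -> pd.DataFrame:
    """One-at-a-time sweep; returns tidy rows (param, factor, A, dA_pct)."""
    a0 = _amplitude(runner, dict(design.baseline), design.T0, design.t_end)
    rows = []
    for name in design.param_names:
        for f in design.factors:
            params = dict(design.baseline)
            params[name] = design.baseline[name] * f
            try:
                a = _amplitude(runner, params, design.T0, design.t_end)
                da = delta_amplitude(a, a0)
            except Exception:  # failed run recorded as missing, sweep continues
                a, da = np.nan, np.nan
            rows.append({"mode": "oat", "param": name, "factor": float(f),
                         "A": a, "deltaA_pct": da})
    df = pd.DataFrame(rows)
    df.attrs["A0"] = a0
    return df


def lhs_sample(n: int, ranges: dict, seed: int = 0) -> pd.DataFrame:
    """Latin hypercube: one sample per 1/n bin per column, independent
    permutations, uniform within bins.  ``ranges`` maps name -> (lo, hi)."""
    names = list(ranges)
    if n < len(names):
        raise ValueError("need at least as many samples as parameters")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in names:
        lo, hi = ranges[name]
        u = (rng.permutation(n) + rng.uniform(size=n)) / n
        cols[name] = lo + u * (hi - lo)
    return pd.DataFrame(cols)


def lhs_ranges(baseline: dict, names, half_width: float = LHS_HALF_WIDTH) -> dict:
    return {k: (baseline[k] * (1 - half_width), baseline[k] * (1 + half_width))
            for k in names}


def prcc(design_matrix: pd.DataFrame, response: np.ndarray) -> pd.Series:
    """Partial rank correlation of each column with the response.

    All columns and the response are rank-transformed (ties -> average
    ranks); the PRCC of parameter k is the Pearson correlation of the
    residuals of its ranks and the response ranks after regressing both on
    the ranks of the remaining parameters.
    """
    x = design_matrix.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(np.ptp(x, axis=0) == 0):
        raise ValueError("constant design column")
    rx = np.apply_along_axis(stats.rankdata, 0, x)
    ry = stats.rankdata(y)
    n, k = rx.shape
    out = {}
    for j, name in enumerate(design_matrix.columns):
        others = np.column_stack([np.ones(n), np.delete(rx, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, rx[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        res_x = rx[:, j] - others @ beta_x
        res_y = ry - others @ beta_y
        out[name] = float(np.corrcoef(res_x, res_y)[0, 1])
    return pd.Series(out, name="prcc")


def lhs_prcc(runner, design: SensitivityDesign) -> tuple[pd.DataFrame, pd.Series]:
    """Run the LHS design and summarize with PRCCs against dA."""
    ranges = lhs_ranges(design.baseline, design.param_names)
    matrix = lhs_sample(design.n_samples, ranges, seed=design.seed)
    a0 = _amplitude(runner, dict(design.baseline), design.T0, design.t_end)
    amps = np.empty(len(matrix))
    for i, row in matrix.iterrows():
        params = dict(design.baseline)
        params.update(row.to_dict())
        amps[i] = _amplitude(runner, params, design.T0, design.t_end)
    matrix = matrix.copy()
    matrix["A"] = amps
    matrix["deltaA_pct"] = 100.0 * (amps / a0 - 1.0)
    coeffs = prcc(matrix[design.param_names], amps)
    return matrix, coeffs


def local_elasticity(runner, design: SensitivityDesign) -> pd.Series:
    """Symmetric central-difference elasticity S per parameter.

    S = (p0/A0) * (A(+) - A(-)) / (p0 * (f+ - f-)) with f± = 0.9, 1.1.
    """
    f_minus, f_plus = LOCAL_FACTORS
    a0 = _amplitude(runner, dict(design.baseline), design.T0, design.t_end)
    if a0 == 0:
        raise ValueError("baseline amplitude A0 is zero; elasticity undefined")
    out = {}
    for name in design.param_names:
        p0 = design.baseline[name]
        vals = {}
        for f in (f_plus, f_minus):
            params = dict(design.baseline)
            params[name] = p0 * f
            vals[f] = _amplitude(runner, params, design.T0, design.t_end)
        out[name] = (p0 / a0) * (vals[f_plus] - vals[f_minus]) \
            / (p0 * (f_plus - f_minus))
    return pd.Series(out, name="S")
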