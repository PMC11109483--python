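"""Surface plasmon resonance processing and steady-state affinity fitting.

The binding model throughout is 1:1 Langmuir interaction at equilibrium,

    Req(C) = C * Rmax / (KD + C)

with ``C`` the injected analyte concentration (uM), ``Rmax`` the maximal
response at saturation (RU) and ``KD`` the dissociation constant (uM).
Sensorgrams are referenced and blank-subtracted, equilibrium responses are
averaged over the tail of the association phase, and (KD, Rmax) are estimated
by unweighted least squares.  A fitted KD above the highest injected
concentration is flagged: the affinity is then outside the tested range and
the estimate is weakly constrained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

KD_BOUNDS = (1e-4, 1e4)  # uM; generous bracket around any measurable affinity


def steady_state_response(conc, kd: float, rmax: float):
    """1:1 Langmuir equilibrium response Req = C*Rmax/(KD + C)."""
    conc = np.asarray(conc, dtype=float)
    return conc * rmax / (kd + conc)


@dataclass
class Sensorgram:
    """One injection cycle: response (RU) against time (s) at concentration C (uM)."""

    cycle: int
    concentration: float  # uM
    time: np.ndarray  # uniform grid, s
    response: np.ndarray  # RU
    association_window: tuple[float, float]
    dissociation_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response grids differ in length")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")
        lo, hi = self.time[0], self.time[-1]
        for t0, t1 in (self.association_window, self.dissociation_window):
            if not (lo <= t0 < t1 <= hi + 1e-9):
                raise ValueError("phase window outside the time grid")


@dataclass
class SteadyStateSeries:
    """Equilibrium responses (RU) over an increasing concentration series (uM)."""

    replicate: int
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration and response vectors differ in length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("non-finite equilibrium response")


@dataclass
class AffinityFit:
    """Result of steady-state fitting: (KD, Rmax) plus replicate statistics."""

    kd: float  # uM (pooled / single fit)
    rmax: float  # RU
    rmse: float
    saturation_flag: bool  # fitted KD exceeds the highest injected concentration
    per_replicate: list[tuple[float, float]] = field(default_factory=list)
    kd_mean: float = float("nan")
    kd_sd: float = float("nan")

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.rmax <= 0:
            raise ValueError("fitted KD and Rmax must be positive")
        if self.saturation_flag:
            warnings.warn(
                f"fitted KD {self.kd:.3g} uM exceeds the tested concentration range; "
                "the affinity estimate may be less accurate"
            )


def reference_blank_subtract(
    active: Sensorgram,
    reference: Sensorgram,
    blank_active: Sensorgram | None = None,
    blank_reference: Sensorgram | None = None,
) -> Sensorgram:
    """Double-reference a sensorgram: (active - reference) - (blank pair).

    With blanks absent, plain single referencing (active - reference) is
    applied.  All curves must share the same time grid.
    """
    curves = [c for c in (reference, blank_active, blank_reference) if c is not None]
    for c in curves:
        if c.time.shape != active.time.shape or not np.array_equal(c.time, active.time):
            raise ValueError("sensorgram time grids do not match")
    corrected = active.response - reference.response
    if (blank_active is None) != (blank_reference is None):
        raise ValueError("blank_active and blank_reference must be given together")
    if blank_active is not None:
        corrected = corrected - (blank_active.response - blank_reference.response)
    return Sensorgram(
        cycle=active.cycle,
        concentration=active.concentration,
        time=active.time.copy(),
        response=corrected,
        association_window=active.association_window,
        dissociation_window=active.dissociation_window,
    )


def extract_equilibrium(
    sensorgram: Sensorgram, window: float = 5.0, slope_tol: float = 0.2
) -> tuple[float, float, bool]:
    """Average the response over the final ``window`` seconds of association.

    Returns ``(C, Req, plateau_ok)``.  ``plateau_ok`` is False when the
    least-squares slope over the averaging window exceeds ``slope_tol``
    (RU/s) in magnitude — the curve has not reached steady state.  Failing
    points are flagged, not dropped.
    """
    t0, t1 = sensorgram.association_window
    if window >= t1 - t0:
        raise ValueError(
            f"averaging window {window}s is not shorter than the association phase ({t1 - t0}s)"
        )
    sel = (sensorgram.time >= t1 - window) & (sensorgram.time <= t1)
    t = sensorgram.time[sel]
    r = sensorgram.response[sel]
    req = float(np.mean(r))
    slope = float(stats.linregress(t, r).slope) if t.size > 1 else 0.0
    return sensorgram.concentration, req, bool(abs(slope) < slope_tol)


def _half_max_conc(conc: np.ndarray, resp: np.ndarray) -> float:
    """Linear interpolation of C at half-maximal response (KD initial guess)."""
    target = 0.5 * resp.max()
    above = np.nonzero(resp >= target)[0]
    if above.size == 0:
        return float(conc[-1])
    i = above[0]
    if i == 0:
        return float(conc[0])
    c0, c1 = conc[i - 1], conc[i]
    r0, r1 = resp[i - 1], resp[i]
    if r1 == r0:
        return float(c1)
    return float(c0 + (target - r0) * (c1 - c0) / (r1 - r0))


def _fit_single(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float]:
    rmax_hi = 10.0 * resp.max()

    def residual(theta):
        return steady_state_response(conc, theta[0], theta[1]) - resp

    def solve(x0):
        return optimize.least_squares(
            residual,
            x0=x0,
            bounds=([KD_BOUNDS[0], 1e-9], [KD_BOUNDS[1], rmax_hi]),
            method="trf",
        )

    kd0 = float(np.clip(_half_max_conc(conc, resp), *KD_BOUNDS))
    best = solve([kd0, resp.max()])
    # multi-start over a log grid guards against the flat likelihood of the
    # weak-binding regime where the primary start can stall
    kd_grid = np.logspace(-3, 3, 7)
    rmax_grid = np.geomspace(0.2 * resp.max(), 5 * resp.max(), 7)
    for kd_s in kd_grid:
        for rm_s in rmax_grid:
            trial = solve([np.clip(kd_s, *KD_BOUNDS), rm_s])
            if trial.cost < best.cost - 1e-12:
                best = trial
    kd, rmax = best.x
    rmse = float(np.sqrt(np.mean(residual(best.x) ** 2)))
    return float(kd), float(rmax), rmse


def fit_steady_state(series: SteadyStateSeries) -> AffinityFit:
    """Least-squares (KD, Rmax) estimate from one equilibrium series.

    Minimizes sum (Req_i - C_i*Rmax/(C_i + KD))^2 with KD bounded in
    [1e-4, 1e4] uM and Rmax in (0, 10*max(Req)].  Initialization uses
    Rmax0 = max(Req) and KD0 = the concentration at half-maximal response;
    a 7x7 log-grid multi-start refines past local stalls.
    """
    if series.concentrations.size < 4:
        raise ValueError("steady-state fitting needs at least 4 concentration points")
    if np.allclose(series.responses, 0.0):
        raise ValueError("all responses are zero; nothing to fit")
    kd, rmax, rmse = _fit_single(series.concentrations, series.responses)
    return AffinityFit(
        kd=kd,
        rmax=rmax,
        rmse=rmse,
        saturation_flag=bool(kd > series.concentrations.max()),
        per_replicate=[(kd, rmax)],
        kd_mean=kd,
        kd_sd=float("nan"),
    )


def fit_triplicates(series_list: list[SteadyStateSeries]) -> AffinityFit:
    """Fit each replicate independently; report mean KD and its sample SD.

    A replicate that fails to fit is excluded with a warning; at least two
    successful replicates are required.  The pooled fit over all points is
    reported as the headline (kd, rmax).
    """
    per_rep: list[tuple[float, float]] = []
    good: list[SteadyStateSeries] = []
    for s in series_list:
        try:
            f = fit_steady_state(s)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"replicate {s.replicate} excluded from affinity fit: {exc}")
            continue
        per_rep.append((f.kd, f.rmax))
        good.append(s)
    if len(per_rep) < 2:
        raise ValueError("fewer than 2 replicates fitted successfully")
    conc = np.concatenate([s.concentrations for s in good])
    resp = np.concatenate([s.responses for s in good])
    order = np.argsort(conc, kind="stable")
    # pooled fit over all replicate points (concentrations may repeat)
    kd_pool, rmax_pool, rmse = _fit_single(conc[order], resp[order])
    kds = np.array([k for k, _ in per_rep])
    return AffinityFit(
        kd=kd_pool,
        rmax=rmax_pool,
        rmse=rmse,
        saturation_flag=bool(kd_pool > conc.max()),
        per_replicate=per_rep,
        kd_mean=float(kds.mean()),
        kd_sd=float(kds.std(ddof=1)),
    )


def read_steady_state(path) -> list[SteadyStateSeries]:
    """Read replicate/concentration_uM/response_RU tab-separated series."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for rep, sub in df.groupby("replicate"):
        sub = sub.sort_values("concentration_uM")
        out.append(
            SteadyStateSeries(
                replicate=int(rep),
                concentrations=sub["concentration_uM"].to_numpy(),
                responses=sub["response_RU"].to_numpy(),
            )
        )
    return out


def write_steady_state(series_list: list[SteadyStateSeries], path) -> None:
    import pandas as pd

    rows = [
        {"replicate": s.replicate, "concentration_uM": c, "response_RU": r}
        for s in series_list
        for c, r in zip(s.concentrations, s.responses)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
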