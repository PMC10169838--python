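"""Normalization, SSE objective and bounded kinetic-parameter estimation.

Observed activation readouts (arbitrary MFI units) and simulated equilibrium
ternary-complex curves are brought onto a common unitless scale before the
sum of squared errors is computed: the observed series is min-max normalized
over its own doses, the simulated series is divided by its own maximum over
the same doses.  Fitting starts from literature rate constants and keeps
every rate within one order of magnitude of its start (box bounds), using a
deterministic local bounded least-squares method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import ConvergenceError, DoseResponseCurve, ternary_at_doses
from .model import BindingParameters, ExperimentSetup, InvalidInputError, RATE_NAMES

__all__ = [
    "DegenerateDataError",
    "ObservedDoseResponse",
    "FitResult",
    "CohortSummary",
    "normalize_pair",
    "sse",
    "fit_pair",
    "fit_cohort",
]

#: Default factor by which a pair's initial SSE must exceed the cohort median
#: of initial SSEs to be flagged as a literature-value outlier.
OUTLIER_FACTOR = 3.0


class DegenerateDataError(ValueError):
    """An observed series carries no usable signal (e.g. constant readout)."""


@dataclass(frozen=True)
class ObservedDoseResponse:
    """One experimental dose-response series for a single antibody/receptor pair."""

    pair_id: str
    doses: np.ndarray  # µg/mL
    readout: np.ndarray  # MFI, arbitrary units
    readout_kind: str = ""

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        readout = np.asarray(self.readout, dtype=float)
        if doses.ndim != 1 or doses.shape != readout.shape:
            raise InvalidInputError("doses and readout must be 1-D arrays of equal length")
        if doses.size == 0:
            raise InvalidInputError(f"{self.pair_id}: empty dose-response series")
        if np.any(doses <= 0):
            raise InvalidInputError(f"{self.pair_id}: doses must be positive")
        if not np.all(np.isfinite(readout)):
            raise InvalidInputError(f"{self.pair_id}: readout must be finite")
        order = np.argsort(doses, kind="stable")
        object.__setattr__(self, "doses", doses[order])
        object.__setattr__(self, "readout", readout[order])


@dataclass(frozen=True)
class FitResult:
    pair_id: str
    params: BindingParameters
    sse_initial: float
    sse_fitted: float
    bounds: dict
    converged: bool
    message: str = ""
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "params": self.params.to_dict(),
            "sse_initial": self.sse_initial,
            "sse_fitted": self.sse_fitted,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "converged": self.converged,
            "message": self.message,
            "n_evaluations": self.n_evaluations,
        }


@dataclass(frozen=True)
class CohortSummary:
    results: tuple  # FitResult per successfully fitted pair
    mean_sse_initial: float
    mean_sse_fitted: float
    outlier_pairs: tuple = ()
    failed_pairs: dict = field(default_factory=dict)  # pair_id -> error message


def _simulated_at(observed_doses: np.ndarray, curve: DoseResponseCurve) -> np.ndarray:
    """Simulated ternary values on the observed doses.

    Exact dose matches are taken directly; otherwise values are interpolated
    linearly in log-dose on the simulated grid.
    """
    sim_d = curve.doses
    sim_v = curve.ternary
    out = np.empty_like(observed_doses, dtype=float)
    pos = sim_d > 0
    for i, d in enumerate(observed_doses):
        hit = np.nonzero(np.isclose(sim_d, d, rtol=1e-9, atol=0.0))[0]
        if hit.size:
            out[i] = sim_v[hit[0]]
            continue
        if not pos.any() or d < sim_d[pos].min() or d > sim_d[pos].max():
            raise InvalidInputError(
                f"observed dose {d} µg/mL outside the simulated grid; cannot interpolate"
            )
        out[i] = np.interp(np.log(d), np.log(sim_d[pos]), sim_v[pos])
    return out


def _normalize_sim(sim: np.ndarray, convention: str) -> np.ndarray:
    if convention == "minmax":
        lo, hi = sim.min(), sim.max()
        return (sim - lo) / (hi - lo) if hi > lo else np.zeros_like(sim)
    if convention == "max":
        peak = sim.max()
        return sim / peak if peak > 0 else np.zeros_like(sim)
    raise InvalidInputError(f"unknown normalization convention {convention!r}")


def normalize_pair(
    observed: ObservedDoseResponse,
    simulated: DoseResponseCurve,
    convention: str = "minmax",
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned unitless series (observed, simulated) on the observed doses.

    The observed series is min-max normalized to [0, 1] over its own doses.
    With the default ``convention="minmax"`` the simulated series is treated
    the same way, making the comparison exactly invariant under any affine
    readout map (MFI = gain * signal + offset); ``convention="max"`` instead
    divides the simulated series by its own maximum, matching normalization
    to a curve's peak.  The convention is isolated here so alternates can be
    swapped without touching the objective.
    """
    lo, hi = observed.readout.min(), observed.readout.max()
    if hi == lo:
        raise DegenerateDataError(f"{observed.pair_id}: constant readout series (max == min)")
    obs_norm = (observed.readout - lo) / (hi - lo)
    sim_norm = _normalize_sim(_simulated_at(observed.doses, simulated), convention)
    return obs_norm, sim_norm


def sse(observed_norm: np.ndarray, simulated_norm: np.ndarray) -> float:
    """Sum of squared errors between two aligned unitless series."""
    a = np.asarray(observed_norm, dtype=float)
    b = np.asarray(simulated_norm, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sum((a - b) ** 2))


def _objective_residuals(
    log10_k: np.ndarray,
    obs_norm: np.ndarray,
    doses: np.ndarray,
    setup: ExperimentSetup,
    method: str,
    convention: str,
) -> np.ndarray:
    params = BindingParameters.from_array(10.0 ** log10_k)
    tern = ternary_at_doses(setup, params, doses, method=method)
    return obs_norm - _normalize_sim(tern, convention)


def fit_pair(
    observed: ObservedDoseResponse,
    literature: BindingParameters,
    setup: ExperimentSetup,
    bound_decades: float = 1.0,
    method: str = "root",
    convention: str = "minmax",
    max_nfev: int | None = 200,
) -> FitResult:
    """Bounded local SSE minimization of the eight rate constants.

    The literature values are the (single) start point; each rate is bounded
    within ``bound_decades`` orders of magnitude of its start.  Optimization
    runs in log10-parameter space with a trust-region reflective least-squares
    method, so the fitted SSE can never exceed the initial SSE.
    """
    lo, hi = observed.readout.min(), observed.readout.max()
    if hi == lo:
        raise DegenerateDataError(f"{observed.pair_id}: constant readout series (max == min)")
    obs_norm = (observed.readout - lo) / (hi - lo)

    x0 = np.log10(literature.as_array())
    lb, ub = x0 - bound_decades, x0 + bound_decades
    bounds = {
        name: (float(10.0 ** l), float(10.0 ** u)) for name, l, u in zip(RATE_NAMES, lb, ub)
    }

    args = (obs_norm, observed.doses, setup, method, convention)
    r0 = _objective_residuals(x0, *args)
    sse_initial = float(np.sum(r0 ** 2))

    try:
        sol = least_squares(
            _objective_residuals,
            x0,
            args=args,
            bounds=(lb, ub),
            method="trf",
            diff_step=1e-4,
            xtol=1e-8,
            ftol=1e-8,
            gtol=1e-8,
            max_nfev=max_nfev,
        )
    except (ConvergenceError, RuntimeError) as exc:
        raise ConvergenceError(
            f"{observed.pair_id}: optimizer failed ({exc}); best-so-far is the start point"
        ) from exc

    sse_fitted = float(2.0 * sol.cost)
    fitted = BindingParameters.from_array(np.clip(10.0 ** sol.x, *zip(*bounds.values())))
    return FitResult(
        pair_id=observed.pair_id,
        params=fitted,
        sse_initial=sse_initial,
        sse_fitted=min(sse_fitted, sse_initial),
        bounds=bounds,
        converged=bool(sol.status > 0),
        message=str(sol.message),
        n_evaluations=int(sol.nfev),
    )


def fit_cohort(
    observations: list[ObservedDoseResponse],
    literature: dict,
    setups: dict,
    outlier_factor: float = OUTLIER_FACTOR,
    **fit_kwargs,
) -> CohortSummary:
    """Fit every pair; per-pair failures are recorded, not propagated.

    ``literature`` and ``setups`` map pair_id to :class:`BindingParameters`
    and :class:`ExperimentSetup`.  A pair is flagged as a literature-value
    outlier when its initial SSE exceeds ``outlier_factor`` times the cohort
    median of initial SSEs (requires >= 3 successfully evaluated pairs).
    """
    if not observations:
        raise InvalidInputError("empty cohort")
    results = []
    failed: dict[str, str] = {}
    for obs in observations:
        try:
            results.append(fit_pair(obs, literature[obs.pair_id], setups[obs.pair_id], **fit_kwargs))
        except (KeyError, DegenerateDataError, ConvergenceError, InvalidInputError) as exc:
            failed[obs.pair_id] = f"{type(exc).__name__}: {exc}"

    if results:
        init = np.array([r.sse_initial for r in results])
        fitted = np.array([r.sse_fitted for r in results])
        mean_initial = float(init.mean())
        mean_fitted = float(fitted.mean())
        outliers: tuple = ()
        if len(results) >= 3:
            med = float(np.median(init))
            outliers = tuple(
                r.pair_id for r in results if med > 0 and r.sse_initial > outlier_factor * med
            )
    else:
        mean_initial = mean_fitted = float("nan")
        outliers = ()
    return CohortSummary(
        results=tuple(results),
        mean_sse_initial=mean_initial,
        mean_sse_fitted=mean_fitted,
        outlier_pairs=outliers,
        failed_pairs=failed,
    )
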