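"""Equilibrium parameter scans with global normalization.

One quantity at a time (a rate constant, a dissociation constant via its
reverse rate, or the antigen density on target cells) is varied on a
log-spaced grid; every grid value gets a full equilibrium dose-response, and
the resulting matrix is normalized by its global maximum.  The default
factorization is a 30-value parameter grid x 30-dose grid (900 simulations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibrium import equilibrium_dose_response
from .model import BindingParameters, ExperimentSetup, InvalidInputError, RATE_NAMES

__all__ = ["AmbiguousScanError", "ScanResult", "SCANNABLE", "scan_parameter", "plateau_threshold"]

#: Quantities accepted by :func:`scan_parameter`.  ``kd1..kd4`` scans alter
#: the reverse rate at fixed forward rate.
SCANNABLE = tuple(RATE_NAMES) + ("kd1", "kd2", "kd3", "kd4", "antigens_per_target")


class AmbiguousScanError(RuntimeError):
    """Row maxima are not monotone, so a plateau threshold is ill-defined."""

    def __init__(self, message: str, profile: np.ndarray | None = None):
        super().__init__(message)
        self.profile = profile


@dataclass(frozen=True)
class ScanResult:
    parameter: str
    values: np.ndarray  # scanned parameter values, ascending
    doses: np.ndarray  # µg/mL
    ternary: np.ndarray  # (n_param, n_dose) equilibrium ternary, nM

    @property
    def normalized(self) -> np.ndarray:
        """Matrix scaled by its global maximum (zeros when everything is zero)."""
        peak = self.ternary.max() if self.ternary.size else 0.0
        if peak <= 0:
            return np.zeros_like(self.ternary)
        return self.ternary / peak

    def row_maxima(self) -> np.ndarray:
        return self.ternary.max(axis=1)


def _apply(name: str, value: float, params: BindingParameters, setup: ExperimentSetup):
    if name in RATE_NAMES:
        return params.replace(**{name: value}), setup
    if name in ("kd1", "kd2", "kd3", "kd4"):
        i = name[-1]
        kf = getattr(params, f"kf{i}")
        return params.replace(**{f"kr{i}": value * kf}), setup
    if name == "antigens_per_target":
        return params, setup.replace(antigens_per_target=value)
    raise InvalidInputError(f"unknown scan parameter {name!r}; allowed: {', '.join(SCANNABLE)}")


def scan_parameter(
    name: str,
    bounds: tuple,
    params: BindingParameters,
    setup: ExperimentSetup,
    n_param: int = 30,
    n_dose: int = 30,
    method: str = "kinetic",
) -> ScanResult:
    """Scan ``name`` over log-spaced ``bounds``, one dose-response per value.

    The dose grid is ``n_dose`` log-spaced points spanning the positive range
    of ``setup.dose_grid``.  Every row is produced by an ordinary
    :func:`~ternabind.equilibrium.equilibrium_dose_response` call on the
    modified inputs, so single rows are reproducible in isolation.
    """
    low, high = float(bounds[0]), float(bounds[1])
    if low <= 0 or high <= 0 or low >= high:
        raise InvalidInputError(f"bounds must satisfy 0 < low < high, got {bounds!r}")
    if n_param < 1 or n_dose < 2:
        raise InvalidInputError("need n_param >= 1 and n_dose >= 2")
    pos = [d for d in setup.dose_grid if d > 0]
    if not pos:
        raise InvalidInputError("setup.dose_grid has no positive doses to span")
    doses = np.geomspace(min(pos), max(pos), n_dose)
    base = setup.replace(dose_grid=tuple(doses))

    values = np.geomspace(low, high, n_param) if n_param > 1 else np.array([low])
    matrix = np.empty((len(values), n_dose))
    for i, v in enumerate(values):
        p_i, s_i = _apply(name, float(v), params, base)
        matrix[i] = equilibrium_dose_response(s_i, p_i, method=method).ternary
    return ScanResult(parameter=name, values=values, doses=doses, ternary=matrix)


def plateau_threshold(
    scan: ScanResult, fraction: float = 0.95, monotone_rtol: float = 1e-6
) -> float:
    """Smallest scanned value whose row-maximum reaches ``fraction`` of the asymptote.

    The asymptote is the row-maximum at the largest scanned value.  Row maxima
    must be non-decreasing (within ``monotone_rtol`` of the asymptote scale);
    otherwise the plateau is ambiguous and an error carrying the full profile
    is raised.
    """
    if not 0 < fraction <= 1:
        raise InvalidInputError(f"fraction must be in (0, 1], got {fraction}")
    maxima = scan.row_maxima()
    asymptote = maxima[-1]
    tol = monotone_rtol * max(asymptote, np.max(maxima), 1e-300)
    if np.any(np.diff(maxima) < -tol):
        raise AmbiguousScanError(
            f"row maxima of the {scan.parameter} scan are not monotone; no unique plateau",
            profile=maxima,
        )
    hit = np.nonzero(maxima >= fraction * asymptote)[0]
    return float(scan.values[hit[0]])
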