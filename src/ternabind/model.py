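"""Core mass-action model of ternary complex formation.

Three binding partners -- an effector-cell receptor (``Tc``), a bridging
adaptor antibody (``Ab``) and a target-cell antigen (``Tu``) -- assemble a
ternary complex through four reversible reactions:

    Tc + Ab    <-> Tc.Ab        (kf1 / kr1)
    Ab + Tu    <-> Ab.Tu        (kf2 / kr2)
    Tc.Ab + Tu <-> Tc.Ab.Tu    (kf3 / kr3)
    Tc + Ab.Tu <-> Tc.Ab.Tu    (kf4 / kr4)

The internal unit system is nM for concentrations and seconds for time.
Bench quantities (µg/mL antibody doses, cells x sites/cell) are converted
at the boundary by :func:`antibody_dose_to_molar` and :func:`sites_to_molar`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import Avogadro

__all__ = [
    "SPECIES",
    "RATE_NAMES",
    "InvalidInputError",
    "BindingParameters",
    "SystemState",
    "ExperimentSetup",
    "reaction_rates",
    "ode_rhs",
    "antibody_dose_to_molar",
    "sites_to_molar",
    "STOICHIOMETRY",
]

#: Species order used in every state vector.
SPECIES = ("Tc", "Ab", "Tu", "Tc_Ab", "Ab_Tu", "Tc_Ab_Tu")

#: Rate-constant order used in every parameter vector.
RATE_NAMES = ("kf1", "kf2", "kf3", "kf4", "kr1", "kr2", "kr3", "kr4")

#: Net stoichiometry of the eight reactions (species x reaction), signed.
#: Column order matches the reaction index rxn1..rxn8.
STOICHIOMETRY = np.array(
    [
        # rxn1 rxn2 rxn3 rxn4 rxn5 rxn6 rxn7 rxn8
        [-1, +1, 0, 0, 0, 0, -1, +1],  # Tc
        [-1, +1, -1, +1, 0, 0, 0, 0],  # Ab
        [0, 0, -1, +1, -1, +1, 0, 0],  # Tu
        [+1, -1, 0, 0, -1, +1, 0, 0],  # Tc.Ab
        [0, 0, +1, -1, 0, 0, -1, +1],  # Ab.Tu
        [0, 0, 0, 0, +1, -1, +1, -1],  # Tc.Ab.Tu
    ],
    dtype=float,
)


class InvalidInputError(ValueError):
    """A user-supplied quantity violates a model precondition."""


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise InvalidInputError(f"{name} must be strictly positive and finite, got {value!r}")


def _require_non_negative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InvalidInputError(f"{name} must be non-negative and finite, got {value!r}")


@dataclass(frozen=True)
class BindingParameters:
    """The eight kinetic rate constants of the four binding reactions.

    Forward constants ``kf1..kf4`` are in nM^-1 s^-1, reverse constants
    ``kr1..kr4`` in s^-1.  Equilibrium dissociation constants are derived
    as ``KD_i = kr_i / kf_i`` (nM).
    """

    kf1: float
    kf2: float
    kf3: float
    kf4: float
    kr1: float
    kr2: float
    kr3: float
    kr4: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            _require_positive(name, getattr(self, name))

    def kd(self, i: int) -> float:
        """Dissociation constant of reaction pair ``i`` (1-based), in nM."""
        if i not in (1, 2, 3, 4):
            raise InvalidInputError(f"reaction index must be 1..4, got {i}")
        return getattr(self, f"kr{i}") / getattr(self, f"kf{i}")

    @property
    def kd1(self) -> float:
        return self.kr1 / self.kf1

    @property
    def kd2(self) -> float:
        return self.kr2 / self.kf2

    @property
    def kd3(self) -> float:
        return self.kr3 / self.kf3

    @property
    def kd4(self) -> float:
        return self.kr4 / self.kf4

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, k: np.ndarray) -> "BindingParameters":
        k = np.asarray(k, dtype=float)
        if k.shape != (8,):
            raise InvalidInputError(f"expected 8 rate constants, got shape {k.shape}")
        return cls(**dict(zip(RATE_NAMES, k.tolist())))

    @classmethod
    def from_dict(cls, d: dict) -> "BindingParameters":
        missing = [n for n in RATE_NAMES if n not in d]
        if missing:
            raise InvalidInputError(f"missing rate constants: {missing}")
        return cls(**{n: float(d[n]) for n in RATE_NAMES})

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in RATE_NAMES}

    def replace(self, **kwargs: float) -> "BindingParameters":
        return replace(self, **kwargs)

    def detailed_balance_ratio(self) -> float:
        """(KD1 * KD3) / (KD2 * KD4): 1.0 for a thermodynamically consistent cycle."""
        return (self.kd1 * self.kd3) / (self.kd2 * self.kd4)

    def check_detailed_balance(self, rtol: float = 1e-6) -> bool:
        """Warn (without failing) when the binding cycle violates detailed balance.

        Independently sourced literature rates need not close the cycle,
        so the check is advisory only.
        """
        ratio = self.detailed_balance_ratio()
        consistent = abs(ratio - 1.0) <= rtol
        if not consistent:
            warnings.warn(
                f"binding cycle violates detailed balance: KD1*KD3/(KD2*KD4) = {ratio:.4g}",
                stacklevel=2,
            )
        return consistent


@dataclass(frozen=True)
class SystemState:
    """Concentrations (nM) of the six species."""

    Tc: float
    Ab: float
    Tu: float
    Tc_Ab: float
    Ab_Tu: float
    Tc_Ab_Tu: float

    def __post_init__(self) -> None:
        for name in SPECIES:
            _require_non_negative(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise InvalidInputError(f"expected 6 species, got shape {y.shape}")
        return cls(**dict(zip(SPECIES, y.tolist())))

    def conserved_totals(self) -> tuple[float, float, float]:
        """(total Tc, total Ab, total Tu) counting bound forms."""
        return (
            self.Tc + self.Tc_Ab + self.Tc_Ab_Tu,
            self.Ab + self.Tc_Ab + self.Ab_Tu + self.Tc_Ab_Tu,
            self.Tu + self.Ab_Tu + self.Tc_Ab_Tu,
        )


@dataclass(frozen=True)
class ExperimentSetup:
    """Bench-level description of a co-incubation experiment.

    ``dose_grid`` holds antibody doses in µg/mL; a zero dose is allowed so
    that no-antibody controls sit on the same grid.
    """

    n_effector_cells: float
    n_target_cells: float
    receptors_per_effector: float
    antigens_per_target: float
    volume_ml: float
    antibody_mw: float
    dose_grid: tuple = field(default_factory=tuple)
    t_max: float = 1e6
    equilibrium_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        _require_positive("n_effector_cells", self.n_effector_cells)
        _require_positive("n_target_cells", self.n_target_cells)
        _require_positive("receptors_per_effector", self.receptors_per_effector)
        _require_positive("antigens_per_target", self.antigens_per_target)
        _require_positive("volume_ml", self.volume_ml)
        _require_positive("antibody_mw", self.antibody_mw)
        _require_positive("t_max", self.t_max)
        _require_positive("equilibrium_tolerance", self.equilibrium_tolerance)
        grid = tuple(float(d) for d in self.dose_grid)
        for d in grid:
            _require_non_negative("dose", d)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise InvalidInputError("dose_grid must be strictly ascending")
        object.__setattr__(self, "dose_grid", grid)

    def replace(self, **kwargs) -> "ExperimentSetup":
        return replace(self, **kwargs)

    # --- unit conversions bound to this setup -------------------------------

    def effector_sites_molar(self) -> float:
        """Total receptor concentration contributed by effector cells (nM)."""
        return sites_to_molar(self.n_effector_cells, self.receptors_per_effector, self.volume_ml)

    def target_sites_molar(self) -> float:
        """Total antigen concentration contributed by target cells (nM)."""
        return sites_to_molar(self.n_target_cells, self.antigens_per_target, self.volume_ml)

    def dose_to_molar(self, dose_ug_per_ml: float) -> float:
        return antibody_dose_to_molar(dose_ug_per_ml, self.antibody_mw)

    def initial_state(self, dose_ug_per_ml: float) -> SystemState:
        """Fully dissociated mixture at the given antibody dose."""
        return SystemState(
            Tc=self.effector_sites_molar(),
            Ab=self.dose_to_molar(dose_ug_per_ml),
            Tu=self.target_sites_molar(),
            Tc_Ab=0.0,
            Ab_Tu=0.0,
            Tc_Ab_Tu=0.0,
        )


# --- array-level kernels (used by the integrator; no validation) ------------


def rates_vector(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """The eight reaction rates (nM/s) for state vector ``y`` and rates ``k``."""
    tc, ab, tu, tcab, abtu, tern = y
    kf1, kf2, kf3, kf4, kr1, kr2, kr3, kr4 = k
    return np.array(
        [
            kf1 * tc * ab,
            kr1 * tcab,
            kf2 * ab * tu,
            kr2 * abtu,
            kf3 * tcab * tu,
            kr3 * tern,
            kf4 * tc * abtu,
            kr4 * tern,
        ]
    )


def rhs_vector(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Time derivative of the six species: signed sum of the reaction rates."""
    return STOICHIOMETRY @ rates_vector(y, k)


def jacobian(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d(rhs)/dy, for stiff implicit integration."""
    tc, ab, tu, tcab, abtu, tern = y
    kf1, kf2, kf3, kf4, kr1, kr2, kr3, kr4 = k
    # d(rates)/dy, rows rxn1..rxn8, columns species
    dr = np.zeros((8, 6))
    dr[0, 0] = kf1 * ab
    dr[0, 1] = kf1 * tc
    dr[1, 3] = kr1
    dr[2, 1] = kf2 * tu
    dr[2, 2] = kf2 * ab
    dr[3, 4] = kr2
    dr[4, 3] = kf3 * tu
    dr[4, 2] = kf3 * tcab
    dr[5, 5] = kr3
    dr[6, 0] = kf4 * abtu
    dr[6, 4] = kf4 * tc
    dr[7, 5] = kr4
    return STOICHIOMETRY @ dr


# --- public operations ------------------------------------------------------


def reaction_rates(state: SystemState, params: BindingParameters) -> np.ndarray:
    """Evaluate the eight mass-action reaction rates (nM/s), rxn1..rxn8."""
    return rates_vector(state.as_array(), params.as_array())


def ode_rhs(state: SystemState, params: BindingParameters) -> np.ndarray:
    """Time derivatives of the six species (nM/s), in :data:`SPECIES` order."""
    return rhs_vector(state.as_array(), params.as_array())


def antibody_dose_to_molar(dose_ug_per_ml: float, mw_g_per_mol: float) -> float:
    """Convert an antibody dose in µg/mL to nM given its molecular weight."""
    _require_non_negative("dose", dose_ug_per_ml)
    _require_positive("molecular weight", mw_g_per_mol)
    # µg/mL = 1e-3 g/L; molar = 1e-3*dose/MW; nM = 1e9 * molar
    return dose_ug_per_ml * 1e6 / mw_g_per_mol


def sites_to_molar(n_cells: float, sites_per_cell: float, volume_ml: float) -> float:
    """Concentration (nM) of ``n_cells * sites_per_cell`` sites in ``volume_ml``."""
    _require_positive("n_cells", n_cells)
    _require_positive("sites_per_cell", sites_per_cell)
    _require_positive("volume_ml", volume_ml)
    volume_l = volume_ml * 1e-3
    return n_cells * sites_per_cell / (Avogadro * volume_l) * 1e9
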