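"""Bundled parameter and setup configurations for the studied antibody panel.

Rate constants are reconstructions from published binding kinetics for each
antibody/antigen pair plus the self-labeling receptor chemistry; site
densities are literature-typical values for the target lines.  They are
shipped as editable YAML under ``ternabind/configs`` so that any value can be
overridden without touching code.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .model import BindingParameters, ExperimentSetup, InvalidInputError

__all__ = ["PAIRS", "ANTIBODIES", "bundled_params", "bundled_setup", "load_pair"]

#: Antibody -> (antigen, params file stem, setup file stem)
ANTIBODIES = {
    "fmc63": "cd19",
    "rituximab": "cd20",
    "herceptin": "her2",
    "cetuximab": "egfr",
}

#: The eight antibody x receptor-type pairs of the experimental design.
PAIRS = tuple(
    f"{ab}_{receptor}" for ab in ANTIBODIES for receptor in ("synnotch", "car")
)


def _read_yaml(subdir: str, stem: str) -> dict:
    ref = resources.files("ternabind").joinpath(f"configs/{subdir}/{stem}.yaml")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise InvalidInputError(f"no bundled {subdir} config named {stem!r}") from exc
    return yaml.safe_load(text)


def params_from_mapping(doc: dict) -> tuple[BindingParameters, dict]:
    """Parse a parameter mapping (keys kf1..kr4 plus optional metadata)."""
    meta = doc.get("metadata", {}) or {}
    return BindingParameters.from_dict(doc), meta


def setup_from_mapping(doc: dict) -> ExperimentSetup:
    """Parse a setup mapping with unit-explicit key names."""
    grid = doc.get("dose_grid_ug_per_ml", ())
    if isinstance(grid, dict):
        grid = np.geomspace(float(grid["min"]), float(grid["max"]), int(grid["n"]))
    try:
        return ExperimentSetup(
            n_effector_cells=float(doc["n_effector_cells"]),
            n_target_cells=float(doc["n_target_cells"]),
            receptors_per_effector=float(doc["receptors_per_effector"]),
            antigens_per_target=float(doc["antigens_per_target"]),
            volume_ml=float(doc["volume_ml"]),
            antibody_mw=float(doc["antibody_mw_g_per_mol"]),
            dose_grid=tuple(float(d) for d in grid),
            t_max=float(doc.get("t_max_s", 1e6)),
            equilibrium_tolerance=float(doc.get("equilibrium_tolerance", 1e-8)),
        )
    except KeyError as exc:
        raise InvalidInputError(f"setup config missing key {exc}") from exc


def bundled_params(antibody: str) -> tuple[BindingParameters, dict]:
    """Literature-derived rate constants for one antibody, with metadata."""
    return params_from_mapping(_read_yaml("params", antibody.lower()))


def bundled_setup(antibody: str) -> ExperimentSetup:
    """Co-incubation setup for one antibody's target pairing."""
    return setup_from_mapping(_read_yaml("setups", antibody.lower()))


def load_pair(pair_id: str) -> tuple[BindingParameters, ExperimentSetup, dict]:
    """Parameters, setup and metadata for a ``<antibody>_<receptor>`` pair id."""
    try:
        antibody, receptor = pair_id.rsplit("_", 1)
    except ValueError:
        raise InvalidInputError(f"pair id must look like '<antibody>_<receptor>', got {pair_id!r}")
    if antibody not in ANTIBODIES or receptor not in ("synnotch", "car"):
        raise InvalidInputError(f"unknown pair {pair_id!r}; known pairs: {', '.join(PAIRS)}")
    params, meta = bundled_params(antibody)
    meta = dict(meta, receptor_type=receptor)
    return params, bundled_setup(antibody), meta
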