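"""Seeded synthetic dose-response datasets with the model's statistical structure.

Ground-truth hook-shaped equilibrium curves are mapped to arbitrary-unit
"MFI" readouts through a per-pair affine map (gain, offset) plus configurable
noise, emulating curve-level flow-cytometry summaries.  Everything is driven
by explicit integer seeds and regenerates byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import catalog
from .equilibrium import DoseResponseCurve, ternary_at_doses
from .fitting import ObservedDoseResponse
from .model import BindingParameters, ExperimentSetup, InvalidInputError

__all__ = ["SyntheticSpec", "generate_truth", "observe", "generate_dataset", "default_specs"]

_NOISE_KINDS = ("additive", "lognormal")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic antibody/receptor pair."""

    pair_id: str
    params: BindingParameters
    setup: ExperimentSetup
    doses: tuple  # µg/mL
    gain: float = 1e4  # MFI per normalized unit
    offset: float = 0.0  # MFI
    noise_sigma: float = 0.05  # on the normalized scale (or log scale for lognormal)
    noise_kind: str = "additive"
    seed: int = 0
    readout_kind: str = "synthetic-MFI"

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InvalidInputError(f"gain must be positive, got {self.gain}")
        if self.offset < 0:
            raise InvalidInputError(f"offset must be non-negative, got {self.offset}")
        if self.noise_sigma < 0:
            raise InvalidInputError(f"noise_sigma must be non-negative, got {self.noise_sigma}")
        if self.noise_kind not in _NOISE_KINDS:
            raise InvalidInputError(f"noise_kind must be one of {_NOISE_KINDS}")
        doses = tuple(float(d) for d in self.doses)
        if not doses or any(d <= 0 for d in doses):
            raise InvalidInputError("doses must be a non-empty tuple of positive values")
        object.__setattr__(self, "doses", doses)

    def to_dict(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "params": self.params.to_dict(),
            "doses": list(self.doses),
            "gain": self.gain,
            "offset": self.offset,
            "noise_sigma": self.noise_sigma,
            "noise_kind": self.noise_kind,
            "seed": self.seed,
            "readout_kind": self.readout_kind,
        }


def generate_truth(spec: SyntheticSpec, method: str = "kinetic") -> DoseResponseCurve:
    """Noise-free equilibrium dose-response at the spec's doses and truth parameters."""
    doses = np.asarray(spec.doses)
    tern = ternary_at_doses(spec.setup, spec.params, doses, method=method)
    return DoseResponseCurve(doses=doses, ternary=tern, antibody=spec.pair_id)


def observe(truth: DoseResponseCurve, spec: SyntheticSpec) -> ObservedDoseResponse:
    """Map a truth curve through the affine readout model plus seeded noise."""
    if truth.doses.shape != (len(spec.doses),) or not np.allclose(truth.doses, spec.doses):
        raise InvalidInputError("truth curve doses do not match the spec doses")
    norm = truth.normalized
    rng = np.random.default_rng(spec.seed)
    if spec.noise_kind == "additive":
        readout = spec.gain * (norm + rng.normal(0.0, spec.noise_sigma, norm.shape)) + spec.offset
    else:  # lognormal: multiplicative on the readout
        readout = (spec.gain * norm + spec.offset) * rng.lognormal(0.0, spec.noise_sigma, norm.shape)
    readout = np.clip(readout, 0.0, None)
    return ObservedDoseResponse(
        pair_id=spec.pair_id,
        doses=truth.doses.copy(),
        readout=readout,
        readout_kind=spec.readout_kind,
    )


def default_specs(
    seed: int,
    n_doses: int = 8,
    noise_sigma: float = 0.05,
    noise_kind: str = "additive",
) -> list[SyntheticSpec]:
    """The default 8-pair bundle: 4 antibodies x 2 receptor types.

    Ground-truth parameters come from the bundled literature configs; the
    per-pair gain (1e3-1e5 MFI, log-uniform) and offset (1e2-1e3 MFI) are
    drawn once from the master seed, as are per-pair noise seeds.
    """
    master = np.random.default_rng(seed)
    doses = tuple(np.geomspace(1e-4, 1e1, n_doses))
    specs = []
    for pair_id in catalog.PAIRS:
        params, setup, meta = catalog.load_pair(pair_id)
        gain = 10.0 ** master.uniform(3.0, 5.0)
        offset = master.uniform(1e2, 1e3)
        pair_seed = int(master.integers(0, 2**31 - 1))
        receptor = meta["receptor_type"]
        specs.append(
            SyntheticSpec(
                pair_id=pair_id,
                params=params,
                setup=setup,
                doses=doses,
                gain=gain,
                offset=offset,
                noise_sigma=noise_sigma,
                noise_kind=noise_kind,
                seed=pair_seed,
                readout_kind="TagBFP-MFI" if receptor == "synnotch" else "CD25-MFI",
            )
        )
    return specs


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_dataset(
    specs: list[SyntheticSpec], outdir: str | Path, method: str = "kinetic"
) -> dict:
    """Write a full bundle (observed CSV, truth CSV, parameter JSON, manifest).

    Returns the manifest, which records every spec and the SHA-256 of every
    written file; replaying the manifest's specs reproduces the bundle
    byte-identically.
    """
    if not specs:
        raise InvalidInputError("need at least one synthetic spec")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    obs_lines = ["pair_id,dose_ug_per_ml,readout_mfi,readout_kind"]
    truth_lines = ["pair_id,dose_ug_per_ml,ternary_nM,ternary_normalized"]
    params_doc = {}
    for spec in specs:
        truth = generate_truth(spec, method=method)
        obs = observe(truth, spec)
        norm = truth.normalized
        for d, r in zip(obs.doses, obs.readout):
            obs_lines.append(f"{spec.pair_id},{_fmt(d)},{_fmt(r)},{obs.readout_kind}")
        for d, t, n in zip(truth.doses, truth.ternary, norm):
            truth_lines.append(f"{spec.pair_id},{_fmt(d)},{_fmt(t)},{_fmt(n)}")
        params_doc[spec.pair_id] = spec.params.to_dict()

    files = {
        "observed.csv": "\n".join(obs_lines) + "\n",
        "truth.csv": "\n".join(truth_lines) + "\n",
        "params.json": json.dumps(params_doc, indent=2, sort_keys=True) + "\n",
    }
    written = {}
    try:
        for name, text in files.items():
            path = outdir / name
            path.write_text(text, encoding="utf-8")
            written[name] = _sha256(path)
    except OSError as exc:
        raise OSError(f"failed writing {name} under {outdir}: {exc}") from exc

    spec_blob = json.dumps([s.to_dict() for s in specs], sort_keys=True)
    manifest = {
        "specs": [s.to_dict() for s in specs],
        "spec_sha256": hashlib.sha256(spec_blob.encode()).hexdigest(),
        "method": method,
        "files": written,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
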