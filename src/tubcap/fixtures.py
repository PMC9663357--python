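"""Packaged fixture generator: the verification scenarios as trace files.

Writes, for a given output directory, the simulated traces used throughout
the validation work plus truth-value JSON for each:

* ``baseline`` — the reference verification circuit, 5 mV step;
* ``rt15/rt30/rt80`` — the same circuit at tubular lumen resistances of
  15, 30 and 80 MOhm (the experimentally observed range);
* ``gamma_mismatch`` — the γ-robustness configuration (R_mt = 345 MOhm, true γ 0.7);
* ``noisy_train`` — a 300-pulse 25 Hz train with additive noise, last 50
  sweeps averaged.

All randomness derives from the single ``seed``; re-running with the same
seed reproduces the files byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

from .circuit import VERIFICATION_CIRCUIT, CircuitParams, StepProtocol
from .io import write_trace
from .simulate import TrainProtocol, simulate_step, simulate_train

__all__ = ["generate_fixtures", "FIXTURE_CIRCUITS"]

FIXTURE_CIRCUITS: dict[str, CircuitParams] = {
    "baseline": VERIFICATION_CIRCUIT,
    "rt15": VERIFICATION_CIRCUIT,
    "rt30": VERIFICATION_CIRCUIT.replace(R_t=30.0),
    "rt80": VERIFICATION_CIRCUIT.replace(R_t=80.0),
    "gamma_mismatch": VERIFICATION_CIRCUIT.replace(R_mt=345.0),
}

_STEP = StepProtocol(U_1=-80.0, U_2=-75.0, t_pre=5.0, t_step=20.0, tau_p=0.05)


def _truth(params: CircuitParams) -> dict:
    return {
        "circuit": params.to_dict(),
        "k": params.k,
        "C_m": params.C_m,
        "f_t": params.f_t,
        "gamma_true": params.gamma,
    }


def generate_fixtures(outdir, seed: int = 0, dt: float = 0.01) -> list[Path]:
    """Write the fixture set into ``outdir`` and return the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, params in FIXTURE_CIRCUITS.items():
        trace = simulate_step(params, _STEP, dt=dt)
        trace.meta["fixture"] = name
        trace.meta["solution"] = "sucrose"
        tpath = outdir / f"{name}.csv"
        write_trace(trace, tpath)
        jpath = outdir / f"{name}_truth.json"
        with jpath.open("w") as fh:
            json.dump(_truth(params), fh, indent=2, sort_keys=True)
            fh.write("\n")
        written += [tpath, jpath]

    train = TrainProtocol(
        holding=-80.0, amplitude=5.0, t_step=20.0, rate=25.0,
        n_pulses=300, n_average=50)
    result = simulate_train(
        VERIFICATION_CIRCUIT, train, tau_p=0.05, dt=dt,
        noise_sigma=0.01, seed=seed)
    avg = result.average
    avg.meta["fixture"] = "noisy_train"
    avg.meta["solution"] = "sucrose"
    tpath = outdir / "noisy_train.csv"
    write_trace(avg, tpath)
    jpath = outdir / "noisy_train_truth.json"
    with jpath.open("w") as fh:
        json.dump(_truth(VERIFICATION_CIRCUIT), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written += [tpath, jpath]
    return written
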