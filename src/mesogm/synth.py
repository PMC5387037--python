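"""Synthetic gas-exchange data from the forward model.

Stands in for leaf-chamber measurements: for every (Ci, O2) pair of a
scenario, the coupled diffusion/biochemistry system is solved and
independent Gaussian noise (mean 0, sd = noise_sd) is added to A only —
Ci and J are treated as error-free, the simplest measurement-noise model
consistent with an instrument that controls Ci and assumes a fixed
fluorescence-derived J.  The noiseless Cc is attached to each record so
estimation paths can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimation import GasExchangeRecord
from .io import ScenarioConfig
from .network import operating_point

__all__ = ["generate_synthetic"]


def generate_synthetic(
    cfg: ScenarioConfig, rng: np.random.Generator | None = None
) -> list[GasExchangeRecord]:
    """Simulate gas-exchange records for a scenario.

    Deterministic for a fixed `cfg.seed` (an explicit `rng` overrides it).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    records = []
    for o in cfg.o2_levels:
        p = replace(cfg.photo, O=float(o))
        for ci in cfg.ci_grid:
            pt = operating_point(float(ci), p, cfg.resistance)
            noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
            records.append(
                GasExchangeRecord(
                    Ci=pt.Ci,
                    A=pt.A + noise,
                    J=p.J,
                    O=float(o),
                    Rd=p.Rd,
                    true_Cc=pt.Cc,
                    noise_sd=cfg.noise_sd,
                )
            )
    return records
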