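"""Synthetic photon TD50-vs-fractions datasets for fitting studies.

Stands in for measured dose–response series: model TD50 values are computed
for each fraction number at a reference dose rate from known generating
parameters, then multiplied by lognormal noise exp(N(0, sd)).  Regeneration
from the same parameters and seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damage import EndpointParams, NucleusModel
from .engines import IrradiationProtocol
from .response import EngineSettings, solve_td50

__all__ = ["SyntheticTD50Dataset", "make_synthetic_td50"]


@dataclass(frozen=True)
class SyntheticTD50Dataset:
    params: EndpointParams
    ref_rate: float
    fractions: tuple[int, ...]
    noise_sd: float
    seed: int
    repair: str
    table: pd.DataFrame = field(compare=False)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# synthetic photon TD50 dataset\n")
            fh.write(
                f"# k_idsb={self.params.k_idsb} k_cdsb={self.params.k_cdsb} "
                f"t_half_idsb={self.params.t_half_idsb} "
                f"t_half_cdsb={self.params.t_half_cdsb}\n"
            )
            fh.write(
                f"# ref_rate_gy_min={self.ref_rate} noise_sd={self.noise_sd} "
                f"seed={self.seed} repair={self.repair}\n"
            )
            self.table.to_csv(fh, index=False)


def make_synthetic_td50(
    params: EndpointParams,
    fractions: list[int],
    ref_rate: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    repair: str = "on",
    nucleus: NucleusModel | None = None,
    settings: EngineSettings | None = None,
    tol: float = 0.05,
) -> SyntheticTD50Dataset:
    """Generate a (n_fractions, td50_gy) table from known parameters."""
    if not fractions:
        raise ValueError("fractions list must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if repair not in ("on", "off"):
        raise ValueError("repair must be 'on' or 'off'")
    nucleus = nucleus or NucleusModel()
    settings = settings or EngineSettings()
    rate = math.inf if repair == "off" else ref_rate
    rng = np.random.default_rng(seed)
    rows = []
    for nf in fractions:
        proto = IrradiationProtocol(
            total_dose=1.0,
            dose_rate=rate,
            n_fractions=int(nf),
            n_timesteps=settings.n_timesteps,
        )
        td50 = solve_td50(proto, params, nucleus, settings, tol=tol).td50
        noisy = td50 * math.exp(rng.normal(0.0, noise_sd)) if noise_sd else td50
        rows.append((int(nf), noisy))
    table = pd.DataFrame(rows, columns=["n_fractions", "td50_gy"])
    return SyntheticTD50Dataset(
        params=params,
        ref_rate=ref_rate,
        fractions=tuple(int(f) for f in fractions),
        noise_sd=noise_sd,
        seed=seed,
        repair=repair,
        table=table,
    )
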