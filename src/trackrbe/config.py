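"""Run configuration: strict YAML parsing with unit-suffixed keys.

All physical quantities carry explicit unit suffixes in their key names
(``dose_gy``, ``rate_gy_min``, ``let_kev_um`` ...) so the mixed Gy/s vs
Gy/min usage common in the dose-rate literature cannot bite silently; the
canonical internal dose-rate unit is Gy/min and ``*_gy_s`` keys are
converted on input.  Unknown keys are rejected.  The full configuration is
echoed verbatim into every output table header.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

import yaml

from .damage import ENDPOINT_PRESETS, EndpointParams, NucleusModel
from .track import DEFAULT_SIGMA_UM, ParticleState, proton_for_let

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated configuration for one CLI invocation."""

    # endpoint
    endpoint_preset: str | None = None
    k_idsb: float | None = None
    k_cdsb: float | None = None
    t_half_idsb_min: float | None = None
    t_half_cdsb_min: float | None = None
    alpha_dsb_per_gy: float = 30.0
    # nucleus
    nucleus_radius_um: float = 5.0
    nucleus_height_um: float = 10.0
    n_domains: int = 3000
    # particle (ion runs)
    let_kev_um: float | None = None
    e_kin_mev_u: float | None = None
    z_ion: int = 1
    # protocol
    dose_gy: list = field(default_factory=list)
    rate_gy_min: list = field(default_factory=list)
    n_fractions: int = 1
    # engine
    n_iter: int = 10000
    n_timesteps: int = 100
    seed: int | None = None
    misrepair: str = "sample"
    enhancement: str = "ssb_pairing"  # or "identity"
    sigma_um: float = DEFAULT_SIGMA_UM

    def endpoint_params(self) -> EndpointParams:
        if self.endpoint_preset is not None:
            if self.endpoint_preset not in ENDPOINT_PRESETS:
                raise ValueError(
                    f"unknown endpoint preset {self.endpoint_preset!r}; "
                    f"available: {sorted(ENDPOINT_PRESETS)}"
                )
            base = ENDPOINT_PRESETS[self.endpoint_preset]
            over = {}
            if self.t_half_idsb_min is not None:
                over["t_half_idsb"] = self.t_half_idsb_min
            if self.t_half_cdsb_min is not None:
                over["t_half_cdsb"] = self.t_half_cdsb_min
            return base.replace(**over) if over else base
        if self.k_idsb is None or self.k_cdsb is None:
            raise ValueError("either endpoint_preset or explicit k_idsb/k_cdsb required")
        return EndpointParams(
            k_idsb=self.k_idsb,
            k_cdsb=self.k_cdsb,
            t_half_idsb=self.t_half_idsb_min or math.inf,
            t_half_cdsb=self.t_half_cdsb_min or math.inf,
            alpha_dsb=self.alpha_dsb_per_gy,
            label="custom",
        )

    def nucleus(self) -> NucleusModel:
        return NucleusModel(
            radius=self.nucleus_radius_um,
            height=self.nucleus_height_um,
            n_domains=self.n_domains,
        )

    def particle(self) -> ParticleState:
        if self.let_kev_um is None:
            raise ValueError("let_kev_um required for ion runs")
        if self.e_kin_mev_u is None:
            return proton_for_let(self.let_kev_um)
        return ParticleState(
            z_ion=self.z_ion, e_kin=self.e_kin_mev_u, let=self.let_kev_um
        )

    def echo_lines(self, version: str) -> list[str]:
        lines = [f"# trackrbe {version}"]
        for key, val in asdict(self).items():
            lines.append(f"# {key} = {val}")
        return lines


def load_config(path: str | None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (strict keys), apply non-None overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
    # accept Gy/s variants and convert to the canonical Gy/min
    if "rate_gy_s" in raw:
        raw["rate_gy_min"] = [60.0 * float(r) for r in _as_list(raw.pop("rate_gy_s"))]
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for key, val in (overrides or {}).items():
        if val is not None:
            if key not in known:
                raise ValueError(f"unknown override {key!r}")
            setattr(cfg, key, val)
    cfg.dose_gy = [float(d) for d in _as_list(cfg.dose_gy)]
    cfg.rate_gy_min = [float(r) for r in _as_list(cfg.rate_gy_min)]
    return cfg


def _as_list(x) -> list:
    if x is None:
        return []
    if isinstance(x, (list, tuple)):
        return list(x)
    return [x]
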