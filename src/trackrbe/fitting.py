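"""Least-squares fitting of the lethality parameters to TD50 data.

`TD50Model` follows the statsmodels Model/Results idiom: the model is built
from a table of measured photon TD50 values versus number of fractions
(plus the fixed experimental conditions — reference dose rate, repair
half-lives, nucleus geometry), and ``fit()`` returns a `TD50ModelResults`
carrying the estimated (K_iDSB, K_cDSB), their approximate standard errors,
residual diagnostics and a ``summary()`` table.

The objective is the sum of squared differences between model TD50
(obtained by the iso-effect solver, with repair kinetics on or off) and the
measured TD50, minimised over log10(K) with a derivative-free simplex —
derivatives are unavailable through the Monte Carlo, and common random
numbers keep the objective a deterministic function of the parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .damage import EndpointParams, NucleusModel
from .engines import IrradiationProtocol
from .response import EngineSettings, solve_td50

__all__ = ["TD50Model", "TD50ModelResults", "fit_lethality_params"]

_LOG_BOUNDS = (-8.0, 0.0)


class TD50Model:
    """Photon TD50 dose–response model over the number of fractions.

    Parameters
    ----------
    data :
        DataFrame with columns ``n_fractions`` and ``td50_gy``.
    t_half_idsb, t_half_cdsb :
        Fixed repair half-lives (minutes) during the fit.
    ref_rate :
        Photon dose rate of the measurements, Gy/min.
    repair :
        "on" solves TD50 with the time-resolved engine at ``ref_rate``;
        "off" uses the acute closed form (dose rate ignored).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        t_half_idsb: float,
        t_half_cdsb: float,
        ref_rate: float,
        repair: str = "on",
        alpha_dsb: float = 30.0,
        nucleus: NucleusModel | None = None,
        settings: EngineSettings | None = None,
        tol: float = 0.05,
    ) -> None:
        if repair not in ("on", "off"):
            raise ValueError("repair must be 'on' or 'off'")
        data = pd.DataFrame(data)
        missing = {"n_fractions", "td50_gy"} - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns {sorted(missing)}")
        if len(data) < 2:
            raise ValueError("need at least 2 TD50 data points to fit 2 parameters")
        if (data["td50_gy"] <= 0).any() or (data["n_fractions"] < 1).any():
            raise ValueError("td50_gy must be positive, n_fractions >= 1")
        self.data = data.reset_index(drop=True)
        self.t_half_idsb = t_half_idsb
        self.t_half_cdsb = t_half_cdsb
        self.ref_rate = ref_rate
        self.repair = repair
        self.alpha_dsb = alpha_dsb
        self.nucleus = nucleus or NucleusModel()
        self.settings = settings or EngineSettings()
        self.tol = tol

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "TD50Model":
        return cls(data, **kwargs)

    def _params_for(self, k_idsb: float, k_cdsb: float) -> EndpointParams:
        return EndpointParams(
            k_idsb=k_idsb,
            k_cdsb=k_cdsb,
            t_half_idsb=self.t_half_idsb,
            t_half_cdsb=self.t_half_cdsb,
            alpha_dsb=self.alpha_dsb,
        )

    def predict(self, k_idsb: float, k_cdsb: float, n_fractions=None) -> np.ndarray:
        """Model TD50 (total dose, Gy) for each fraction number."""
        if n_fractions is None:
            n_fractions = self.data["n_fractions"].to_numpy()
        ep = self._params_for(k_idsb, k_cdsb)
        rate = math.inf if self.repair == "off" else self.ref_rate
        out = np.empty(len(n_fractions))
        for i, nf in enumerate(np.atleast_1d(n_fractions)):
            proto = IrradiationProtocol(
                total_dose=1.0,
                dose_rate=rate,
                n_fractions=int(nf),
                n_timesteps=self.settings.n_timesteps,
            )
            out[i] = solve_td50(
                proto, ep, self.nucleus, self.settings, tol=self.tol
            ).td50
        return out

    def _objective(self, log_k: np.ndarray) -> float:
        lo, hi = _LOG_BOUNDS
        penalty = 0.0
        clipped = np.clip(log_k, lo, hi)
        penalty = 1e6 * float(np.sum((log_k - clipped) ** 2))
        k_i, k_c = np.minimum(10.0 ** clipped, 1.0)
        if k_i > k_c:  # keep the clustered damage at least as lethal
            penalty += 1e4 * (math.log10(k_i) - math.log10(k_c)) ** 2
            k_i = k_c
        pred = self.predict(k_i, k_c)
        obs = self.data["td50_gy"].to_numpy()
        return float(np.sum((pred - obs) ** 2)) + penalty

    def fit(
        self,
        x0: tuple[float, float] = (1e-4, 1e-2),
        xatol: float = 1e-4,
        fatol: float = 1e-10,
        maxiter: int = 400,
    ) -> "TD50ModelResults":
        """Minimise the TD50 residual sum of squares over (K_i, K_c)."""
        log0 = np.log10(np.asarray(x0, dtype=float))
        res = minimize(
            self._objective,
            log0,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
        )
        k_i, k_c = np.minimum(10.0 ** np.clip(res.x, *_LOG_BOUNDS), 1.0)
        pred = self.predict(k_i, k_c)
        obs = self.data["td50_gy"].to_numpy()
        resid = obs - pred
        bse = self._log10_bse(res.x, resid)
        boundary = bool(
            np.any(np.isclose(res.x, _LOG_BOUNDS[0], atol=1e-3))
            or np.any(np.isclose(res.x, _LOG_BOUNDS[1], atol=1e-3))
        )
        return TD50ModelResults(
            model=self,
            k_idsb=float(k_i),
            k_cdsb=float(k_c),
            fittedvalues=pred,
            resid=resid,
            rss=float(np.sum(resid**2)),
            converged=bool(res.success),
            boundary_pinned=boundary,
            nit=int(res.nit),
            bse_log10=bse,
        )

    def _log10_bse(self, log_k: np.ndarray, resid: np.ndarray) -> np.ndarray:
        """Gauss-Newton standard errors on the log10 scale (finite
        differences with common random numbers)."""
        n, p = len(resid), 2
        if n <= p:
            return np.full(2, np.nan)
        h = 0.05
        jac = np.empty((n, p))

        def _ks(lk):
            return np.minimum(10.0 ** np.clip(lk, *_LOG_BOUNDS), 1.0)

        base = self.predict(*_ks(log_k))
        for j in range(p):
            step = log_k.copy()
            step[j] -= h  # inward step keeps boundary-pinned fits in range
            jac[:, j] = (base - self.predict(*_ks(step))) / h
        sigma2 = float(np.sum(resid**2)) / (n - p)
        try:
            cov = sigma2 * np.linalg.inv(jac.T @ jac)
            return np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            return np.full(2, np.nan)


@dataclass
class TD50ModelResults:
    """Fit results: point estimates, diagnostics, and a summary table."""

    model: TD50Model
    k_idsb: float
    k_cdsb: float
    fittedvalues: np.ndarray
    resid: np.ndarray
    rss: float
    converged: bool
    boundary_pinned: bool
    nit: int
    bse_log10: np.ndarray

    @property
    def params(self) -> dict[str, float]:
        return {"k_idsb": self.k_idsb, "k_cdsb": self.k_cdsb}

    def endpoint_params(self) -> EndpointParams:
        return self.model._params_for(self.k_idsb, self.k_cdsb)

    def summary(self) -> str:
        m = self.model
        lines = [
            "TD50 lethality-parameter fit",
            "=" * 46,
            f"observations:       {len(self.resid)}",
            f"repair kinetics:    {m.repair} (ref rate {m.ref_rate} Gy/min)",
            f"half-lives [min]:   {m.t_half_idsb} / {m.t_half_cdsb}",
            f"converged:          {self.converged} (iters {self.nit})",
            f"boundary pinned:    {self.boundary_pinned}",
            f"residual SS [Gy²]:  {self.rss:.4g}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'se(log10)':>12}",
            f"{'K_iDSB':<10}{self.k_idsb:>12.4g}{self.bse_log10[0]:>12.3g}",
            f"{'K_cDSB':<10}{self.k_cdsb:>12.4g}{self.bse_log10[1]:>12.3g}",
        ]
        return "\n".join(lines)


def fit_lethality_params(
    td50_data: pd.DataFrame,
    ref_rate: float,
    repair: str,
    t_half_idsb: float,
    t_half_cdsb: float,
    nucleus: NucleusModel | None = None,
    settings: EngineSettings | None = None,
    x0: tuple[float, float] = (1e-4, 1e-2),
    tol: float = 0.05,
) -> TD50ModelResults:
    """Functional wrapper around :class:`TD50Model` (construct + fit)."""
    model = TD50Model(
        td50_data,
        t_half_idsb=t_half_idsb,
        t_half_cdsb=t_half_cdsb,
        ref_rate=ref_rate,
        repair=repair,
        nucleus=nucleus,
        settings=settings,
        tol=tol,
    )
    return model.fit(x0=x0)
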