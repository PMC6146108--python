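"""15N tracer uptake rates and the new-production budget.

Rates follow the standard tracer mass-balance: the transfer of 15N atom
percent excess from the dissolved pool into particulate N over the
incubation, scaled by the particulate N concentration,

    rate = (A_PN(t_f) - A_PN(t_0)) / (A_dis - A_PN(t_0)) * PN / t .

Rates measured at the three light depths are trapezoid-integrated over
the euphotic zone (surface value extended to 0 m, bottom at the deepest
sampled depth), converted to carbon with the Redfield 106:16 ratio, and
combined into the f-ratio: new production (nitrate uptake + N2 fixation)
over total production (nitrate + N2 + ammonium + urea).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NATURAL_ATOM_PCT_15N, REDFIELD_C_N, AnalysisConfig
from .errors import InputError, UndefinedPoolError
from .io import UptakeObservation

BUDGET_SUBSTRATES = ("NH4", "NO3", "urea", "N2")


def dissolved_atom_pct(
    ambient: float,
    spike: float,
    spike_atom_pct: float,
    natural_atom_pct: float = NATURAL_ATOM_PCT_15N,
) -> float:
    """15N atom% of the dissolved pool after the tracer spike (mass-
    weighted mixing of spike and ambient substrate)."""
    if ambient < 0 or spike < 0:
        raise InputError("concentrations must be >= 0")
    total = ambient + spike
    if total == 0:
        raise UndefinedPoolError("ambient + spike pool is empty")
    return (spike * spike_atom_pct + ambient * natural_atom_pct) / total


def irms_correct(
    raw_atom_pct: float | np.ndarray,
    size_signal: float | np.ndarray = 0.0,
    drift_index: float | np.ndarray = 0.0,
    calibration: tuple[float, float] | None = None,
) -> float | np.ndarray:
    """Linear size-effect / drift correction of raw IRMS atom%.

    ``calibration`` supplies ``(a, b)`` so that
    ``corrected = raw - (a * size_signal + b * drift_index)``. Without a
    calibration the data pass through unchanged, with a warning.
    """
    if calibration is None:
        warnings.warn("no IRMS calibration supplied; returning raw atom%",
                      stacklevel=2)
        return raw_atom_pct
    a, b = calibration
    return raw_atom_pct - (a * np.asarray(size_signal)
                           + b * np.asarray(drift_index))


def fit_irms_calibration(standards: pd.DataFrame) -> tuple[float, float]:
    """Least-squares (a, b) from reference standards.

    ``standards`` columns: raw_atom_pct, true_atom_pct, size_signal,
    drift_index. Fits residual = a*size + b*drift.
    """
    resid = (standards["raw_atom_pct"] - standards["true_atom_pct"]).to_numpy()
    X = standards[["size_signal", "drift_index"]].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, resid, rcond=None)
    return float(coef[0]), float(coef[1])


def uptake_rate(obs: UptakeObservation,
                natural_atom_pct: float = NATURAL_ATOM_PCT_15N) -> float:
    """Tracer uptake rate in µmol N l^-1 d^-1 from one incubation.

    Negative apparent rates (t_f below t_0 within instrument noise) are
    floored at zero with a warning.
    """
    if obs.duration_d <= 0:
        raise InputError("duration must be positive")
    a_dis = dissolved_atom_pct(
        obs.ambient_conc_umol_l, obs.spike_conc_umol_l,
        obs.spike_atom_pct, natural_atom_pct)
    if a_dis <= obs.atom_pct_t0:
        raise InputError(
            "dissolved pool atom% must exceed the t0 particulate atom%")
    ape = obs.atom_pct_tf - obs.atom_pct_t0
    rate = (ape / (a_dis - obs.atom_pct_t0)) * obs.pn_conc_umol_l \
        / obs.duration_d
    if rate < 0:
        warnings.warn(
            f"negative apparent uptake ({rate:.3g}) floored at 0",
            stacklevel=2)
        return 0.0
    return float(rate)


def depth_integrate(
    depths: np.ndarray | list[float],
    rates: np.ndarray | list[float],
    z_top: float = 0.0,
    z_bottom: float | None = None,
) -> float:
    """Trapezoid-integrate a rate profile over depth.

    Rates in µmol N l^-1 d^-1 (= mmol N m^-3 d^-1) against depths in m
    give mmol N m^-2 d^-1. The shallowest rate is extended up to
    ``z_top``; integration stops at ``z_bottom`` (default: the deepest
    measurement), interpolating if it falls between measurements.
    """
    z = np.asarray(depths, dtype=float)
    r = np.asarray(rates, dtype=float)
    if z.size == 0:
        raise InputError("at least one depth is required")
    if z.size != r.size:
        raise InputError("depths and rates must have equal length")
    if np.any(np.diff(z) <= 0):
        raise InputError("depths must be strictly increasing")
    if np.any(r < 0):
        raise InputError("rates must be >= 0")
    if z_bottom is None:
        z_bottom = float(z[-1])
    if z_bottom <= z_top:
        raise InputError("z_bottom must exceed z_top")
    # clip profile to [z_top, z_bottom] with boundary extension/interpolation
    zz = np.concatenate(([z_top], z[(z > z_top) & (z < z_bottom)],
                         [z_bottom]))
    rr = np.interp(zz, z, r)  # np.interp extends endpoints as constants
    return float(np.trapezoid(rr, zz))


def f_ratio(no3: float, n2: float, nh4: float, urea: float) -> float:
    """New production over total production.

    New = nitrate uptake + N2 fixation; total adds ammonium and urea.
    """
    for name, v in (("no3", no3), ("n2", n2), ("nh4", nh4), ("urea", urea)):
        if v < 0:
            raise InputError(f"{name} rate must be >= 0")
    total = no3 + n2 + nh4 + urea
    if total <= 0:
        raise InputError("total production is zero; f-ratio undefined")
    return (no3 + n2) / total


def redfield_c(n_rate: float, c_n: float = REDFIELD_C_N) -> float:
    """Carbon fixation supportable by an N uptake rate (Redfield 106:16)."""
    if n_rate < 0:
        raise InputError("n_rate must be >= 0")
    return n_rate * c_n


@dataclass
class UptakeBudget:
    """Depth-integrated production budget across the four N sources."""

    integrated: dict[str, float]       # mmol N m^-2 d^-1 per substrate
    fractions: dict[str, float]        # share of the computed total
    c_equivalent: dict[str, float]     # mmol C m^-2 d^-1 per substrate
    total_n: float
    total_c: float
    f_ratio: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"substrate": s,
             "n_uptake_mmol_m2_d": self.integrated[s],
             "fraction_of_total": self.fractions[s],
             "c_fixation_mmol_m2_d": self.c_equivalent[s]}
            for s in BUDGET_SUBSTRATES
        ]
        rows.append({"substrate": "total",
                     "n_uptake_mmol_m2_d": self.total_n,
                     "fraction_of_total": 1.0,
                     "c_fixation_mmol_m2_d": self.total_c})
        rows.append({"substrate": "f_ratio",
                     "n_uptake_mmol_m2_d": np.nan,
                     "fraction_of_total": self.f_ratio,
                     "c_fixation_mmol_m2_d": np.nan})
        return pd.DataFrame(rows)


def build_budget(
    profiles: dict[str, tuple[list[float], list[float]]],
    config: AnalysisConfig | None = None,
) -> UptakeBudget:
    """Assemble the budget from per-substrate (depths, rates) profiles.

    Missing substrates are treated as zero with a warning; an all-zero
    budget raises (f-ratio undefined).
    """
    config = config or AnalysisConfig()
    integrated: dict[str, float] = {}
    for s in BUDGET_SUBSTRATES:
        if s not in profiles:
            warnings.warn(f"no profile for {s}; treating as zero uptake",
                          stacklevel=2)
            integrated[s] = 0.0
            continue
        depths, rates = profiles[s]
        integrated[s] = depth_integrate(
            depths, rates, z_top=config.z_top, z_bottom=config.z_bottom)
    total = sum(integrated.values())
    if total <= 0:
        raise InputError("all-zero uptake profiles; budget undefined")
    fractions = {s: v / total for s, v in integrated.items()}
    c_equiv = {s: redfield_c(v, config.redfield_c_n)
               for s, v in integrated.items()}
    return UptakeBudget(
        integrated=integrated, fractions=fractions, c_equivalent=c_equiv,
        total_n=total, total_c=redfield_c(total, config.redfield_c_n),
        f_ratio=f_ratio(integrated["NO3"], integrated["N2"],
                        integrated["NH4"], integrated["urea"]),
    )


def rates_from_observations(
    observations: list[UptakeObservation],
    natural_atom_pct: float = NATURAL_ATOM_PCT_15N,
) -> pd.DataFrame:
    """Per-observation uptake rates, one row per incubation."""
    rows = []
    for obs in observations:
        rows.append({
            "substrate": obs.substrate, "depth_m": obs.depth_m,
            "light_level": obs.light_level,
            "rate_umol_l_d": uptake_rate(obs, natural_atom_pct),
        })
    return pd.DataFrame(
        rows, columns=["substrate", "depth_m", "light_level", "rate_umol_l_d"])


def profiles_from_rates(rates: pd.DataFrame
                        ) -> dict[str, tuple[list[float], list[float]]]:
    """Group per-observation rates into per-substrate depth profiles,
    averaging replicates at the same depth."""
    out: dict[str, tuple[list[float], list[float]]] = {}
    for s, sub in rates.groupby("substrate"):
        prof = (sub.groupby("depth_m")["rate_umol_l_d"].mean()
                .sort_index())
        out[str(s)] = (list(prof.index), list(prof.values))
    return out
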