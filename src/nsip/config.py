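"""Configuration objects for simulation and analysis.

Two frozen dataclasses hold every tunable threshold; both can be loaded
from a single YAML file with ``simulation:`` and ``analysis:`` sections.
All defaults are documented in docs/methods.md.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

#: Natural abundance of 15N, atom percent.
NATURAL_ATOM_PCT_15N = 0.366

#: Canonical Redfield C:N molar ratio (106:16).
REDFIELD_C_N = 106.0 / 16.0

SUBSTRATES = ("NH4", "NO3", "urea", "N2")
LABELS = ("15N", "14N_control")
LIGHT_LEVELS = ("50", "10", "1")

#: Light level (% surface PAR) -> sampling depth in metres at the study site.
LIGHT_DEPTH_M = {"50": 5.0, "10": 17.0, "1": 35.0}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic CsCl-gradient experiment.

    Densities in g ml^-1, DNA masses in ng, volumes in µl.
    """

    n_fractions: int = 50
    fraction_volume_ul: float = 100.0
    density_min: float = 1.66
    density_max: float = 1.77
    band_sd: float = 0.006          # Gaussian band width at equilibrium
    delta_rho_max: float = 0.016    # density gain at 100 atom% 15N
    gc_slope: float = 0.098         # g/ml per unit GC fraction
    gc_intercept: float = 1.660     # g/ml at GC = 0
    reads_per_fraction: int = 50000
    dna_total_ng: float = 2000.0
    qubit_cv: float = 0.05          # multiplicative bulk-DNA quantification CV
    seq_min_mass_share: float = 1e-6  # fraction sequenced only above this
                                      # share of total gradient DNA
    refractometer_sd: float = 1e-4  # additive density measurement noise
    irms_sd: float = 0.0            # atom% instrument noise for uptake sims
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.density_min < self.density_max:
            raise ConfigError("density_min must be < density_max")
        if self.band_sd <= 0:
            raise ConfigError("band_sd must be positive")
        if self.delta_rho_max < 0:
            raise ConfigError("delta_rho_max must be >= 0")
        if self.n_fractions < 1:
            raise ConfigError("n_fractions must be >= 1")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and constants of the enrichment and budget analyses."""

    min_fraction_reads: int = 100   # drop fractions with fewer total reads
    min_band_fractions: int = 3     # minimum retained fractions per band
    band_tail_pct: float = 2.0      # band window: >= this % of the OTU's peak
    min_otu_reads: int = 500        # exclude OTU bands with fewer summed reads
    min_effective_n: float = 2.0    # minimum Kish n for the Welch test
    fdr: float = 0.1                # Benjamini-Hochberg false discovery rate
    min_percent: float = 30.0       # minimum % DNA enrichment to call positive
    delta_rho_max: float = 0.016    # full-label shift for % enrichment scaling
    two_sided: bool = False         # default one-sided (15N only adds density)
    natural_atom_pct: float = NATURAL_ATOM_PCT_15N
    redfield_c_n: float = REDFIELD_C_N
    z_top: float = 0.0              # integration surface boundary, m
    z_bottom: float | None = None   # None -> deepest sampled depth

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ConfigError("fdr must be in (0, 1)")
        if self.delta_rho_max <= 0:
            raise ConfigError("delta_rho_max must be positive")


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown {where} keys: {sorted(unknown)}")
    try:
        return cls(**section)
    except TypeError as exc:  # wrong type sneaks through dataclass init
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> tuple[SimConfig, AnalysisConfig]:
    """Load ``simulation:`` and ``analysis:`` sections from a YAML file.

    Missing sections or keys fall back to defaults; unknown keys raise
    :class:`ConfigError` rather than being ignored.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    sim = _build(SimConfig, raw.get("simulation", {}) or {}, "simulation")
    ana = _build(AnalysisConfig, raw.get("analysis", {}) or {}, "analysis")
    return sim, ana
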