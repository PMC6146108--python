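"""Synthetic DNA-SIP experiments.

Generates CsCl gradients, per-fraction amplicon read counts, and tracer
incubation measurements with the statistical structure the analysis
assumes: each OTU's DNA forms a Gaussian band in buoyant density whose
center is set by GC content and rises linearly with the fraction of 15N
incorporated into its DNA; fractions are collected densest-first; reads
are drawn multinomially per fraction from the community's DNA-mass
proportions; bulk DNA quantification and density measurements carry
instrument noise.

All randomness flows from ``SimConfig.seed``; per-gradient generators are
split deterministically from the gradient id, so adding a gradient never
reshuffles another gradient's draws.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import NATURAL_ATOM_PCT_15N, SimConfig
from .errors import ConfigError, InfeasibleRateError
from .io import Gradient, Treatment, UptakeObservation

GC_RANGE = (0.35, 0.65)
ABUNDANCE_LOGNORMAL_SIGMA = 0.8


@dataclass
class OTUDef:
    """Ground-truth definition of one simulated OTU."""

    otu_id: str
    gc_fraction: float
    domain_flag: str  # "prokaryote" | "eukaryote_chloroplast"
    baseline_abundance: float
    #: treatment key -> atom fraction of 15N in this OTU's DNA (0 for
    #: non-assimilators and for every 14N control).
    atom_fraction_15n: dict[str, float] = field(default_factory=dict)

    def atom_fraction(self, treatment: Treatment) -> float:
        if treatment.is_control:
            return 0.0
        return self.atom_fraction_15n.get(treatment.key, 0.0)


def otu_ids(n_otus: int) -> list[str]:
    """The otu_id labels :func:`simulate_community` assigns for ``n_otus``."""
    width = len(str(n_otus))
    return [f"OTU{i + 1:0{width}d}" for i in range(n_otus)]


def simulate_community(
    n_otus: int,
    config: SimConfig,
    true_assimilators: Mapping[Treatment, Iterable[str]] | None = None,
    atom_fraction: float = 0.5,
    euk_fraction: float = 0.2,
) -> list[OTUDef]:
    """Draw a community of ``n_otus`` OTUs.

    GC fractions are uniform on [0.35, 0.65]; relative abundances are
    lognormal (a skewed species-abundance form) normalized to sum to 1.
    OTUs listed in ``true_assimilators`` incorporate 15N at
    ``atom_fraction`` in that treatment; everyone else, and every control,
    stays at natural abundance.
    """
    if n_otus < 1:
        raise ConfigError("n_otus must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5eed]))
    ids = otu_ids(n_otus)
    gc = rng.uniform(*GC_RANGE, size=n_otus)
    raw = rng.lognormal(mean=0.0, sigma=ABUNDANCE_LOGNORMAL_SIGMA, size=n_otus)
    abundance = raw / raw.sum()
    n_euk = int(round(euk_fraction * n_otus))
    flags = np.array(["prokaryote"] * n_otus, dtype=object)
    if n_euk:
        flags[rng.choice(n_otus, size=n_euk, replace=False)] = \
            "eukaryote_chloroplast"

    community = [
        OTUDef(otu_id=ids[i], gc_fraction=float(gc[i]),
               domain_flag=str(flags[i]),
               baseline_abundance=float(abundance[i]))
        for i in range(n_otus)
    ]
    by_id = {o.otu_id: o for o in community}
    for treatment, members in (true_assimilators or {}).items():
        if treatment.is_control:
            raise ConfigError("controls cannot carry 15N assimilators")
        for oid in members:
            if oid not in by_id:
                raise ConfigError(
                    f"unknown otu_id {oid!r} in true_assimilators")
            by_id[oid].atom_fraction_15n[treatment.key] = float(atom_fraction)
    return community


def band_center(otu: OTUDef, treatment: Treatment,
                config: SimConfig) -> float:
    """Equilibrium buoyant density of one OTU's DNA band (g ml^-1).

    Linear in GC content plus a linear gain of ``delta_rho_max`` at full
    15N labeling.
    """
    if not 0 <= otu.gc_fraction <= 1:
        raise ConfigError("gc_fraction must be in [0, 1]")
    return (config.gc_intercept + config.gc_slope * otu.gc_fraction
            + config.delta_rho_max * otu.atom_fraction(treatment))


def _gradient_rng(config: SimConfig, gradient_id: str) -> np.random.Generator:
    # split deterministically per gradient from the master seed
    tag = zlib.crc32(gradient_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def simulate_gradient(
    community: Sequence[OTUDef],
    treatment: Treatment,
    config: SimConfig,
    gradient_id: str | None = None,
) -> tuple[Gradient, pd.DataFrame]:
    """Simulate one ultracentrifugation run for ``treatment``.

    Returns the :class:`Gradient` (fraction densities and noisy bulk-DNA
    masses) and a long count table (gradient_id, otu_id, fraction, reads).
    Fraction 1 is the densest. Each OTU's expected DNA mass per fraction is
    its abundance times the Gaussian band mass falling in that fraction's
    density interval; reads are multinomial within each fraction.
    """
    if not community:
        raise ConfigError("community must be non-empty")
    if config.reads_per_fraction <= 0:
        raise ConfigError("reads_per_fraction must be positive")
    if gradient_id is None:
        gradient_id = f"G_{treatment.key}"
    rng = _gradient_rng(config, gradient_id)

    n = config.n_fractions
    # collection order: densest first -> decreasing edges
    edges = np.linspace(config.density_max, config.density_min, n + 1)
    lo, hi = edges[1:], edges[:-1]           # per-fraction density interval
    midpoints = 0.5 * (lo + hi)

    centers = np.array([band_center(o, treatment, config) for o in community])
    abund = np.array([o.baseline_abundance for o in community])
    sd = config.band_sd
    # mass_frac[i, f]: OTU i's expected DNA mass (as a fraction of total
    # community DNA) landing in fraction f
    upper = stats.norm.cdf((hi[None, :] - centers[:, None]) / sd)
    lower = stats.norm.cdf((lo[None, :] - centers[:, None]) / sd)
    mass = abund[:, None] * (upper - lower)

    bulk_true = mass.sum(axis=0) * config.dna_total_ng
    if config.qubit_cv > 0:
        sigma = np.sqrt(np.log1p(config.qubit_cv ** 2))
        noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n)
        bulk = bulk_true * noise
    else:
        bulk = bulk_true

    densities = midpoints.copy()
    if config.refractometer_sd > 0:
        densities = densities + rng.normal(0, config.refractometer_sd, size=n)

    # fractions with essentially no DNA yield no sequenceable library
    counts = np.zeros((len(community), n), dtype=int)
    col_mass = mass.sum(axis=0)
    seq_floor = config.seq_min_mass_share * col_mass.sum()
    for f in range(n):
        if col_mass[f] <= seq_floor:
            continue
        p = mass[:, f] / col_mass[f]
        counts[:, f] = rng.multinomial(config.reads_per_fraction, p)

    gradient = Gradient(
        gradient_id=gradient_id, treatment=treatment,
        fractions=pd.DataFrame({
            "fraction": np.arange(1, n + 1),
            "density_g_ml": densities,
            "dna_ng": bulk,
        }),
    )
    long = pd.DataFrame({
        "gradient_id": gradient_id,
        "otu_id": np.repeat([o.otu_id for o in community], n),
        "fraction": np.tile(np.arange(1, n + 1), len(community)),
        "reads": counts.ravel(),
    })
    long = long[long["reads"] > 0].reset_index(drop=True)
    return gradient, long


def simulate_experiment(
    community: Sequence[OTUDef],
    treatments: Sequence[Treatment],
    config: SimConfig,
) -> tuple[list[Gradient], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one gradient per treatment and assemble the full table set.

    Returns (gradients, counts, otus, ground_truth) where ``ground_truth``
    records the simulated atom fraction per OTU x labeled treatment.
    """
    gradients: list[Gradient] = []
    count_tables = []
    for t in treatments:
        g, c = simulate_gradient(community, t, config)
        gradients.append(g)
        count_tables.append(c)
    counts = pd.concat(count_tables, ignore_index=True)
    otus = pd.DataFrame({
        "otu_id": [o.otu_id for o in community],
        "domain_flag": [o.domain_flag for o in community],
        "taxonomy": ["synthetic" for _ in community],
    })
    truth_rows = []
    for t in treatments:
        if t.is_control:
            continue
        for o in community:
            truth_rows.append({
                "otu_id": o.otu_id, "substrate": t.substrate,
                "light_level": t.light_level,
                "atom_fraction_15n": o.atom_fraction(t),
            })
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["otu_id", "substrate", "light_level", "atom_fraction_15n"])
    return gradients, counts, otus, ground_truth


def simulate_uptake_obs(
    true_rate: float,
    pn_conc: float,
    dissolved_atom_pct: float,
    duration: float = 1.0,
    irms_sd: float = 0.0,
    *,
    natural_atom_pct: float = NATURAL_ATOM_PCT_15N,
    substrate: str = "NH4",
    light_level: str = "50",
    depth_m: float = 5.0,
    ambient_conc: float = 0.0,
    spike_conc: float = 1.0,
    spike_atom_pct: float | None = None,
    rng: np.random.Generator | None = None,
) -> UptakeObservation:
    """Invert the tracer rate equation to fabricate an IRMS observation.

    With ``irms_sd = 0`` the uptake module recovers ``true_rate`` exactly;
    otherwise Gaussian instrument noise is added to both atom% readings.
    ``spike_atom_pct`` defaults to ``dissolved_atom_pct`` so the recorded
    pool metadata reproduces the requested dissolved enrichment when
    ``ambient_conc`` is 0.
    """
    if true_rate < 0:
        raise ConfigError("true_rate must be >= 0")
    if pn_conc <= 0:
        raise ConfigError("pn_conc must be positive")
    if dissolved_atom_pct <= natural_atom_pct:
        raise ConfigError(
            "dissolved_atom_pct must exceed natural abundance")
    t0 = natural_atom_pct
    tf = t0 + true_rate * duration * (dissolved_atom_pct - t0) / pn_conc
    if tf > dissolved_atom_pct:
        raise InfeasibleRateError(
            f"implied t_f atom% {tf:.4g} exceeds the dissolved pool "
            f"enrichment {dissolved_atom_pct:.4g}; rate too high")
    if irms_sd > 0:
        rng = rng or np.random.default_rng()
        t0 = t0 + rng.normal(0, irms_sd)
        tf = tf + rng.normal(0, irms_sd)
    return UptakeObservation(
        depth_m=depth_m, light_level=light_level, substrate=substrate,
        pn_conc_umol_l=pn_conc, atom_pct_t0=float(t0), atom_pct_tf=float(tf),
        ambient_conc_umol_l=ambient_conc, spike_conc_umol_l=spike_conc,
        spike_atom_pct=(dissolved_atom_pct if spike_atom_pct is None
                        else spike_atom_pct),
        duration_d=duration,
    )
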