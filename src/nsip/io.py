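"""Tabular input/output and the pipeline's domain objects.

All tables are tab-separated UTF-8 with a header row. Fraction index 1 is
the densest fraction (first collected from the tube bottom); densities are
expected to decrease with fraction index and a warning is emitted if they
do not. Floats are written with 6 significant digits, which preserves
densities to refractometer precision and q-values to 1e-6.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import LABELS, LIGHT_LEVELS, SUBSTRATES
from .errors import FormatError, LinkageError, VocabularyError

FLOAT_FMT = "%.6g"

FRACTION_COLUMNS = [
    "gradient_id", "fraction", "density_g_ml", "dna_ng",
    "substrate", "label", "light_level",
]
COUNT_COLUMNS = ["gradient_id", "otu_id", "fraction", "reads"]
OTU_COLUMNS = ["otu_id", "domain_flag", "taxonomy"]
UPTAKE_COLUMNS = [
    "depth_m", "light_level", "substrate", "pn_conc_umol_l",
    "atom_pct_t0", "atom_pct_tf", "ambient_conc_umol_l",
    "spike_conc_umol_l", "spike_atom_pct", "duration_d",
]
ENRICHMENT_COLUMNS = [
    "otu_id", "substrate", "light_level", "control_density", "labeled_density",
    "shift", "t_stat", "df", "p_value", "q_value", "percent_enrichment",
    "enriched", "excluded", "exclude_reason",
]

DOMAIN_FLAGS = ("prokaryote", "eukaryote_chloroplast")


@dataclass(frozen=True)
class Treatment:
    """One incubation condition: substrate x isotope label x light level."""

    substrate: str
    label: str
    light_level: str

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise VocabularyError(f"unknown substrate {self.substrate!r}")
        if self.label not in LABELS:
            raise VocabularyError(f"unknown label {self.label!r}")
        if str(self.light_level) not in LIGHT_LEVELS:
            raise VocabularyError(f"unknown light level {self.light_level!r}")

    @property
    def is_control(self) -> bool:
        return self.label == "14N_control"

    @property
    def key(self) -> str:
        return f"{self.substrate}:{self.label}:{self.light_level}"


@dataclass
class Gradient:
    """One ultracentrifugation run: ordered fractions with densities and
    bulk DNA masses, plus the treatment it belongs to."""

    gradient_id: str
    treatment: Treatment
    fractions: pd.DataFrame  # columns: fraction, density_g_ml, dna_ng

    def __post_init__(self) -> None:
        fr = self.fractions
        required = {"fraction", "density_g_ml", "dna_ng"}
        missing = required - set(fr.columns)
        if missing:
            raise FormatError(
                f"gradient {self.gradient_id}: missing columns {sorted(missing)}")
        fr = fr.sort_values("fraction").reset_index(drop=True)
        idx = fr["fraction"].to_numpy()
        if len(idx) == 0:
            raise FormatError(f"gradient {self.gradient_id}: no fractions")
        if len(np.unique(idx)) != len(idx):
            raise FormatError(
                f"gradient {self.gradient_id}: duplicate fraction indices")
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise FormatError(
                f"gradient {self.gradient_id}: fraction indices must be "
                f"contiguous from 1")
        dens = fr["density_g_ml"].to_numpy(dtype=float)
        if not np.all(np.isfinite(dens)) or np.any(dens <= 0):
            raise FormatError(
                f"gradient {self.gradient_id}: densities must be positive")
        if np.any(fr["dna_ng"].to_numpy(dtype=float) < 0):
            raise FormatError(
                f"gradient {self.gradient_id}: bulk DNA must be >= 0")
        if len(dens) > 1 and not np.all(np.diff(dens) < 0):
            warnings.warn(
                f"gradient {self.gradient_id}: densities are not strictly "
                f"decreasing with fraction index (fraction 1 should be the "
                f"densest, collected first from below)",
                stacklevel=2,
            )
        self.fractions = fr

    @property
    def densities(self) -> np.ndarray:
        return self.fractions["density_g_ml"].to_numpy(dtype=float)

    @property
    def bulk_dna(self) -> np.ndarray:
        return self.fractions["dna_ng"].to_numpy(dtype=float)


@dataclass(frozen=True)
class UptakeObservation:
    """One tracer incubation: particulate-N atom% at t0 and t_f plus the
    pool information needed to compute an uptake rate."""

    depth_m: float
    light_level: str
    substrate: str
    pn_conc_umol_l: float       # particulate N concentration
    atom_pct_t0: float
    atom_pct_tf: float
    ambient_conc_umol_l: float  # ambient dissolved substrate
    spike_conc_umol_l: float    # tracer addition
    spike_atom_pct: float       # tracer enrichment (> 98 atom% in practice)
    duration_d: float

    def __post_init__(self) -> None:
        if self.duration_d <= 0:
            raise FormatError("duration_d must be positive")
        for name in ("atom_pct_t0", "atom_pct_tf", "spike_atom_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise FormatError(f"{name}={v} outside [0, 100] atom%")
        if self.spike_atom_pct <= self.atom_pct_t0:
            raise FormatError(
                "spike_atom_pct must exceed the t0 particulate atom%")


# ---------------------------------------------------------------------------
# readers / writers

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, where: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    if out.isna().any():
        bad = df.loc[out.isna(), col].iloc[0]
        raise FormatError(f"{where}: non-numeric value {bad!r} in column {col}")
    return out


def read_fractions(path: str | Path) -> list[Gradient]:
    """Read a fraction table into validated :class:`Gradient` objects."""
    df = _read_table(path, FRACTION_COLUMNS)
    df["fraction"] = _numeric(df, "fraction", "fractions").astype(int)
    df["density_g_ml"] = _numeric(df, "density_g_ml", "fractions")
    df["dna_ng"] = _numeric(df, "dna_ng", "fractions")
    dup = df.duplicated(subset=["gradient_id", "fraction"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"duplicate (gradient_id, fraction) = "
            f"({row['gradient_id']!r}, {row['fraction']})")
    gradients = []
    for gid, grp in df.groupby("gradient_id", sort=True):
        meta = grp[["substrate", "label", "light_level"]].drop_duplicates()
        if len(meta) != 1:
            raise FormatError(
                f"gradient {gid}: inconsistent treatment metadata across rows")
        treatment = Treatment(*meta.iloc[0])
        gradients.append(Gradient(
            gradient_id=str(gid), treatment=treatment,
            fractions=grp[["fraction", "density_g_ml", "dna_ng"]].copy(),
        ))
    return gradients


def write_fractions(gradients: Iterable[Gradient], path: str | Path) -> None:
    rows = []
    for g in gradients:
        fr = g.fractions.copy()
        fr.insert(0, "gradient_id", g.gradient_id)
        fr["substrate"] = g.treatment.substrate
        fr["label"] = g.treatment.label
        fr["light_level"] = g.treatment.light_level
        rows.append(fr[FRACTION_COLUMNS])
    out = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=FRACTION_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_counts(path: str | Path, gradients: Sequence[Gradient]) -> pd.DataFrame:
    """Read long-format read counts and validate them against ``gradients``.

    Returns a long DataFrame (gradient_id, otu_id, fraction, reads) with
    integer reads. Missing (otu, fraction) pairs are implicitly zero; the
    bands module zero-fills when it pivots per gradient.
    """
    df = _read_table(path, COUNT_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=COUNT_COLUMNS).astype(
            {"fraction": int, "reads": int})
    df["fraction"] = _numeric(df, "fraction", "counts").astype(int)
    reads = _numeric(df, "reads", "counts")
    if (reads < 0).any():
        raise FormatError("counts: negative read count")
    if not np.allclose(reads, np.round(reads)):
        raise FormatError("counts: non-integer read count")
    df["reads"] = reads.astype(int)
    dup = df.duplicated(subset=["gradient_id", "otu_id", "fraction"])
    if dup.any():
        row = df[dup].iloc[0]
        raise LinkageError(
            f"duplicate count row for (gradient={row['gradient_id']!r}, "
            f"otu={row['otu_id']!r}, fraction={row['fraction']}); refusing "
            f"to sum silently")
    valid = {g.gradient_id: set(g.fractions["fraction"]) for g in gradients}
    for gid, grp in df.groupby("gradient_id"):
        if gid not in valid:
            raise LinkageError(f"counts reference unknown gradient {gid!r}")
        extra = set(grp["fraction"]) - valid[gid]
        if extra:
            raise LinkageError(
                f"counts reference fraction(s) {sorted(extra)} absent from "
                f"gradient {gid!r}")
    return df.reset_index(drop=True)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_otus(path: str | Path) -> pd.DataFrame:
    """Read the OTU table (otu_id, domain_flag, taxonomy)."""
    df = _read_table(path, OTU_COLUMNS)
    bad = ~df["domain_flag"].isin(DOMAIN_FLAGS)
    if bad.any():
        raise VocabularyError(
            f"unknown domain_flag {df.loc[bad, 'domain_flag'].iloc[0]!r}")
    if df["otu_id"].duplicated().any():
        raise FormatError("otus: duplicate otu_id")
    return df[OTU_COLUMNS].reset_index(drop=True)


def write_otus(otus: pd.DataFrame, path: str | Path) -> None:
    otus[OTU_COLUMNS].to_csv(path, sep="\t", index=False)


def read_uptake(path: str | Path) -> list[UptakeObservation]:
    df = _read_table(path, UPTAKE_COLUMNS)
    obs = []
    for _, row in df.iterrows():
        obs.append(UptakeObservation(
            depth_m=float(row["depth_m"]),
            light_level=str(row["light_level"]),
            substrate=str(row["substrate"]),
            pn_conc_umol_l=float(row["pn_conc_umol_l"]),
            atom_pct_t0=float(row["atom_pct_t0"]),
            atom_pct_tf=float(row["atom_pct_tf"]),
            ambient_conc_umol_l=float(row["ambient_conc_umol_l"]),
            spike_conc_umol_l=float(row["spike_conc_umol_l"]),
            spike_atom_pct=float(row["spike_atom_pct"]),
            duration_d=float(row["duration_d"]),
        ))
    return obs


def write_uptake(observations: Iterable[UptakeObservation],
                 path: str | Path) -> None:
    rows = [{c: getattr(o, c) for c in UPTAKE_COLUMNS} for o in observations]
    out = pd.DataFrame(rows, columns=UPTAKE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_enrichment(results: pd.DataFrame, path: str | Path) -> None:
    """Write per-OTU x treatment enrichment results with a stable column
    order and fixed float precision."""
    if results is None:
        raise FormatError("results must not be None")
    out = results.reindex(columns=ENRICHMENT_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_enrichment(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ENRICHMENT_COLUMNS)
    for col in ("control_density", "labeled_density", "shift", "t_stat",
                "df", "p_value", "q_value", "percent_enrichment"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("enriched", "excluded"):
        df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    df["exclude_reason"] = df["exclude_reason"].fillna("")
    return df


def write_budget(budget_frame: pd.DataFrame, path: str | Path) -> None:
    budget_frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
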