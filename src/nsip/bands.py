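"""Per-OTU DNA band isolation and weighted mean buoyant density.

The chain mirrors how SIP gradient data are reduced in practice:

1. read counts -> relative abundance within each fraction (low-read
   fractions dropped);
2. relative abundance x bulk DNA -> ng DNA per OTU per fraction;
3. band tails trimmed to a common density window per OTU across all of
   that OTU's gradients, and re-normalized to percent of the OTU's DNA;
4. weighted mean density, weighted variance and a Kish effective sample
   size computed over the retained band.

Only bands of the same OTU are ever compared downstream, which cancels
organism-level density offsets such as GC content.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import EmptyGradientError, InputError
from .io import Gradient


@dataclass
class BandProfile:
    """One OTU's retained DNA band within one gradient.

    ``profile`` columns: fraction, density, otu_dna (ng), otu_dna_pct
    (percent of this OTU's within-window DNA), reads.
    """

    otu_id: str
    gradient_id: str
    profile: pd.DataFrame
    window: tuple[float, float]  # (density_lo, density_hi)


@dataclass
class DensityEstimate:
    """Weighted mean buoyant density of a band (possibly pooled)."""

    mean_density: float
    weighted_variance: float
    effective_n: float
    total_reads: int
    n_fractions: int

    @property
    def low_information(self) -> bool:
        return self.n_fractions <= 1


def relative_abundance(counts_wide: pd.DataFrame,
                       min_fraction_reads: int = 0) -> pd.DataFrame:
    """Convert an OTU x fraction count matrix to within-fraction proportions.

    Fractions whose total reads fall below ``min_fraction_reads`` (or are
    zero) are dropped, not divided by zero. Raises
    :class:`EmptyGradientError` if nothing survives.
    """
    totals = counts_wide.sum(axis=0)
    keep = totals[(totals > 0) & (totals >= min_fraction_reads)].index
    if len(keep) == 0:
        raise EmptyGradientError(
            "every fraction fell below the read-count threshold")
    kept = counts_wide[keep]
    return kept.div(kept.sum(axis=0), axis=1)


def otu_mass(proportions: pd.DataFrame, gradient: Gradient) -> pd.DataFrame:
    """ng DNA per (OTU, fraction): within-fraction proportion x bulk DNA."""
    bulk = gradient.fractions.set_index("fraction")["dna_ng"]
    missing = [f for f in proportions.columns if f not in bulk.index]
    if missing:
        raise InputError(
            f"fractions {missing} absent from gradient {gradient.gradient_id}")
    return proportions.mul(bulk.loc[proportions.columns], axis=1)


def _smooth3(m: np.ndarray) -> np.ndarray:
    """Binomial [1/4, 1/2, 1/4] smoothing, renormalized at the edges.

    Used only for band-boundary detection, never for the density weights:
    it damps per-fraction quantification noise that would otherwise jitter
    the tail cut-offs (and, once windows are intersected across gradients,
    bias them narrow)."""
    n = len(m)
    if n < 3:
        return m.astype(float)
    out = np.empty(n)
    out[0] = (0.5 * m[0] + 0.25 * m[1]) / 0.75
    out[-1] = (0.5 * m[-1] + 0.25 * m[-2]) / 0.75
    out[1:-1] = 0.25 * m[:-2] + 0.5 * m[1:-1] + 0.25 * m[2:]
    return out


def band_window(mass: pd.Series, densities: pd.Series,
                band_tail_pct: float = 2.0) -> tuple[float, float] | None:
    """Density window of one OTU's band in one gradient (peak-fraction
    policy).

    Retains the contiguous run of fractions, containing the peak fraction,
    whose (lightly smoothed) mass is at least ``band_tail_pct`` percent of
    the peak mass. The window extends half a fraction's density width
    beyond the outer retained midpoints, because each fraction covers a
    density interval rather than a point. Returns ``None`` when the OTU
    has no mass at all.
    """
    m = mass.to_numpy(dtype=float)
    if len(m) == 0 or m.max() <= 0:
        return None
    order = np.argsort(mass.index.to_numpy())  # fraction index order
    m = m[order]
    d = densities.to_numpy(dtype=float)[order]
    sm = _smooth3(m)
    peak = int(np.argmax(sm))
    thr = (band_tail_pct / 100.0) * sm[peak]
    lo = peak
    while lo > 0 and sm[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(m) - 1 and sm[hi + 1] >= thr:
        hi += 1
    window_d = d[lo:hi + 1]
    half_width = 0.5 * float(np.median(np.abs(np.diff(d)))) if len(d) > 1 \
        else 0.0
    return (float(window_d.min()) - half_width,
            float(window_d.max()) + half_width)


def intersect_windows(
    windows: Sequence[tuple[float, float] | None],
) -> tuple[float, float] | None:
    """Intersection of per-gradient density windows; ``None`` if empty."""
    live = [w for w in windows if w is not None]
    if not live:
        return None
    lo = max(w[0] for w in live)
    hi = min(w[1] for w in live)
    if lo > hi:
        return None
    return lo, hi


def trim_and_normalize(
    otu_id: str,
    gradient: Gradient,
    mass: pd.Series,
    reads: pd.Series,
    window: tuple[float, float],
    min_band_fractions: int = 1,
) -> BandProfile | None:
    """Cut one OTU's mass profile to ``window`` and renormalize to percent.

    Returns ``None`` when fewer than ``min_band_fractions`` retained
    fractions carry positive mass (band undefined in this gradient).
    """
    dens = gradient.fractions.set_index("fraction")["density_g_ml"]
    d = dens.loc[mass.index]
    inside = (d >= window[0]) & (d <= window[1])
    kept = mass[inside]
    total = kept.sum()
    if (kept > 0).sum() < min_band_fractions or total <= 0:
        return None
    prof = pd.DataFrame({
        "fraction": kept.index.to_numpy(),
        "density": d[inside].to_numpy(dtype=float),
        "otu_dna": kept.to_numpy(dtype=float),
        "otu_dna_pct": 100.0 * kept.to_numpy(dtype=float) / total,
        "reads": reads.reindex(kept.index).fillna(0).to_numpy(dtype=int),
    }).sort_values("fraction").reset_index(drop=True)
    return BandProfile(otu_id=otu_id, gradient_id=gradient.gradient_id,
                       profile=prof, window=window)


def weighted_density(band: BandProfile) -> DensityEstimate:
    """Weighted mean density of a band, weighting by DNA mass.

    mean = sum(d*w)/sum(w); variance = sum(w*(d-mean)^2)/sum(w);
    effective n is Kish's (sum w)^2 / sum(w^2). The normalized percent
    column is used as the weight, which is identical to ng for a single
    band and lets pooled bands weight each gradient equally.
    """
    prof = band.profile
    if len(prof) == 0:
        raise InputError("empty band profile")
    d = prof["density"].to_numpy(dtype=float)
    w = prof["otu_dna_pct"].to_numpy(dtype=float)
    sw = w.sum()
    mean = float(np.sum(d * w) / sw)
    var = float(np.sum(w * (d - mean) ** 2) / sw)
    n_eff = float(sw ** 2 / np.sum(w ** 2))
    return DensityEstimate(
        mean_density=mean, weighted_variance=var, effective_n=n_eff,
        total_reads=int(prof["reads"].sum()), n_fractions=len(prof),
    )


def band_profiles(
    gradients: Sequence[Gradient],
    counts: pd.DataFrame,
    config: AnalysisConfig,
) -> tuple[dict[tuple[str, str], BandProfile], pd.DataFrame]:
    """Compute every OTU x gradient band profile over a common per-OTU
    window.

    Returns ``(profiles, exclusions)`` where ``profiles`` maps
    ``(otu_id, gradient_id)`` to a :class:`BandProfile` and ``exclusions``
    logs OTUs dropped in a gradient with a reason (``no_mass``,
    ``empty_window``, ``too_few_fractions``).
    """
    per_gradient: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    windows: dict[str, dict[str, tuple[float, float] | None]] = {}
    for g in gradients:
        sub = counts[counts["gradient_id"] == g.gradient_id]
        wide = (sub.pivot_table(index="otu_id", columns="fraction",
                                values="reads", aggfunc="sum", fill_value=0)
                if len(sub) else pd.DataFrame())
        if wide.empty:
            continue
        # zero-fill fractions that received no reads at all
        wide = wide.reindex(columns=g.fractions["fraction"], fill_value=0)
        try:
            props = relative_abundance(wide, config.min_fraction_reads)
        except EmptyGradientError:
            continue
        masses = otu_mass(props, g)
        reads = wide[masses.columns]
        per_gradient[g.gradient_id] = (masses, reads)
        dens = g.fractions.set_index("fraction")["density_g_ml"]
        for otu in masses.index:
            windows.setdefault(otu, {})[g.gradient_id] = band_window(
                masses.loc[otu], dens.loc[masses.columns],
                config.band_tail_pct)

    profiles: dict[tuple[str, str], BandProfile] = {}
    excl_rows = []
    by_id = {g.gradient_id: g for g in gradients}
    for otu, wmap in windows.items():
        common = intersect_windows(list(wmap.values()))
        for gid, w in wmap.items():
            if w is None:
                excl_rows.append({"otu_id": otu, "gradient_id": gid,
                                  "reason": "no_mass"})
                continue
            if common is None:
                excl_rows.append({"otu_id": otu, "gradient_id": gid,
                                  "reason": "empty_window"})
                continue
            masses, reads = per_gradient[gid]
            band = trim_and_normalize(
                otu, by_id[gid], masses.loc[otu], reads.loc[otu], common,
                config.min_band_fractions)
            if band is None:
                excl_rows.append({"otu_id": otu, "gradient_id": gid,
                                  "reason": "too_few_fractions"})
            else:
                profiles[(otu, gid)] = band
    exclusions = pd.DataFrame(
        excl_rows, columns=["otu_id", "gradient_id", "reason"])
    return profiles, exclusions


def bands_table(profiles: Mapping[tuple[str, str], BandProfile]
                ) -> pd.DataFrame:
    """Flatten band profiles into one long table for inspection."""
    rows = []
    for (otu, gid), band in profiles.items():
        prof = band.profile.copy()
        prof.insert(0, "otu_id", otu)
        prof.insert(1, "gradient_id", gid)
        prof["window_lo"] = band.window[0]
        prof["window_hi"] = band.window[1]
        rows.append(prof)
    cols = ["otu_id", "gradient_id", "fraction", "density", "otu_dna",
            "otu_dna_pct", "reads", "window_lo", "window_hi"]
    return (pd.concat(rows, ignore_index=True)[cols]
            if rows else pd.DataFrame(columns=cols))
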