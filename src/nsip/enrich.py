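"""Enrichment calling: pooled controls, Welch tests, BH correction.

For each OTU the control bands from every unlabeled incubation are pooled
into a single density estimate (unlabeled N cannot change buoyant
density, so controls differ only by measurement precision). Each labeled
band is then compared to the pooled control with Welch's t-test, using
the weighted band variance and the Kish effective sample size. P-values
from all OTU x treatment tests surviving the read filters form one
Benjamini-Hochberg family at FDR 0.1; a positive call additionally
requires a positive shift amounting to at least ``min_percent`` of the
full-label density gain (default 30%).
"""
from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bands import BandProfile, DensityEstimate, band_profiles, weighted_density
from .config import AnalysisConfig
from .errors import InputError
from .io import ENRICHMENT_COLUMNS, Gradient


def pool_controls(bands: Sequence[BandProfile]) -> DensityEstimate:
    """Pool one OTU's control bands into a single density estimate.

    Bands are already trimmed to the OTU's common window and normalized to
    percent, so concatenating their fractions weights each control
    gradient equally; a single weighted mean is then computed over the
    combined set.
    """
    if not bands:
        raise InputError("pool_controls requires at least one control band")
    if len(bands) == 1:
        return weighted_density(bands[0])
    combined = pd.concat([b.profile for b in bands], ignore_index=True)
    merged = BandProfile(
        otu_id=bands[0].otu_id, gradient_id="pooled_controls",
        profile=combined, window=bands[0].window)
    return weighted_density(merged)


def welch_test(
    labeled: DensityEstimate,
    control: DensityEstimate,
    two_sided: bool = False,
) -> tuple[float, float, float, bool]:
    """Welch's t-test between two weighted density estimates.

    Returns ``(t, df, p, degenerate)``. The variance of each mean is taken
    as weighted band variance / Kish effective n, and the degrees of
    freedom follow Welch-Satterthwaite. By default the test is one-sided
    for a positive shift (labeled denser than control), since 15N can only
    increase buoyant density. Two zero-variance estimates are degenerate:
    p = 1 when the means agree, p = 0 (flagged) when they differ.
    """
    diff = labeled.mean_density - control.mean_density
    vl = labeled.weighted_variance / labeled.effective_n
    vc = control.weighted_variance / control.effective_n
    se2 = vl + vc
    if se2 == 0:
        if diff == 0:
            return 0.0, float("nan"), 1.0, True
        return math.copysign(float("inf"), diff), float("nan"), 0.0, True
    t = diff / math.sqrt(se2)
    denom = 0.0
    if vl > 0:
        denom += vl ** 2 / max(labeled.effective_n - 1.0, 1e-12)
    if vc > 0:
        denom += vc ** 2 / max(control.effective_n - 1.0, 1e-12)
    df = se2 ** 2 / denom
    if two_sided:
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = stats.t.sf(t, df)
    return float(t), float(df), float(p), False


def bh_correct(p_values: Sequence[float], fdr: float = 0.1
               ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns ``(q_values, reject)``; rejections are q <= fdr. Empty input
    yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, reject


def run_enrichment(
    gradients: Sequence[Gradient],
    counts: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full enrichment analysis for every OTU x labeled treatment.

    Returns one row per test with densities, Welch statistics, BH q-value,
    percent enrichment (100 * shift / delta_rho_max) and the final call.
    Excluded rows (no control, too few reads, degenerate bands) are kept
    with a reason and never enter the BH family.
    """
    config = config or AnalysisConfig()
    profiles, _ = band_profiles(gradients, counts, config)

    by_gradient: dict[str, Gradient] = {g.gradient_id: g for g in gradients}
    control_ids = [g.gradient_id for g in gradients if g.treatment.is_control]
    labeled_ids = [g.gradient_id for g in gradients
                   if not g.treatment.is_control]

    otus = sorted({otu for otu, _ in profiles})
    rows = []
    for otu in otus:
        controls = [profiles[(otu, gid)] for gid in control_ids
                    if (otu, gid) in profiles]
        pooled = pool_controls(controls) if controls else None
        for gid in labeled_ids:
            if (otu, gid) not in profiles:
                continue
            t = by_gradient[gid].treatment
            band = profiles[(otu, gid)]
            est = weighted_density(band)
            row = {
                "otu_id": otu, "substrate": t.substrate,
                "light_level": t.light_level,
                "control_density": np.nan,
                "labeled_density": est.mean_density,
                "shift": np.nan, "t_stat": np.nan, "df": np.nan,
                "p_value": np.nan, "q_value": np.nan,
                "percent_enrichment": np.nan,
                "enriched": False, "excluded": False, "exclude_reason": "",
            }
            if pooled is None:
                row.update(excluded=True, exclude_reason="no_control")
                rows.append(row)
                continue
            shift = est.mean_density - pooled.mean_density
            row.update(control_density=pooled.mean_density, shift=shift,
                       percent_enrichment=100.0 * shift / config.delta_rho_max)
            if (est.total_reads < config.min_otu_reads
                    or pooled.total_reads < config.min_otu_reads):
                row.update(excluded=True, exclude_reason="low_reads")
                rows.append(row)
                continue
            if (est.effective_n < config.min_effective_n
                    or pooled.effective_n < config.min_effective_n):
                row.update(excluded=True, exclude_reason="low_effective_n")
                rows.append(row)
                continue
            t_stat, df, p, degenerate = welch_test(
                est, pooled, two_sided=config.two_sided)
            row.update(t_stat=t_stat, df=df, p_value=p)
            if degenerate:
                row["exclude_reason"] = "degenerate_variance"
            rows.append(row)

    results = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if results.empty:
        return results

    in_family = (~results["excluded"]) & results["p_value"].notna()
    q, reject = bh_correct(results.loc[in_family, "p_value"].to_numpy(),
                           config.fdr)
    results.loc[in_family, "q_value"] = q
    enriched = (
        in_family
        & results["q_value"].le(config.fdr)
        & results["shift"].gt(0)
        & results["percent_enrichment"].ge(config.min_percent)
    )
    results["enriched"] = enriched.fillna(False).astype(bool)
    return results


def summarize_activity(results: pd.DataFrame,
                       taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Counts of enriched OTUs per substrate x light level, by domain.

    ``taxonomy`` must carry (otu_id, domain_flag). Adds eukaryote share of
    the enriched community per condition.
    """
    merged = results.merge(taxonomy[["otu_id", "domain_flag"]],
                           on="otu_id", how="left")
    grp = merged.groupby(["substrate", "light_level"], sort=True)
    rows = []
    for (substrate, light), sub in grp:
        enr = sub[sub["enriched"]]
        n_prok = int((enr["domain_flag"] == "prokaryote").sum())
        n_euk = int((enr["domain_flag"] == "eukaryote_chloroplast").sum())
        total = len(enr)
        rows.append({
            "substrate": substrate, "light_level": light,
            "n_tested": int(len(sub)), "n_enriched": total,
            "n_prokaryote": n_prok, "n_eukaryote": n_euk,
            "eukaryote_share": (n_euk / total) if total else 0.0,
        })
    return pd.DataFrame(rows, columns=[
        "substrate", "light_level", "n_tested", "n_enriched",
        "n_prokaryote", "n_eukaryote", "eukaryote_share"])


def activity_per_otu(results: pd.DataFrame,
                     taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Number of treatments each OTU is enriched in (multi-treatment
    activity), with the mean per enriched OTU by domain available via a
    groupby on the result."""
    enr = results[results["enriched"]]
    per_otu = (enr.groupby("otu_id").size().rename("n_treatments_enriched")
               .reset_index())
    return per_otu.merge(taxonomy[["otu_id", "domain_flag"]],
                         on="otu_id", how="left")


def mean_activity_by_domain(results: pd.DataFrame,
                            taxonomy: pd.DataFrame) -> pd.Series:
    """Mean number of enriched treatments per enriched OTU, by domain."""
    per_otu = activity_per_otu(results, taxonomy)
    if per_otu.empty:
        return pd.Series(dtype=float)
    return per_otu.groupby("domain_flag")["n_treatments_enriched"].mean()
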