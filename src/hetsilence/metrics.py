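"""Silencing metrics: efficiency, stability, occupancy change, pathway shares.

With theta_ChIP, theta_RIP and theta_pARNA the replicate-averaged TPM of a
gene (or region) for one genotype:

    transcription efficiency  TE   = theta_RIP / theta_ChIP
    RNA stability             S    = theta_pARNA / theta_RIP
    delta Pol II occupancy         = log2(theta_ChIP^mu / theta_ChIP^wt)
    RNA output                     = theta_ChIP * TE * S  (= theta_pARNA)

Silencing is decomposed relative to the heterochromatin-free reference
(clr4, complete loss of silencing): per region and pathway p,
FC_p = measure_p(ref) / measure_p(wt).  Because RNA output is multiplicative,
only log fold changes are additive, so pathway contribution shares are
computed in log2 space: share_p = log2 FC_p / sum_q log2 FC_q.  Pathways
with FC < 1 (anti-silencing, e.g. compensating degradation) yield negative
shares and are reported as-is, flagged.

Regions aggregate member-gene theta by summation *before* any ratio is
taken (ratios of sums, never averages of per-gene ratios).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import ExpressionSummary
from .genome import GenomeAnnotation

logger = logging.getLogger(__name__)

#: theta floor (TPM) below which ratios are reported NA instead of unstable
TPM_FLOOR = 1.0

PATHWAYS = ("occupancy", "efficiency", "stability")


class MetricsError(ValueError):
    pass


def _guard(num: pd.Series, den: pd.Series, floor: float) -> pd.Series:
    out = num / den
    out[den < floor] = np.nan
    return out


def transcription_efficiency(
    summary: ExpressionSummary, floor: float = TPM_FLOOR
) -> pd.Series:
    """TE = theta_RIP / theta_ChIP; NA where theta_ChIP is below the floor."""
    return _guard(summary.theta["rip"], summary.theta["chip"], floor)


def rna_stability(
    summary: ExpressionSummary, floor: float = TPM_FLOOR
) -> pd.Series:
    """Stability = theta_pARNA / theta_RIP; NA below the floor."""
    return _guard(summary.theta["pa_rna"], summary.theta["rip"], floor)


def delta_polII(
    summary_mu: ExpressionSummary,
    summary_wt: ExpressionSummary,
    floor: float = TPM_FLOOR,
) -> pd.Series:
    """log2(theta_ChIP^mu / theta_ChIP^wt); NA when either is below the floor."""
    mu = summary_mu.theta["chip"]
    wt = summary_wt.theta["chip"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(mu / wt)
    out[(mu < floor) | (wt < floor)] = np.nan
    return out


def rna_output(summary: ExpressionSummary, floor: float = TPM_FLOOR) -> pd.Series:
    """theta_ChIP * TE * S, computed through the three factors.

    Telescopes to theta_pARNA identically wherever all factors are defined.
    """
    te = transcription_efficiency(summary, floor)
    st = rna_stability(summary, floor)
    return summary.theta["chip"] * te * st


def aggregate_region(
    summary: ExpressionSummary,
    annotation: GenomeAnnotation,
    categories: str | Sequence[str],
    strand_mode: str = "combined",
) -> pd.DataFrame:
    """Sum member-gene theta into region-level theta rows.

    Only representative copies (plus non-family genes) of the requested
    categories contribute, so family signal is not double counted.
    ``strand_mode='by_strand'`` emits one row per member strand
    (e.g. dh+ / dh-), keyed on the representative's strand; ``'combined'``
    pools everything into a single row.
    """
    if isinstance(categories, str):
        categories = [categories]
    members = [
        g for g in annotation
        if g.category in categories
        and (not g.copy_group or g.is_representative)
        and g.gene_id in summary.theta.index
    ]
    if not members:
        raise MetricsError(f"no genes in categories {list(categories)}")
    label = "+".join(categories)
    if strand_mode == "combined":
        groups = {label: members}
    elif strand_mode == "by_strand":
        groups = {}
        for g in members:
            groups.setdefault(f"{label}({g.strand})", []).append(g)
    else:
        raise MetricsError(f"unknown strand_mode {strand_mode!r}")
    rows = {
        name: summary.theta.loc[[g.gene_id for g in gs]].sum(axis=0)
        for name, gs in groups.items()
    }
    out = pd.DataFrame(rows).T
    out.index.name = "region"
    return out


def _region_measures(theta_row: pd.Series) -> dict[str, float]:
    with np.errstate(divide="ignore", invalid="ignore"):
        return {
            "occupancy": float(theta_row["chip"]),
            "efficiency": float(theta_row["rip"] / theta_row["chip"]),
            "stability": float(theta_row["pa_rna"] / theta_row["rip"]),
            "output": float(theta_row["pa_rna"]),
        }


@dataclass
class SilencingDecomposition:
    """Per-region pathway fold changes and contribution shares.

    ``table`` rows are regions; columns: fc_<pathway>, fc_output,
    share_<pathway> (fractions of the total log2 output change; negative for
    anti-silencing pathways), and a ``flags`` column.
    """

    table: pd.DataFrame
    reference: str
    baseline: str

    def shares_percent(self) -> pd.DataFrame:
        return 100.0 * self.table[[f"share_{p}" for p in PATHWAYS]]


def _decompose_row(m_base: Mapping, m_ref: Mapping) -> dict:
    row: dict = {}
    flags = []
    logs = {}
    for p in PATHWAYS:
        fc = m_ref[p] / m_base[p] if m_base[p] > 0 else np.nan
        row[f"fc_{p}"] = fc
        if not np.isfinite(fc) or fc <= 0:
            logs[p] = np.nan
            flags.append(f"nonpositive_fc_{p}")
            warnings.warn(f"non-positive fold change for pathway {p}")
        else:
            logs[p] = np.log2(fc)
            if fc < 1:
                flags.append(f"anti_silencing_{p}")
    row["fc_output"] = row["fc_occupancy"] * row["fc_efficiency"] * row["fc_stability"]
    total = sum(v for v in logs.values() if np.isfinite(v))
    for p in PATHWAYS:
        row[f"share_{p}"] = logs[p] / total if total != 0 else np.nan
    row["flags"] = ";".join(flags)
    return row


def pathway_decomposition(
    summary_wt: ExpressionSummary,
    summary_ref: ExpressionSummary,
    regions: Mapping[str, dict],
    annotation: GenomeAnnotation,
) -> SilencingDecomposition:
    """Quantify each pathway's contribution to silencing, per region.

    ``regions`` maps region name -> {categories: [...], strand_mode: ...}.
    The reference summary is the heterochromatin-free state (clr4): for each
    pathway FC_p = measure_p(ref) / measure_p(wt), and shares are log2 FC
    fractions (they sum to 1 whenever all FC > 0).
    """
    rows = {}
    for name, region_def in regions.items():
        cats = region_def["categories"] if isinstance(region_def, Mapping) else region_def
        mode = region_def.get("strand_mode", "combined") if isinstance(region_def, Mapping) else "combined"
        agg_wt = aggregate_region(summary_wt, annotation, cats, mode)
        agg_ref = aggregate_region(summary_ref, annotation, cats, mode)
        for region in agg_wt.index:
            m_base = _region_measures(agg_wt.loc[region])
            m_ref = _region_measures(agg_ref.loc[region])
            key = name if len(agg_wt) == 1 else f"{name} {region}"
            rows[key] = _decompose_row(m_base, m_ref)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "region"
    return SilencingDecomposition(
        table=table,
        reference=summary_ref.genotype,
        baseline=summary_wt.genotype,
    )


def residual_contributions(
    summary_mu: ExpressionSummary,
    summary_ref: ExpressionSummary,
    regions: Mapping[str, dict],
    annotation: GenomeAnnotation,
    summary_wt: ExpressionSummary | None = None,
) -> pd.DataFrame:
    """Residual silencing still active in a mutant, per pathway (log2 units).

    residual_p(mu) = log2(measure_p(ref) / measure_p(mu)) — zero when the
    mutant has lost the pathway entirely (mu = ref), and equal to the full
    decomposition numerators when mu = wt.  If ``summary_wt`` is given, a
    ``bar_height`` column reports log2 of the RNA-output fold change of the
    mutant relative to wild type.
    """
    rows = {}
    for name, region_def in regions.items():
        cats = region_def["categories"] if isinstance(region_def, Mapping) else region_def
        mode = region_def.get("strand_mode", "combined") if isinstance(region_def, Mapping) else "combined"
        agg_mu = aggregate_region(summary_mu, annotation, cats, mode)
        agg_ref = aggregate_region(summary_ref, annotation, cats, mode)
        agg_wt = (
            aggregate_region(summary_wt, annotation, cats, mode)
            if summary_wt is not None else None
        )
        for region in agg_mu.index:
            m_mu = _region_measures(agg_mu.loc[region])
            m_ref = _region_measures(agg_ref.loc[region])
            key = name if len(agg_mu) == 1 else f"{name} {region}"
            row = {}
            for p in PATHWAYS:
                with np.errstate(divide="ignore", invalid="ignore"):
                    row[f"residual_{p}"] = (
                        np.log2(m_ref[p] / m_mu[p])
                        if m_mu[p] > 0 and m_ref[p] > 0 else np.nan
                    )
            if agg_wt is not None:
                m_wt = _region_measures(agg_wt.loc[region])
                row["bar_height"] = np.log2(m_mu["output"] / m_wt["output"])
            rows[key] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "region"
    return out


def ratio_sem(
    replicates_numerator: Sequence[float],
    replicates_denominator: Sequence[float],
) -> tuple[np.ndarray, float]:
    """SEM of a ratio of unpaired replicate sets.

    Forms all n x m pairwise ratios between the two assays' replicates and
    returns (ratios, sd(ratios)/sqrt(n*m)).  Zero denominators are excluded
    with a warning.
    """
    num = np.asarray(list(replicates_numerator), dtype="float64")
    den = np.asarray(list(replicates_denominator), dtype="float64")
    if num.size == 0 or den.size == 0:
        raise MetricsError("both replicate lists must be non-empty")
    keep = den != 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero denominator replicate(s)")
        den = den[keep]
        if den.size == 0:
            raise MetricsError("all denominator replicates are zero")
    ratios = (num[:, None] / den[None, :]).ravel()
    if ratios.size < 2:
        return ratios, 0.0
    sem = float(np.std(ratios, ddof=1) / np.sqrt(ratios.size))
    return ratios, sem
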