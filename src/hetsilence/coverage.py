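"""Fractional coverage profiles, depth normalization and IP-input subtraction.

Coverage profiles count read alignments per genomic base; a multi-mapping
read contributes 1/NH at each of its NH locations, so the total profile mass
equals the summed read lengths regardless of multi-mapping.

ChIP background correction anchors on the three central-core regions
(Cenp-A chromatin, near-zero Pol II): for each region r a scaling factor

    lambda_r = sum_i x_i / sum_i y_i

matches the input profile y to the IP profile x over the region, and the
median of the three lambda_r is the final scaling factor.  The subtracted
track is max(x_i - lambda * y_i, 0); the signed (un-clamped) region sums are
kept for QC — the median region's signed sum is exactly zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import AlignmentRecord, CountTable
from .genome import GenomeAnnotation, HETEROCHROMATIC_CATEGORIES


class CoverageError(ValueError):
    pass


@dataclass
class CoverageProfile:
    """Per-chromosome per-base depth vectors with a normalization state."""

    values: dict[str, np.ndarray]
    state: str = "raw"  # raw | depth_normalized | input_subtracted
    depth_millions: float | None = None
    region_qc: dict[str, float] = field(default_factory=dict)
    #: un-clamped difference kept by subtract_input for gene-level signal
    signed_values: dict[str, np.ndarray] | None = None

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def copy_with(self, values, state, **kw) -> "CoverageProfile":
        return CoverageProfile(values=values, state=state, **kw)

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.values[chrom][start:end].sum())


def build_coverage(
    alignments: Iterable[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
) -> CoverageProfile:
    """Accumulate 1/NH fractional depth over every alignment location.

    Uses difference arrays (add at start, subtract at end, cumulative sum),
    so cost is linear in the number of alignment lines.
    """
    diff = {c: np.zeros(length + 1) for c, length in chrom_lengths.items()}
    for rec in alignments:
        w = 1.0 / rec.nh
        for chrom, start, end, _ in rec.locations:
            if chrom not in diff:
                raise CoverageError(f"unknown chromosome {chrom!r}")
            if start < 0 or end > chrom_lengths[chrom]:
                raise CoverageError(
                    f"read {rec.read_id!r}: interval out of bounds on {chrom}"
                )
            diff[chrom][start] += w
            diff[chrom][end] -= w
    values = {c: np.cumsum(d[:-1]) for c, d in diff.items()}
    return CoverageProfile(values=values, state="raw")


def depth_normalize(
    profile: CoverageProfile,
    counts: CountTable | pd.Series | float,
    basis: str = "protein_coding",
    annotation: GenomeAnnotation | None = None,
) -> CoverageProfile:
    """Divide the profile by (reads mapping to the basis category) / 1e6.

    ``basis`` is ``protein_coding`` or ``heterochromatic``; the read count is
    taken from a one-sample :class:`CountTable` (requires ``annotation``),
    from a per-gene Series, or given directly as a number.
    """
    if isinstance(counts, CountTable):
        if annotation is None:
            raise CoverageError("annotation required with a CountTable")
        if len(counts.sample_ids) != 1:
            raise CoverageError("depth_normalize expects a one-sample table")
        series = counts.counts.iloc[:, 0]
        if basis == "protein_coding":
            ids = [gid for gid in series.index
                   if annotation[gid].category == "protein_coding"]
        elif basis == "heterochromatic":
            ids = [gid for gid in series.index
                   if annotation[gid].category in HETEROCHROMATIC_CATEGORIES]
        else:
            raise CoverageError(f"unknown basis {basis!r}")
        n_reads = float(series[ids].sum())
    elif isinstance(counts, pd.Series):
        n_reads = float(counts.sum())
    else:
        n_reads = float(counts)
    if n_reads <= 0:
        raise CoverageError(f"zero reads in normalization basis {basis!r}")
    millions = n_reads / 1e6
    values = {c: v / millions for c, v in profile.values.items()}
    return CoverageProfile(values=values, state="depth_normalized",
                           depth_millions=millions)


@dataclass
class ScalingFactor:
    """Per-region lambda_r over the three core centromeric regions and the
    final lambda = median (middle order statistic of the three)."""

    regions: list[tuple[str, int, int]]
    lambdas: list[float]
    value: float

    @property
    def median_region(self) -> tuple[str, int, int]:
        order = int(np.argsort(self.lambdas)[len(self.lambdas) // 2])
        return self.regions[order]


def compute_lambda(
    ip: CoverageProfile,
    input_profile: CoverageProfile,
    core_regions: Sequence[tuple[str, int, int]],
) -> ScalingFactor:
    """Solve sum(x_i) - lambda * sum(y_i) = 0 per region; take the median."""
    if len(core_regions) != 3:
        raise CoverageError(
            f"expected exactly 3 core regions, got {len(core_regions)}"
        )
    lambdas = []
    for chrom, start, end in core_regions:
        x = ip.region_sum(chrom, start, end)
        y = input_profile.region_sum(chrom, start, end)
        if y <= 0:
            raise CoverageError(
                f"core region {chrom}:{start}-{end} has zero input coverage"
            )
        lambdas.append(x / y)
    return ScalingFactor(
        regions=[tuple(r) for r in core_regions],
        lambdas=lambdas,
        value=float(np.median(lambdas)),
    )


def subtract_input(
    ip: CoverageProfile,
    input_profile: CoverageProfile,
    scaling: ScalingFactor,
) -> CoverageProfile:
    """Return max(ip - lambda * input, 0) with signed core-region sums as QC."""
    if set(ip.values) != set(input_profile.values):
        raise CoverageError("IP and input cover different chromosome sets")
    lam = scaling.value
    values = {}
    signed_values = {}
    for chrom, x in ip.values.items():
        y = input_profile.values[chrom]
        if x.shape != y.shape:
            raise CoverageError(f"length mismatch on {chrom}")
        signed = x - lam * y
        signed_values[chrom] = signed
        values[chrom] = np.maximum(signed, 0.0)
    qc = {}
    for chrom, start, end in scaling.regions:
        qc[f"{chrom}:{start}-{end}"] = float(
            signed_values[chrom][start:end].sum()
        )
    return CoverageProfile(values=values, state="input_subtracted",
                           region_qc=qc, signed_values=signed_values)


def gene_signal_from_profile(
    profile: CoverageProfile,
    annotation: GenomeAnnotation,
) -> pd.Series:
    """Per-gene mean depth over the gene span.

    Repeat families report at the representative copy the *sum* of member
    mean depths (commensurate with counting, where all family reads accrue
    to the representative); non-representative members report 0.  rRNA genes
    are excluded, matching the counting convention.

    For input-subtracted profiles the mean is taken over the *signed*
    difference and clamped at zero per gene: per-base clamping would inflate
    genes whose signal is small against the background noise, biasing fold
    changes between genotypes.
    """
    source = profile.signed_values or profile.values
    counted = annotation.counted_gene_ids()
    out = pd.Series(0.0, index=pd.Index(counted, name="gene_id"))
    for g in annotation:
        if g.category == "rRNA":
            continue
        mean_depth = max(float(source[g.chrom][g.start:g.end].mean()), 0.0)
        if g.copy_group:
            rep = annotation.representative(g.copy_group).gene_id
            out[rep] += mean_depth
        else:
            out[g.gene_id] += mean_depth
    return out


def tpm_like(signal: pd.Series) -> pd.Series:
    """Rescale per-gene mean-depth signal to sum to 1e6 (TPM-like units).

    Mean depth is already length-normalized (mass / length), so this puts
    input-subtracted ChIP gene signal on the same scale as count TPM.
    """
    total = signal.sum()
    if total <= 0:
        raise CoverageError("cannot rescale an all-zero signal")
    return 1e6 * signal / total


# -- track output ----------------------------------------------------------


def write_wiggle(profile: CoverageProfile, path: str | Path, step: int = 1) -> None:
    """fixedStep wiggle (1-based starts per the wiggle standard)."""
    with open(path, "w") as fh:
        for chrom in sorted(profile.values):
            v = profile.values[chrom]
            fh.write(f"fixedStep chrom={chrom} start=1 step={step}\n")
            if step > 1:
                n = len(v) // step * step
                v = v[:n].reshape(-1, step).mean(axis=1)
            fh.write("\n".join(f"{x:g}" for x in v))
            fh.write("\n")


def write_bedgraph(profile: CoverageProfile, path: str | Path) -> None:
    """Run-length-compressed bedGraph (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for chrom in sorted(profile.values):
            v = profile.values[chrom]
            if len(v) == 0:
                continue
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")
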