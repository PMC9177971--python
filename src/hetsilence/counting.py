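"""Read counting, TPM normalization, replicate QC and intron retention.

Counting rules
--------------
A read is counted for at most one gene:

* reads overlapping any rRNA gene at any of their mapped locations are removed;
* uniquely mapping reads (NH = 1) are assigned by intersection-strict
  semantics over the gene span (exons + introns): the read is counted for a
  gene iff every base lies within that gene's span and no second gene also
  contains the whole read (ambiguous reads are dropped);
* for RNA assays (RIP, pA RNA, total RNA) the read strand must equal the
  gene strand; ChIP and input ignore strand;
* multi-mapping reads are counted only when NH < 16 and every mapped location
  lies inside a heterochromatic repeat gene of one shared copy family, in
  which case they add exactly 1 to the family's representative copy
  (the 16 cut-off removes low-complexity reads while keeping reads from the
  12-13-copy pericentromeric dg/dh families).

Counts are never fractional; fractional 1/NH weights exist only in coverage
profiles (:mod:`hetsilence.coverage`).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .genome import GenomeAnnotation, HETEROCHROMATIC_CATEGORIES

logger = logging.getLogger(__name__)

ASSAYS = ("chip", "input", "rip", "pa_rna", "total_rna")
#: assays whose library prep is stranded: read strand must match gene strand
STRANDED_ASSAYS = frozenset({"rip", "pa_rna", "total_rna"})
#: multi-mappers with NH >= this many locations are discarded
MULTIMAP_MAX_NH = 16

DROP_BUCKETS = (
    "counted",
    "rRNA",
    "no_feature",
    "ambiguous",
    "strand",
    "multimapper",
)


class CountingError(ValueError):
    pass


@dataclass
class AlignmentRecord:
    """One sequencing read with its full set of mapped locations.

    ``locations`` are (chrom, start, end, strand) with 0-based half-open
    coordinates; ``nh`` is the number-of-hits and must equal the number of
    locations.
    """

    read_id: str
    locations: list[tuple[str, int, int, str]]
    nh: int = 0

    def __post_init__(self) -> None:
        if self.nh == 0:
            self.nh = len(self.locations)
        if self.nh != len(self.locations) or self.nh < 1:
            raise CountingError(
                f"read {self.read_id!r}: nh={self.nh} but "
                f"{len(self.locations)} locations"
            )
        for chrom, start, end, strand in self.locations:
            if start >= end or strand not in ("+", "-"):
                raise CountingError(f"read {self.read_id!r}: bad location")


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM file, grouping lines by read id.

    NH is taken from the ``NH:i`` tag when present; otherwise it is inferred
    from the number of alignment lines sharing the read id (1 if ungrouped).
    Unmapped records are skipped.
    """
    groups: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []
    nh_tags: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            qname = aln.query_name
            if qname not in groups:
                groups[qname] = []
                order.append(qname)
            groups[qname].append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                )
            )
            if aln.has_tag("NH"):
                nh_tags[qname] = aln.get_tag("NH")
    for qname in order:
        locs = groups[qname]
        nh = nh_tags.get(qname, len(locs))
        if nh != len(locs):
            # tolerate NH tags describing alignments filtered upstream
            nh = max(nh, len(locs))
        yield AlignmentRecord(read_id=qname, locations=locs, nh=nh)


# -- interval containment index -------------------------------------------


class _ChromIndex:
    """Containment queries against genes of one chromosome.

    Genes are sorted by start; ``prefix_max_end[i]`` is the running maximum of
    ends, which bounds the backwards scan so the common non-overlapping case
    costs a single bisect.
    """

    def __init__(self, genes: Sequence) -> None:
        genes = sorted(genes, key=lambda g: (g.start, g.end))
        self.genes = genes
        self.starts = [g.start for g in genes]
        self.prefix_max_end: list[int] = []
        m = 0
        for g in genes:
            m = max(m, g.end)
            self.prefix_max_end.append(m)

    def containing(self, start: int, end: int) -> list:
        """All genes whose span contains [start, end)."""
        i = bisect_right(self.starts, start) - 1
        out = []
        while i >= 0 and self.prefix_max_end[i] >= end:
            g = self.genes[i]
            if g.end >= end:
                out.append(g)
            i -= 1
        return out

    def overlapping(self, start: int, end: int) -> list:
        i = bisect_right(self.starts, end - 1) - 1
        out = []
        while i >= 0 and self.prefix_max_end[i] > start:
            g = self.genes[i]
            if g.end > start and g.start < end:
                out.append(g)
            i -= 1
        return out


class _Engine:
    def __init__(self, annotation: GenomeAnnotation) -> None:
        self.annotation = annotation
        by_chrom: dict[str, list] = {c: [] for c in annotation.chrom_lengths}
        rrna_by_chrom: dict[str, list] = {c: [] for c in annotation.chrom_lengths}
        for g in annotation:
            if g.category == "rRNA":
                rrna_by_chrom[g.chrom].append(g)
            else:
                by_chrom[g.chrom].append(g)
        self.index = {c: _ChromIndex(gs) for c, gs in by_chrom.items()}
        self.rrna = {c: _ChromIndex(gs) for c, gs in rrna_by_chrom.items()}
        self.representatives = {
            name: annotation.representative(name).gene_id
            for name in annotation.copy_groups()
        }

    def overlaps_rrna(self, record: AlignmentRecord) -> bool:
        for chrom, start, end, _ in record.locations:
            if self.rrna[chrom].overlapping(start, end):
                return True
        return False


def _classify_unique(engine, loc, stranded) -> tuple[str, object]:
    chrom, start, end, strand = loc
    containing = engine.index[chrom].containing(start, end)
    if not containing:
        return "no_feature", None
    if stranded:
        matching = [g for g in containing if g.strand == strand]
        if not matching:
            return "strand", None
        containing = matching
    if len(containing) > 1:
        return "ambiguous", None
    return "counted", containing[0]


def _classify_multi(engine, record, stranded, require_all_het) -> tuple[str, object]:
    if record.nh >= MULTIMAP_MAX_NH:
        return "multimapper", None
    shared: set | None = None
    n_het_locations = 0
    for chrom, start, end, strand in record.locations:
        containing = engine.index[chrom].containing(start, end)
        if stranded:
            containing = [g for g in containing if g.strand == strand]
        groups = {
            g.copy_group
            for g in containing
            if g.is_heterochromatic and g.copy_group
        }
        if not groups:
            if require_all_het:
                return "multimapper", None
            continue
        n_het_locations += 1
        shared = groups if shared is None else (shared & groups)
        if not shared:
            return "multimapper", None
    if shared is None or n_het_locations == 0 or len(shared) != 1:
        return "multimapper", None
    group = next(iter(shared))
    return "counted", engine.annotation[engine.representatives[group]]


def _count_core(
    alignments: Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    assay: str,
    require_all_het: bool = True,
    track_introns: bool = False,
):
    if assay not in ASSAYS:
        raise CountingError(f"unknown assay {assay!r}")
    stranded = assay in STRANDED_ASSAYS
    engine = _Engine(annotation)
    counts: dict[str, int] = {gid: 0 for gid in annotation.counted_gene_ids()}
    drops = {b: 0 for b in DROP_BUCKETS}
    intron_counts: dict[tuple[str, int, int], int] = {}
    introns_of: dict[str, list[tuple[int, int]]] = {}
    if track_introns:
        for g in annotation:
            if g.introns:
                introns_of[g.gene_id] = g.introns
                for a, b in g.introns:
                    intron_counts[(g.gene_id, a, b)] = 0

    for record in alignments:
        for chrom, start, end, _ in record.locations:
            if chrom not in annotation.chrom_lengths:
                raise CountingError(
                    f"read {record.read_id!r}: unknown chromosome {chrom!r}"
                )
            if end > annotation.chrom_lengths[chrom]:
                raise CountingError(
                    f"read {record.read_id!r}: past end of {chrom}"
                )
        if engine.overlaps_rrna(record):
            drops["rRNA"] += 1
            continue
        if record.nh == 1:
            bucket, gene = _classify_unique(engine, record.locations[0], stranded)
        else:
            bucket, gene = _classify_multi(engine, record, stranded, require_all_het)
        if bucket != "counted":
            drops[bucket] += 1
            continue
        drops["counted"] += 1
        counts[gene.gene_id] += 1
        if track_introns and gene.gene_id in introns_of and record.nh == 1:
            _, rstart, rend, _ = record.locations[0]
            for a, b in introns_of[gene.gene_id]:
                if rstart < b and rend > a:
                    intron_counts[(gene.gene_id, a, b)] += 1
    return counts, drops, intron_counts


# -- tables ----------------------------------------------------------------


@dataclass
class CountTable:
    """Per-gene raw counts (and optionally TPM) for one or more samples.

    ``counts``/``tpm`` are gene x sample DataFrames; ``meta`` is indexed by
    sample id with columns assay/genotype/replicate; ``drop_stats`` records
    the fate of every read so that counted + dropped = total.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    drop_stats: pd.DataFrame
    tpm: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @staticmethod
    def concat(tables: Sequence["CountTable"]) -> "CountTable":
        counts = pd.concat([t.counts for t in tables], axis=1)
        meta = pd.concat([t.meta for t in tables], axis=0)
        drops = pd.concat([t.drop_stats for t in tables], axis=0)
        tpms = [t.tpm for t in tables]
        tpm = pd.concat(tpms, axis=1) if all(t is not None for t in tpms) else None
        if counts.columns.duplicated().any():
            raise CountingError("duplicate sample ids in concat")
        return CountTable(counts=counts, meta=meta, drop_stats=drops, tpm=tpm)

    def write_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.counts.to_csv(f"{prefix}.counts.tsv", sep="\t")
        if self.tpm is not None:
            self.tpm.to_csv(f"{prefix}.tpm.tsv", sep="\t")
        self.drop_stats.to_csv(f"{prefix}.dropstats.tsv", sep="\t")


def count_reads(
    alignments: Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    assay: str,
    sample_id: str = "sample",
    genotype: str = "",
    replicate: int = 1,
    require_all_het: bool = True,
) -> CountTable:
    """Count a stream of alignments into a one-sample :class:`CountTable`."""
    counts, drops, _ = _count_core(
        alignments, annotation, assay, require_all_het=require_all_het
    )
    counts_df = pd.DataFrame({sample_id: pd.Series(counts, dtype="int64")})
    counts_df.index.name = "gene_id"
    meta = pd.DataFrame(
        {"assay": [assay], "genotype": [genotype], "replicate": [replicate]},
        index=pd.Index([sample_id], name="sample_id"),
    )
    drop_stats = pd.DataFrame([drops], index=meta.index)
    drop_stats["total"] = drop_stats[list(DROP_BUCKETS)].sum(axis=1)
    return CountTable(counts=counts_df, meta=meta, drop_stats=drop_stats)


def count_sam(
    path: str | Path,
    annotation: GenomeAnnotation,
    assay: str,
    **kwargs,
) -> CountTable:
    return count_reads(read_sam(path), annotation, assay, **kwargs)


def tpm_normalize(table: CountTable, annotation: GenomeAnnotation) -> CountTable:
    """Fill the TPM matrix: TPM_g = 1e6 * (c_g/L_g) / sum_h (c_h/L_h).

    L_g is the gene span length; a repeat family's counts sit on the
    representative copy and use that copy's length.  An all-zero sample
    yields NA TPM with a warning.
    """
    lengths = pd.Series(
        {gid: annotation[gid].length for gid in table.counts.index}, dtype="float64"
    )
    rate = table.counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        logger.warning(
            "all-zero sample(s) %s: TPM set to NA", list(denom.index[zero])
        )
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return CountTable(
        counts=table.counts, meta=table.meta, drop_stats=table.drop_stats, tpm=tpm
    )


# -- replicate QC and averaging --------------------------------------------


class ReplicateQCError(ValueError):
    def __init__(self, message: str, correlation: pd.DataFrame):
        super().__init__(f"{message}\n{correlation}")
        self.correlation = correlation


@dataclass
class ReplicateQC:
    """Outcome of replicate concordance filtering for one condition/assay."""

    assay: str
    correlation: pd.DataFrame
    retained: list[str]
    excluded: list[str]
    theta: pd.Series
    replicate_tpm: pd.DataFrame


def replicate_qc(
    table: CountTable,
    threshold: float = 0.8,
) -> ReplicateQC:
    """Filter replicates by pairwise Spearman of log2(TPM+1), then average.

    All pairwise coefficients among retained replicates must be >= the
    threshold; the worst-correlated replicate is removed iteratively (its
    exclusion is logged).  Correlations are computed over genes with TPM > 0
    in at least one replicate.  If no concordant pair survives, a
    :class:`ReplicateQCError` carries the full correlation matrix.
    """
    if table.tpm is None:
        raise CountingError("replicate_qc requires TPM (run tpm_normalize first)")
    assays = set(table.meta["assay"])
    if len(assays) != 1:
        raise CountingError(f"replicate_qc expects one assay, got {assays}")
    assay = assays.pop()
    tpm = table.tpm
    expressed = tpm.gt(0).any(axis=1)
    logt = np.log2(tpm.loc[expressed] + 1.0)
    samples = list(tpm.columns)
    n = len(samples)
    corr = pd.DataFrame(np.ones((n, n)), index=samples, columns=samples)
    for i in range(n):
        for j in range(i + 1, n):
            rho = stats.spearmanr(logt.iloc[:, i], logt.iloc[:, j]).statistic
            corr.iloc[i, j] = corr.iloc[j, i] = rho

    retained = list(samples)
    excluded: list[str] = []
    def worst_pair(names):
        sub = corr.loc[names, names].to_numpy()
        off = sub[~np.eye(len(names), dtype=bool)]
        return off.min() if off.size else 1.0

    # tiny epsilon so a coefficient of exactly 0.8 passes "at least 0.8"
    # despite rank-arithmetic floating noise
    while len(retained) > 1 and worst_pair(retained) < threshold - 1e-12:
        if len(retained) == 2:
            raise ReplicateQCError(
                f"{assay}: no replicate pair reaches Spearman >= {threshold}",
                corr,
            )
        mean_rho = {
            s: corr.loc[s, [t for t in retained if t != s]].mean() for s in retained
        }
        drop = min(mean_rho, key=mean_rho.get)
        retained.remove(drop)
        excluded.append(drop)
        logger.warning(
            "%s: excluding replicate %s (mean Spearman %.3f below concordance)",
            assay, drop, mean_rho[drop],
        )
    theta = tpm[retained].mean(axis=1)
    return ReplicateQC(
        assay=assay,
        correlation=corr,
        retained=retained,
        excluded=excluded,
        theta=theta,
        replicate_tpm=tpm[retained],
    )


@dataclass
class ExpressionSummary:
    """Replicate-averaged TPM per gene for one genotype.

    ``theta`` has columns ``chip``, ``rip``, ``pa_rna`` (average TPM over
    retained replicates); ``replicates`` keeps the per-replicate TPM matrices
    for SEM computation.
    """

    genotype: str
    theta: pd.DataFrame
    replicates: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for assay, reps in self.replicates.items():
            if assay not in self.theta.columns:
                continue
            lo = reps.min(axis=1) - 1e-9
            hi = reps.max(axis=1) + 1e-9
            th = self.theta[assay]
            ok = th.between(lo, hi) | th.isna()
            if not ok.all():
                raise CountingError(
                    f"{self.genotype}/{assay}: theta outside replicate range"
                )


def summarize_genotype(
    genotype: str,
    qc_by_assay: dict[str, ReplicateQC],
) -> ExpressionSummary:
    """Assemble an :class:`ExpressionSummary` from per-assay QC results."""
    theta = pd.DataFrame({a: qc.theta for a, qc in qc_by_assay.items()})
    reps = {a: qc.replicate_tpm for a, qc in qc_by_assay.items()}
    return ExpressionSummary(genotype=genotype, theta=theta, replicates=reps)


# -- intron retention -------------------------------------------------------


def intron_retention(
    alignments: Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    assay: str,
) -> pd.DataFrame:
    """Relative intronic read counts per (gene, intron).

    value = (intron_reads / intron_length) / (gene_reads / gene_length);
    NA when the gene has no counted reads.  Intron overlap is assessed for
    the reads counted for the gene.
    """
    counts, _, intron_counts = _count_core(
        alignments, annotation, assay, track_introns=True
    )
    rows = []
    for (gene_id, a, b), n_intron in sorted(intron_counts.items()):
        g = annotation[gene_id]
        n_gene = counts.get(gene_id, 0)
        if n_gene == 0:
            rel = np.nan
        else:
            rel = (n_intron / (b - a)) / (n_gene / g.length)
        rows.append(
            dict(
                gene_id=gene_id, intron_start=a, intron_end=b,
                intron_length=b - a, intron_reads=n_intron,
                gene_reads=n_gene, relative_intronic_count=rel,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "intron_start", "intron_end", "intron_length",
            "intron_reads", "gene_reads", "relative_intronic_count",
        ],
    )
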