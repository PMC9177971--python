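"""Synthetic ground truth and SAM alignment simulator for the four assays.

The generative model mirrors what the analysis assumes about each assay.
Per gene g with Pol II occupancy ``o_g``, transcription efficiency
``e_g`` in (0, 1] and RNA stability ``s_g`` > 0, the expected signal is

* ChIP:    o_g * span(g)           plus a uniform genomic background,
* input:   background only,
* RIP:     o_g * e_g * span(g)     (nascent RNA, partially unspliced),
* pA RNA:  o_g * e_g * s_g * exonic(g)   (mature, spliced RNA).

Reads are Poisson-sampled around these expectations and placed uniformly
(within exons for the spliced fraction, across the whole span for the
intron-retaining fraction, ``rho_nascent`` > ``rho_mature``).  A read from a
multi-copy repeat family is emitted once per family copy at the same offset
with ``NH`` = family size, exactly as a real multi-mapper's alignment
records.  RNA-assay reads carry the transcript strand; ChIP/input reads are
unstranded.  The three central-core regions are transcriptionally silent
(o = 0) and anchor the input scaling downstream.

The default wild-type/clr4 scenario pair encodes the study conditions:
heterochromatic efficiency 8-fold below euchromatic, 4-fold higher repeat
occupancy without heterochromatin, and pericentromeric log2 fold changes of
2 : 1.44 : 2.1 for occupancy : efficiency : stability (silencing shares
36 / 26 / 38 percent).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import ASSAYS, ExpressionSummary
from .genome import GeneModel, GenomeAnnotation

__all__ = [
    "SimTruth",
    "toy_annotation",
    "make_truth",
    "expected_counts",
    "expected_summary",
    "simulate_alignments",
    "simulate_dataset",
    "SCENARIOS",
    "CLR4_REPEAT_LOG2FC",
]


class SimulationError(ValueError):
    pass


# -- default toy genome ----------------------------------------------------


def toy_annotation(
    n_protein_coding: int = 200,
    intron_every: int = 7,
    chrom: str = "chrT",
) -> GenomeAnnotation:
    """Build the default toy genome: one chromosome with every category.

    ~200 protein-coding genes (1 kb; every ``intron_every``-th carries one
    150 bp intron), a 12-copy dg family, a 13-copy dh family split into
    strand-homogeneous subfamilies (7 forward / 6 reverse), 2 tlh repeat
    genes, 6 other subtelomeric genes, cenH and mat loci, three 20 kb
    central-core background regions (long, transcriptionally silent — they
    anchor the input scaling) and 2 rRNA genes.
    """
    genes: list[GeneModel] = []
    cur = 1000

    def add(gene_id, length, strand, category, copy_group=None, rep=False,
            exons=None, gap=500):
        nonlocal cur
        start, end = cur, cur + length
        ex = [(start + a, start + b) for a, b in exons] if exons else []
        genes.append(
            GeneModel(
                gene_id=gene_id, chrom=chrom, start=start, end=end,
                strand=strand, category=category, exons=ex,
                copy_group=copy_group, is_representative=rep,
            )
        )
        cur = end + gap

    # left subtelomere: tlh repeat family + 3 subtelomeric genes
    add("tlh1", 2000, "+", "tlh_repeat", copy_group="tlh", rep=True, gap=1000)
    add("tlh2", 2000, "+", "tlh_repeat", copy_group="tlh", gap=1000)
    for i in range(1, 4):
        add(f"sub{i}", 1500, "+" if i % 2 else "-", "subtelomeric")

    # euchromatic arm with two rRNA genes embedded
    for i in range(1, n_protein_coding + 1):
        exons = None
        if intron_every and i % intron_every == 0:
            exons = [(0, 400), (550, 1000)]  # one 150 bp intron
        add(f"pc{i:04d}", 1000, "+" if i % 2 else "-", "protein_coding",
            exons=exons, gap=200)
        if i == n_protein_coding // 4:
            add("rrn1", 3000, "+", "rRNA")
        if i == n_protein_coding // 2:
            add("rrn2", 3000, "+", "rRNA")

    # centromere: three central-core anchors, then dg / dh repeat families
    for i in range(1, 4):
        add(f"cc{i}", 20000, "+", "central_core", gap=1000)
    for i in range(1, 13):
        add(f"dg{i:02d}", 2000, "+", "dg", copy_group="dg", rep=(i == 1))
    for i in range(1, 8):
        add(f"dh{i:02d}", 1800, "+", "dh", copy_group="dh_fwd", rep=(i == 1))
    for i in range(8, 14):
        add(f"dh{i:02d}", 1800, "-", "dh", copy_group="dh_rev", rep=(i == 8))

    # mating-type region and right subtelomere
    add("cenH", 2000, "+", "cenH", gap=1000)
    add("mat", 2000, "+", "mat", gap=1000)
    for i in range(4, 7):
        add(f"sub{i}", 1500, "+" if i % 2 else "-", "subtelomeric")

    return GenomeAnnotation(genes, {chrom: cur + 1000})


# -- scenarios -------------------------------------------------------------

#: wild-type per-category (occupancy, efficiency, stability)
WT_PARAMS: dict[str, tuple[float, float, float]] = {
    "protein_coding": (1.0, 0.5, 1.0),
    "dg": (0.1, 0.0625, 2.0 ** -2.1),
    "dh": (0.1, 0.0625, 2.0 ** -2.1),
    "tlh_repeat": (0.1, 0.015, 2.0 ** -0.615),
    "subtelomeric": (0.3, 0.0625, 1.0),
    "cenH": (0.3, 0.0625, 1.0),
    "mat": (0.3, 0.0625, 1.0),
    "central_core": (0.0, 0.5, 1.0),
    "rRNA": (5.0, 0.8, 1.0),
}

#: pericentromeric log2 fold changes (occupancy, efficiency, stability)
#: in clr4 relative to wild type; silencing shares 36.1 / 26.0 / 37.9 %
CLR4_REPEAT_LOG2FC = (2.0, 1.44, 2.1)

#: strand-resolved baseline tweak: dh transcripts from the two strands have
#: distinct stability (uniform across genotypes, so region fold changes are
#: unaffected but by-strand reporting separates them)
GROUP_STABILITY_FACTORS = {"dh_fwd": 1.2, "dh_rev": 0.8}

_REPEATS = ("dg", "dh")
_ALL_HET = ("dg", "dh", "tlh_repeat", "subtelomeric", "cenH", "mat")

_CLR4 = {
    "dg": {"o_mul": 2.0 ** CLR4_REPEAT_LOG2FC[0],
           "e_mul": 2.0 ** CLR4_REPEAT_LOG2FC[1],
           "s_mul": 2.0 ** CLR4_REPEAT_LOG2FC[2]},
    "tlh_repeat": {"o_mul": 4.0, "e_mul": 2.0 ** 5.08, "s_mul": 2.0 ** 0.615},
    "subtelomeric": {"o_mul": 1.5, "e_set": 0.5, "s_set": 1.0},
}
_CLR4["dh"] = _CLR4["dg"]
_CLR4["cenH"] = _CLR4["mat"] = _CLR4["subtelomeric"]

def _ccr4_not(e_jitter: float, s_mul: float) -> dict:
    # Ccr4-Not mutants: efficiency restored to the heterochromatin-independent
    # (clr4-like) level, occupancy unchanged, degradation increased.
    out = {
        "dg": {"e_mul": 2.0 ** 1.44 * e_jitter, "s_mul": s_mul},
        "tlh_repeat": {"e_mul": 2.0 ** 5.08 * e_jitter, "s_mul": s_mul},
        "subtelomeric": {"e_set": 0.5 * e_jitter},
    }
    out["dh"] = out["dg"]
    out["cenH"] = out["mat"] = out["subtelomeric"]
    return out

def _chromatin(o_mul: float, e_mul: float, s_mul: float) -> dict:
    out = {c: {"o_mul": o_mul, "e_mul": e_mul, "s_mul": s_mul} for c in
           ("dg", "dh", "tlh_repeat")}
    out["subtelomeric"] = {"o_mul": 1.0 + (o_mul - 1.0) * 0.2}
    return out

SCENARIOS: dict[str, dict] = {
    "wt": {},
    "clr4": _CLR4,
    "caf1": _ccr4_not(1.00, 0.55),
    "ccr4": _ccr4_not(0.95, 0.50),
    "mot2": _ccr4_not(1.05, 0.60),
    "swi6": _chromatin(2.5, 1.3, 1.1),
    "clr3": _chromatin(1.8, 1.2, 1.05),
    "ago1": {"dg": {"s_mul": 3.0}, "dh": {"s_mul": 3.0}},
}


@dataclass
class SimTruth:
    """Ground-truth parameters for one genotype.

    ``params`` is indexed by gene_id with columns occupancy / efficiency /
    stability; depths and background fractions are per assay (background is
    the uniform genomic component captured by the input sample).
    """

    genotype: str
    params: pd.DataFrame
    seed: int
    read_length: int = 50
    depth: dict[str, float] = field(
        default_factory=lambda: {a: 1e5 for a in ASSAYS}
    )
    background_frac: dict[str, float] = field(
        default_factory=lambda: {
            "chip": 0.3, "input": 1.0, "rip": 0.0,
            "pa_rna": 0.0, "total_rna": 0.0,
        }
    )
    rho_nascent: float = 0.3
    rho_mature: float = 0.02
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        p = self.params
        if not np.isfinite(p.to_numpy()).all():
            raise SimulationError("non-finite truth parameters")
        if (p["occupancy"] < 0).any():
            raise SimulationError("negative occupancy")
        if ((p["efficiency"] <= 0) | (p["efficiency"] > 1)).any():
            raise SimulationError("efficiency must lie in (0, 1]")
        if (p["stability"] <= 0).any():
            raise SimulationError("stability must be positive")
        if not (0 <= self.rho_mature < self.rho_nascent <= 1):
            raise SimulationError("need 0 <= rho_mature < rho_nascent <= 1")

    def write_tsv(self, path: str | Path) -> None:
        self.params.to_csv(path, sep="\t")


def _normalize_scenario(name: str) -> str:
    """Map genotype spellings like 'clr4Δ' / 'clr4d' onto scenario keys."""
    key = name.lower().replace("Δ", "").replace("δ", "")
    key = key.replace("delta", "").strip("_ ")
    if key not in SCENARIOS and key.endswith("d") and key[:-1] in SCENARIOS:
        key = key[:-1]
    return key


def make_truth(
    scenario: str | Mapping,
    annotation: GenomeAnnotation,
    seed: int,
    depth: float | Mapping[str, float] = 1e5,
    occupancy_sigma: float = 0.5,
    **kwargs,
) -> SimTruth:
    """Instantiate ground truth for a named scenario (or a custom transform).

    Protein-coding baseline occupancies are log-normal across genes
    (sigma ``occupancy_sigma``), drawn from ``seed`` alone so that the same
    seed yields identical euchromatic baselines across genotypes; the
    scenario then applies deterministic per-category transforms
    (``o_mul``/``e_mul``/``s_mul`` multipliers or ``o_set``/``e_set``/``s_set``
    overrides).  Deterministic given (scenario, seed).
    """
    if isinstance(scenario, str):
        key = scenario.lower()
        if key not in SCENARIOS:
            key = _normalize_scenario(scenario)
        if key not in SCENARIOS:
            raise SimulationError(
                f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}"
            )
        transform = SCENARIOS[key]
        genotype = key
    else:
        transform = dict(scenario)
        genotype = kwargs.pop("genotype", "custom")

    rng = np.random.default_rng(seed)
    rows = {}
    for g in annotation:
        o, e, s = WT_PARAMS[g.category]
        if g.category == "protein_coding":
            o = o * float(np.exp(rng.normal(0.0, occupancy_sigma)))
        if g.copy_group in GROUP_STABILITY_FACTORS:
            s = s * GROUP_STABILITY_FACTORS[g.copy_group]
        t = transform.get(g.category, {})
        o = t.get("o_set", o * t.get("o_mul", 1.0))
        e = t.get("e_set", e * t.get("e_mul", 1.0))
        s = t.get("s_set", s * t.get("s_mul", 1.0))
        rows[g.gene_id] = (o, min(e, 1.0), s)
    params = pd.DataFrame.from_dict(
        rows, orient="index", columns=["occupancy", "efficiency", "stability"]
    )
    params.index.name = "gene_id"
    if not isinstance(depth, Mapping):
        depth = {a: float(depth) for a in ASSAYS}
    else:
        depth = {a: float(depth.get(a, 1e5)) for a in ASSAYS}
    return SimTruth(genotype=genotype, params=params, seed=seed,
                    depth=dict(depth), **kwargs)


# -- closed-form expectations (test oracle, no randomness) -----------------


def expected_intensity(
    truth: SimTruth, annotation: GenomeAnnotation, assay: str
) -> pd.Series:
    """Unnormalized expected signal per gene (all genes, including rRNA).

    ChIP ~ o*span, RIP ~ o*e*span, pA/total ~ o*e*s*exonic, input ~ 0;
    read expectations are these intensities rescaled to the assay depth.
    """
    p = truth.params
    vals = {}
    for g in annotation:
        o, e, s = p.loc[g.gene_id]
        if assay == "chip":
            v = o * g.length
        elif assay == "input":
            v = 0.0
        elif assay == "rip":
            v = o * e * g.length
        elif assay in ("pa_rna", "total_rna"):
            v = o * e * s * g.exonic_length
        else:
            raise SimulationError(f"unknown assay {assay!r}")
        vals[g.gene_id] = v
    return pd.Series(vals, dtype="float64")


def _signal_read_expectations(truth, annotation, assay) -> pd.Series:
    inten = expected_intensity(truth, annotation, assay)
    z = inten.sum()
    d = truth.depth[assay]
    bg = truth.background_frac.get(assay, 0.0)
    if z <= 0:
        return inten * 0.0
    exp = d * (1.0 - bg) * inten / z
    if not np.isfinite(exp).all() or (exp < 0).any():
        raise SimulationError(f"invalid read expectations for {assay}")
    return exp


def expected_counts(
    truth: SimTruth, annotation: GenomeAnnotation, assay: str
) -> pd.Series:
    """Expected *counted* reads per gene under the pipeline's counting rules.

    Pure closed-form: signal reads accrue in full (placement keeps them inside
    the gene span); a repeat family's reads all land on the representative
    copy; rRNA reads are removed; uniform background reads (ChIP/input)
    contribute to each gene in proportion to its fully-containing start
    positions.  Assumes a non-overlapping annotation, which the toy genome
    satisfies.
    """
    sig = _signal_read_expectations(truth, annotation, assay)
    counted = annotation.counted_gene_ids()
    out = pd.Series(0.0, index=pd.Index(counted, name="gene_id"))
    for g in annotation:
        if g.category == "rRNA":
            continue
        target = (
            annotation.representative(g.copy_group).gene_id
            if g.copy_group else g.gene_id
        )
        out[target] += sig[g.gene_id]

    bg = truth.background_frac.get(assay, 0.0)
    if bg > 0:
        rl = truth.read_length
        positions = sum(
            max(L - rl + 1, 0) for L in annotation.chrom_lengths.values()
        )
        n_bg = truth.depth[assay] * bg
        for g in annotation:
            if g.category == "rRNA":
                continue
            out[g.gene_id] += n_bg * max(g.length - rl + 1, 0) / positions
    return out


def expected_summary(truth: SimTruth, annotation: GenomeAnnotation) -> ExpressionSummary:
    """Analytic ExpressionSummary (theta_ChIP / theta_RIP / theta_pA).

    theta_ChIP follows the input-subtracted coverage path: per-gene mean
    subtracted depth (family-summed onto the representative) rescaled to 1e6;
    the RNA assays are expected-count TPM.  Used as the deterministic oracle
    for parameter-recovery and monotonicity checks.
    """
    counted = annotation.counted_gene_ids()
    # ChIP: subtracted mean depth per gene ~ o_g (family-summed at the rep)
    chip = pd.Series(0.0, index=pd.Index(counted, name="gene_id"))
    for g in annotation:
        if g.category == "rRNA":
            continue
        o = truth.params.loc[g.gene_id, "occupancy"]
        if g.copy_group:
            rep = annotation.representative(g.copy_group).gene_id
            chip[rep] += o * g.length / annotation[rep].length
        else:
            chip[g.gene_id] += o
    theta = {"chip": 1e6 * chip / chip.sum()}
    for assay, col in (("rip", "rip"), ("pa_rna", "pa_rna")):
        c = expected_counts(truth, annotation, assay)
        lengths = pd.Series({gid: annotation[gid].length for gid in c.index})
        rate = c / lengths
        theta[col] = 1e6 * rate / rate.sum()
    return ExpressionSummary(genotype=truth.genotype, theta=pd.DataFrame(theta))


# -- SAM simulation --------------------------------------------------------


def _family_members(annotation, group):
    members = sorted(
        (g for g in annotation if g.copy_group == group),
        key=lambda g: (g.chrom, g.start),
    )
    lengths = {m.length for m in members}
    if len(lengths) != 1:
        raise SimulationError(
            f"copy_group {group!r}: members must share one length"
        )
    return members


def _draw_counts(rng, expectations: np.ndarray, overdispersion: float) -> np.ndarray:
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, expectations * overdispersion)
        return rng.poisson(lam)
    return rng.poisson(expectations)


def _place_reads(rng, gene: GeneModel, n: int, rho_span: float, rl: int) -> np.ndarray:
    """Start positions for n reads: fraction rho_span uniform over the span
    (may cross introns), the rest confined to single exons."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    hi = gene.end - rl
    if hi < gene.start:
        raise SimulationError(f"{gene.gene_id}: shorter than read length")
    exons = [(a, b) for a, b in gene.exons if b - a >= rl]
    if rho_span >= 1.0 or len(gene.exons) == 1 or not exons:
        return rng.integers(gene.start, hi + 1, n)
    k = rng.binomial(n, rho_span)
    span_starts = rng.integers(gene.start, hi + 1, k)
    weights = np.array([b - a - rl + 1 for a, b in exons], dtype="float64")
    choice = rng.choice(len(exons), size=n - k, p=weights / weights.sum())
    ex_starts = np.array(
        [rng.integers(exons[c][0], exons[c][1] - rl + 1) for c in choice],
        dtype=np.int64,
    )
    return np.concatenate([span_starts, ex_starts])


def simulate_alignments(
    truth: SimTruth,
    annotation: GenomeAnnotation,
    assay: str,
    replicate: int,
    path: str | Path,
) -> int:
    """Write one simulated SAM file; returns the number of reads emitted.

    Per-gene read counts are Poisson (optionally gamma-overdispersed) around
    the closed-form expectations; repeat-family reads are written once per
    copy with NH = family size (secondary flag on the non-source copies).
    The replicate index perturbs the random stream but not the expectations.
    """
    if assay not in ASSAYS:
        raise SimulationError(f"unknown assay {assay!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [truth.seed, zlib.crc32(truth.genotype.encode()) % (2**31),
             ASSAYS.index(assay), int(replicate)]
        )
    )
    rl = truth.read_length
    stranded = assay in ("rip", "pa_rna", "total_rna")
    rho_span = {"rip": truth.rho_nascent,
                "pa_rna": truth.rho_mature,
                "total_rna": truth.rho_mature}.get(assay, 1.0)

    sig = _signal_read_expectations(truth, annotation, assay)
    genes = list(annotation)
    n_per_gene = _draw_counts(rng, sig[[g.gene_id for g in genes]].to_numpy(),
                              truth.overdispersion)

    families = {name: _family_members(annotation, name)
                for name in annotation.copy_groups()}

    lines: list[str] = []
    serial = 0
    prefix = f"{truth.genotype}_{assay}_r{replicate}"

    def emit(qname, flag, chrom, pos0, nh):
        lines.append(
            f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t255\t{rl}M\t*\t0\t0\t*\t*\tNH:i:{nh}"
        )

    for g, n in zip(genes, n_per_gene):
        if n == 0:
            continue
        starts = _place_reads(rng, g, int(n), rho_span, rl)
        if stranded:
            flags = np.full(n, 16 if g.strand == "-" else 0)
        else:
            flags = np.where(rng.random(int(n)) < 0.5, 16, 0)
        members = families.get(g.copy_group) if g.copy_group else None
        for s, f in zip(starts, flags):
            qname = f"{prefix}_{serial:07d}"
            serial += 1
            if members is None:
                emit(qname, int(f), g.chrom, int(s), 1)
            else:
                offset = int(s) - g.start
                nh = len(members)
                for m in members:
                    flag = int(f) if m.gene_id == g.gene_id else int(f) | 0x100
                    emit(qname, flag, m.chrom, m.start + offset, nh)

    bg = truth.background_frac.get(assay, 0.0)
    if bg > 0:
        chroms = sorted(annotation.chrom_lengths)
        pos_per_chrom = np.array(
            [max(annotation.chrom_lengths[c] - rl + 1, 0) for c in chroms],
            dtype="float64",
        )
        n_bg = int(rng.poisson(truth.depth[assay] * bg))
        which = rng.choice(len(chroms), size=n_bg,
                           p=pos_per_chrom / pos_per_chrom.sum())
        for ci in which:
            s = int(rng.integers(0, int(pos_per_chrom[ci])))
            flag = 16 if rng.random() < 0.5 else 0
            emit(f"{prefix}_{serial:07d}", flag, chroms[ci], s, 1)
            serial += 1

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{annotation.chrom_lengths[chrom]}\n")
        fh.write("@PG\tID:hetsilence-sim\tPN:hetsilence\n")
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")
    return serial


def simulate_dataset(
    annotation: GenomeAnnotation,
    scenarios: Sequence[str],
    outdir: str | Path,
    seed: int,
    depth: float | Mapping[str, float] = 1e5,
    replicates: int = 2,
    assays: Sequence[str] = ("chip", "input", "rip", "pa_rna"),
    **truth_kwargs,
) -> pd.DataFrame:
    """Simulate a full multi-genotype dataset and write a sample sheet.

    Writes one SAM per (genotype, assay, replicate), a truth TSV per
    genotype, and ``sample_sheet.tsv`` (sample_id, path, assay, genotype,
    replicate; paths relative to ``outdir``).  Returns the sheet.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scenario in scenarios:
        truth = make_truth(scenario, annotation, seed, depth=depth, **truth_kwargs)
        truth.write_tsv(outdir / f"truth_{truth.genotype}.tsv")
        for assay in assays:
            for rep in range(1, replicates + 1):
                name = f"{truth.genotype}_{assay}_rep{rep}.sam"
                simulate_alignments(truth, annotation, assay, rep, outdir / name)
                rows.append(
                    dict(
                        sample_id=f"{truth.genotype}_{assay}_rep{rep}",
                        path=name, assay=assay,
                        genotype=truth.genotype, replicate=rep,
                    )
                )
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    return sheet
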