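"""Annotated genome model: gene coordinates, heterochromatin categories, repeat families.

The genome is represented as a flat collection of :class:`GeneModel` records.
Coordinates are 0-based half-open internally; GFF3 I/O converts from/to the
1-based closed convention of that format, BED is read as 0-based half-open.

Heterochromatic loci carry a ``category`` label (``dg``, ``dh``, ``tlh_repeat``,
``subtelomeric``, ``cenH``, ``mat``); multi-copy repeat families additionally
carry a ``copy_group`` naming the family, with exactly one member flagged as
the representative copy that receives all of the family's multi-mapping reads
during counting.  Three ``central_core`` regions (Cenp-A chromatin, near-zero
Pol II signal) anchor the ChIP input scaling.
"""

from __future__ import annotations

import fnmatch
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

CATEGORIES = (
    "protein_coding",
    "dg",
    "dh",
    "tlh_repeat",
    "subtelomeric",
    "cenH",
    "mat",
    "central_core",
    "rRNA",
)

#: categories treated as heterochromatic for multi-mapper eligibility and
#: for the silencing metrics / feature vectors
HETEROCHROMATIC_CATEGORIES = frozenset(
    {"dg", "dh", "tlh_repeat", "subtelomeric", "cenH", "mat"}
)


class AnnotationError(ValueError):
    """Base class for annotation problems."""


class ParseError(AnnotationError):
    """Malformed record in an annotation file (names the offending line)."""


class ClassificationError(AnnotationError):
    """A feature could not be resolved to a category."""


class ValidationError(AnnotationError):
    """Annotation violates a structural invariant."""


@dataclass
class GeneModel:
    """One locus: coordinates, strand, category, exon structure, repeat family.

    ``exons`` default to the full span (single-exon gene).  Introns are exactly
    the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    copy_group: str | None = None
    is_representative: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.gene_id}: unknown category {self.category!r}"
            )
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise ValidationError(f"{self.gene_id}: empty exon ({a},{b})")
            if a < self.start or b > self.end:
                raise ValidationError(
                    f"{self.gene_id}: exon ({a},{b}) outside gene span"
                )
            if prev_end is not None and a < prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
            prev_end = b

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, as (start, end) half-open intervals."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out

    @property
    def is_heterochromatic(self) -> bool:
        return self.category in HETEROCHROMATIC_CATEGORIES


class GenomeAnnotation:
    """Validated collection of gene models plus chromosome lengths.

    Validation enforces unique gene ids, chromosome bounds, exactly one
    representative per repeat family (auto-assigned to the lowest-coordinate
    member, with a warning, when none is flagged) and exactly three
    ``central_core`` background regions when any are present.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_lengths: Mapping[str, int],
    ) -> None:
        self.genes: dict[str, GeneModel] = {}
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        for g in genes:
            if g.gene_id in self.genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            if g.chrom not in self.chrom_lengths:
                raise ValidationError(
                    f"{g.gene_id}: unknown chromosome {g.chrom!r}"
                )
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValidationError(
                    f"{g.gene_id}: extends past end of {g.chrom}"
                )
            self.genes[g.gene_id] = g
        self._fix_representatives()
        cores = self.category_index().get("central_core", [])
        if cores and len(cores) != 3:
            raise ValidationError(
                f"expected exactly 3 central_core regions, found {len(cores)}"
            )

    def _fix_representatives(self) -> None:
        groups: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            if g.copy_group:
                groups.setdefault(g.copy_group, []).append(g)
        for name, members in groups.items():
            reps = [g for g in members if g.is_representative]
            if len(reps) == 1:
                continue
            if len(reps) > 1:
                raise ValidationError(
                    f"copy_group {name!r} has {len(reps)} representatives"
                )
            members.sort(key=lambda g: (g.chrom, g.start))
            members[0].is_representative = True
            logger.warning(
                "copy_group %r had no representative; assigned %s "
                "(lowest-coordinate member)",
                name,
                members[0].gene_id,
            )

    # -- indexed views ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def category_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for g in self.genes.values():
            idx.setdefault(g.category, []).append(g.gene_id)
        return idx

    def copy_groups(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for g in self.genes.values():
            if g.copy_group:
                idx.setdefault(g.copy_group, []).append(g.gene_id)
        return idx

    def representative(self, copy_group: str) -> GeneModel:
        for g in self.genes.values():
            if g.copy_group == copy_group and g.is_representative:
                return g
        raise KeyError(copy_group)

    def counted_gene_ids(self) -> list[str]:
        """Genes that participate in count tables and the TPM denominator.

        rRNA genes are excluded (their reads are removed before counting);
        non-representative repeat copies stay included — they can receive
        unique (background) reads, while family multi-mappers accrue to the
        representative.
        """
        return [g.gene_id for g in self.genes.values() if g.category != "rRNA"]

    def heterochromatic_gene_ids(self, representatives_only: bool = True) -> list[str]:
        out = []
        for g in self.genes.values():
            if not g.is_heterochromatic:
                continue
            if representatives_only and g.copy_group and not g.is_representative:
                continue
            out.append(g.gene_id)
        return out

    def core_regions(self) -> list[tuple[str, int, int]]:
        """The three central-core background intervals, sorted by coordinate."""
        cores = [
            (g.chrom, g.start, g.end)
            for g in self.genes.values()
            if g.category == "central_core"
        ]
        if len(cores) != 3:
            raise ValidationError(
                f"need exactly 3 central_core regions, found {len(cores)}"
            )
        return sorted(cores)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: (g.start, g.end),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return (
            self.chrom_lengths == other.chrom_lengths
            and self.genes == other.genes
        )


# -- category configuration ------------------------------------------------


def load_category_config(path: str | Path) -> dict:
    """Read a YAML/JSON category config.

    Recognized keys: ``categories`` (gene_id or glob pattern -> category),
    ``copy_groups`` (family name -> {members: [ids/patterns], representative}),
    ``core_centromeric_regions`` (gene ids -> central_core),
    ``rRNA_ids`` (gene ids -> rRNA).
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _resolve_category(gene_id: str, config: Mapping) -> str | None:
    if gene_id in config.get("rRNA_ids", []):
        return "rRNA"
    if gene_id in config.get("core_centromeric_regions", []):
        return "central_core"
    cats = config.get("categories", {})
    if gene_id in cats:
        return cats[gene_id]
    for pattern, cat in cats.items():
        if fnmatch.fnmatchcase(gene_id, pattern):
            return cat
    return None


def _resolve_copy_group(gene_id: str, config: Mapping) -> tuple[str | None, bool]:
    for name, spec in config.get("copy_groups", {}).items():
        members = spec.get("members", []) if isinstance(spec, Mapping) else spec
        rep = spec.get("representative") if isinstance(spec, Mapping) else None
        for pat in members:
            if gene_id == pat or fnmatch.fnmatchcase(gene_id, pat):
                return name, gene_id == rep
    return None, False


# -- GFF3 / BED I/O --------------------------------------------------------


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for chunk in attr.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        k, v = chunk.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def load_annotation(
    path: str | Path,
    categories: Mapping | str | Path | None = None,
) -> GenomeAnnotation:
    """Load a GFF3 or BED6 annotation into a validated :class:`GenomeAnnotation`.

    ``categories`` is a config mapping (or path to one) used to classify
    features; GFF3 attributes ``category``, ``copy_group`` and
    ``representative`` written by :func:`write_gff3` take precedence, so a
    round-trip needs no config.  Coordinates are converted to the internal
    0-based half-open convention.
    """
    if isinstance(categories, (str, Path)):
        categories = load_category_config(categories)
    config = categories or {}
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _load_bed(path, config)
    return _load_gff3(path, config)


def _classify(gene_id: str, attrs: Mapping[str, str], config: Mapping, lineno: int):
    category = attrs.get("category") or _resolve_category(gene_id, config)
    if category is None:
        raise ClassificationError(
            f"line {lineno}: gene {gene_id!r} has no category "
            "(not matched by config, no category attribute)"
        )
    if "copy_group" in attrs:
        group = attrs["copy_group"] or None
        is_rep = attrs.get("representative", "false").lower() == "true"
    else:
        group, is_rep = _resolve_copy_group(gene_id, config)
    return category, group, is_rep


def _load_gff3(path: Path, config: Mapping) -> GenomeAnnotation:
    chrom_lengths: dict[str, int] = {}
    raw_genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attr = fields
            try:
                start = int(start1) - 1  # GFF3 is 1-based closed
                end = int(end1)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad coordinates") from exc
            attrs = _parse_gff3_attributes(attr)
            if ftype == "gene":
                gene_id = attrs.get("ID")
                if not gene_id:
                    raise ParseError(f"line {lineno}: gene feature without ID")
                if gene_id in raw_genes:
                    raise ValidationError(f"duplicate gene_id {gene_id!r}")
                category, group, is_rep = _classify(gene_id, attrs, config, lineno)
                raw_genes[gene_id] = dict(
                    chrom=chrom, start=start, end=end, strand=strand,
                    category=category, copy_group=group,
                    is_representative=is_rep, exons=[],
                )
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if not parent or parent not in raw_genes:
                    raise ParseError(
                        f"line {lineno}: exon with unknown Parent {parent!r}"
                    )
                raw_genes[parent]["exons"].append((start, end))
    genes = [GeneModel(gene_id=gid, **spec) for gid, spec in raw_genes.items()]
    if not chrom_lengths:
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes, chrom_lengths)


def _load_bed(path: Path, config: Mapping) -> GenomeAnnotation:
    genes = []
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: BED6 needs 6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            category, group, is_rep = _classify(name, {}, config, lineno)
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, start=int(start), end=int(end),
                    strand=strand, category=category,
                    copy_group=group, is_representative=is_rep,
                )
            )
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), int(end))
    return GenomeAnnotation(genes, chrom_lengths)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write GFF3 that round-trips through :func:`load_annotation` unchanged."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in sorted(annotation.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(annotation, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = [f"ID={g.gene_id}", f"category={g.category}"]
            if g.copy_group:
                attrs.append(f"copy_group={g.copy_group}")
                attrs.append(f"representative={'true' if g.is_representative else 'false'}")
            fh.write(
                "\t".join(
                    [g.chrom, "hetsilence", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", ";".join(attrs)]
                ) + "\n"
            )
            for i, (a, b) in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [g.chrom, "hetsilence", "exon", str(a + 1), str(b),
                         ".", g.strand, ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]
                    ) + "\n"
                )


def intron_catalog(
    annotation: GenomeAnnotation,
) -> list[tuple[str, int, int, int]]:
    """Enumerate every intron as (gene_id, start, end, length).

    One entry per inter-exon gap; single-exon genes contribute nothing.
    """
    out = []
    for g in annotation:
        for a, b in g.introns:
            out.append((g.gene_id, a, b, b - a))
    return out
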