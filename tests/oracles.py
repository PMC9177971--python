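"""Independent brute-force oracles used by the test suite.

The counting oracle enumerates per-base sets of covering genes (built by
walking every gene's bases — no interval index, no bisect) and applies the
counting rules from first principles.  It shares no code with the package's
counting engine.
"""

from collections import Counter

import numpy as np

from hetsilence.counting import (
    MULTIMAP_MAX_NH,
    STRANDED_ASSAYS,
    AlignmentRecord,
)
from hetsilence.genome import GeneModel, GenomeAnnotation


def brute_force_count(records, annotation, assay, require_all_het=True):
    """Per-gene counts and drop buckets by per-base set enumeration."""
    stranded = assay in STRANDED_ASSAYS
    counts = Counter({gid: 0 for gid in annotation.counted_gene_ids()})
    drops = Counter(
        counted=0, rRNA=0, no_feature=0, ambiguous=0, strand=0, multimapper=0
    )

    # per-base covering sets, built by brute enumeration of every gene's bases
    base_sets = {
        chrom: [set() for _ in range(length)]
        for chrom, length in annotation.chrom_lengths.items()
    }
    rrna_bases = {
        chrom: np.zeros(length, dtype=bool)
        for chrom, length in annotation.chrom_lengths.items()
    }
    for g in annotation:
        for b in range(g.start, g.end):
            if g.category == "rRNA":
                rrna_bases[g.chrom][b] = True
            else:
                base_sets[g.chrom][b].add(g.gene_id)

    def whole_read_set(chrom, start, end, strand_filter=None):
        common = set.intersection(*(base_sets[chrom][b] for b in range(start, end)))
        if strand_filter is not None:
            common = {
                gid for gid in common
                if annotation[gid].strand == strand_filter
            }
        return common

    for rec in records:
        if any(rrna_bases[c][s:e].any() for c, s, e, _ in rec.locations):
            drops["rRNA"] += 1
            continue
        if rec.nh == 1:
            chrom, start, end, strand = rec.locations[0]
            common = whole_read_set(chrom, start, end)
            if not common:
                drops["no_feature"] += 1
                continue
            if stranded:
                common = {
                    gid for gid in common if annotation[gid].strand == strand
                }
                if not common:
                    drops["strand"] += 1
                    continue
            if len(common) > 1:
                drops["ambiguous"] += 1
                continue
            drops["counted"] += 1
            counts[common.pop()] += 1
        else:
            if rec.nh >= MULTIMAP_MAX_NH:
                drops["multimapper"] += 1
                continue
            group_sets = []
            ok = True
            for chrom, start, end, strand in rec.locations:
                common = whole_read_set(
                    chrom, start, end, strand if stranded else None
                )
                groups = {
                    annotation[gid].copy_group
                    for gid in common
                    if annotation[gid].is_heterochromatic
                    and annotation[gid].copy_group
                }
                if not groups:
                    if require_all_het:
                        ok = False
                        break
                    continue
                group_sets.append(groups)
            if not ok or not group_sets:
                drops["multimapper"] += 1
                continue
            shared = set.intersection(*group_sets)
            if len(shared) != 1:
                drops["multimapper"] += 1
                continue
            rep = annotation.representative(shared.pop())
            drops["counted"] += 1
            counts[rep.gene_id] += 1
    return dict(counts), dict(drops)


def brute_force_tpm(counts, lengths):
    """Two-pass TPM arithmetic independent of pandas broadcasting."""
    rates = {g: counts[g] / lengths[g] for g in counts}
    total = sum(rates.values())
    return {g: 1e6 * rates[g] / total for g in counts}


# -- random instances for oracle-equivalence testing -----------------------


def random_instance(rng, max_genes=30, max_reads=500, chrom_len=3000):
    """A random (records, annotation, assay) counting problem.

    Genes may overlap or nest; categories mix euchromatic, heterochromatic
    and rRNA; up to two repeat families with shared-offset multi-mappers;
    reads mix unique, family multi-mappers (with occasional NH >= 16) and
    scattered multi-mappers on both strands.
    """
    genes = []
    n_families = int(rng.integers(0, 3))
    fam_members = {}
    gid = 0
    for f in range(n_families):
        name = f"fam{f}"
        k = int(rng.integers(2, 6))
        length = int(rng.integers(60, 200))
        members = []
        for _ in range(k):
            start = int(rng.integers(0, chrom_len - length))
            genes.append(
                GeneModel(
                    f"g{gid}", "c1", start, start + length,
                    rng.choice(["+", "-"]),
                    rng.choice(["dg", "dh", "tlh_repeat"]),
                    copy_group=name, is_representative=not members,
                )
            )
            members.append(genes[-1])
            gid += 1
        fam_members[name] = members
    n_target = int(rng.integers(min(gid + 5, max_genes), max_genes + 1))
    while gid < n_target:
        length = int(rng.integers(40, 400))
        start = int(rng.integers(0, chrom_len - length))
        category = rng.choice(
            ["protein_coding"] * 5 + ["subtelomeric", "mat", "cenH", "rRNA"]
        )
        genes.append(
            GeneModel(f"g{gid}", "c1", start, start + length,
                      rng.choice(["+", "-"]), category)
        )
        gid += 1
    annotation = GenomeAnnotation(genes, {"c1": chrom_len})

    records = []
    n_reads = int(rng.integers(1, max_reads + 1))
    for i in range(n_reads):
        kind = rng.random()
        rlen = int(rng.integers(20, 61))
        strand = str(rng.choice(["+", "-"]))
        if kind < 0.6 or not fam_members:
            start = int(rng.integers(0, chrom_len - rlen))
            locs = [("c1", start, start + rlen, strand)]
        elif kind < 0.9:
            # family multi-mapper at a shared offset, sometimes padded with
            # decoy locations or duplicated to push NH to the cut-off
            fam = fam_members[rng.choice(sorted(fam_members))]
            flen = fam[0].length
            rlen = min(rlen, flen)
            offset = int(rng.integers(0, flen - rlen + 1))
            locs = [
                (m.chrom, m.start + offset, m.start + offset + rlen,
                 m.strand if rng.random() < 0.8 else strand)
                for m in fam
            ]
            while rng.random() < 0.15 and len(locs) < 18:
                start = int(rng.integers(0, chrom_len - rlen))
                locs.append(("c1", start, start + rlen, strand))
            while rng.random() < 0.1 and len(locs) < MULTIMAP_MAX_NH + 2:
                locs.append(locs[0])
        else:
            nh = int(rng.integers(2, 19))
            locs = []
            for _ in range(nh):
                start = int(rng.integers(0, chrom_len - rlen))
                locs.append(("c1", start, start + rlen, str(rng.choice(["+", "-"]))))
        records.append(AlignmentRecord(f"r{i}", locs))
    assay = str(rng.choice(["chip", "rip", "pa_rna"]))
    return records, annotation, assay
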