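"""End-to-end orchestration: samples -> counts -> theta -> decomposition.

The pipeline consumes a sample sheet (sample_id, path, assay, genotype,
replicate), an annotation and a config, and runs: counting -> TPM ->
replicate QC/averaging -> ChIP coverage with lambda-anchored input
subtraction -> per-gene metrics -> region decomposition.  Every output is a
TSV; a manifest records content hashes so reruns can be verified
byte-for-byte.

theta_ChIP is derived from the input-subtracted coverage path (per-gene mean
subtracted depth, family-summed at representatives, rescaled to 1e6), which
keeps it on the same TPM-like scale as the count-based theta_RIP and
theta_pA; each ChIP replicate is paired with the input replicate of the same
genotype and index.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.manifold import TSNE

from . import counting, coverage, metrics
from .counting import CountTable, ExpressionSummary
from .genome import GenomeAnnotation, load_annotation

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = {
    "centromeric_repeats": {"categories": ["dg", "dh"]},
    "tlh": {"categories": ["tlh_repeat"]},
    "subtelomeric": {"categories": ["subtelomeric"]},
    "mat": {"categories": ["cenH", "mat"]},
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run; round-trips through YAML."""

    sample_sheet: str
    annotation: str
    outdir: str
    categories: str | None = None
    reference_genotype: str = "clr4"
    baseline_genotype: str = "wt"
    multimap_max: int = 16
    spearman_threshold: float = 0.8
    tpm_floor: float = 1.0
    perplexity: float = 5.0
    te_feature_scale: float = 100.0
    seed: int = 0
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))

    def __post_init__(self) -> None:
        if self.multimap_max <= 0 or self.spearman_threshold <= 0:
            raise PipelineError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "path", "assay", "genotype", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise PipelineError(f"sample sheet missing columns {sorted(missing)}")
    base = Path(path).parent
    sheet["path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in sheet["path"]
    ]
    return sheet


@dataclass
class PipelineResult:
    summaries: dict[str, ExpressionSummary]
    per_gene: pd.DataFrame
    decomposition: metrics.SilencingDecomposition
    residuals: dict[str, pd.DataFrame]
    scaling: dict[str, list[coverage.ScalingFactor]]
    manifest: dict


def _chip_theta_replicates(
    sheet: pd.DataFrame,
    genotype: str,
    annotation: GenomeAnnotation,
) -> tuple[pd.DataFrame, list[coverage.ScalingFactor]]:
    """Input-subtracted TPM-like ChIP signal, one column per replicate."""
    sel = sheet[sheet["genotype"] == genotype]
    chip = sel[sel["assay"] == "chip"].set_index("replicate")
    inp = sel[sel["assay"] == "input"].set_index("replicate")
    shared = sorted(set(chip.index) & set(inp.index))
    if not shared:
        raise PipelineError(f"{genotype}: no paired chip/input replicates")
    cols = {}
    factors = []
    cores = annotation.core_regions()
    for rep in shared:
        ip_cov = coverage.build_coverage(
            counting.read_sam(chip.loc[rep, "path"]), annotation.chrom_lengths
        )
        in_cov = coverage.build_coverage(
            counting.read_sam(inp.loc[rep, "path"]), annotation.chrom_lengths
        )
        sf = coverage.compute_lambda(ip_cov, in_cov, cores)
        factors.append(sf)
        sub = coverage.subtract_input(ip_cov, in_cov, sf)
        signal = coverage.gene_signal_from_profile(sub, annotation)
        cols[f"{genotype}_chip_rep{rep}"] = coverage.tpm_like(signal)
    return pd.DataFrame(cols), factors


def build_summaries(
    sheet: pd.DataFrame,
    annotation: GenomeAnnotation,
    spearman_threshold: float = 0.8,
) -> tuple[dict[str, ExpressionSummary], dict[str, list[coverage.ScalingFactor]]]:
    """Count, normalize and QC every genotype in the sheet into summaries."""
    summaries = {}
    scaling = {}
    for genotype, sub in sheet.groupby("genotype", sort=True):
        qc_by_assay: dict[str, counting.ReplicateQC] = {}
        # ChIP via coverage subtraction
        chip_reps, factors = _chip_theta_replicates(sheet, genotype, annotation)
        scaling[genotype] = factors
        qc_by_assay["chip"] = _qc_from_tpm("chip", chip_reps, spearman_threshold)
        # RNA assays via counting
        for assay in ("rip", "pa_rna", "total_rna"):
            rows = sub[sub["assay"] == assay]
            if rows.empty:
                continue
            tables = [
                counting.count_sam(
                    r.path, annotation, assay,
                    sample_id=r.sample_id, genotype=genotype,
                    replicate=int(r.replicate),
                )
                for r in rows.itertuples()
            ]
            table = counting.tpm_normalize(CountTable.concat(tables), annotation)
            qc_by_assay[assay] = counting.replicate_qc(table, spearman_threshold)
        summaries[genotype] = counting.summarize_genotype(genotype, qc_by_assay)
    return summaries, scaling


def _qc_from_tpm(assay, tpm: pd.DataFrame, threshold) -> counting.ReplicateQC:
    """Run the Spearman replicate filter on an already-TPM matrix."""
    fake = CountTable(
        counts=tpm, tpm=tpm,
        meta=pd.DataFrame(
            {"assay": assay, "genotype": "", "replicate": range(1, tpm.shape[1] + 1)},
            index=pd.Index(tpm.columns, name="sample_id"),
        ),
        drop_stats=pd.DataFrame(index=tpm.columns),
    )
    return counting.replicate_qc(fake, threshold)


def per_gene_metrics(
    summaries: Mapping[str, ExpressionSummary],
    baseline: str,
    floor: float = metrics.TPM_FLOOR,
) -> pd.DataFrame:
    """Tidy per-(genotype, gene) table of TE, stability, output, delta Pol II."""
    frames = []
    for genotype, s in summaries.items():
        df = pd.DataFrame(
            {
                "theta_chip": s.theta["chip"],
                "theta_rip": s.theta["rip"],
                "theta_pa": s.theta["pa_rna"],
                "efficiency": metrics.transcription_efficiency(s, floor),
                "stability": metrics.rna_stability(s, floor),
                "rna_output": metrics.rna_output(s, floor),
            }
        )
        if genotype != baseline and baseline in summaries:
            df["delta_polII"] = metrics.delta_polII(s, summaries[baseline], floor)
        df.insert(0, "genotype", genotype)
        frames.append(df)
    out = pd.concat(frames)
    out.index.name = "gene_id"
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the report bundle.

    Writes per-genotype theta tables, the per-gene metrics table, the
    region decomposition, residual-contribution tables for every non-baseline
    genotype, lambda reports, and ``manifest.json`` with a sha256 per output.
    Deterministic: identical inputs give byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = load_annotation(config.annotation, config.categories)
    sheet = read_sample_sheet(config.sample_sheet)

    try:
        summaries, scaling = build_summaries(
            sheet, annotation, config.spearman_threshold
        )
    except Exception as exc:  # annotate with stage context
        raise PipelineError(f"stage=build_summaries: {exc}") from exc

    baseline = config.baseline_genotype
    reference = config.reference_genotype
    if baseline not in summaries or reference not in summaries:
        raise PipelineError(
            f"need both baseline {baseline!r} and reference {reference!r} "
            f"in the sheet; found {sorted(summaries)}"
        )

    per_gene = per_gene_metrics(summaries, baseline, config.tpm_floor)
    decomposition = metrics.pathway_decomposition(
        summaries[baseline], summaries[reference], config.regions, annotation
    )
    residuals = {
        genotype: metrics.residual_contributions(
            s, summaries[reference], config.regions, annotation,
            summary_wt=summaries[baseline],
        )
        for genotype, s in summaries.items()
        if genotype != baseline
    }

    outputs: list[Path] = []

    def write(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, sep="\t", float_format="%.10g")
        outputs.append(p)

    for genotype, s in sorted(summaries.items()):
        write(s.theta, f"theta_{genotype}.tsv")
    write(per_gene, "per_gene_metrics.tsv")
    write(decomposition.table, "decomposition.tsv")
    for genotype, res in sorted(residuals.items()):
        write(res, f"residuals_{genotype}.tsv")
    lam_rows = [
        {"genotype": genotype, "replicate": i + 1,
         **{f"lambda_{j + 1}": l for j, l in enumerate(sf.lambdas)},
         "lambda_final": sf.value}
        for genotype, sfs in sorted(scaling.items())
        for i, sf in enumerate(sfs)
    ]
    write(pd.DataFrame(lam_rows).set_index("genotype"), "lambda_report.tsv")

    manifest = {
        "seed": config.seed,
        "baseline": baseline,
        "reference": reference,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        summaries=summaries, per_gene=per_gene, decomposition=decomposition,
        residuals=residuals, scaling=scaling, manifest=manifest,
    )


def verify_manifest(outdir: str | Path) -> bool:
    """Re-hash every output listed in the manifest; True if all match."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return all(
        _sha256(outdir / name) == digest
        for name, digest in manifest["outputs"].items()
    )


# -- mutant feature matrix and 2-D embedding -------------------------------


def build_feature_matrix(
    summaries: Mapping[str, ExpressionSummary],
    annotation: GenomeAnnotation,
    te_scale: float = 100.0,
    floor: float = metrics.TPM_FLOOR,
) -> pd.DataFrame:
    """Mutant x feature matrix for embedding.

    Features concatenate log2(theta_ChIP + 1) and log2(TE * te_scale + 1)
    over all heterochromatic genes (representatives for repeat families),
    in one fixed gene order shared by all mutants.  TE is a ratio, not a
    TPM, so it is scaled to TPM-like magnitude before the log; NA values are
    floored to 0 signal.
    """
    if len(summaries) < 2:
        raise PipelineError("need at least 2 mutants for a feature matrix")
    het = sorted(annotation.heterochromatic_gene_ids())
    rows = {}
    for genotype, s in summaries.items():
        missing = {"chip", "rip"} - set(s.theta.columns)
        if missing:
            raise PipelineError(f"{genotype}: missing assay(s) {sorted(missing)}")
        chip = s.theta["chip"].reindex(het)
        te = metrics.transcription_efficiency(s, floor).reindex(het)
        feats = np.concatenate(
            [
                np.log2(chip.fillna(0.0).clip(lower=0.0) + 1.0),
                np.log2((te.fillna(0.0).clip(lower=0.0) * te_scale) + 1.0),
            ]
        )
        rows[genotype] = feats
    columns = [f"chip:{g}" for g in het] + [f"te:{g}" for g in het]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    out.index.name = "genotype"
    return out


def embed_2d(
    matrix: pd.DataFrame,
    perplexity: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """t-SNE of the mutant feature matrix to two dimensions (seeded).

    Delegates to scikit-learn; perplexity is capped below the number of rows
    (with a warning) since the neighborhood size cannot exceed the panel.
    """
    n = matrix.shape[0]
    if n < 3:
        raise PipelineError("need at least 3 rows to embed")
    eff_perplexity = perplexity
    if n <= perplexity:
        eff_perplexity = max(1.0, (n - 1) / 3.0)
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; using "
            f"{eff_perplexity}"
        )
    if n < 3 * perplexity:
        warnings.warn(f"fewer than 3 x perplexity rows (n={n})")
    tsne = TSNE(
        n_components=2, perplexity=eff_perplexity, random_state=seed,
        init="pca", max_iter=1000,
    )
    coords = tsne.fit_transform(matrix.to_numpy())
    return pd.DataFrame(coords, index=matrix.index, columns=["tsne1", "tsne2"])
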