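"""Full pipeline: decompose heterochromatic silencing into three pathways.

Runs counting, TPM, replicate QC, input subtraction and the wt-vs-clr4
decomposition on a simulated dataset.  clr4 cells lack H3K9 methylation
entirely, so fold changes clr4/wt measure how much each pathway —
Pol II occupancy, transcription efficiency, RNA stability — contributed to
silencing in wild type; shares are log2-fold-change fractions.
"""

import tempfile
from pathlib import Path

import hetsilence as hs
from hetsilence.genome import write_gff3
from hetsilence.pipeline import PipelineConfig, run_pipeline

root = Path(tempfile.mkdtemp(prefix="hetsil_pipe_"))
ann = hs.toy_annotation()
hs.simulate_dataset(ann, ["wt", "clr4"], root / "sim", seed=7, depth=1e5,
                    replicates=2)
write_gff3(ann, root / "sim" / "annotation.gff3")

cfg = PipelineConfig(
    sample_sheet=str(root / "sim" / "sample_sheet.tsv"),
    annotation=str(root / "sim" / "annotation.gff3"),
    outdir=str(root / "out"),
    seed=7,
)
res = run_pipeline(cfg)

print("pathway decomposition (clr4 relative to wild type):")
cols = ["fc_occupancy", "fc_efficiency", "fc_stability", "fc_output"]
print(res.decomposition.table[cols].round(2).to_string())
print("\ncontribution shares (% of total log2 RNA-output change):")
print(res.decomposition.shares_percent().round(1).to_string())
print(
    "\nAt the pericentromeric repeats the generative truth is "
    "36.1 / 26.0 / 37.9 % (occupancy / efficiency / stability); at tlh the "
    "truth is 26 / 66 / 8 % — efficiency dominates subtelomeric silencing."
)
print(f"\nall tables and a hash manifest are under {root / 'out'}")
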