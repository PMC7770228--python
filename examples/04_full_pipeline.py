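"""Run the whole pipeline from a config and print its reproducibility report.

Writes the synthetic inputs to disk, runs every stage (both networks,
modules, summaries, overlap, per-timepoint counts), and renders the report
from the run directory's artifacts alone — after verifying their checksums.
"""
import tempfile
from pathlib import Path

import varnet

workdir = Path(tempfile.mkdtemp(prefix="varnet_example_"))
tensor, truth = varnet.generate(varnet.default_spec(seed=1))
varnet.write_expression(tensor, workdir / "expr.tsv", workdir / "meta.tsv")
varnet.write_gene_list(sorted(truth.hvg), workdir / "hvg.txt")

config = varnet.RunConfig(
    expression=str(workdir / "expr.tsv"),
    metadata=str(workdir / "meta.tsv"),
    hvg=str(workdir / "hvg.txt"),
    fdr=0.10, k=4, gaps=1, alpha=0.05,
    seed=0, restarts=10, min_module_size=5,
)
out = varnet.run_pipeline(config, workdir / "run")
print(varnet.report(out))
print(f"\nartifacts in {out}")
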