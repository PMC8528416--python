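"""Differential enhancer landscape between control and treated conditions.

Super-enhancers are identified separately per condition, collapsed into one
union set of regions, and each region's depth-normalized H3K27ac coverage is
compared between conditions: regions losing acetylation are decommissioned
enhancers, gaining regions are de novo enhancers of the new cell state.
"""

from collections import Counter

from secircuit.pipeline import run_synthetic_study

dataset, result = run_synthetic_study(seed=1)

counts = Counter(r.status for r in result.differential)
print(f"{len(result.differential)} collapsed-union regions: {dict(counts)}")
print("\nstatus   log2FC   region                        assigned gene")
for r in sorted(result.differential, key=lambda r: r.log2_fold_change):
    if r.status != "stable":
        span = f"{r.region.chrom}:{r.region.start}-{r.region.end}"
        print(f"{r.status:<8} {r.log2_fold_change:+6.2f}   {span:<28}  {r.assigned_gene}")
print(
    "\nNegative log2FC = enhancer lost on treatment, positive = gained; the "
    "assigned gene is the nearest TSS expressed in any sample. Planted truth: "
    f"{sorted(dataset.manifest['gene_classes']['lost'])} hosts lose their "
    "super-enhancer, the 'gained' class acquires one."
)
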