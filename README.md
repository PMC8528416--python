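# secircuit

Super-enhancer landscapes and core regulatory circuitry from binned coverage
tracks.

`secircuit` is a Python library (plus a thin CLI) for the regulatory-genomics
workflow used to study how a cell's identity-defining transcription-factor
circuit is rewired — for example, when a differentiation agent decommissions
the super-enhancers of one circuit and builds another in its place. It is
aimed at computational biologists who have ChIP-seq / CUT&RUN coverage
(H3K27ac, TF occupancy, IgG control) and spike-in normalized RNA-seq counts,
and want a tested, scriptable implementation of the full analysis chain:

1. **Coverage tracks** — reads extended to 200 bp, binned at 50 bp, and
   normalized to reads per million mapped (RPM).
2. **Peak calling and filtering** — a simple Poisson upper-tail caller at two
   stringencies whose union is collapsed (external MACS peak files are
   accepted interchangeably), with removal of peaks contacting configured
   exclusion regions such as an amplified locus.
3. **Super-enhancer identification** (ROSE-style) — peaks fully inside
   TSS ± *t* (default 1000 bp) are removed, the rest are stitched when gaps
   are ≤ *s* (default 12 500 bp), regions are ranked by integrated RPM
   signal, and the hockey-stick cutoff is placed where the rescaled
   rank-vs-signal curve has slope 1 (equivalently, at max *x* − *y* below the
   diagonal for a convex curve). Regions above the cutoff are super-enhancers.
4. **Gene assignment** — a gene is *expressed* when its promoter
   (TSS ± 500 bp) H3K27ac coverage is in the top two-thirds of all genes;
   each enhancer is assigned to the expressed gene whose TSS is nearest the
   enhancer center.
5. **Differential landscape** — super-enhancers identified separately per
   sample are collapsed into one union set; per-region RPM coverage is
   compared between conditions as log₂((B + c)/(A + c)) and classified
   gained / lost / stable against a fold threshold.
6. **Occupancy and circuit inference** — a region × target signal matrix
   (rows enriched over IgG for ≥ 1 target, ranked by integrated H3K27ac) and
   a directed TF → TF-gene binding graph; the core regulatory circuit (CRC)
   is the largest set of expressed, super-enhancer-driven TFs that bind their
   own and each other's super-enhancers (a complete directed subgraph with
   self-loops, computed exactly).
7. **Spike-in expression analysis** — per-sample size factors as the median
   of spike-in count ratios against a geometric-mean pseudo-reference
   (rescaled so the median sample factor is 1), TPM with spike-ins excluded
   from the denominator, a strict base-mean TPM > 10 filter, and
   spike-in-scaled log₂ fold changes. Spike-in factors preserve global
   expression shifts that library-size or TPM normalization cancels.

Everything runs end-to-end on the built-in synthetic-data module
(`secircuit.simulate`), which plants typical enhancers, condition-specific
super-enhancer gain/loss, TF occupancy coupled to a known circuit graph,
Poisson bin noise, and spike-in counts encoding a known global shift — with a
ground-truth manifest that scores every stage.

## Worked example

```
python examples/03_circuit_inference.py
```

```
control: admissible ['G000', 'G001', 'G010', 'G011'] -> members ['G000', 'G001', 'G010', 'G011']
  occupancy matrix: 301 enriched regions x 8 targets (rows ranked by H3K27ac)
treated: admissible ['G005', 'G006', 'G010', 'G011'] -> members ['G005', 'G006', 'G010', 'G011']
  occupancy matrix: 298 enriched regions x 8 targets (rows ranked by H3K27ac)

circuit delta: {'shared': ['G010', 'G011'], 'lost': ['G000', 'G001'], 'gained': ['G005', 'G006']}
planted truth: {'shared': ['G010', 'G011'], 'lost': ['G000', 'G001'], 'gained': ['G005', 'G006']}
```

The pipeline identified each condition's circuit from coverage alone: in the
control state TFs G000/G001/G010/G011 are expressed, drive super-enhancers,
and mutually bind them; after treatment G000/G001 are decommissioned,
G005/G006 join, and G010/G011 persist — exactly the planted rewiring. The
other examples print the ranked super-enhancer table
(`01_super_enhancers.py`: 21 super-enhancers among 304 stitched regions), the
differential landscape (`02_differential_landscape.py`: 10 lost and 10 gained
regions at |log₂FC| ≈ 5, each assigned to its host gene), and the spike-in
head-to-head (`04_spikein_expression.py`: a planted 2× global depression
reads −0.994 under spike-in factors and −0.004 under library-size factors).

The same stages are available as shell subcommands:

```
secircuit simulate --seed 1 --outdir study/
secircuit run-all  --seed 1 --outdir results/
secircuit superenhancers --track study/control_H3K27ac.wig \
    --genome study/genome.chrom.sizes --annotation study/annotation.tsv \
    --outdir se/
```

`run-all` chains every stage on a fresh synthetic study and writes result
tables, a circuit report and a manifest-comparison score; identical
seed/config yields byte-identical outputs.

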