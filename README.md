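# lysoscreen

High-content screening pipeline for **lysosomal clustering around the
microtubule-organizing center (MTOC)**, written for cell biologists running
plate-based searches for autophagy modulators.

Lysosomal positioning controls autophagic flux: lysosomes gathered at the
MTOC meet autophagosomes sooner and fuse more readily, so compounds that pull
lysosomes inward are candidate autophagy inducers — of interest for clearing
aggregation-prone proteins such as α-synuclein.  The package implements the
whole quantitative chain of such a screen: per-cell image scoring, per-well
normalisation, multi-stage hit calling, flow-cytometry flux readouts, and a
ground-truth synthetic-data generator used to validate every step.

## The statistic

For each cell, with lysosomal-marker intensity $I(x)$, cell region $C$, and a
circle $B$ of diameter 7 µm centred on the MTOC (localised from the
γ-tubulin channel):

$$r \;=\; \frac{\sum_{x \in B \cap C} I(x)}{\sum_{x \in C} I(x)} \in [0,1]$$

Per-well summaries of $r$ are divided by the pooled control-well summary to
give the **lysosomal clustering value**; a compound is a hit when its value
exceeds a **1.1-fold** change (strict inequality).  Secondary screening uses
the RFP/GFP ratio of a tandem-fluorescent LC3 reporter measured by flow
cytometry (GFP quenches in acidic autolysosomes, so a higher ratio means
more flux), with DAPI dead-cell exclusion and an RFP-positive gate.
Auto-fluorescent compounds are removed by annotation, and a final
microscopy confirmation stage is recorded from annotations, never computed.

Further positioning/flux metrics: the peripheral-lysosome cell percentage
(central region = ~70 % of the cell area toward the centre, delineated by
iterative erosion), lysosome intensity within aggregate masks
(colocalization), the pixels-above-threshold ROS readout, the HaloTag-LC3
processing ratio $100\,x/(x+y)$, and generic densitometry band ratios.

## Worked example

```bash
lysoscreen demo --seed 7
```

generates a miniature screen (60 compounds, 5 planted hits) plus one
clustered (κ = 0.8) and one dispersed (κ = 0.2) image well, scores them end
to end, and prints a report containing:

```
"imaging": {
    "control_well_value": 1.0,
    "treated_well_value": 2.6747772437975614,
    "treated_gt_control": true
},
...
"recovered_primary_exactly": true
```

The control well scores exactly 1 by construction (it is normalised against
itself); the clustered well's value of 2.67 is far above the 1.1-fold hit
threshold, and the cascade ledger recovers exactly the planted hits.

The numbered drivers under `analysis/` run the same campaign at full scale
(`01` simulates all inputs into `scratch/`, `02`–`05` score, call hits,
compute flux readouts and validate parameter recovery, writing tables under
`results/`).  `03_hit_calling_cascade.py` prints the screening funnel

```
screening funnel: 1200 -> 63 -> 15 -> 10 -> 6
primary hits: 63 called, 63 of 63 planted recovered, 0 false positives
```

i.e. 1200 compounds screened, 63 primary hits over 1.1-fold, 15 passing the
flux screen, 10 after removing the 5 auto-fluorescent compounds, and 6
confirmed candidates.

A CLI wraps the library for shell use: `lysoscreen simulate | score |
screen | flow | demo` (exit code 0 on success, 2 for validation errors,
3 for data errors).

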