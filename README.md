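# longtemplate

A desk-scale model of Illumina-style template-based cluster calling: why
sequencing libraries with **low initial sequence diversity** (reads sharing a
fixed 5′ barcode) produce catastrophically bad data, how extending the
cluster **template** past the non-diverse prefix (the Long Template Protocol)
fixes it, and why merged clusters — not index sequencing errors — drive
**sample bleeding** between multiplexed samples.

The package is for people who want to study or teach these mechanisms
without a sequencer: it simulates four-channel 16-bit flowcell tile images
with a Gaussian PSF, rebuilds cluster templates from the first *K* cycles
exactly the way the instrument software does (spots per cycle → golden and
silver cycles → registered union), calls bases with a chastity filter,
filters and demultiplexes reads, and measures sample bleeding against a
binomial null model.

## The model in brief

**Template generation.** Cluster positions are estimated once, from the
images of the first *K* cycles (`TemplateCycleCount`, historically 4). Spots
are detected in each cycle separately; the cycle with the most spots is the
*golden* cycle, the runner-up the *silver*; the template is the union of
their registered spot lists and is never corrected afterwards. If all *K*
cycles fall inside a shared 5′ prefix, every cluster occupies the same
channel, neighbours within ~2 PSF sigmas merge, and the damaged template
corrupts the entire read: merged ("mixed") clusters show two strong channels
in later diverse cycles and are discarded by the chastity filter
(chastity = I₁/(I₁+I₂) over the two brightest channels; a read fails if
more than one of its first 25 cycles drops below 0.6). Choosing
*K* ≥ barcode length + 2 lets golden and silver land on fully diverse
cycles.

**Memory model.** Holding *K* cycles of images in RAM costs
`channels × width × height × bytes/pixel` per cycle — about 2.6 GB for four
16-bit 2048×160000 images, i.e. ≈ 4 GB per template cycle at instrument
scale, which caps the feasible template length at `⌊RAM / 4 GB⌋`.

**Sample bleeding.** Under the classical explanation (sequencing errors
morphing one valid index into another) the rate is the binomial upper tail
P(X ≥ d), X ~ Binomial(n, p) for an n-nt index at per-base error p and
index distance d — e.g. 9.3×10⁻⁹ for n = 6, d = 4, p = 0.5 %. Observed
bleeding exceeds this by orders of magnitude because a merged cluster pair
can have its insert read follow one sample and its separately-primed index
read the other. Longer templates resolve more clusters and cut bleeding.

## Worked example

Simulate a 100 % low-diversity library (5 nt shared prefix `TCGAG`) at
normal cluster density and compare a standard 4-cycle template with a
7-cycle (barcode + 2) template:

```python
from longtemplate import SimConfig, TemplateConfig
from longtemplate.report import run_cell

for k in (4, 7):
    rep = run_cell(
        SimConfig(n_cycles=25, seed=7, lowdiv_fraction=1.0,
                  prefix_sequences=("TCGAG",)),
        TemplateConfig(template_cycle_count=k),
        sample=f"K{k}",
    )
    print(f"{rep.sample}: protocol={rep.protocol} "
          f"recovery={rep.template_recovery:.3f} reads={rep.n_reads} "
          f"pctQ30={rep.pct_q30:.1f} barcoded={rep.pct_barcoded_norm:.1f}%")
```

prints

```
K4: protocol=standard recovery=0.757 reads=3565 pctQ30=95.8 barcoded=100.0%
K7: protocol=long_template recovery=0.961 reads=4436 pctQ30=93.4 barcoded=100.0%
```

The 4-cycle template, built entirely inside the shared prefix, finds a
one-to-one match for only 76 % of the true clusters — the rest are merged
into mixed positions — while extending the template two cycles past the
prefix recovers 96 % and yields ~25 % more chastity-passing reads from the
same tile.

The same stages are available from the shell:

```
longtemplate simulate --out run/ --lowdiv-fraction 1.0 --prefix TCGAG --seed 7
longtemplate template --run-dir run/ --template-cycle-count 7
longtemplate call --run-dir run/ --out reads.fastq
longtemplate qc --fastq reads.fastq --out qc.tsv
longtemplate bleed --seed 1 --n-seeds 3 --out bleed.tsv
longtemplate memory --template-cycle-count 20 --ram-gb 48
```

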