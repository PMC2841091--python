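# resarray

Analysis toolkit for **resequencing microarrays** — tiling arrays that read
out targeted genomic regions (e.g. a panel of deafness genes) by
hybridizing labelled patient DNA to probe quartets.  Every interrogated
base is covered by 8 features: four 25-mer probes differing only at the
central base (A/C/G/T) on the forward strand, and their reverse
complements on the reverse strand.  A base call is made by comparing the
four feature intensities of each strand.

The package is aimed at people building or evaluating array-based
clinical resequencing pipelines.  It provides:

* **`resarray.design`** — the tiled array model: probe tiling from a
  FASTA reference and BED regions, probe composition analytics
  (G/C content, runs of ≥ 4 Gs — "G-stacks" — which degrade
  hybridization).
* **`resarray.simulate`** — a seeded hybridization simulator with the
  empirically observed failure modes: affinity decaying faster in probe
  G-content than C-content, a multiplicative G-stack penalty,
  cross-hybridization, 50%-dosage heterozygotes, and regional signal
  loss around indels.  It produces per-feature intensities plus ground
  truth, so the entire calling stack is testable without array data.
* **`resarray.caller`** — a conservative quartet base caller
  (hom / het / no-call with log2-ratio qualities).
* **`resarray.sprofiler`** — **sPROFILER**, the core algorithm: rescue
  of primary-caller no-calls from single-strand evidence.
* **`resarray.filters`**, **`resarray.indels`**, **`resarray.report`** —
  false-positive screens, indel-region scanning, and performance /
  follow-up-triage reporting.

## The rescue algorithm

Primary array callers demand concordant evidence from both strands, so a
position whose probe on one strand is G-rich or carries a G-stack often
becomes a no-call even when the other strand is unambiguous — and every
no-call must be resolved by follow-up dideoxy sequencing.  sPROFILER
re-examines no-calls using the clean strand alone:

1. For each strand *s*, learn a threshold *t_s* from the array itself:
   the empirical *q*-quantile (default *q* = 0.05) of peak/second
   intensity ratios at bases called wild-type whose strand peak equals
   the reference.
2. Scale the threshold per position by the batch-wide wild-type
   proportion *w(p)* (Laplace-smoothed fraction of arrays calling *p*
   wild-type):

   *t*_eff(*p*, *s*) = *t_s* · (1 + α·(1 − *w(p)*)),  α = 1 by default,

   so positions frequently called variant across arrays require stronger
   evidence before being assigned wild-type.
3. Convert a no-call to wild-type iff at least one strand ranks the
   reference base first with peak/second ≥ *t*_eff.  Wild-type calls
   sitting inside no-call stretches (a classic indel signature) are
   first re-tested under a stricter both-strands rule and demoted when
   they fail.  No other existing call is ever modified.

An optional `with_variant_assign` mode also converts no-calls with a
single dominant alternate base to homozygous variant calls, always
flagged `requires_confirmation`.

## Worked example

Simulate the default study batch (24 arrays × 26,292 interrogated bases
over 180 exon fragments), call it, rescue no-calls, filter and score:

```python
from resarray import PipelineConfig, analyze_batch
from resarray.pipeline import simulate_default_batch, render_report_text

cfg = PipelineConfig(n_arrays=24).with_seed(1)
design, truths, samples = simulate_default_batch(cfg)
result = analyze_batch(
    design, samples, call_params=cfg.caller,
    q=cfg.sprofiler.q, alpha=cfg.sprofiler.alpha,
    mode=cfg.sprofiler.mode, min_run=cfg.sprofiler.min_run,
    filter_params=cfg.filters, truths=truths,
)
print(render_report_text(result))
```

prints

```
Number of arrays	24
Bases per array	26292
Array call rate	99.7%
Call accuracy	100.00%
Total false positive rate	0.00% (0.0)
Variant false positive rate	0.0%
Variant false negative rate	0.0%
No-calls (primary -> final)	686.2 -> 89.8
Exons to sequence / total	49.1/180
No-calls resolved by sPROFILER	87%
```

Reading: the primary caller leaves ~686 no-calls per array (2.6% of
bases, essentially all at G-stack positions); sPROFILER resolves 87% of
them from single-strand evidence, lifting the call rate to 99.7% without
introducing false negatives, and cutting the number of exons that would
need confirmatory dideoxy sequencing from ~78 to ~49 per array.

The same run is available from the shell:

```bash
resarray run --seed 1 --out results/run1      # full pipeline, all TSV outputs
resarray simulate --seed 1 --out sim/         # intensities + truth only
resarray resolve --calls calls.tsv --intensities sim/intensities.tsv \
    --fasta sim/reference.fasta --bed sim/regions.bed --q 0.05 --alpha 1.0 \
    --mode wildtype_only --out resolved.tsv
```

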