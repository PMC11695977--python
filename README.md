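# triadmap

Analysis toolkit for studies asking **how trans-acting long non-coding
RNAs guide a chromatin remodeler to cell-type-specific enhancers**.  It
implements the full computational chain such a study needs, as an
importable library with a thin CLI:

* **Chimeric read parsing** — locate a 37-nt bridge adapter inside
  RNA-DNA proximity-ligation reads (<= 4 mismatches, both orientations),
  split DNA and 5'-RNA parts (cutadapt-style `-m 14 -O 37 -e 0.11`
  semantics), validate `^GGG`/`CCC$` 3'-RNA mates, and map parts to
  unique loci.
* **Contact mapping** — RNA-gene x 5-kb-bin contact tables, normalised
  to contacts per million; contacts are *trans* when the bin lies > 5 Mb
  from the gene or on another chromosome; enrichment at protein-binding
  peaks is tested with a paired Wilcoxon signed-rank test against
  shuffled-peak controls.
* **iCLIP analysis** — reproducible 7-nt binding sites (drop the lowest
  2% of crosslink scores, >= 3 covered positions, >= 4/5 replicates),
  coverage enrichment `log2(iCLIP RPKM / RNA-seq RPKM)`, per-biotype
  Fisher exact enrichment over the CPM > 5 expressed universe, and
  candidate lncRNA ranking by the mean of four z-scored metrics.
* **Peak annotation** — promoter/intronic/intergenic context, chromatin
  states from tiling segmentations, trans/cis/mixed/none RNA classes,
  and cross-cell-type enhancer specificity.
* **Differential binding** — FRiP-normalised, empirical-Bayes moderated
  t-test with BH control (FDR < 0.05) for replicate count matrices, and
  the log10 Poisson likelihood-ratio statistic with the 3.84 cutoff for
  pileup comparisons.
* **Enhancer-hub integration** — adapted activity-by-contact scores
  `abc(e,g) = A_e C_eg / sum_e' A C` thresholded at > 0.02, DEG filters
  (|log2FC| >= 0.59, padj <= 0.05, mean >= 5), upset overlaps of lost
  enhancers, degrader-versus-knockdown attribution and DEG hub degrees.

A first-class **synthetic data generator** plants guide lncRNAs with
distal target enhancers, binding sites, knockdown-lost peaks, loops and
DEGs, and records the ground truth, so the entire chain is testable —
every recovery number below is measured against planted truth.

## Worked example

```python
from triadmap.synthetic import SyntheticConfig
from triadmap.pipeline import run_all

result = run_all(SyntheticConfig(seed=42))
print(result.summary)
```

prints (about a minute):

```
{'bridge_detection_rate': 0.99928,   # matches binomial(37, 0.02) CDF at 4 mismatches
 'contact_recall': 1.0,              # planted guide->enhancer-bin pairs recovered
 'contact_precision': 1.0,           # no background pair above the frequency floor
 'site_recall': 1.0,                 # planted 7-nt binding sites re-called
 'site_precision': 1.0,
 'guides_in_top_n': 5,               # the 5 planted guides take composite ranks 1-5
 'mean_target_recall': 1.0,          # knockdown-lost peaks found at target enhancers
 'protac_recall': 1.0,
 'attributed_fraction': 0.804,       # degrader losses explained by lncRNA knockdowns
 'mean_deg_recovery': 1.0,           # planted DEGs reached via ABC links
 'trans_peak_enhancer_fraction': 1.0}
```

Each number is a recovery rate against the generator's ground-truth
manifest: for example `mean_target_recall = 1.0` says every planted
guide-target enhancer peak was re-identified as significantly lost in
that guide's knockdown, and `attributed_fraction ~ 0.8` reproduces the
planted design in which 200 of 250 degrader-sensitive enhancers are
lncRNA targets.

The `examples/` directory holds one narrative script per capability
(simulation + extraction, contact mapping, binding sites + candidate
ranking, differential + network, full recovery).  Each builds a small
input, runs the method and prints what the numbers mean.

A thin CLI mirrors the stages:

```bash
triadmap simulate --seed 1 --outdir sim/
triadmap extract --fastq1 sim/reads_1.fastq --fastq2 sim/reads_2.fastq \
                 --genome sim/genome.fa --out parts.tsv
triadmap contacts --parts parts.tsv --annotation sim/genes.tsv \
                  --genome sim/genome.fa --out contacts.tsv
triadmap run-all --seed 1
```

## Layout

```
src/triadmap/
  synthetic.py   planted multi-omic generator + ground-truth manifest
  chimera.py     bridge search, read splitting, exact unique alignment
  contacts.py    contact tables, cis/trans, peak enrichment, shuffling
  iclip.py       coverage, binding sites, Fisher enrichment, ranking
  annotate.py    context, chromatin states, RNA classes, specificity
  diffbind.py    moderated differential test, Poisson log-LR, BH
  network.py     ABC links, DEG filters, upset/attribution/hub degrees
  pipeline.py    end-to-end orchestration with recovery metrics
  io.py, cli.py  plain-text I/O and the click CLI
docs/methods.md  model, parameter and design documentation
examples/        one narrative script per capability
tests/           unit, property and end-to-end recovery suites
```
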