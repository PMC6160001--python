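# cobind-clock

Cistrome proximity analysis for transcription-factor co-binding, built
around the question of how the circadian repressor REVERBa times the
liver's response to glucocorticoids. Given two ChIP-Seq peak sets — a
query cistrome such as the glucocorticoid receptor (GR) and a reference
cistrome such as REVERBa — the package quantifies co-binding from
summit-to-summit distances, extracts co-bound regions, maps them to genes,
stratifies time-of-day-specific target gene sets, profiles
histone-acetylation coverage around transcription start sites, ranks
known-motif enrichment in co-bound regions, and normalizes ChIP-ddPCR
measurements to a chromatin spike-in. A synthetic-data generator with
recorded ground truth makes the whole pipeline testable end to end.

It is intended for regulatory-genomics analysts who already have called
peaks (BED/narrowPeak), differential-expression gene lists and binned
coverage, and want the downstream co-binding analysis to be reproducible
and unit-tested.

## The co-binding statistic

For each query peak *i* with summit *s<sub>i</sub>*, let

&nbsp;&nbsp;&nbsp;&nbsp;*d<sub>i</sub>* = min<sub>j on same chromosome</sub> |*s<sub>i</sub>* − *t<sub>j</sub>*|

be the distance to the nearest reference summit *t<sub>j</sub>*. With a
proximity threshold *τ* (default 120 bp), the co-binding ratio is

&nbsp;&nbsp;&nbsp;&nbsp;*R* = #{*d<sub>i</sub>* < *τ*} / #{*d<sub>i</sub>* ≥ *τ*},

the count of proximal ("co-binding") events over non-proximal ones.
Because *R* compares relative abundances within the query cistrome, it is
insensitive to the total peak count of either cistrome. High-stringency
analyses first filter the query cistrome by peak-caller fold enrichment
(FE ≥ 30 by convention, with 10/20/30 as the default stringency tiers),
and reference cistromes pooled across circadian timepoints can be used to
sidestep phase differences between clock factors. Under a uniform
reference of density ρ the chance-proximity rate is 1 − e<sup>−2τρ</sup>,
which the package uses to correct observed proximal fractions when
estimating a planted co-bound fraction.

## Worked example

```python
from cobindclock import (SimConfig, simulate_cistromes, filter_by_fe,
                         nearest_summit_distances, cobinding_ratio,
                         extract_cobound_pairs)

config = SimConfig(seed=7, cobound_fraction=0.3)   # 10 Mb toy genome
ref, query, truth = simulate_cistromes(config)
query_fe30 = filter_by_fe(query, 30)               # high-stringency tier
dset = nearest_summit_distances(query_fe30, ref)
summary = cobinding_ratio(dset)
pairs = extract_cobound_pairs(query_fe30, ref)
```

which prints, with the fields formatted as below:

```
query peaks (FE >= 30): 479 of 2000
proximal (<120 bp):     395
non-proximal:           84
co-binding ratio:       4.70
median proximal dist:   27 bp
co-bound pairs:         395
```

The generator plants 30% of the 2000 query summits near reference summits
with Laplace-distributed offsets (scale 40 bp) and gives those peaks
higher fold-enrichment scores. Filtering at FE ≥ 30 therefore enriches
for planted co-bound peaks: 395 of the 479 surviving peaks fall within
120 bp of a reference summit, a co-binding ratio of 4.70, and the median
proximal distance of 27 bp matches the planted offset scale
(median of |Laplace(b)| = b ln 2 ≈ 27.7 bp at b = 40). The number of
extracted co-bound pairs always equals the proximal count.

The same analyses are available from the shell: `cobind-clock simulate`,
`cobind-clock cobind`, `cobind-clock stratify`, `cobind-clock metagene`,
`cobind-clock motifs`, `cobind-clock ddpcr-norm`, and
`cobind-clock peaks validate`. See `cobind-clock --help`.

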