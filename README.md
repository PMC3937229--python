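# cis-select

Statistics for retroviral insertional-mutagenesis screens: detection of
common insertion sites (CISs) by multi-scale Gaussian kernel convolution
with Monte-Carlo random-integration nulls, orientation-bias and
clonal-selection tests, saturation analysis, and cohort/genotype
comparisons — together with a synthetic integration-cohort generator
with planted ground truth for calibrating all of the above.

## Who this is for

Screens that accelerate tumour formation with a gamma-retrovirus (e.g.
MoMLV) read out selection as recurrent integration clusters. Separating
*oncogenic selection* from the virus's own *integration preference*
(which itself clusters near transcription start sites) is a statistical
problem: a locus is a CIS only if insertions recur there beyond what
random integration would produce, and a CIS shows *enhancer-mode*
activation only if its insertions share an orientation beyond chance.
This package implements that chain of inference for cohorts of mapped
insertion sites (BED6), starting after read alignment.

## The model

Unique insertion positions x_i on a chromosome are smoothed with an
unnormalised Gaussian kernel at scale σ:

    f_σ(x) = Σ_i exp(−(x − x_i)² / (2σ²))

over a ladder of scales (default 2 kb … 500 kb). For each scale the
genome-wide significance threshold is the (1 − α) quantile of the
maximum of f_σ over cohorts of the same size placed uniformly on the
genome (Monte-Carlo max-statistic, α = 0.05 per scale) — so a uniformly
integrating cohort of 12,485 sites yields essentially no CISs.
Above-threshold regions become candidates; candidates overlapping
across scales are consolidated at the *matched* scale (maximum height
relative to that scale's threshold), which keeps reported CIS widths at
the resolution of the cluster that produced them.

Selection statistics follow the screen literature: per CIS a one-tailed
Fisher exact test of its members' strand counts against all remaining
sites (majority orientation as the tested tail, ties → p = 1),
Benjamini–Hochberg correction, and q < 0.05 defining the "biased CIS"
set; signed distances to the nearest TSS; a fixed-window cluster rule
(≥ 3 sites within 12,587 nt) for near-baseline vector datasets;
clonal-expansion flagging at ≥ 100 reads; Fisher/Mann-Whitney genotype
comparisons; 30-kb-bin contingency enrichment against region sets; and
sample-combination saturation curves from ±7.5 kb pseudo-kernels.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic screen (28 tumours, ~12,485 sites, 50 planted
drivers):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_call_cis.py
python analysis/03_selection_stats.py
python analysis/04_saturation.py
python analysis/05_genotype_comparison.py
```

which prints, among other things:

```
cohort: 12497 unique insertion sites from 28 tumours (seed 1)
  roles: {'background': 10248, 'passenger': 1125, 'driver': 1124}
  expanded clones (>=100 reads): 2249 RISs, median 79 per tumour
...
called 50 CISs (median width 9.7 kb; a uniform cohort of this size yields 0-3)
...
orientation bias: 31/50 CISs biased at BH q < 0.05
  chr5:53893019-53931579  21/21 same strand  q=2.49e-05
...
marginal coverage gain at n=20: real 10 kb vs control 515 kb (ratio 0.020)
```

Reading these: all 50 planted drivers are recovered as CISs while a
uniform cohort of the same size would give at most a handful; the 30
enhancer-mode drivers (planted with 0.9 orientation preference) drive
the biased set; and once the drivers are exhausted the coverage curve
flattens to ~2% of the random control's growth — the saturation
signature that says the screen has found what there is to find.

Library use mirrors the scripts:

```python
from cis_select import (GkcConfig, call_cis, merge_sites, mm9_like_genome,
                        default_screen_config, simulate_cohort)
cohort, truth = simulate_cohort(default_screen_config(seed=1))
cis = call_cis(merge_sites(cohort), mm9_like_genome(), GkcConfig(seed=0))
```

A `cis-select` command-line tool wraps the same operations
(`simulate`, `merge`, `call-cis`, `orient`, `saturate`, `run`).

## Layout

- `src/cis_select/` — the library (I/O, RIS merging, GKC caller,
  selection statistics, saturation, synthetic cohorts, pipeline + CLI)
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — pytest suite with brute-force oracles
- `docs/methods.md` — model, parameter and design documentation
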