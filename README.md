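# dsbquant

Quantification pipelines for the standard assays used to study DNA
double-strand-break (DSB) repair kinetics in budding yeast and mammalian
cells: the qPCR resection-rate assay, locus-directed γ-H2AX ChIP, western and
Southern blot densitometry, and per-nucleus repair-focus counting. It is
aimed at researchers who have the raw numbers from these assays (qPCR
quantities or Cq values, IP/input quantities, gel band intensities, focus
counts) and want reproducible, scriptable quantification instead of
spreadsheet arithmetic.

Every analysis stage is paired with a seeded stochastic generator that emits
the same table schema the stage reads, with closed-form expectations, so the
whole pipeline is testable end to end without any external dataset.

## What it computes

**Resection rate.** After induction of a single site-specific DSB (e.g. by
HO endonuclease), 5′→3′ resection destroys qPCR signal at amplicons placed
at increasing distances *d* from the break. The signal is double-normalized,

s(t, d) = [q(t, d) / q(t, ctrl)] / [q(0, d) / q(0, ctrl)]  (= 2^−ΔΔCq),

and for each timepoint the distance d\*(t) where the signal-vs-distance
curve crosses a threshold θ = 0.75 is found by linear interpolation between
the nearest amplicons. Ordinary least squares of d\* on t gives the
population front velocity in kb/h (slope) and an onset lag (x-intercept).

**ChIP enrichment.** Fold-enrichment E(x, t) = [(IP/input)at locus /
(IP/input)at control locus], referenced to t = 0; plus spreading extent
(max |x| with E ≥ 2) and persistence ratios (fold over t = 0 at late times).

**Densitometry.** Lane levels (band / loading control, referenced to t = 0
or any lane), fold-changes between conditions, log-linear exponential decay
fits yielding protein half-lives (cycloheximide/caffeine chases), and
single-strand-annealing repair fractions from Southern product bands.

**Foci.** Per-condition summaries of per-nucleus focus counts, fold
decreases of pooled means, and a self-implemented Wilcoxon rank-sum test:
exact enumeration of all rank assignments for pooled n ≤ 16, tie-corrected
normal approximation with continuity correction otherwise.

The stochastic generators model a population of arrested cells in which each
cell is cut at an exponentially distributed time (95% ever cut, rate 3/h by
default), then resects at a per-cell speed drawn from a Gamma distribution;
measurement noise is multiplicative lognormal. Named presets
(`wt_untreated`, `caffeine_50mM`, `irreparable_caffeine_2h`,
`sae2_caffeine`, `rpa_ir`, …) freeze the generative parameters for each
study condition; see `dsbquant.preset_names()`.

## Worked example

```sh
$ python -c "from dsbquant import default_panel; \
    default_panel().to_frame().to_csv('panel.csv', index=False)"
$ dsbquant simulate --preset wt_untreated --seed 1 --out table.csv
wrote 90 rows to table.csv
$ dsbquant resect-rate --table table.csv --panel panel.csv
{
  "rate_kb_h": 3.960769975682991,
  "intercept_h": -0.21980490591146276,
  "r_squared": 0.9888970849978956,
  "n_points": 7,
  ...
  "dropped_timepoints": [
    "t=0 h: signal >= threshold everywhere",
    "t=8 h: signal < threshold everywhere"
  ]
}
```

The simulated wild-type culture (true front speed 4.2 kb/h, 10⁴ cells,
amplicons 0.7–30 kb, hourly samples 0–8 h) yields a fitted front velocity of
3.96 kb/h from 7 usable timepoints with r² = 0.99: t = 0 carries no
crossing (nothing resected yet) and by 8 h the front has passed the last
amplicon, so both are dropped and logged rather than extrapolated. The same
estimator is exposed programmatically:

```python
from dsbquant import default_panel, get_preset, simulate_resection_qpcr, estimate_rate

panel = default_panel()
table = simulate_resection_qpcr(get_preset("caffeine_50mM", seed=1), panel,
                                timepoints_h=range(9))
est = estimate_rate(table, panel)
print(est.rate_kb_h)   # 2.367 — caffeine slows the front (truth: 2.4 kb/h)
```

Equivalent subcommands exist for the other assays: `dsbquant chip`,
`dsbquant blot`, `dsbquant southern`, `dsbquant foci`.

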