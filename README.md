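# minikin

Miniature IPSC kinetics and nociception-behavior analysis, with a
closed-loop synthetic-data generator.

## The problem

GABA_A-receptor miniature inhibitory postsynaptic currents (mIPSCs) report
the state of synaptic inhibition: their decay slows or accelerates with
development and with neurosteroid tone, and the standard per-neuron readout
is the **weighted decay constant** of the mean mIPSC,

    tau_w = tau_fast * P1 + tau_slow * P2,

where (tau_fast, tau_slow) are the time constants of a biexponential fit to
the decay of the rise-midpoint-aligned mean event and P1, P2 = 1 - P1 are
the amplitude fractions of the two components at the peak.  Because single
events are too noisy to fit, the analysis chain is: detect candidate events
(amplitude <= -5 pA, duration > 2 ms, 10-90% rise <= 1 ms), require at
least 50 accepted events per cell, align accepted events at the midpoint of
the rising phase and average, fit mono- and biexponential decays, choose
between them with an extra-sum-of-squares F test on the residual SDs, and
carry tau_w into cohort statistics (mean +/- SD, t tests, one-way ANOVA
with Newman-Keuls post hoc, percent-of-control normalization).  The
companion behavioral assays — tail-flick latency with a 15 s cutoff and its
%MPE transform, von Frey response frequencies (10 presses per mouse), and
rotarod latencies censored at 300 s — are scored and compared with
rank-based tests (Mann-Whitney, Kruskal-Wallis, Wilcoxon).

`minikin` implements this pipeline for researchers who want a tested,
scriptable version of it, together with a trace simulator whose ground
truth is exact, so the whole chain can be validated by parameter recovery:
simulate a cohort whose true tau_w is a documented group mean, analyse it
blind, and check the recovered statistics.  Cohort presets cover
developmental series in spinal dorsal horn lamina II and the thalamic
nucleus reticularis (nRT), adult cortical layer 2/3 neurons, and
neurosteroid (allopregnanolone) treatment arms defined as
percent-of-control tau_w shifts, plus wild-type and ob/ob behavioral
groups.

## Worked example

```python
from minikin.simulate import simulate_cohort
from minikin.io import PipelineConfig, analyze_cohort
from minikin.stats import compare

groups = {}
for name in ("nRT_P6_7", "nRT_P9_10", "nRT_P17_25"):
    cells = simulate_cohort(name, seed=42)           # known ground truth
    df, _ = analyze_cohort(cells, PipelineConfig())  # detect -> average -> fit
    groups[name] = df["tau_w"].to_numpy()
    print(f"{name}: mean={groups[name].mean():.1f} sd={groups[name].std(ddof=1):.1f} n={len(df)}")
res = compare(groups, design="anova_1way")
print(f"ANOVA F={res.statistic:.1f} p={res.p_value:.3g}")
print(res.posthoc)
```

Output:

```
nRT_P6_7: mean=33.5 sd=0.9 n=24
nRT_P9_10: mean=22.8 sd=0.8 n=14
nRT_P17_25: mean=18.3 sd=0.6 n=32
ANOVA F=2932.2 p=5.92e-66
[('nRT_P6_7', 'nRT_P9_10', True), ('nRT_P6_7', 'nRT_P17_25', True), ('nRT_P9_10', 'nRT_P17_25', True)]
```

The three cohorts were generated with true tau_w of 33.2, 22.5 and
18.2 ms; the full pipeline recovers the means within a few tenths of a
millisecond, the developmental ANOVA is overwhelmingly significant, and
the Newman-Keuls step-down finds every pairwise difference significant —
the same qualitative pattern the presets encode.

A command-line interface mirrors the library
(`minikin simulate|detect|fit|cohort|behavior|run`), e.g.

```sh
minikin run --preset spinal_P8_11 --seed 1 --out run1
minikin behavior simulate --preset obob --n 15 --seed 0 --out obob.tsv
```

## Layout

- `minikin.simulate` — event waveform model, sweep/cohort generator, presets
- `minikin.detect` — series-resistance QC, baseline, event detection/metrics
- `minikin.kinetics` — rise-midpoint averaging, decay fits, F-test selection, tau_w
- `minikin.stats` — cohort summaries, tests, Newman-Keuls, percent of control
- `minikin.behavior` — MPE, von Frey, rotarod scoring, rank tests, generator
- `minikin.io` / `minikin.cli` — trace formats (text + HDF5), pipeline, CLI

See `docs/methods.md` for the model, the generator's assumptions and
defaults, numerical choices, and known limitations.
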