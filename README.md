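# mcta

Multiparametric color tendency analysis for flow cytometry.

Instead of chaining two-parameter dot plots, `mcta` looks at many
fluorescence labelings of each event at once: every compensated,
background-subtracted intensity becomes a planar vector whose angle is the
channel's assigned hue, the per-event vector sum ("resultant") picks an HSL
color driven by the predominant labelings, and the result is drawn on a
conventional FSC-A x SSC-A dot plot. Events are gated by boolean marker
positivity (conjunctive inclusion channels plus veto exclusion channels) —
no hand-drawn regions, no downsampling, fully deterministic.

## What's in the box

| module | what it does |
|---|---|
| `mcta.fcs_io` | minimal FCS 3.0/3.1 list-mode reader and FCS 3.1 writer |
| `mcta.config` | `in.dat`-style / JSON configuration parsing and validation |
| `mcta.preprocess` | percent-spillover compensation, background subtraction |
| `mcta.color_model` | equal-division hue assignment, resultant vectors, HSL→RGB |
| `mcta.gating` | include/exclude marker gating (COLORED / EXCLUDED / NON_GATED) |
| `mcta.reporting` | geometric mean/SD/median stats, hue-range filters |
| `mcta.plotting` | FSC x SSC dot plots with per-event colors + hue rule legend |
| `mcta.synth` | seeded synthetic experiments with ground truth (incl. the packaged 5-color spillover panel) |
| `mcta.cli` | `mcta run / filter / synth / validate` |

## Configuration file

Line-oriented text (`#` comments allowed); a JSON equivalent with the same
field names is accepted interchangeably:

```
file = sample.fcs
total_columns = 7
used_columns = 1,2,3,4,5,6,7
scatter = FSC-A:1, SSC-A:2
channel 1 = column:3, label:FITC,    emission:519, background:25
channel 2 = column:4, label:PE,      emission:578, background:25
channel 3 = column:5, label:PerCP,   emission:675, background:25
channel 4 = column:6, label:APC,     emission:660, background:25
channel 5 = column:7, label:APC Cy7, emission:774, background:25
spillover =
  100.00  1.40   0.00   0.00   0.00
  18.22 100.00   0.00   0.00   0.00
   2.80  15.42 100.00   0.00   0.00
   0.00   0.41   6.86 100.00  14.49
   0.00   0.00   0.00   6.54 100.00
roles = 2 -4 0:1 0:3 0:5
```

`roles` tokens: `k` (or `+k`) = inclusion channel, `-k` = exclusion
channel, `0:k` = channel used for the resultant color; unlisted channels
are neutral. The spillover matrix is in percent, rows = source
fluorochrome, columns = detector. Hues are assigned by ranking channels by
maximal emission and dividing 360° into `nc` equal parts; an explicit
`hue:<deg>` field on a channel line overrides its assigned hue.

## CLI

```sh
# full analysis: stats.csv, events.csv, resultant plot (+ optional filter)
mcta run --config in.dat --out results/ [--filter 235:245] [--plot-format png|svg]

# re-filter a previous run's per-event CSV without recomputation
mcta filter --events results/events.csv --range 331:341 --out sub.csv

# generate a synthetic experiment (FCS + config + ground truth)
mcta synth --spec experiment.json --seed 7 --out fixture/

# lint a configuration against its FCS file
mcta validate --config in.dat
```

`mcta run` exits 0 on success, 2 on validation findings, 1 on I/O errors.
Two runs on the same inputs produce byte-identical CSVs.

## Library use

```python
import mcta

cfg = mcta.parse_config("in.dat")
table = mcta.read_fcs(cfg.fcs_file)
result = mcta.analyze(cfg, table)      # PipelineResult
print(result.stats.pretty())           # geometric mean / SD / median block
```

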