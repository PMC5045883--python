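# foldplot

Automated statistical analysis and publication plotting for grouped
replicate measurements — western blot densitometry, endpoint/quantitative
PCR, ELISA and enzyme activity assays. The package targets the bench
scientist's most common design: one standard (control) condition and one
or more treatment conditions, a handful of biological replicates each,
possibly with missing data points from outlier removal.

Everything operates on one universal CSV layout:

```
Groups,Cyclin A,Cyclin B1,...
Control,1,1,...
Control,1.19604093,0.709922771,...
40% Dehydrated,0.653315462,0.243093923,...
...
```

Column 1 holds the group labels (one row per replicate; the first group
to appear is the standard), columns 2+ hold the dependent variables, and
empty cells are missing replicates. From that single file the package
produces:

- a plain-text statistics report per variable: Shapiro–Wilk normality per
  group, Bartlett's equal-variance test, the omnibus test (pooled
  Student's *t* or one-way ANOVA) and post-hoc comparisons
  (Tukey–Kramer all pairs, or two-sided Dunnett versus the control),
  with automatic verification that the chosen test suits the number of
  groups;
- an annotated fold-change bar chart with error bars, a compact letter
  display (shared letter ⇔ no significant difference; the first group is
  always "a") or asterisks, mirrored right y-axis and unlabeled minor
  ticks, plus a plot-metrics CSV;
- a joint-point curve of raw means over a continuous x (e.g. elution
  fractions), with error bars only when the data carry replication;
- a simple fold-change heatmap on the same input layout;
- axis range finding: given an intended number of major ticks it returns
  the optimal major tick interval, estimated limits, and every admissible
  minor-tick count.

## The statistics in brief

For each variable, group means are normalized to the standard group's
mean *m*₀: fold change = *m*ᵍ/*m*₀ and normalized error =
(SD/√*n*)/*m*₀, where SD is the sample standard deviation of the
non-missing replicates and *n* counts **all** replicate rows of the
group, missing cells included. Significance labels come from the
post-hoc p-values at α = 0.05.

The axis range finder rounds the raw interval onto a 0.05·10ⁱ grid:

```
raw = (1.1·max − min) / intended_ticks ,  i = ⌈log₁₀ raw⌉
major interval = ⌈raw / 10ⁱ / 0.05⌉ · 0.05 · 10ⁱ
```

and enumerates minor-tick options as interval/d − 1 over the decimal
divisors d of the interval (the interval is scaled to an integer by a
power of ten, with one extra factor of ten whenever the largest option
would fall below four).

## Worked example

Using the bundled wood-frog liver cyclin dataset (3 conditions × 4
replicates, 4 cyclins, missing cells included):

```
$ foldplot fixtures --dataset casestudy1 --out casestudy1.csv
$ foldplot stats casestudy1.csv --test tukey
wrote casestudy1.stats.txt
$ foldplot autorange-bar casestudy1.csv --ticks 5
y-axis optimal major tick range: 0.3
y-axis estimated limits: 0 to 1.5
y-axis minor tick options: 0, 1, 2, 4, 5, 9, 14, 29
...
$ foldplot hist casestudy1.csv --test tukey --ylabel "Relative Intensity"
wrote casestudy1.hist.pdf
wrote casestudy1.hist.metrics.csv
```

The metrics file (excerpt) reads:

```
Id,Condition,variable,NrmMean,variableSEM,NrmSEM,variableLbl,Lbl
1,Control,Cyclin A,1.0,Cyclin ASEM,0.044782408990818326,Cyclin ALbl,a
2,40% Dehydrated,Cyclin A,0.7252259914102812,Cyclin ASEM,0.062004167643982824,Cyclin ALbl,b
3,Rehydrated,Cyclin A,1.1027255514353977,Cyclin ASEM,0.041801494648000474,Cyclin ALbl,a
```

Read: dehydration drops Cyclin A to 0.73× the control mean (letter "b":
significantly different from both the control and the rehydrated group,
which share "a"), and rehydration restores it (1.10×, not significantly
different from control). The range-finder output says a y-axis with major
ticks every 0.3 up to 1.5 accommodates the tallest bar-plus-error-bar
with 10% headroom, and that 0.3 admits minor-tick counts
{0, 1, 2, 4, 5, 9, 14, 29}.

The same pipeline is available as a library
(`read_grouped_table`, `analyze_all`, `fold_change_table`,
`annotation_for`, `autorange_bar_y`, `render_histogram`, ...), and
`foldplot.fixtures.generate` draws synthetic tables with configurable
group means, SDs, replicate counts and missing rates for testing.

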