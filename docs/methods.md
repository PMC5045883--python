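# Methods

## Scope and model

foldplot automates the analysis most molecular-biology bench experiments
reduce to: a one-way layout with a standard (control) group and one or
more treatment groups, a few biological replicates per group, and one or
more dependent variables measured on every replicate. The package is
strictly one-way: no factorial, repeated-measures or mixed designs, and
no non-parametric fallbacks — assumption tests are reported so the user
can judge the parametric results, but the workflow never switches tests
on its own.

Input is a single CSV matrix (groups in column 1, one row per replicate,
variables from column 2, empty cells missing). Groups are identified by
label and ordered by first appearance; they do not have to form
contiguous blocks. The first group is the standard for both
normalization and Dunnett comparisons.

## Statistical workflow

Per dependent variable, in order:

1. **Normality.** Shapiro–Wilk per group over non-missing values.
   Computable for 3 ≤ n ≤ 5000 and non-degenerate variance; otherwise the
   group is flagged not-computable with a reason — reported, never fatal.
2. **Variance homogeneity.** Bartlett's test across all groups with ≥ 2
   non-missing values (chosen over Levene because the downstream tests
   already assume normality).
3. **Test verification.** Student's *t* is valid only for exactly two
   groups; the ANOVA variants only for three or more. An invalid request
   produces a message naming the appropriate test, written into that
   variable's report section; other variables are still analyzed.
4. **Omnibus + post-hoc.**
   - *t*-test: pooled-variance (equal-variance form, consistent with
     testing homogeneity first), two-sided.
   - Tukey: one-way ANOVA F, then Tukey–Kramer studentized-range
     pairwise p-values (unequal n supported), all unordered pairs.
   - Dunnett: ANOVA F, then two-sided Dunnett comparisons of each group
     against the standard. The multivariate-t integral is evaluated by
     seeded quasi-Monte-Carlo; p-values are reproducible given a seed and
     accurate to ~1e-4.

α defaults to 0.05 and is configurable. Each variable is analyzed
independently; no multiplicity correction is applied across variables.
Missing values are dropped per (group, variable).

All distributional computations are delegated to scipy
(`shapiro`, `bartlett`, `f_oneway`, `ttest_ind`, `tukey_hsd`, `dunnett`);
the test suite cross-checks them against values frozen from R 4.3.3
(`shapiro.test`, `bartlett.test`, `TukeyHSD`, `t.test(var.equal=TRUE)`,
`multcomp::glht`) on fixed vectors.

## Fold change and error normalization

For group g and variable v with non-missing replicate values x₁..xₙ:

- mean = Σxᵢ/n over non-missing values; SD uses the n−1 denominator.
- SEM = SD/√N where **N is the total number of replicate rows of the
  group, counting missing cells**. This "slots" convention is what the
  reference outputs for this layout require (a group of four rows with
  one missing cell divides by √4, not √3); a strict mode using the
  non-missing count is available via `strict_n=True`.
- fold change = mean(g)/mean(standard); normalized error =
  (SEM or SD)/mean(standard). The standard group's fold change is
  exactly 1 by construction.
- A single replicate leaves SD/SEM absent (not zero): bars and curve
  points then render without error bars.

The curve path reports raw means and raw SEM/SD (no normalization) per
group against numeric x values parsed from the variable names, and
suppresses error bars entirely when no (group, x) cell has more than one
replicate. A (group, x) cell whose values are all missing is skipped
rather than treated as an error.

## Significance annotation

Tukey results are condensed into a compact letter display by the
insert-and-absorb algorithm: start with one column holding all groups;
for each significant pair (processed in normalized index order for
determinism) duplicate every column containing both members and remove
one member from each copy; then absorb duplicates, empties and strict
subsets. The resulting columns are exactly the maximal cliques of the
non-significance graph (property-tested against clique enumeration), so
two groups share a letter iff they are not significantly different.
Columns are lettered in order of their earliest member, which pins "a"
to the first group in input order; pair labels are normalized
standard-first ("stress-control" → "control-stress") before any
letter work. Letters continue "aa", "ab", ... past "z". Note the number
of distinct letters can exceed the number of groups for adversarial
significance patterns (the maximal-clique count governs it).

t-test and Dunnett annotations are asterisks on each non-standard group
whose comparison against the standard has p < α. Annotation is driven by
the pairwise results only; the omnibus F is reported but does not gate
the letters.

## Axis range finding

With data maximum M (largest fold change + normalized error for bars;
mean + error for curves), minimum m (0 for bars by default), intended
major tick count T and headroom h:

    raw = (h·M − m)/T,  i = ⌈log₁₀ raw⌉,
    interval = ⌈raw/10ⁱ/0.05⌉·0.05·10ⁱ,
    upper = interval·⌈h·M/interval⌉,  lower = 0 or interval·⌊m/interval⌋.

Numerical guards: values are rounded to 12 significant digits and an
ε = 1e-9 is subtracted inside each ceiling (added inside floors) so that
exact grid multiples do not round away under binary floating point.

Minor-tick options are interval/d − 1 over the decimal divisors d of the
interval: the interval is scaled by the smallest power of ten making it
an integer N (via its decimal representation, then integer divisor
enumeration with sympy), with an extra factor of ten applied while
N − 1 < 4 so at least one option of four or more minors always exists.
Minor ticks subdivide each major interval at spacing
interval/(n_minor + 1).

Headroom defaults to 1.1 for the bar path — it both reserves space above
the tallest bar for annotation strings and reproduces the reference
behaviour of the range finder on the bundled dataset — and to 1.0 for
curves (which hug the data); for curves it multiplies both extremes, so
negating the data negates and swaps the limits. Both are parameters.

## Rendering

matplotlib with the Agg backend; PDF output by default (PNG/SVG via the
output path's suffix). Bars cluster by variable with groups in input
order; annotations sit 2% of the y-span above mean + error
(configurable). The right-hand y-axis mirrors the left's major and minor
tick marks with no labels. Default bar y-scheme: interval 0.5, 4 minors,
lower limit 0, upper limit the smallest grid multiple covering
1.1 × the data maximum; curve x defaults to interval 0.5 with no minors.
Heatmaps color tiles by fold change on a diverging map anchored at 1
(the standard); uniform data fall back to a symmetric window around 1.
Tests assert plotted coordinates, tick positions and annotation strings
through matplotlib's object model — pixel appearance is not a contract.

## Synthetic data

`fixtures.generate` draws each group's replicates from per-variable
normal distributions and masks cells independently at a configurable
missing rate (≤ 0.5), always keeping the first replicate of each group
so every cell retains one observation and the pipeline stays runnable.
The default recipe mirrors a small densitometry experiment: control plus
two treatments, four replicates, fold-change-scale means (0.6–1.4×) with
~10% relative scatter, no missing cells. What the generator does *not*
emulate: inter-blot batch effects, heteroscedasticity that grows with
the mean, censoring at detection limits, or correlated variables — so
green tests demonstrate correctness of the computations, not robustness
of the t/ANOVA machinery to those real-data pathologies. The bundled
curve dataset is likewise a synthetic, deterministic two-peak elution
profile, not measured data.

## Numerical and design choices

- Metrics CSV columns are fixed (`Id,Condition,variable,NrmMean,
  variableSEM,NrmSEM,variableLbl,Lbl`), numbers at full float precision;
  a write-then-read round trip is the identity to 12 significant digits.
  Variable names are written verbatim (no identifier mangling).
- The report file format is plain text with `== variable ==` section
  headers and bracketed block labels, so scripts can grep it
  deterministically. t-test sections carry the single comparison as the
  omnibus line and no post-hoc block.
- Degenerate inputs fail loudly and specifically: non-numeric cells name
  their row/column, an all-missing cell names its group/variable, a
  zero-mean standard is a division-by-zero error, a sub-2-replicate
  group makes variance undefined for testing.
- Problem sizes in the test suite are the bundled 12-row dataset and
  synthetic tables of comparable size; property tests run a few hundred
  randomized cases each, which this pipeline covers in seconds.

## Known limitations

One-way designs only; no outlier handling (remove outliers upstream, as
the bundled dataset's authors did); no log or date axes; Dunnett
p-values are stochastic at the 1e-4 level across seeds; the heatmap is
deliberately minimal (no clustering, no dendrograms).
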