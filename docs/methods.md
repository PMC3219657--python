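# Methods

## Windowed properties

Properties are computed over windows tiling the sequence from position 1
(1-based inclusive coordinates throughout the data model). The default step
equals the window size, matching the condensation arithmetic used for track
resolution (window = ⌈L / resolution⌉, e.g. 4,639,000 bp at 4,000 units →
1,160 bp windows). The final partial window is computed over the remaining
bases on linear sequences and wraps through position 1 on circular ones;
neither behaviour pads.

Ambiguity codes (N etc.) are excluded from every count, so skew and content
denominators shrink rather than distort. A window whose denominator is
empty (e.g. no G or C for GC skew) scores 0 rather than NaN — this keeps
condensed vectors finite for the wavelet and correlation stages — and the
event is logged once per track. Legend statistics use the population
standard deviation (ddof = 0).

The global minimum and maximum of a cumulative skew are reported as
candidate origin/terminus positions, ties broken toward the smallest
position. Note that because the running sum starts at the first window's
value, a perfectly Λ-shaped chromosome whose origin is at bp 1 attains its
minimum at the *last* window (circularly adjacent to bp 1, value ≈ 0);
callers comparing against a programmed origin should use circular distance.

## Condensation

`condense` resamples a windowed track onto exactly 2^m equal bins spanning
the track's coverage. Each bin's value is the bp-overlap-weighted mean of
the source windows that intersect it; when the track has fewer windows than
bins this degenerates to piecewise-constant upsampling. m defaults to 11
(N = 2048), the setting used throughout the demonstration analyses;
m ∈ [10, 15] is typical for full chromosomes. All vectors entering a
cross-correlation must share the same N, which condensation guarantees.

## MODWT

The maximal-overlap discrete wavelet transform is implemented directly via
the pyramid algorithm with periodic (circular) boundary treatment —
appropriate since the chromosomes analysed are circular. MODWT filters are
the unit-energy DWT filters rescaled by 1/√2; scaling filters for haar, d4
(Daubechies-4) and la8 (least-asymmetric 8) are taken from PyWavelets, and
the 4-tap Fejér–Korovkin (fk4) scaling filter is embedded as coefficients
(verified orthonormal). The wavelet filter is the quadrature mirror
h_l = (−1)^l g_{L−1−l}, which for Haar gives the level-1 identity
W_{1,t} = (x_t − x_{t−1 mod N})/2.

Each level yields N coefficients; energy conservation and perfect
reconstruction hold to ~1e−12 relative and are enforced in tests at 1e−8.
"Denoising" is the multiresolution smooth at level J: the inverse transform
with all detail coefficients zeroed. J defaults to 4; J must satisfy
2^J ≤ N, and larger J removes progressively lower frequencies.

A Haar-specific diagnostic, `haar_reverse_cumulative_similarity`,
correlates the level-J Haar details of a cumulated signal with the level-J
denoised raw signal — for Haar, differencing undoes accumulation, so the
two are similar but not identical. On noisy synthetic GC skews condensed
by averaging (more source windows than bins) the correlation is ≥ 0.95 at
J = 1 and J = 4; upsampled low-resolution vectors correlate less tightly
at high J because the level-J smooth spans too large a fraction of the
vector.

## Correlation

The ACF uses the biased (divide-by-N, fixed global mean) estimator:
r(k) = Σ_{t≤N−k} (x_t − x̄)(x_{t+k} − x̄) / Σ (x_t − x̄)², lags 0…N−1. The
CCF normalizes by N·s_x·s_y with biased standard deviations, lags
−(N−1)…(N−1), so ccf(x, y)(k) = ccf(y, x)(−k) and ccf(x, x)(0) = 1. This
convention's taper is load-bearing: a symmetric triangular (Λ) vector has
r(N/2) = −0.5 exactly, which is how the half-length peak value of ≈ −0.50
arises for Λ-shaped cumulative skews. The taper also pulls the strongest
local extremum of |r| slightly below N/2 (to ≈ 0.43–0.48·N depending on
shape) — the peak *location* is shape-dependent while the −0.5 at
half-length is structural.

The significance bound is CI = Z_p/√N with Z_p the two-sided normal
critical value, computed at full precision (1.96/2.58/3.29 are rounded
displays). Zero-variance inputs are an error: correlation is undefined,
and silently returning 0 would mask degenerate condensations.

A "peak" is the local extremum of |r| (strictly greater than both
neighbours) of maximum magnitude at |lag| ≥ min_lag (default 1 bin), ties
toward the smallest |lag|; lag 0 is excluded for ACF since r(0) = 1 is
structural. If no local extremum exists in range, the global max-|r| lag is
returned flagged not-significant.

`similarity_summary` averages J+1 magnitudes: the maximum |CCF| between
the level-j details of the two inputs for j = 1…J, plus the maximum |CCF|
between their denoised versions. Magnitudes (absolute values) are averaged
because the underlying maxima of mirrored signals are negative while the
summary is meant as a [0, 1] similarity score. Self-similarity is 1, the
score is invariant to affine rescaling of either input, and k tracks incur
exactly k(k−1)/2 cross-correlations.

## Atlas rendering

The SVG document contains one named group per track in configured order and
one legend group per track in a right-hand panel; property legends place
min/max/mean/sd at the four corners and the condensation window size below.
Property tracks contribute exactly `resolution` drawable units (bars, dots
or gradient cells); resolution defaults to 3000. Histogram/dot styles use a
two-color rule about a threshold (default: track mean); the gradient style
interpolates the two scheme colors with the darkest ends at the property
minimum and maximum (a constant track renders the mid-ramp color).

Circular layout maps position t to angle 360°·t/L with 0 at 12 o'clock,
clockwise — chosen to match common prokaryote atlas practice. Circular property values
grow outward from the annulus baseline by default (`values_outward` flag).
The interactive manipulations are static config transforms: translate,
rotate (circular; composes additively mod 360), flips (involutions),
opacity, width, and a radial offset standing in for the "size" control.
The caterpillar device references a linear track twice via `<use>` at ±span
so a horizontal shift wraps around; it is rejected on circular layouts.
Scale-independent mode draws all chromosomes at the longest display span;
proportional mode preserves length ratios. Forward/reverse CDS tracks
render blue/red; customized features without colors draw from a palette
with a seeded generator, so equal configurations produce byte-identical
SVG. A COG functional-category palette is embedded and overridable.

Legend numbers use up to 4 significant digits; structural properties (group
counts, unit counts, well-formedness) are promised, pixel output is not.

## Synthetic data

`make_skewed_genome` samples bases independently with
P(G) − P(C) = ±skew_strength·gc_content, the sign flipping at the
programmed oriC and terminus; optional per-base Gaussian skew noise and a
sinusoidal skew modulation at a given period are supported. Defaults
(200 kb, skew_strength 0.3, gc_content 0.5, noise_sd 0) give an
unambiguous Λ/V geometry at 1 kb window resolution while staying fast;
skew_strength 0.2 with noise_sd 0.05 is the harder recovery condition
exercised in tests (origin recovered within 2 windows in ≥ 95% of 50
seeds). What the generator does **not** emulate: codon/gene structure,
dinucleotide correlations, repeats, horizontally transferred islands, or
the weak/absent polarity of thermophiles — so passing recovery tests show
the pipeline's correctness on controlled skew geometry, not predictive
accuracy on arbitrary real chromosomes.

The acceptance script scales the shifted-Λ demonstration to the full
4,639.7 kb published geometry (polarity switches at 3,923.4 kb and
1,603.6 kb, 1 kb windows, N = 2048) so the condensation direction
(averaging ≈ 2.3 windows per bin) matches the real-chromosome setting;
smaller 100 kb genomes are used where only structure (pair counts, atlas
groups) is being measured.

## Numerical choices

- Resampling is exact overlap-weighted averaging (oracle-tested to 1e−12);
  bins never covered by a window inherit the nearest preceding value.
- Normal quantiles via scipy's `norm.ppf`; no table lookups.
- Float serialization in GDF uses `repr`, so property round-trips are
  bit-exact.
- GDF is this package's own fully-specified TSV dialect (header
  `#gdf<TAB>kind<TAB>seq_id<TAB>seq_length`); the historical format it
  stands in for was never publicly archived.

## Known limitations

- Only single-record FASTA and single-locus GenBank inputs; no
  multi-contig assemblies, .ptt, GFF or BED ingestion.
- Oligonucleotide skews and gene-strand skews are not implemented (never
  defined in the source literature for this tool class).
- Wavelet-coefficient plots show raw MODWT details, not MRA detail series;
  the two differ by a circular filter, and either is a defensible display.
- Rasterization of SVG output is delegated to external tools and untested.
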