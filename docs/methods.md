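# Methods

This note documents the models behind each `camseed` module, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Electropherogram processing

A trace is a signal sampled on a strictly increasing apparent-size grid
(kDa). The instrument's migration-time-to-size calibration is taken as
given; no attempt is made to model it.

**Baseline.** The baseline estimate is the grey (morphological) opening of
the signal — a rolling minimum followed by a rolling maximum over the same
window (`window_kda`, default 8 kDa). Opening follows constant offsets and
drifts exactly but cannot follow features narrower than the window, so
peaks survive subtraction; because opening is idempotent, so is the
subtraction. The window must exceed the widest peak (default 10× the
default peak sigma) or peak area is eaten into.

**Peak calling.** Local maxima of a Savitzky–Golay-smoothed signal
(polyorder 3, window matched to `min_separation_kda` — features narrower
than the separation floor are noise by definition) with prominence at
least `min_rel_height` (default 0.02) of the global maximum and mutual
separation at least `min_separation_kda` (default 1 kDa). Areas are
trapezoidal integrals of the *raw* signal between flanking minima, falling
back to ±4 estimated sigmas at the trace edges; sigma is estimated from
the full width at half height. These thresholds are this package's
defaults — the commercial instrument software's thresholds are not
published — and are all exposed as function arguments and CLI flags.

**Quantification.** `percent_i = 100 · area_i / Σ area` over non-shoulder
peaks; percents sum to 100 within 0.1. Scaling the signal by any positive
constant leaves percents (and hence classifications) unchanged, because
every threshold is relative.

**Nominal matching.** A nominal call ("the 17 kDa peak") matches the
largest-area detected peak within `tol_kda` (default 1.5 kDa, covering
"ca." calls spaced ≥2 kDa apart); area ties break toward the closest apex.

**Shoulders.** On a clean Gaussian flank the second derivative changes
sign exactly once (the tail inflection). An unresolved secondary component
adds further curvature sign changes while the first derivative keeps its
sign; a resolved neighbour instead makes the first derivative cross zero
and is a peak, not a shoulder. Derivatives are Savitzky–Golay estimates
over a 0.5 kDa window — the shoulder's curvature excursion is only ~1% of
the apex curvature, so wider windows erase it. The zero threshold for
curvature is the larger of 0.1% of the apex curvature and 3× a robust
(MAD-based) estimate of the trace's curvature noise. Consequence: at noise
levels around 2% of the maximum signal, genuine shoulders fall below the
noise floor and profile-1 samples are reported unassigned rather than
guessed — a deliberate trade against false profile calls.

## Classification schemes

The species scheme is a fixed binary decision tree over peak
presence/absence: a 17 kDa reducing peak separates the
sativa/microcarpa/rumelica group from neglecta/laxa/hispida; 14 kDa
(reduced) identifies *C. sativa*; 33 kDa (reduced) separates the rumelica
group from *C. microcarpa*; 54 kDa (non-reduced) separates *C. microcarpa*
4X from 6X; 12 kDa (reduced) identifies *C. neglecta*; 33 and 29 kDa
(reduced) separate *C. laxa* from the hispida group. The published scheme
does not state which of laxa/hispida carries the 33/29 kDa pair; this
implementation places them on *C. laxa*. Rumelica subspecies and hispida
varieties are left as group leaves — the scheme does not separate them.
The tree is serialisable to YAML so thresholds and branches can be edited
without touching code. Samples matching no leaf are reported unassigned
with a reason, never forced to the nearest label.

The *C. sativa* profile scheme operationalises qualitative descriptors as
configurable bounds: the profile-2 "doublet of relatively equal abundance"
is an area ratio within [0.5, 2.0]; profile-3 "two large peaks" each carry
≥10% of total area; and any profile marker must itself carry ≥5% of total
area to count as present, so residual noise wiggles cannot register as
markers. Under reducing conditions more than three profiles exist in the
field data but only three are described quantitatively; no sub-
classification beyond the three is attempted.

## Protomer physicochemistry

Elemental formulas are sums of free-amino-acid formulas minus one water
per peptide bond; average mass uses conventional atomic weights (C 12.011,
H 1.008, N 14.007, O 15.999, S 32.06). Charged-residue counts follow the
property-table convention: negative = Asp+Glu, positive = Arg+Lys
(histidine excluded); "total charge" is the residue-count difference
pos − neg, with the pH-dependent Henderson–Hasselbalch curve exposed
separately. GRAVY is the mean Kyte–Doolittle hydropathy. Net charge is
strictly decreasing in pH, so the pI is its unique root, found by
bisection on [0.1, 13.9] to 1e-4 pH. The pKa set defaults to the EMBOSS
values (D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5, termini
8.6/3.6); published pI values computed with unstated tools should be
compared at ±0.1 pH. Sequences are consumed exactly as given — no
signal-peptide trimming; mature-chain boundaries are the caller's
responsibility.

## Composition statistics

%w/w is mg of one analyte over total recovered mg per replicate (the
analyte list, with Asx/Glx as combined hydrolysis analytes and Cys/Met as
their oxidised forms, is treated as authoritative). Technical replicates
are averaged within biological replicate before inference; the biological
replicate is the experimental unit. One-way ANOVA (F, p) is paired with
Tukey–Kramer HSD pairwise p-values from the studentized range distribution
with pooled variance and the unequal-n correction (via
`scipy.stats.tukey_hsd`).

Compact letter displays are computed as an exact minimum clique cover of
the non-significant graph: each letter is a clique (no significant pair
shares a letter) and the cover must span every group and every
non-significant pair. For ≤10 groups the minimum cover is found exactly
(Bron–Kerbosch maximal cliques, then exhaustive search; note a cycle of
non-significant pairs can need more letters than groups); beyond 10 an
insert-and-absorb sweep is used, which is valid but not guaranteed
minimal.

## Expression summaries

TPM divides counts by annotated transcript length and scales each sample
to 10⁶; effective-length corrections are not attempted. Quantile
normalisation replaces each sample's order statistics by the across-sample
mean of order statistics; ties receive the mean of their tied quantile
values. The defining property (identical sorted columns) therefore holds
exactly only for tie-free data — zero-inflated TPM columns tie at zero and
deviate by the tie policy. Normalisation is applied to TPM, and is
idempotent.

Cruciferin-type fractions are TPM shares within the family per sample;
samples with zero family expression are flagged undefined rather than
reported as zeros. Sub-genome partitioning distinguishes a homeologue that
is *structurally absent* (no gene on that sub-genome, e.g. napin on G2,
CruA on G3) from one that is present but silent.

Temporal windows: the onset is the first interval between consecutive
timepoints over which expression rises by ≥`rise_fold` (default 5; a rise
from exactly zero counts as sharp) to above `min_tpm` (default 50 TPM);
the offset is the first later interval falling by the same factor from
above the floor. Pooled samples carry no time axis and are refused.

## Synthetic data: what it emulates, and what it does not

**Traces** are sums of Gaussians (apex at the nominal size, sigma 0.8 kDa,
area proportional to template abundance, total area 1000 signal·kDa) plus
a linear baseline drift and white Gaussian noise (default 1% of the clean
maximum). Species templates carry the discriminating peaks of the decision
scheme plus a shared set of common peaks (10/21/26/39/46 kDa reduced,
20/31/39/48 kDa non-reduced) whose nominal sizes are kept >2 kDa away from
every discriminating nominal; the full published peak lists are not
printed numerically, so abundances are free parameters of the generator.
Real electropherograms have asymmetric peaks, size-dependent widths and
correlated baseline structure; none of that is emulated, so passing
recovery tests demonstrates the processing chain's correctness, not
instrument-grade robustness.

**Amino-acid tables** draw multiplicative lognormal technical noise with
unit mean around prescribed %w/w group means (defaults: the six printed
accession columns of the composition panel), with 3 biological × 3
technical replicates. Expected %w/w equals the generating means up to
closure (renormalisation over the analyte list). Biological variance is
not separated from technical variance unless requested.

**Count matrices** place a fixed plateau budget per seed-protein family
(cruciferin 0.30, napin 0.15, vicilin 0.05, oleosin 0.05 of the transcript
pool; background genes fill the rest with a fixed spread of flat levels),
split the cruciferin budget by the configurable type fractions, and
modulate seed-protein genes by a logistic induction window: rise centred
at onset+2 daa, fall at offset+2 daa (defaults 8–12 and 28–32 daa), edge
scale 0.2 daa. The sharp edge scale keeps pre-onset expression around
10⁻⁴ of plateau even after per-sample TPM renormalisation (background
genes dominate pre-onset libraries), which is what makes the generating
window exactly recoverable. Counts are negative-binomial with dispersion
0.1 by default (variance μ + 0.1 μ²); dispersion 0 gives rounded
expectations. The catalogue mirrors the annotated gene complement: 12
cruciferins (CruA ×2 on G1 + 1 on G2, no G3 copy; CruB/C/D one per
sub-genome), 8 napins (4 on G1, 4 on G3, none on G2), 8 vicilins and 12
oleosins. Library-preparation biases, gene-length effects on dispersion
and biological replicate structure are not emulated.

All generators are pure functions of their spec including the seed, with
per-operation random streams, so adding one generator call never shifts
another's output.

## Problem sizes and runtime choices

Simulation-based checks use: 50 noisy traces for profile recovery, 100
replicates per noise level for robustness monotonicity, 20 seeds for
count-matrix share recovery (a single library at dispersion 0.1 with three
genes per type carries ~0.03 share noise, so recovery is judged on the
Monte-Carlo mean — each share within 0.02, mean absolute error < 0.01),
and 10,000 vectorised null simulations for ANOVA/Tukey type-I calibration
(for equal group sizes, "any Tukey pair significant" equals the max
studentized-range statistic exceeding one critical value, so the
simulation needs a single quantile evaluation; a 100-simulation
consistency check ties the fast statistic to `anova_tukey`'s decisions).

## Known limitations

- Shoulder detection is reliable only on low-noise traces (see above);
  profile-1 assignment degrades to "unassigned" as noise grows.
- The peak integrator exchanges tail mass between adjacent peaks closer
  than ~4 sigma; percent errors stay within ~1.5 points at the 2–3 kDa
  spacings the schemes use but grow for heavily overlapped peaks.
- Tukey–Kramer p-values inherit the studentized-range approximation for
  unequal n; agreement with exact permutation tests is ~5% relative at
  moderate p and worse in the far tails.
- The insert-and-absorb letter display used above 10 groups is valid but
  may use more letters than the minimum.
- Printed table values are reproduced by arithmetic on printed inputs;
  properties that depend on the deposited sequences themselves (pI and
  GRAVY of real protomers) are oracle-checked instead when the sequences
  are not available.
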