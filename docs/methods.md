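# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention) in every module.
Distance from a point to an interval is 0 when the point is contained and
otherwise the separation to the nearest *contained* base (`start` or
`end − 1`), since distances measure base-to-base separation, not distance
to an exclusive bound. Genomes are in-memory uppercase strings over
{A,C,G,T,N}; N is permitted (real assemblies contain gaps) but never
matches in any scanner.

## PG4 motif grammar

A potential G-quadruplex motif is `n_runs` (default 4) *maximal* guanine
runs of length ≥ `run_len` (default 3) separated by loops of length in
`[loop_min, loop_max]`. The presets G3L1-7, G3L1-12 and G3L1-15 differ only
in `loop_max`; the registry is configurable because the exact list of loop
configurations worth scanning is an analysis choice, not a fixed fact.

Matching semantics, chosen to mirror the common quadparser convention:

- **Tracts are maximal runs.** Excess guanine belongs to the tract, never
  to the loop: a tract may not start or end inside a longer G-run. Loops
  may contain G (in runs shorter than `run_len`, or in qualifying runs
  skipped because their gap violates the loop bounds) and any of A/C/T;
  any N in the hit span disqualifies it.
- **Leftmost, lazy.** The scanner reports the match with the smallest
  start; among those, loop lengths are minimized left-to-right (regex-lazy
  order, realized as depth-first search over the maximal-run list trying
  nearest next tracts first).
- **Per-strand non-overlap.** After accepting a hit, scanning resumes at
  its end. The minus strand is scanned on the reverse complement and
  mapped back to plus coordinates; overlapping plus/minus hits are both
  kept, as G-rich and C-rich tracts are chemically distinct sites.

The test suite checks this grammar against an independent brute-force
enumerator (per-start character walking over all loop tuples in lazy
order) on hundreds of random ~2 kb sequences, plus strand-symmetry,
loop-bound-monotonicity and tract-integrity properties.

Telomeric reads are defined by content: a read is telomeric iff it
contains ≥ 2 tandem copies of TTAGGG on either strand (i.e. the substring
`TTAGGGTTAGGG` or `CCCTAACCCTAA`). Interstitial telomere-repeat peaks are
peaks whose sequence contains at least one TTAGGG unit on either strand.

## Replicate peak intersection

Two replicate peak sets are merged into common peaks by connected overlap
components: any maximal chain of mutually overlapping peaks containing at
least one member from each replicate becomes one peak
`[min(starts), max(ends))`. The pairwise min-start/max-end rule generalizes
to chains (A1–B1–A2) this way; peaks overlapping only within one replicate
are discarded. Touching half-open intervals (`[0,100)`, `[100,200)`) share
no base and do not chain. A networkx connected-component oracle checks the
sweep implementation on random fixtures.

## Enrichment against length-matched controls

For each observed peak, `n_per_peak` (default 100) control regions of the
peak's exact length are sampled genome-wide: chromosome chosen with
probability proportional to length, start uniform among fitting positions,
rejecting draws that overlap an exclusion set (default: the observed peaks,
to avoid contamination) or contain > 10% N. Controls are pooled into a
single 2×2 table per pattern — matching a single Fisher p per comparison —
rather than per-peak empirical p-values. Length is the only matched
covariate; GC- or masking-matched permutation schemes are out of scope.

Two table constructions cover both directions of the association:

- **Motif count:** row = (non-overlapping motif count, bases not covered
  by motifs) for peaks vs pooled controls. This keeps both margins
  well-defined counts while comparing per-base motif density.
- **Peak presence:** row = (#regions with ≥ 1 hit, #regions with none).

Both use the two-sided Fisher's exact test (scipy) with the odds ratio
`ad/bc` (Haldane–Anscombe +0.5 correction when a cell is zero). A
degenerate margin returns p = 1.0 with a warning — no evidence either way.
The implementation is verified against an exact integer hypergeometric
enumeration on every 2×2 table with total ≤ 40.

Under the null synthetic generator (equal motif density inside and outside
peaks) the motif-count test's rejection rate at 0.05 is checked to lie in
0.05 ± 0.03 over 200 seeded replicates. The calibration check is asserted
on the count-based test: with a few dozen peaks the presence table is
strongly discrete, making its null rejection rate conservative by
construction rather than informative about miscalibration.

## Bin-level ChIP-vs-input enrichment

The genome is divided into fixed bins (default 50 bp; reads assigned by
midpoint). Each bin's ChIP count is tested one-sided against
`Binomial(chip_total, p₀)` with `p₀ = (input_bin + 1)/(input_total +
n_bins)`; the +1 pseudo-count keeps bins with empty input testable.
Per-bin p-values are corrected by Benjamini–Hochberg at the configured FDR
(default 5%) and the significant-bin fraction reported. Both the exact
test behind bin significance and the use (or not) of multiple-testing
correction are analysis choices surfaced in configuration, not facts of
nature; the binomial + BH combination is the simplest calibrated default.

FRiP is the fraction of reads whose midpoint (`pos + length/2`, floored)
lies in any (merged) peak — midpoint membership is unambiguous for reads
straddling peak edges. Sub-telomeric means any base within 0.5 Mb of a
chromosome terminus; everything else is interstitial.

## Feature annotation

Peaks are classified by midpoint against gene models with fixed priority
promoter > downstream > exon > intron > intergenic: promoter = within a
configurable half-width of a TSS; downstream = within 5 kb (default) past
the transcript end *on the gene's strand*. The categories are therefore
mutually exclusive. TSS distance for proximity counts uses the whole peak
interval (distance 0 if the TSS is inside), since peak summits are not
guaranteed to exist downstream of arbitrary peak callers.

## FID titration analysis

Percent probe displacement is the ratio form
`TOD(x) = 100 − (FAₓ/FA₁)·100`, which satisfies the boundary identities
TOD(FA₁) = 0 and TOD(0) = 100 and is invariant under rescaling all
fluorescence areas. DC₅₀ is obtained by linear interpolation between the
bracketing titration points of the running-maximum-smoothed displacement
curve; a non-monotone crossing uses the first crossing and warns. TOD
values are clamped to [0, 100] for reporting only — raw values are kept
for fitting, because noise can push areas above FA₁. The indicative
dissociation midpoint is the K of a least-squares Hill fit
`TOD(c) = 100·cʰ/(cʰ + Kʰ)` initialized at (DC₅₀, h = 1) with positive
bounds; the Hill-midpoint convention defines "indicative K_d" here.

## Synthetic study conditions

The generator's defaults define the conditions all statistical checks run
under:

| parameter | default | rationale |
|---|---|---|
| genome | 4 chromosomes × 100 kb | desk-scale; several chromosomes exercise length-weighted sampling |
| base composition | A/C/G/T = 0.30/0.20/0.20/0.30 | mammalian-like ~40% GC; spurious PG4 rate negligible at G3L1-7 |
| peaks | 40 × 1 kb, non-overlapping uniform | enough peaks for a stable presence table |
| motif densities | 1.5/kb in peaks vs 0.3/kb background | the 5× planted contrast probed by the power check |
| replicate jitter | Normal sd 25 bp on endpoints, 5 decoys/replicate | peak-boundary noise well under peak_length/10 |
| reads | 10⁴ × 36 bp, 5× start-rate inside peaks | thinning-based two-rate model |
| telomeric fraction | 0.23 | the telomeric read share reported for a telomere-binding factor |
| controls | 100 per peak | the standard control multiplicity used throughout |
| FID | DC₅₀ = 2 molar eq, h = 1, 2% noise, 10 points on 0–10 eq | titrant range of a typical displacement experiment |

Backgrounds are i.i.d. per base — no repeats, no isochores, no chromatin
structure — which suffices to calibrate length-matched nulls but means
passing tests say nothing about confounding by GC content, mappability or
repeat context in real genomes. Planted motifs use four `run_len`-G tracts
with loops drawn uniformly over {A,C,T} (so loops can never extend a
tract); planting positions avoid already-planted motifs, and a motif that
cannot be placed after bounded retries is dropped with a warning. Replicate
generation, read generation and FID noise each consume an independent
stream derived from the spec seed, so every generator is a pure function
of (spec, seed). In the pipeline, one root seed is split per stage by
stable stage names (CRC-based), keeping reruns byte-identical.

## Numerical and degenerate-input choices

- Fisher p-value ties: tables with probability ≤ observed × (1 + 1e-7) are
  included in the two-sided sum (the enumeration oracle applies the same
  tolerance in exact integer arithmetic).
- Control sampling aborts with the offending peak's name after 1000 draws
  per region on average — pathological exclusion sets fail loudly.
- `frip` raises on zero reads; `bin_enrichment` raises on zero totals;
  empty TSS lists warn and return zero counts.
- Hill fitting bounds h to [0.05, 20] and K to positive values; when 50%
  displacement is never reached, the fit initializes at the median positive
  concentration instead of DC₅₀.

## Known limitations

- Genome-scale results from the original ChIP-seq context (tens of
  millions of reads against hg19) are not reproducible at this scale; the
  statistical checks validate calibration, power and recovery on synthetic
  conditions instead.
- The scanner implements the perfect-tract grammar only — no bulged or
  two-tetrad quadruplexes, and no thermodynamic scoring.
- Fisher's test on pooled controls treats control regions as independent;
  heavy oversampling of a small background (many controls per peak on a
  tiny genome) makes the pooled control row mildly overdispersed. At the
  default conditions the net effect, combined with the discreteness of the
  test, keeps the null rejection rate within the checked band.
- IDR values are consumed as a peak attribute (filter at ≤ 0.01 upstream
  if desired); the replicate-consistency model itself is not implemented.
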