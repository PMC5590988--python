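# Methods

## Problem and model

`insfill` genotypes insertion variants whose breakpoints and approximate
lengths are already known. Each site is reduced to a gap-filling problem:
for a breakpoint *p* on reference *R* and length estimate *d*, the inserted
sequence is reconstructed as a path in a de Bruijn graph of the reads from
the left boundary k-mer *s = R[p−k..p]* to the right boundary k-mer
*t = R[p..p+k]*, with path length close to *d*. Splicing the filled
sequences into the reference reconstructs the donor genome locally.

The de Bruijn graph is a plain directed graph over observed k-mers with
(k+1)-mer edges. Reverse complements of all reads are added before k-mer
extraction so both strands are represented; k-mers are *not* collapsed to
canonical form, which keeps the path-length dynamic program a statement
about a plain directed graph. Ambiguous bases split reads into fragments,
so no k-mer spans an N.

## Exact path-length dynamic program

`count_paths` fills *M[v][i]* = number of walks from the source reaching
*v* at cost exactly *i*, for *i* up to the interval's upper bound; a
breadth-first pass per cost layer adds *M[w][i]* into *M[v][i+c(w,v)]* for
every edge. Properties and choices:

- **Walk semantics.** The recurrence counts walks (vertices may repeat);
  that is what the table means and what the traceback traverses.
- **Saturation.** Counts cap at 2³¹−1. Path counts can be exponential in
  cost; the traceback needs only positivity, so saturation never changes
  which paths are findable. Reported path-multiplicity values (`n_paths`)
  are exact below the cap and a lower bound at it.
- **Positive costs only.** Edge costs must be ≥ 1 (unit on de Bruijn
  graphs). Zero-cost edges would require a within-layer closure the
  layered search does not perform; nothing in this pipeline needs them.
- **Sparse layers.** Each cost layer stores only reached vertices. From a
  flank anchor the reachable frontier is typically a handful of vertices,
  so work scales with the local graph, not with |V|·d.
- **Deterministic traceback.** Among valid costs the one closest to the
  interval midpoint is taken (ties → smaller); at each backward step the
  lexicographically smallest eligible predecessor k-mer is chosen. The
  midpoint preference reflects that the interval is centred on the length
  estimate.
- **Unreachable targets** yield all-zero rows and a clean failure; work is
  bounded by construction at the interval's upper cost layer.

## Gap filling and flank fuzz

A path of cost *c* between two k-mers spells *c + k* characters. With
anchors shifted *a* bases into the left flank and *b* bases into the right
flank, the bases strictly between the original flank boundaries number
*c − k − a − b*; the search accepts costs for which that value lies in
[*d* − slack, *d* + slack] (lower bound clamped at 0). Offsets are tried
in ascending *a + b* (then ascending *a*) and the first success is
returned, making results deterministic; one forward DP per left offset
serves all right offsets. Only the strictly-between bases are reported:
offset-skipped flank bases are re-spelled from the graph path (they may
correct flank errors) but belong to the flank, not the insertion.

Defaults: slack `max(10, ⌈0.1·d⌉)` (tolerates length-estimate noise from
insert-size inference while keeping the DP small), fuzz 10, flank windows
of 2ℓ reference bases per side. Offsets are searched inward only; the
search never extends outward past the breakpoint.

## Read filtering

The filter operates on the gapped coordinate system in which a gap of
length *d* replaces the insertion. Mapped reads overlapping the gap
(≥ 1 bp, half-open intervals) are kept, plus unmapped reads whose mapped
mate starts inside `S_left = [s−(max+2ℓ) .. e−(min+ℓ)]` or
`S_right = [s+(min+ℓ) .. e+(max+ℓ)]`. Since alignments are against the
ungapped reference, the implementation translates these queries back to
reference coordinates (a mapped read overlaps the gap exactly when it
crosses *p*; right-side bounds shift down by *d*).

- **Insert-size convention.** μ and σ describe the *inner* mate distance
  (fragment length minus 2ℓ). Under this convention the printed region
  formulas are exactly the possible mate-start positions of a pair whose
  other read touches the gap; with an outer-distance convention they would
  be systematically offset by read lengths. The simulator uses the same
  convention.
- **Bounds.** min/max = ⌊μ − zσ⌋ / ⌈μ + zσ⌉ with z the two-sided normal
  critical value at the configured confidence (1.96 at the default 95%);
  negative bounds clamp to 0. Regions are clamped at coordinate 0 and
  treated as empty when inverted.
- **Orientation-free.** Mate rescue uses only the mate's start coordinate;
  strand is ignored, as the region formulas are orientation-free.
- **Coverage and fallback.** Realized fold coverage is
  (selected reads × ℓ) / (gap length + 2ℓ); the gap is extended by ℓ per
  side because partially overlapping reads still contribute k-mers. When
  it falls below the threshold — `⌊0.85 · coverage⌋`, e.g. 25 for 30x, 10
  for 15x-class data — every unmapped read is added. Pairs with both ends
  unmapped are reachable only through this fallback.
- **Known limitation.** The rescue regions alone cannot reach recall 1.0
  under Normal insert sizes: reads crossing the left breakpoint whose
  pairs have near-minimum inserts fall just left of `S_right`, and ~5% of
  inserts lie outside the confidence bounds. The full scheme compensates
  through the fallback (which fires precisely when coverage drops), at the
  cost of precision.

Per-site graphs are rebuilt from the selected reads (cheap at the scales
involved) rather than masking a global graph; when the fallback fires,
the k-mer counts of the (site-independent) unmapped read set are computed
once and reused across sites. Without alignments a single global graph
over all reads is shared by every site.

## Synthetic data generator

The generator emulates the evaluation protocol: a uniform random
reference (default 1 Mb), 100 insertions with lengths uniform in
[10..1000] bp (the length distribution is not otherwise constrained, so
uniform is used and exposed), 100 bp pairs at 30x, inner insert distances
Normal(μ, σ) rounded and truncated at 0, second mate reverse-complemented,
optional uniform substitution errors (default 0). Breakpoints are laid on
a minimum-separation grid (2·(μ + 4σ), plus jitter from sorted uniform
offsets) so neighbouring filter regions cannot interact; positions are
therefore near-uniform but not exactly uniform. Pair count is
⌈coverage·|donor|/(2ℓ)⌉.

Truth-mode alignment projects true donor coordinates onto the reference:
any read overlapping an inserted segment by ≥ 1 bp is unmapped, everything
else maps at its shifted coordinate. This is a conservative stand-in for a
real aligner — no soft-clipped partial placements, no mismapping, perfect
mate information. Consequently, passing tests demonstrate the method's
behaviour under ideal alignment and error-free reads; they do not bound
performance on real libraries with error profiles, repeats at breakpoints,
or aligner artifacts.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k | 31 | graph order; also the flank k-mer length |
| min_abundance | 2 (1 for error-free reads) | drops singleton error k-mers at 30x without touching signal |
| slack | max(10, ⌈0.1·d⌉) nt | half-width of the accepted length interval |
| fuzz | 10 nt | max anchor offset into each flank |
| μ, σ, ℓ | 1500, 150, 100 nt | library model (inner insert distance) |
| confidence | 0.95 | insert-size interval → 1.96σ bounds |
| threshold | ⌊0.85·coverage⌋, else 25 | fold-coverage trigger for the unmapped fallback |
| max_cost | d + slack + k (+offsets) | hard cap on DP layers |

## Test and verification scales

The protocol-scale recovery check runs the full pipeline on a 1 Mb
reference with 100 insertions (≈ 157 k read pairs) and verifies that ≥ 90%
of sites whose fill path is provably unique (acceptable-path count exactly
1 at zero offsets) are reconstructed with score exactly 0. Filter-recall
behaviour is checked with the μ=150/σ=15 library on a 250 kb reference, 30
sites, where both length regimes (d < min and d > max insert) are well
populated. The dynamic program is validated against an independent
exhaustive walk-enumeration oracle on random small graphs with cycles, and
the region formulas against a from-scratch re-derivation using the stdlib
normal quantile.

## Known limitations

- Breakpoint *detection* is out of scope; positions and length estimates
  are inputs.
- Calls are haploid: one sequence per site, no heterozygous genotypes.
- Repeat-induced path ambiguity is reported (`n_paths`) but not resolved;
  the deterministic traceback returns one witness path.
- Gap filling requires a length estimate; unknown-length gaps are not
  supported.
- The edit-distance step uses edlib; VCF/SAM/FASTA/FASTQ I/O uses
  pysam/Biopython. The graph, path-length solver, filter and simulator are
  implemented here.
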