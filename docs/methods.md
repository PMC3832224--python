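# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations behind each analysis.  No number stated here is taken
on faith: everything quantitative is recomputed by the test suite or by
`scripts/acceptance.py`.

## Coordinates and sequence handling

All intervals are 0-based half-open internally; GenBank and GFF3
(1-based inclusive) are converted on ingest, BED is passed through.
Circular replicons are linearized at position 0; features or alignments
spanning the origin are not reconstructed — for the genome-scale
statistics and recruitment profiles computed here the effect is confined
to at most one feature per replicon.  Ambiguous bases (N) are excluded
from the GC denominator, excluded from k-mer seeding, and always count
as mismatches inside alignments.

## Streamlining metrics

* **GC content** = (G+C)/(A+C+G+T), case-insensitive.
* **Intergenic spacers**: features of the selected kinds (default CDS,
  rRNA, tRNA) are sorted by start, strand-blind, and each consecutive
  pair contributes `max(0, start_next − end_prev)`.  Overlapping
  neighbours clamp to 0 by default, which keeps the spacer count fixed
  at (#features − 1) and biases the median downward consistently — the
  conservative reading for a streamlining claim.  `policy="exclude"`
  drops overlapping pairs instead.  No strand rule is applied because
  none is standard; both the kind set and the policy are configurable.
* **Coding density** = |union of CDS intervals| / genome length, so
  stacked or duplicated annotations are counted once.

## Local alignment

The aligner is a self-contained seed-and-extend local aligner used by
both ANI and recruitment:

1. **Seeding** — exact k-mer matches on both strands via a sorted-array
   index (k = 13 for reads, 11 for 1020-bp ANI fragments; the smaller k
   keeps seed survival high in the 70–80% identity regime, since a k-mer
   survives 20% divergence with probability 0.8^11 ≈ 9% per position).
   k-mers occurring more than 128 times in the subject are skipped as
   repeats.
2. **Chaining** — seeds are grouped into diagonal bands of width equal
   to the DP band (default 16); the densest one or two bands are
   extended.
3. **Extension** — banded affine-gap Smith–Waterman around the chain
   diagonal: match +1, mismatch −2, gap open −5, gap extend −2 (a gap of
   length L costs −5 −2(L−1)), with full traceback.  The band half-width
   of 16 columns bounds recoverable indel offset; the acceptance oracle
   shows ≥ 99% exact score agreement with an exhaustive unbanded
   Smith–Waterman on 60-bp pairs wherever a seed exists.  Queries with
   no seed are the documented miss class and return no hit.

Percent identity counts gap columns in the denominator
(matches / columns × 100), matching the convention of BLASTN's reported
identity.  Only the single best hit per query is kept (recruitment
counts reads, not HSPs); ties break to the lower subject start, then the
forward strand.  The DP kernel is numba-compiled; results are integer
arithmetic and platform-independent.

## ANI

Fragment-based: non-overlapping 1020-bp query windows (terminal
remainder discarded), retention at ≥ 30% identity over ≥ 70% of the
fragment length, ANI = mean identity of retained fragments.  All three
constants are config keys.  Because the method is asymmetric, both
directions and their mean are reported; the headline value is the
direction whose query id sorts first.  Zero retained fragments yields an
explicitly flagged undefined result.  Local end-trimming of terminal
mismatches biases ANI upward by ≲ 0.2 points at ≤ 10% divergence; the
acceptance suite verifies recovery of planted substitution rates of
1/5/10% within ±0.5 points and monotonicity through 20%.

## Recruitment and islands

Each read is aligned once per genome; the best hit is kept iff identity
≥ 95% and aligned columns ≥ 50 bp (`abs_len`) or ≥ 50% of the read
length (`frac_len`).  Both thresholds are exact at the boundary: 95.0%
and 50 columns pass, 94.99% and 49 columns fail.  Normalized recruitment
is kept hits / (genome Mbp × database Mbp) with database size = total
read bases; the symmetric per-Mbp² form is a declared choice (the
normalization constant cancels in all ratio comparisons) and is
unit-tested: doubling the database with non-recruiting reads halves the
value exactly.  In multi-genome mode a read goes to the highest-identity
genome; exact ties are split 1/n to avoid abundance inflation.

Island calling has no published algorithm to follow, so the defaults are
declared, not inferred: 10-kb windows stepped by 1 kb, windows below
0.2 × the genome-wide median windowed coverage flagged, flagged windows
merged across gaps ≤ 2 kb, merged intervals < 5 kb dropped, labels
GI1..GIn left to right.  With ~10× read coverage, a 10-kb window mean
has a coefficient of variation of a few percent, so the 0.2 threshold is
many standard deviations below the median and false calls are
effectively impossible outside genuinely depleted regions; a window is
flagged only when > 80% of it lies inside a zero-coverage interval,
which bounds call boundaries to within ±2 kb of a true island edge.
An all-zero profile produces a warning and an empty call list, not
wall-to-wall islands.

## Isoelectric points

Net charge at a given pH:

    Z(pH) = Σ_basic  n·10^pKa / (10^pH + 10^pKa)
          − Σ_acidic n·10^pH  / (10^pH + 10^pKa)

with basic groups {N-terminus, K, R, H} and acidic groups {C-terminus,
D, E, C, Y}; unknown residues (X, B, Z) carry no charge.  The pKa table
defaults to the EMBOSS `iep` set (N-term 8.6, K 10.8, R 12.5, H 6.5,
C-term 3.6, D 3.9, E 4.1, C 8.5, Y 10.1) and is selectable; no single
table is canonical, and EMBOSS is the conventional reference.  Z is
strictly decreasing in pH, so bisection on [0, 14] (stop at |Z| < 1e-4
or interval < 1e-4) finds the unique root; the acceptance oracle checks
agreement within 0.01 pH against a 1e-3 grid scan, and single D/K
insertions are verified never to raise/lower the pI.

Proteome profiles bin pI values at 0.2 pH and smooth with a Gaussian
kernel of bandwidth 0.3 pH before peak picking (scipy `find_peaks`,
height ≥ 10% and prominence ≥ 15% of the maximum).  Published virtual
2D-gel figures do not state their smoothing, so these are declared
defaults.  Proteins shorter than 10 aa or containing internal stops are
excluded and counted in the profile's QC field, since pseudogene
fragments distort the density tail.

## Synthetic data

One integer-seeded PCG64 generator (`numpy.random.default_rng`) drives
everything; identical seeds give bit-identical outputs, and every
acceptance simulation is reconstructible from its spec and seed.

* **Genomes**: i.i.d. bases at the target GC; alternating gene/spacer
  layout with ~900-bp genes (normal, rounded to whole codons, min 90 bp)
  and geometric spacers of mean 15 nt — a streamlined layout whose
  coding density (~98%) and spacer median (~10 nt) resemble the genomes
  being emulated.
* **Lineages**: per-base i.i.d. substitutions (always to a different
  base) with a full mutation log, so identity truth is exactly
  computable.  Indels are deliberately excluded from the lineage model —
  they would decouple Hamming distance from alignment identity; the
  aligner's gap handling is exercised separately by the oracle tests.
* **Reads**: members are sampled proportionally to abundance × genome
  length; each read comes from one of 4 lineage copies at the member's
  divergence (default 1%, i.e. clonal microdiversity that still clears a
  95% recruitment cut-off), start positions are uniform with island
  intervals accepted only at their population frequency (frequency 0 ⇒
  no reads), strands are random, and per-base errors (default 0.5%,
  short-read scale) are applied last.  Read length defaults to 100 bp.
  Island carriage is decided per read rather than per lineage — the
  marginal coverage inside an island is exactly `frequency ×` background
  either way, which is the quantity island calling sees.
* **Proteomes**: the halophile style over-weights D/E (≈ 16.5% combined)
  and depletes K/R, giving a single acidic peak (median pI ≈ 4.2); the
  freshwater style is a 60/40 mixture of a mildly acidic and a mildly
  basic compositional class.  The mixture is deliberate: drawing every
  residue from one uniform background makes most proteins nearly
  charge-balanced and produces a single neutral peak, which is not what
  non-halophile proteomes look like — their bimodality comes from
  per-protein compositional polarization, and the two-class model is the
  simplest generator that reproduces it.

What passing on synthetic data does *not* show: real metagenomes have
uneven coverage (GC bias, strain mixtures at varying divergence),
structured errors, and islands that are divergent rather than absent;
the generator models none of these, so thresholds tuned here should be
re-examined on real data.

## Problem sizes and runtime

The default validation scale — 300–500-kb genomes, 50,000 × 100-bp read
sets, 294 ANI fragments per direction, 500–1000 oracle pairs — was
chosen so each statistical check has comfortable resolution (e.g. a
±15% band on a 4:1 ratio at 50 k reads is > 10σ wide) while the whole
suite completes in a few minutes on a single CPU.  Deposited ~1.9-Mb
replicons run through the same code paths unchanged; ANI between two
such genomes takes a few minutes at k = 11.

## Known limitations

* No multi-HSP chaining across distant loci, no E-values, no protein
  alignment; hits longer than the DP band's indel capacity are split or
  clipped rather than chained.
* Origin-spanning features are dropped on linearization.
* ANI here is the fragment (BLAST-style) variant; MUMmer-based ANIm or
  tetranucleotide statistics are out of scope.
* The island caller detects recruitment depletion only; it does not
  distinguish "absent in the population" from "diverged below the
  identity cut-off" (both depress coverage).
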