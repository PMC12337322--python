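# Methods

## The duplex-state model

A CpG dyad carries one of {C, mC, hmC} on each strand, giving nine ordered
duplex states; the canonical order used in every vector, matrix and table
is MM, CC, MC, CM, HC, CH, HM, MH, HH, with the first letter the plus
strand (HC = hmC on plus, CH = hmC on minus). The chemistry induces, per
strand, an (original, copy) call pair: the original call is 1 iff the
cytosine was protected from deamination (mC, hmC), and the copy call is 1
iff maintenance copy-methylation fired, which requires mC on the original
template (glucosylation of hmC blocks it; an unmodified original offers no
substrate). Hence the per-strand decode (1,1) → M, (1,0) → H, (0,0) → C,
with (0,1) impossible, and the quad decode is the product of two strand
decodes. Exactly 9 of the 16 quads are valid; the 7 implausible ones are
precisely those with (original 0, copy 1) on at least one strand. Calls are
ordered `(a, d, b, c)` — original plus, copy of plus, original minus, copy
of minus — because a/d and b/c are the complementary pairs aligned
together.

One deliberate caveat: the decode table is *derived from the chemistry*,
not transcribed from any published lookup figure, and is pinned by tests to
the 9-valid/7-implausible count and to a forward simulation of the
chemistry. Any future discrepancy with an external table should be treated
as a finding, not silently patched.

## Forward simulator

The simulator emulates the laboratory workflow stage by stage. Fragments
are drawn with clipped-normal lengths (default mean 100 bp, s.d. 10 bp,
clipped to [40, 200]) at uniform positions, mirroring sonication plus
size selection of ~100 bp duplexes. Each fragment becomes a hairpin
construct with four converted inserts; reads follow the fixed layout

```
R1 = a + intact hairpin + b + remnant      (truncated at read_len, default 300)
R2 = c + remnant        + d + intact hairpin
```

The protocol constrains only which inserts share a read and which pairs
are complementary; the within-read order above is this package's
convention, shared by simulator and parser. The remnant of the cleaved
(dU-containing) adapter is modeled as a fixed 10 nt suffix of the
cleavable adapter — a delimiter the parser needs; the true remnant length
is a chemistry detail the model does not attempt to capture.

Default adapters are synthetic 25-mers, ≥ 12 substitutions apart, with no
shared 12-mer (validated at construction; violations are a configuration
error because parsing would be ambiguous). Adapter cytosines are treated
as deamination-resistant — as for methylated or otherwise protected
adapter bases — so adapters pass through conversion unchanged. This is
also what makes adapter detection robust: converted inserts are strongly
C-depleted, so a C-containing adapter almost never matches insert sequence
by chance.

Side products (ligation constructs with two adapters of the same type)
carry only the two original strands and lack the target adapter
configuration; they are emitted at `side_product_rate` and removed by the
parser. PCR/cluster duplication appends extra copies of a pair with
probability `dup_rate` each (geometric tail). Sequencing error is a flat
per-base substitution rate; indels and quality modeling are out of scope,
and quality strings are constant (Phred 37) because no stage uses them.

### Chemistry error model — defaults and rationale

| parameter | default | meaning |
|---|---|---|
| `p_fail_deam` | 0.005 | unmodified C escapes deamination |
| `p_overdeam_m` | 0.005 | protected mC deaminated anyway |
| `p_overdeam_h` | 0.01 | protected hmC deaminated anyway |
| `p_copy_fail` | 0.01 | copy-methylation missed opposite mC |
| `p_copy_spurious` | 0.002 | copy-methylation opposite C or hmC |
| `p_seq_err` | 0.001 | per-base substitution |
| `dup_rate` | 0.122 | duplication probability per emitted pair |
| `side_product_rate` | 0.165 | fraction of pairs that are side products |

`side_product_rate` and `dup_rate` reproduce library-level statistics
reported for real runs of this chemistry class (16.5% non-target pairs;
12.2% duplication). The per-enzyme failure rates are not published for the
real kits; the defaults are plausible magnitudes chosen once so that the
resulting per-state call accuracy stays comfortably above the 94% floor
the method class demonstrates on spike-ins (the defaults give ≈ 95–97%
minimum diagonal). They claim no fidelity to any specific reagent lot.

Copy-methylation is decided by the template mark *before* deamination, so
original and copy calls are conditionally independent given the mark;
`strand_outcome_probs` gives the exact outcome distribution and
`analytic_confusion` the exact expected 9×9 call-rate matrix, which the
tests use as the oracle for the sampled pipeline (e.g. with only
`p_overdeam_m = ε`, a true MM site is miscalled MH or HM with mass
2ε(1−ε), from deamination of either copy-strand mC).

## Read processing

A pair is retained iff the intact hairpin occurs at exactly one position
in R1 and the remnant at exactly one position in R2, each within
`max_mismatch` substitutions (default 2; Hamming matching only — the
simulator produces no indels). Rejections are logged by reason
(`no_adapter`, `ambiguous`) and the reasons partition the rejected set.
Because all four inserts of one fragment are equal-length by chemistry, b
and d are trimmed to the length of their complementary partners (a and c,
which are always complete read prefixes); this also disposes of trailing
adapter carry-over in reads long enough to run past the insert. Pairs that
cannot produce four complete inserts are discarded (`incomplete_quad`,
`inconsistent_pair`), never fatal.

## Alignment and calling

Reads in deaminated space are matched under the asymmetric three-letter
rule (read T matches reference C or T; read C only reference C; A/G
exact). The aligner is a k-mer-seeded scanner on the C→T-collapsed
alphabet (default k = 16, three seed offsets per insert, full-length
verification, mismatch budget 5): insert a seeds the plus strand, b the
minus strand, and both must agree on one fragment interval; d and c are
then verified against the opposite strands at that locus but never seed
alignment. A unique best placement is required — ties (e.g. repeated
sequence) leave the quad unaligned. This design removes any external
aligner dependency and is exhaustively checked against a brute-force
every-offset scan on small genomes; it is adequate for the desk-scale
genomes this package targets and is *not* a general-purpose read mapper
(no gaps, no mapping quality, no multi-mapping rescue).

Duplicates are collapsed on the fragment interval alone (coordinate-based
duplicate marking); the lexicographically smallest read name is kept for
determinism. Calls are extracted at every dyad fully inside the fragment;
a non-C/T base at a dyad position (sequencing error) skips that site for
that fragment. Per-site tallies record the nine state counts plus an
implausible-quad count; depth is *double-stranded depth* — one
deduplicated fragment contributes exactly 1 at each dyad it covers, i.e.
one unit equals two single-strand observations.

## Spike-in evaluation and correction

The spike-in panel holds one synthetic ~160 bp duplex per state, each with
four CpGs of that state in otherwise CpG-free sequence, screened to be
free of adapter-like subsequences. All spike-in CpG sites enter the
call-rate estimate. The confusion matrix is **column-stochastic over valid
calls**: entry (i,j) = count(called i | true j) / valid calls on true j,
with the implausible rate reported separately per true state — implausible
calls are discarded downstream and therefore excluded from both **O** and
**P**. The orientation (columns = true states) makes `O = P·T` read
exactly as the correction model. Correction is a direct `solve`; negative
entries are clamped to zero *after* solving and the vector is deliberately
not renormalized — only the clamping step is part of the contract, and the
reported sum makes the deficit visible. The pre-clamp solution, residual
and condition number are always returned; a singular/ill-conditioned
matrix raises with advice to sequence spike-ins deeper. A
simplex-constrained estimator would be a different method and is
intentionally not the default behavior.

## Site summaries

Filters run in the fixed order depth → blacklist → errors (first failing
criterion claims the site): double-stranded depth < 5 by default;
blacklist overlap of the 2 bp dyad; "multiple calling errors" interpreted
as implausible-quad count ≥ 2 (the threshold is a flag — the method class
names the criterion without a number). Per-site output gives each state as
a percentage of valid calls plus the asymmetric groupings MC+CM, HC+CH,
HM+MH. Region means average site percentages over the CpGs a region
contains; regions without CpGs propagate as missing, never zero, and the
same rule applies to empty profile bins so sparse-CpG regions do not drag
profiles toward zero. Shuffled backgrounds place each region uniformly at
random within its own contig, preserving length, without avoiding the
blacklist or other regions (plain shuffle semantics; a documented
divergence risk versus more restrictive shufflers). Binned profiles
support midpoint-anchored windows and body-scaled mode (default
pseudo-length 5 kb, 200 bp bins).

## Synthetic data: what it does and does not emulate

The generator controls CpG-dyad density (realized within ±20% of target at
≥ 10 kb), draws duplex states i.i.d. from a requested composition
(default: a primed-mESC-like mixture — MM ≈ 60%, CC ≈ 22%, hemimethylation
≈ 13%, asymmetric hmC ≈ 5.6%, HH ≈ 0.1%), and keeps non-CpG cytosines
unmodified (they serve only as deamination substrate). It does **not**
model chromatin-domain autocorrelation of states, SNPs, CHG/CHH contexts,
5fC/5caC, coverage bias, or indel errors. Passing tests therefore
demonstrate correctness of the decoding *logic* under the stated error
model, not performance on real libraries with structured error modes.

## Numerical and operational choices

* Problem sizes: the test suite runs on 3–100 kb genomes with 10²–10⁵ read
  pairs; the acceptance script uses 5000 pairs per spike-in state and 10⁵
  fragments for the side-product measurement — sizes at which every
  stochastic check has comfortable statistical margin on one CPU.
* Determinism: every stochastic entry point takes a seed;
  coordinate-duplicate resolution and dedup representative choice are
  name-lexicographic; fixtures are byte-identical across runs.
* All tabular outputs carry a `#` header with tool version and config
  hash; readers skip comments, so the provenance rides along with the
  data.
* Degenerate inputs: empty methylomes fragment to empty lists; contigs
  shorter than the mean fragment length are skipped with a warning; sites
  whose calls are all implausible have undefined percentages (NaN).

## Known limitations

* The aligner's k-mer index is held in a Python dict; memory and build
  time scale linearly and make multi-megabase genomes impractical — by
  design.
* Coordinate deduplication on short references (spike-in duplexes)
  collapses genuinely distinct molecules that happen to share fragment
  coordinates; this mirrors real coordinate-based duplicate marking and
  costs depth, not accuracy.
* Fragments longer than the read layout allows lose their trailing
  inserts and are discarded as incomplete quads (rare at the default
  length distribution; visible in extraction summaries).
* The correction solves a single global 9×9 system; per-region or
  per-depth-stratum correction is out of scope.
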