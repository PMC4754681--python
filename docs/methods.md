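# Methods

This note documents the models, parameter choices and numerical decisions
behind the pipeline, and what its synthetic-data tests do and do not show.

## Distances and the barcode gap

Pairwise distances are computed on pairwise global alignments, not on a
single multiple alignment, so that no record's distance is distorted by
columns induced by unrelated records. The aligner is Needleman–Wunsch with
affine gaps (a gap of length L costs `open + (L−1)·extend`), implemented as
a numba-compiled kernel; traceback ties are broken deterministically
(diagonal > up > left). Distance scoring uses match +1, mismatch −1,
gap open −2, gap extend −0.5 (overridable).

Distances use **pairwise deletion**: columns with a gap or ambiguity code on
either side are excluded. This matters because ITS2 lengths differ by up to
~2× between species; complete deletion would discard most sites. Two models
are reported: the *p*-distance and Kimura's two-parameter correction
`d = −½ ln[(1−2P−Q)·√(1−2Q)]` with transition proportion P and transversion
proportion Q. K2P is the default (the convention in barcoding studies).
When `1−2P−Q ≤ 0` or `1−2Q ≤ 0` the correction is undefined (saturation);
the value is reported as NaN with a warning rather than aborting the matrix.
K2P ≥ p entrywise, and the two agree to 1e-6 below p ≈ 0.001.

The per-species summary takes the min/mean/max of the within-species and
cross-species distance multisets; a species "has a barcoding gap" iff
`inter_min > intra_max`. The headline significance test is a Welch
two-sample t-test (scipy, unequal variances, Welch–Satterthwaite df)
contrasting the 10 per-species `intra_max` values with the 10 `inter_min`
values — with two samples of ~10 values this yields df near 10, matching
the scale of df a study of this design reports. A species with one record
has undefined intraspecific fields (NaN, flagged, not an error).

## Multiple alignment and diagnostic SNPs

SNP discovery needs positional homology, so the MSA uses deliberately stiff
gap costs (open −6, extend −3): with cheap gaps, optimal alignments of
~40%-divergent sequences chase spurious matches and scramble columns, while
a genuine 1–2 bp indel still pays for itself against hundreds of downstream
sites.

The construction is a center-star alignment (deterministic, O(k·n²)): the
center is the record with the smallest summed pairwise distance, every
other record is aligned to it, and gaps are merged slot-wise (per
inter-residue position, the maximum gap run required by any pairwise
alignment; insertions are left-aligned within a slot). One refinement:
records are **routed through their species leader** — each record is
aligned to the member of its own species closest to the rest of that
species (a near-identity alignment with unambiguous gap placement), and
that alignment is composed with the leader-to-center alignment. Without
routing, each noisy individual's indels land independently against a deeply
diverged center and within-species columns drift apart, which empirically
destroys most diagnostic sites in 50-row species. `route_within_species=False`
restores the plain algorithm; an externally computed alignment can be
supplied as aligned FASTA instead.

A **diagnostic site** for species S is a column where every S row carries
the same A/C/G/T base (gaps and ambiguity codes disqualify the column — a
primer 3' terminus cannot sit on an uncertain state) and at most a fraction
`max_offtarget_share` (default 0) of non-S rows carry that base. Raising
the share threshold only ever adds sites.

## Primer design

Candidates are windows (18–25 nt, both strands) of the **majority-rule
species consensus** (gap-majority columns dropped; ties and ambiguity
majorities become 'N' and block windows). Majority rule rather than
unanimity is used for the window body because rare intra-species variants
are tolerated by PCR away from the 3' end; fixation is still required at
the diagnostic columns themselves. Every candidate must cover ≥1 diagnostic
site within its 3'-terminal 3 bases.

Filters (all thresholds configurable; defaults follow the published
criteria):

* GC ∈ [30, 70] %.
* Tm ∈ [50, 65] °C from unified nearest-neighbor thermodynamics:
  `Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15` with the Allawi/SantaLucia
  unified ΔH/ΔS stack table, duplex-initiation terms, entropic salt
  correction `ΔS += 0.368·(N−1)·ln[Na+]` at 50 mM Na+, total strand
  concentration 250 nM (C_T/4 for non-self-complementary duplexes; symmetry
  correction otherwise). The implementation agrees with Biopython's
  independent `Tm_NN` to 0.01 °C under identical conditions. Against the
  published panel's printed Tm values (produced by a proprietary tool whose
  exact model is unknown) agreement is a soft ±5 °C check; 18 of the 19
  unambiguous printed values fall inside, one (printed 65.1 °C) computes
  5.8 °C lower under these conditions.
* |ΔG37| of the 3'-terminal pentamer ≤ 9 kcal/mol (four stacks,
  `ΔG = ΔH − 310.15·ΔS/1000`): overly stable 3' ends promote mispriming.
* Hairpin stem ≤ 3 bp (contiguous self-pairing with a ≥3-base loop) and
  **3'-anchored** self/cross dimer stems ≤ 3 bp. The dimer cap applies to
  duplexes involving a 3'-terminal base — the extensible structures — not
  to the longest stem at any offset: the published panel itself contains
  internal stems up to 10 bp but no 3'-anchored stem above 4, so an
  any-offset cap of 3 would reject the panel wholesale. The any-offset
  statistic is still computed and reported per candidate.
* False priming ≤ 100: the maximum over off-target windows (both strands of
  the whole-library consensus, the candidate's own footprint excluded) of a
  3'-weighted identity, weight 2 on the five 3'-most positions and 1
  elsewhere, scaled to 0–100. At the printed threshold of 100 this only
  rejects perfect off-target duplicates; the threshold is configurable for
  stricter screening.

Pair selection is lexicographic over feasible forward/reverse combinations
(product = 5' of forward to 5' of reverse inclusive, default 100–300 bp,
both footprints non-overlapping): pairs with a 3'-anchored cross-dimer
stem > 3 are disqualified; the rest are ranked by |ΔTm|, then combined
false-priming, then product length, then leftmost forward. Enumeration
order is fixed, so identical inputs give byte-identical candidate lists.

## In-silico PCR

Binding sites are mismatch-counted footprints on both strands (IUPAC codes
in the template match when compatible), by default ≤2 mismatches overall
and **0 in the 3'-terminal 3 bases** — the allele-specific extension logic
that makes SNP-anchored primers specific. An amplicon is any forward(+)
site with a reverse(−) site downstream, product ≤ 2000 bp (the
electrophoretic-detectability stand-in; band intensity and template
dilution are wet-lab chemistry and are not modeled). The specificity matrix
marks a pair × species cell when ≥1 record of the species yields ≥1
product. An unknown is **called** when exactly one pair produces a product
within ±10% of its design fragment; the report includes the nearest library
record by percent identity of the global alignment (terminal overhangs
excluded, internal gap columns excluded from the comparison).

## Synthetic libraries

The generator emulates the sampling frame the analysis assumes, not psocid
biology: a star phylogeny (the analysis only uses intra/inter partitions,
so no nested topology is needed) in which each of 10 species' root cores is
drawn by mutating a shared ancestral core at `inter_div = 0.25`
substitutions/site, truncated to a species-specific length uniform in
293–614 bp; identical 60 bp flanks on all records model the conserved rDNA
regions where universal primers sit. Individuals mutate their species root
at `intra_rate = 0.005` substitutions/site plus indels at 0.002 events/site
(geometric lengths, mean 2). Populations mirror the study's survey: per
species (4, 9, 4, 8, 4, 2, 1, 1, 1, 1) populations — 35 in all — assigned
round-robin to the five study countries, 6 individuals each (210 records).
Substitutions are uniform over the three alternative bases, so realized
transitions ≈ ½ × transversions; no transition bias is simulated (K2P is
still estimable, and tests do not assert a bias). Everything is driven by
one integer seed; regeneration is byte-identical.

What passing tests show — and don't: the simulator guarantees deep
interspecific divergence with species-private fixed differences and
conserved flanks. Real ITS2 data adds features the simulator omits —
rDNA concerted-evolution artifacts, intragenomic ITS2 copy variation,
alignment-hostile microsatellite runs, uneven base composition and real
transition bias — so green end-to-end tests demonstrate the pipeline's
correctness under its stated model, not field performance on real
sequences. Realized inter-species distances under the default
configuration appear as K2P ≈ 0.15–0.25 rather than the naive ≈ 2×0.25,
because optimal alignment of deeply diverged cores legitimately absorbs
part of the divergence into gaps; the barcode gap (two orders of magnitude
between intra and inter) is unaffected.

## Problem sizes and determinism

The default study run aligns all 21 945 record pairs (~1 ms per ~600 bp
pair in the compiled kernel, ~1 min total), builds one MSA (~1 s), designs
10 pairs (~10 s) and screens 10 × 210 templates (<1 s). Acceptance and the
test suite run the full default configuration; oracle-equivalence checks
use 100 randomized small instances per operation against pure-Python
brute-force references. All stochastic tests are seeded; hypothesis
property tests run derandomized.

## Known limitations

* Center-star (even species-routed) is a heuristic MSA; for real data an
  external aligner's output can be supplied instead.
* Nearest-neighbor Tm is computed for perfect duplexes only; mismatch and
  dangling-end thermodynamics are not modeled, and agreement with
  proprietary design tools is approximate by nature.
* Identification inherits allele-specific PCR's sensitivity to noise on
  the 3' anchor: at 1% sequence noise, roughly one sample in ten loses a
  primer's 3'-terminal trinucleotide and yields "no call" rather than a
  wrong call.
* The false-priming screen at its printed threshold is permissive; it is
  retained for fidelity to the published criteria and is configurable.
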