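# Methods

## The model

An LTR retrotransposon inserts as a unit: two identical long terminal
repeats (LTRs) flanking an internal Gag-Pol coding region, the whole
element bracketed by a short target site duplication (TSD, typically
5 bp) created at the insertion site. From that moment the element decays:
each LTR accumulates substitutions independently at the neutral rate μ,
unequal homologous recombination between the two LTRs can collapse the
element to a single LTR that retains its TSD (a recombination solo-LTR),
and accumulated deletions fragment elements into truncated copies (one
LTR plus partial internal sequence) or TSD-less solo LTRs. The package
measures three consequences of this process:

- **Insertion age.** Because the LTRs start identical, their divergence
  dates the insertion. The Kimura two-parameter (K2P) distance
  K = −½·ln(1−2P−Q) − ¼·ln(1−2Q), with P and Q the transition and
  transversion proportions over ungapped, unambiguous aligned columns,
  estimates 2μT, so T = K/(2μ). When a log argument is non-positive the
  pair is reported saturated, with no numeric age. Default
  μ = 1.3×10⁻⁸ substitutions·site⁻¹·year⁻¹.
- **Removal rates.** The ratio of solo (S) and truncated (T) counts to
  intact (I) counts proxies how fast a genome deletes elements relative
  to retaining them. Genome-wide ratios are quotients of summed counts,
  never means of per-cluster ratios; clusters without intact members are
  reported but excluded from per-cluster ratios and from the denominator
  of the proportion of clusters with S:I > 3.
- **Mechanism signature.** Recombination solos keep their TSD; truncated
  elements and fragmentation solos essentially never do. TSD presence is
  recorded descriptively and never reclassifies a remnant.

## Stage-by-stage procedure and key parameters

**Structural detection** (`ltrdyn.detect`). Exact 20-mer seeds shared by
two genome positions are grouped by diagonal; each seed run is extended
into the maximal-scoring matching segment along its diagonal (match +1 /
mismatch −2, Kadane scan), trimmed so each end starts with four
consecutive matches. Boundaries are then refined by searching ±20 bp for
an anchored TSD of 5–6 bp; a snap must keep 12 bp just inside each
boundary matching between the copies (≥7/12) while the 12 bp outside the
TSD copies must not match near-perfectly (<10/12) — the latter is the
signature of a boundary slid into the repeat interior, where flanking
sequence can spell an anchored repeat by chance. Candidates must have
LTRs of 100–3,000 bp, spans of 1–15 kb (read as the 5′-LTR start to
3′-LTR end distance, matching the cited detector's distance options
rather than inter-candidate spacing), and ≥80% LTR–LTR identity from a
global alignment (match +2 / mismatch −3 / gap open −5 / extend −2;
identity = matches ÷ columns). A low-complexity guard discards
candidates whose LTR has <3 distinct bases or whose top two bases make
up ≥90% of it. Overlap resolution keeps the higher-identity, then
longer, then leftmost candidate, which also enforces maximality. TSD
presence is recorded but never required for acceptance.

**Domain scan** (`ltrdyn.domains`). Six-frame translations are locally
aligned (BLOSUM62, gap open −11 / extend −1) against every library
exemplar; a hit needs ≥50% exemplar coverage, >30% identity and
E ≤ 1e-8. E-values follow Karlin–Altschul statistics over an effective
space of (translated length × library length): protein λ = 0.267,
K = 0.041 (the standard gapped BLOSUM62 constants); the nucleotide λ is
solved from the score matrix at import, with K fixed at 0.1 as a
documented heuristic. "Complete Gag-Pol" means all of
{GAG, PR, RT, RH, INT} hit (configurable); the same thresholds serve the
intactness call and the remnant flank scan, since only the flank usage
is specified quantitatively and reusing them keeps one threshold set.
The element's clade is the modal clade label among hits, ties broken
lexicographically. The bundled exemplar library is **synthetic** —
deterministic random proteins labelled with GyDB-style clade names — so
the package is self-contained; real analyses should supply a real
exemplar FASTA.

**Remnant classification** (`ltrdyn.remnants`). Each intact element's
5′-LTR (the clustering stage's exemplar, not a consensus) is searched
against the genome via 16-mer seeds grouped by offset, each candidate
window locally aligned. Hits need E ≤ 1e-10, identity ≥90%, and ≥90% of
the query LTR aligned (the overlap denominator is the query length;
"90% overlap in length" is ambiguous and this reading is documented).
Hit intervals are extended to the full query extent because local
alignment trims mismatching terminal bases, which would misplace the
element boundary and any anchored TSD by a few bp. Intact loci are
masked; overlapping hits from different sources are merged with the
best-scoring source winning, so no locus is double counted. Flanks of
3 kb per side (clipped at sequence ends) are scanned for Gag-Pol:
0 sides hit → SOLO, 1 → TRUNCATED, 2 → AMBIGUOUS. The two-sided case is
an unannotated intact-like locus; it is reported separately and kept out
of the S and T tallies and ratios.

**Dating** (`ltrdyn.dating`). LTR pairs are aligned with the same
deterministic global affine-gap aligner used elsewhere — for two
sequences this replaces a progressive multiple-aligner with an exact,
reproducible equivalent, a deliberate substitution. Gap and N columns
are excluded from the P/Q denominator. Near saturation the aligner
occasionally absorbs mismatch-dense runs into spurious short gaps, which
deflates the estimated divergence slightly: in simulations the mean
estimated age is unbiased at 1 and 5 Mya and about 5% low at 10 Mya
(pairwise divergence ~26%), an alignment artifact shared by any
gap-permitting dating pipeline.

**Clustering** (`ltrdyn.cluster`). Edges require the best local
alignment to cover ≥70% of *both* sequences ("mutually") at ≥60%
identity (superfamily) or ≥80% (family); clusters are connected
components (Silix semantics, implemented over networkx). Remnants join
the cluster of the intact 5′-LTR with the highest alignment score (ties:
higher identity, then lowest intact id) and must themselves satisfy the
same coverage/identity thresholds, else they are reported unassigned and
excluded from ratios.

**Reporting** (`ltrdyn.stats`). Age histograms use half-open 1-Mya bins
over [0, 20) with an overflow bin; saturated elements are counted
separately, so bins + overflow + saturated equals the number of intact
elements dated. Gene proximity is the bp gap to the nearest gene on the
same sequence (0 with an overlap flag when they intersect; ties go to
the lower-coordinate gene), with summary bins {overlap, 0–1, 1–3, 3–5,
5–10, >10 kb}. Elements are reported on plus-strand coordinates with
strand left as an attribute, since the analysis never depends on
orientation.

## The simulator

`ltrdyn.simulate` builds what the pipeline is designed to see: an
order-0 Markov background at GC 0.358 (the composition of the assembly
the analysis models); per family, an ancestral 500-bp LTR and a 5-kb
internal region encoding the five domain exemplars in frame (GAG first,
INT last, spacers only between domains, so any ≥20% truncation fragment
still covers most of one domain); intact elements
(TSD+LTR+internal+LTR+TSD), recombination solos (TSD+LTR+TSD),
fragmentation solos (bare LTR) and truncated elements (LTR plus a random
20–80% internal prefix or suffix). Ages are drawn per element from a
mixture of uniform components — default 70% Uniform(2,10) Mya and 30%
Uniform(0,1) Mya, mirroring an ancient amplification peak plus recent
activity — and both LTR copies evolve independently for that age under
the exact K2P continuous-time process (per-site substitution
probabilities from the closed-form transition matrix at rate μ and
transition/transversion ratio κ = 2), so the dating estimator is
consistent even at 10-Mya divergences where multiple hits matter. No
indel process is applied by default, keeping site counts exact. Loci are
placed with ≥16 kb spacing — above the 15-kb maximum element span, so
solo LTRs of one family can never pair across loci into spurious
structural candidates — and a sparse gene annotation is planted at known
distances. Everything derives from one seeded generator; identical
configs give byte-identical files.

What the simulator does **not** emulate: nested insertions, indels and
rearrangements, gene conversion between LTRs, segmental duplications,
genuine low-complexity and satellite landscapes, and real Gag-Pol
sequence structure. Passing tests therefore demonstrate correctness of
the measurement machinery under the stated element model, not
performance on real assemblies, where nested and degenerate copies make
detection strictly harder.

## Problem sizes and numerical choices

Validation runs use 0.8–2 Mb genomes with 30–50 planted loci and two
families, 200 LTR pairs per age point for estimator calibration, and
≤200-node graphs for the clustering oracle — sizes chosen so the full
suite exercises every stage end-to-end while remaining quick on a
laptop. Determinism is treated as a contract: fixed inputs and config
give byte-identical outputs, verified by manifest content hashes.

Known limitations: detection assumes substitution-dominated divergence
(the seed-and-diagonal search has no indel tolerance beyond overlap
resolution); E-value constants are internal equivalents of BLAST's, not
calibrated against it; clade assignment is by best hit against the
supplied library, with no phylogenetic placement; boundary refinement
prefers TSDs of ≥5 bp, so genuine 4-bp TSDs are reported by the
anchored detector but never move boundaries.
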