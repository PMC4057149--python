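# Methods

This note documents the model, the conventions and the numerical choices
behind `cescan`, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and alphabets

All intervals — genomic, transcript-local, site, window — are 0-based,
half-open, the BED convention; 1-based coordinates appear only in
human-readable messages. miRNA positions follow the field's 1-based 5′→3′
convention (position 1 is the miRNA 5′ end). Transcripts may arrive in DNA
or RNA space: the comparison layer canonicalises T→U, so `CACTCC` and
`CACUCC` are the same target pattern. `N` never pairs and counts as a
mismatch wherever a distance is computed.

## Site discovery

### Seed classes

For a miRNA with seed `s6` (positions 2–7) and `s7` (positions 2–8), the
target-side patterns in target 5′→3′ orientation are

| class   | pattern                      |
|---------|------------------------------|
| 6mer    | revcomp(s6)                  |
| 7mer-m8 | revcomp(s7)                  |
| 7mer-A1 | revcomp(s6) + `A`            |
| 8mer    | revcomp(s7) + `A`            |

The A1/8mer anchor is an adenine on the target opposite miRNA position 1
regardless of the miRNA's first base, the standard convention for these
class names. Each 6mer-core locus is classified once into the most
specific class it supports (8mer > 7mer-m8 > 7mer-A1 > 6mer); ties among
equal classes cannot arise because classification is per core position,
and the leftmost coordinate is inherent in the scan order. Seed pairing is
strict Watson–Crick — no G:U wobble in seed columns — matching the
practice of the seed-based predictors this pipeline is modelled on; wobble
is permitted only in the 3′ region, where thermodynamically it is
tolerated.

### Mismatch tolerance and 3′ compensation

In mismatch mode a locus whose core pairs positions 2–7 (plus the
position-8 column when it pairs) with exactly one mismatched position is
admitted iff the target contains the perfect reverse complement of miRNA
positions 13–18 inside the alignment window, upstream of the site (in the
antiparallel duplex the miRNA 3′ half pairs upstream of the seed on the
target). We chose to test this condition combinatorially (substring
presence) rather than thresholding the alignment score: the two are
equivalent under the default scoring (a present block contributes its full
+30 to the local alignment), and the combinatorial form makes the finder
bit-for-bit comparable to an independent brute-force scanner. The
alignment still reports the paired 13–18 columns. By default mismatch
mode applies to lncRNA transcripts only — the tolerance is described for
lncRNA scanning — and is a flag (`allow_mismatch`) otherwise.

### Alignment window and scoring

The window spans the seed-paired region, the target base opposite miRNA
position 1, and the remaining bases upstream on the target, truncated to
25 in total (and at transcript ends). Including the position-1 base means
a target window that is the exact reverse complement of a 22-nt miRNA
scores 22 × match = 110 — the natural perfect-duplex ceiling — for every
site class.

Scoring parameters (miRanda-like magnitudes): match +5, wobble +2,
mismatch −3, gap open −8, gap extend −2. Seed columns are anchored, not
realigned: Watson–Crick columns earn the match score, the single tolerated
seed mismatch is penalised, an unpaired flanking column (e.g. a non-A1
anchor) contributes 0. The miRNA 3′ tail (positions 9 to the end) is
aligned to the upstream window by a local Smith–Waterman with affine gaps
(Gotoh), so the 3′ contribution is never negative. `min_report_score`
defaults to 0: perfect-seed sites are accepted by class — the score is an
annotation, not a filter — and no minimum alignment score is imposed on
them, a deliberate reading of an underdetermined choice.

## Annotation

Genomic intervals are projected to spliced coordinates through exon
cumulative offsets; minus-strand transcripts are reversed so position 0 is
the transcript 5′ end; intron-spanning intervals split per exon.
Conservation requires the whole seed region inside one conserved block of
length ≥ 8 (shorter blocks are discarded); requiring full containment of
the functional seed is the stringent reading of an unspecified choice.
AGO support needs only ≥ 1 base of overlap because CLIP cluster boundaries
are fuzzy; demanding containment would create false negatives. Both flags
are tri-state: transcripts absent from an annotation source remain
*unknown* (`NA` in TSV), never silently false. Annotation only sets flags;
it never adds or removes sites. Conserved-only / AGO-only analyses are
implemented by filtering the site table and *recomputing* the MRE index,
so numerator and denominator of the score change together.

## Pair statistics

The ceRNA score is denominated by the candidate lncRNA: shared MREs are
the lncRNA's MREs for miRNAs shared with the mRNA, and the denominator is
the lncRNA's total MRE count. This follows the definition of the score as
a property of the candidate gene; a flag reports the mRNA-denominated
variant instead, which changes the score but — by construction — never
m_c or the p-value.

The hypergeometric test is the inclusive upper tail P(X ≥ m_c), the
standard over-representation convention, summed over the support in log
space (`logsumexp` of `hypergeom.logpmf`) so that extreme tails (p ≈
1e-300) remain finite; m_c = 0 returns exactly 1. `M_T` defaults to the
number of distinct miRNAs actually observed, because the universe must
match the panel that was scanned — a genome-wide constant would be
annotation-version dependent; it is overridable. Benjamini–Hochberg
q-values use `scipy.stats.false_discovery_control`.

Pairs are sorted by shared-miRNA count descending, then p-value ascending,
then ids — a total, deterministic order, so identical inputs give
byte-identical tables.

## Expression profiling

Expression is gene-level. Missing abundance is *unknown*, never zero:
every flag is false when either value is absent. Defaults — detectability
1.0 (FPKM-like units) for transcripts and miRNAs, near-equimolar window
2.0-fold — are conventional cutoffs, all overridable; "co-expressed" has
no canonical numeric definition, so the threshold rule is a declared
convention of this package. An optional Spearman correlation across
tissues is provided as clearly-labelled extra output, outside the core
contracts.

## Synthetic data

The generator emulates the statistical structure the pair statistics
assume: per-transcript miRNA target sets drawn from a universe of size
M_T, with 1–3 MREs per realised interaction planted as literal sites in
synthetic transcripts. Default universe: 30 miRNAs, 6 lncRNAs, 8 mRNAs,
independent targeting probability 0.25, 22 named tissues (mirroring the
tissue panels of public RNA-Seq compendia) with log-normal gene
abundances (log-mean 2, log-sd 1), 5% missing cells, and Bernoulli(0.8)
miRNA detectability. These sizes keep every statistic non-degenerate
while a full universe builds in a few seconds.

Backgrounds are guaranteed pattern-free by construction: bases are drawn
one at a time rejecting any completion of a forbidden 6-mer (every panel
seed pattern, its whole one-mismatch neighbourhood, and every 13–18
complement), with randomized depth-first backtracking because some
5-prefixes admit no extension. Plant junctions — windows straddling
written site content and background — are then verified by a full scan
and locally redrawn until the assembled transcript contains exactly the
intended sites and nothing else. Panel seeds are rejection-sampled to
pairwise Hamming distance ≥ 2 and against a small set of shift-collision
constraints, without which writing one miRNA's site could
deterministically create a site of another (or, next to a planted 13–18
block, a shifted spurious site of the same miRNA).

The null-calibration universe uses 2000 designated pairs, each an
independent fresh (lncRNA, mRNA) draw, M_T = 4000 and targeting
probability 0.35. The margins (~1400) make the hypergeometric support
fine-grained; with small margins the discrete inclusive-tail test is
conservative (the achievable tail just below α can sit well under α) and
the fraction of p < α would undershoot for structural, not
implementation, reasons.

**What passing tests show — and don't.** Exact recovery of planted sites
shows the finder implements its stated rules precisely; it does not show
those rules find physiological sites — real transcripts have composition
bias, secondary structure and site accessibility effects the generator
deliberately omits. Likewise the calibration null validates the test's
uniformity under independence, not the biological independence of real
miRNA target sets.

## Known limitations

* No thermodynamic (ΔG) filtering, accessibility or context scores: site
  quality is seed class + complementarity score only.
* Conservation is consumed as pre-computed intervals; the package does not
  score multiple alignments.
* The ceRNA statistics are purely combinatorial; expression-conditioned
  inference (partial correlation, conditional mutual information) is out
  of scope.
* `predict_all` is a per-pair scanner (O(transcripts × miRNAs)); it is
  intended for panels of tens-to-hundreds of miRNAs, not genome-wide
  screens in one process.
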