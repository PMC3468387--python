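# Methods

## Scope and model

`adnamap` treats the identification of endogenous ancient-DNA reads as a
post-alignment classification problem. The aligner itself is external:
`bwa_params` emits the recommended `bwa aln` invocations and the rest of
the toolkit consumes SAM, so every stage can equally run on real BWA
output or on the simulator's truth alignments. All per-position statistics
are computed in read orientation (position 1 = sequencing 5' terminus),
complementing reverse-strand alignments, following the mapDamage
convention. SAM coordinates are 1-based inclusive internally; any exported
interval tables would be BED-style 0-based half-open.

### Edit-distance cap

BWA's read-length-dependent maximum edit distance is the smallest k ≥ 1
such that the upper tail P(X > k) of a Poisson variable with mean
`per_base_error × read_length` falls strictly below the missing-alignment
fraction (`-n`). `per_base_error` defaults to 0.02 (BWA's internal
constant) and is exposed as a parameter. The implementation evaluates the
tail with `scipy.stats.poisson.sf`; the test suite checks equivalence
against a direct term-by-term Poisson summation over lengths 17–250.
Descriptions of these thresholds sometimes attach each mismatch count to
the "shorter than" side of its breakpoint; the Poisson construction is
authoritative here and reproduces the same breakpoint lengths (38/64 nt
for -n 0.04, 34/58 for 0.03, 29/51 for 0.02), so only the phrasing, not
the table, differs.

### High-quality hits and contamination filtering

A hit is high-quality endogenous iff XT:A:U, X1:i:0, MAPQ ≥ `mapq_min`
(default 25) and, when duplicate exclusion is enabled, not flagged 0x400.
A record lacking the X1 tag is treated as non-classifiable (reported
`non_unique` with the reason) rather than assumed to have zero suboptimal
hits. Strict filtering removes any read with a qualifying contaminant hit;
in `any_hit` mode every mapped contaminant alignment qualifies, including
repeats/paralogs (the conservative choice for human contamination), while
`hq_hit` mode requires the contaminant hit itself to be high-quality.
Best-hit filtering retains a read iff NM(target) < NM(contaminant); ties
are filtered, which is conservative and makes Retained(strict) ⊆
Retained(besthit) a structural invariant. Duplicate flags are honoured
only on target alignments — the merged target BAM is where duplicates are
marked — and ignored on contaminant alignments. Orchestration is pairwise
(target vs one contaminant, plus an optional outgroup monitor); no
criterion ever combines three genomes.

### Column reconstruction and NM

The CIGAR+MD walk recovers reference bases at mismatches and deletions
without the reference FASTA. NM is defined as mismatches + inserted +
deleted bases, soft clips excluded (the modern BWA/`samtools calmd`
convention; older tool versions differ, which is why the toolkit
recomputes rather than trusts NM when both MD and CIGAR are present).
Conventions chosen so that tests are deterministic: insertions take the
read position of their first inserted base; deletions take the read
position of the base that follows them *in read orientation* (on the
reverse strand this is the SAM-preceding base, re-indexed). Soft clips are
excluded from substitution denominators and tracked as their own rate
class. Columns containing N in read or reconstructed reference are
excluded from numerators and denominators alike.

### Damage profiles

Substitution rates divide the mismatches of each ordered class at a
position by the count of that reference base observed there; insertion,
deletion and clip rates divide affected bases by read depth at the
position. 15 positions per end are profiled by default; the 3' block is
indexed 1..window inward from the 3' terminus and reported separately.
The cumulative terminal damage statistic (fraction of all mismatches that
are GC→AT within the terminal n positions, default 5) pools both ends by
default, counting a column once even when a short read places it within n
of both ends (tracked via a joint (pos5, pos3) histogram); a 5'-only
variant is exposed. The damage–length correlation uses the 5'-position-1
damage-class rate per read length and Pearson's r with the two-sided
t-transform p-value; zero-variance rates are flagged degenerate instead
of fabricating a coefficient.

### Trimming

Only reads ≥ 30 nt before trimming are candidates; 1 or 2 bases are
removed from the 5' end only (damage concentrates there; 3' trimming and
deeper trimming are out of scope). The mismatch a trimmed base would have
caused is inferred against the genome of the accepted post-trim hit only,
extending the alignment upstream: positions [pos−k, pos−1] on the forward
strand, [end+1, end+k] complemented and reversed on the reverse strand, so
inferred bases line up with trimmed bases in sequencing order; positions
off the contig are unclassifiable. For two-base trims the damage bin
requires both bases to be the damage class (the consecutive-mismatch
reading); an at-least-one variant is exposed. Blind trimming (all
candidates regardless of base identity) is supported alongside
class-conditioned reporting. The post-trim contamination filter is
conservative: a candidate is excluded if either its trimmed or untrimmed
version maps to the contaminant.

### Divergence

d = (transversions + indel bases + 2·AT→GC) / n_sites over aligned
non-masked match/mismatch columns passing the BQ threshold. GC→AT
transitions are excluded because damage inflates them; true-divergence
transitions are symmetric, so the reciprocal AT→GC class is doubled.
Indels are counted per base (sharing the per-site denominator), outside
the end mask, without a BQ condition — deleted bases carry no quality;
this is a documented choice, switchable in principle. Quality-free
(Helicos) columns raise an error rather than silently passing. BQ curves
use cumulative thresholds (BQ ≥ t) by default with a per-bin mode
available. The contingency comparison is Pearson's χ² without continuity
correction, df = 1. No evolutionary-model correction (e.g. Jukes–Cantor)
is applied; rates are raw.

## The simulator

The generator emulates: start-site context bias (11-position PWM over
−5..+5, frequency-product scoring by default, log-odds optional; sampled
by rejection against the maximum attainable score, which bounds memory and
is exact), both strands of each reference (reads that would cross a strand
boundary or contain N are discarded and resampled), the Helicos error
profile (insertions 1.5 %, deletions 3 % per base, substitutions
0/0.5/1.0/1.5 % with substituting and inserted bases drawn from the base
composition), uniform or empirical fragment lengths (default uniform
25–57 nt), the Helicos TT-start trimming (leading runs of ≥ 2 T removed
post-generation with truth coordinates re-anchored; off by default), and
an Illumina profile with a two-level base-quality model (error bases low,
others high). The deamination overlay — C read as T at 5' position i with
probability p₀·decay^(i−1) up to a maximum overhang — is an extension
beyond the error-only model and defaults to off.

Event semantics are chosen so configured rates are exactly the per-base
Bernoulli frequencies of the process: each emitted base is an insertion
with probability `insertion_rate`; otherwise a geometric run of deletion
draws (probability `deletion_rate` each) precedes the consumed template
base; the damage draw is applied to the consumed base before the
substitution draw, and a deaminated base is exempt from substitution, so
every read base carries at most one truth event and oracle tests can
demand exact event recovery. The first consumed base of a read anchors
the alignment and is not subject to the deletion draw (no alignment
begins with a deletion), which is why realized deletion frequency is
measured per deletion *opportunity* (traversed bases minus one per read)
in `realized_error_rates`: deleted/traversed would be biased by a factor
(T−1)/T. A single `random.Random` stream seeded per call makes all output
deterministic across platforms.

The controlled-divergence generator (`diverge_sequence`) substitutes
exactly round(L·d) sites — half transversions, half the transition
available at each site — so a genome pair has divergence d by
construction, with transition directions balanced in expectation under a
balanced composition. `fixture_genomes` adds a conserved (identical)
block to the contaminant and an unrelated outgroup.

What the generator does **not** emulate: real fragment-length
distributions and GC-biased fragmentation, sequence-composition bias of
the Helicos poly-A chemistry beyond the TT-start rule, mapping ambiguity
(every truth alignment is unique with MAPQ 37 — repeats, paralogy and
MAPQ noise are absent), quality-score distributions beyond two levels,
and indel-containing divergence between homologous genomes (divergence is
substitution-only so coordinates stay shared). Consequently, passing
tests demonstrate correctness of the statistics and filters under their
stated models, not performance on repetitive real genomes; contaminant
"mapping failure" in fixtures is emulated by the edit-distance cap, which
is the dominant, but not the only, reason real cross-species alignments
fail.

## Test and acceptance problem sizes

The suite validates the edit-distance model exhaustively over lengths
17–250 against a brute-force Poisson oracle; simulator calibration at
100,000 reads (3-binomial-SD bands on realized insertion and deletion
frequencies); oracle closure — every injected event recovered through
truth SAM and column reconstruction, and the deamination curve recovered
within simultaneous 95% binomial confidence intervals (Bonferroni across
the five overhang positions) — at 20,000 reads on a 100 kb genome;
filter semantics exactly on an 800-read conserved-block fixture;
divergence recovery at 1.0% on a 40 kb genome pair at ~8× read coverage
(binomial CI at the genome size, which dominates the uncertainty at that
coverage); and trimming semantics exactly on a 400-read fixture in which
precisely the deaminated reads fail baseline classification. These sizes
were chosen so each property is measured at meaningful statistical
resolution while the whole suite stays fast enough to run on every
change.

## Known limitations

BAM/CRAM beyond what pysam transparently provides, MAPQ recomputation,
species assignment beyond two genomes, likelihood models of damage
(no rescaling of base qualities), paired-end reads, and workflow-manager
integration are all out of scope. The QC module's adapter matching is
exact-prefix only (≥ 8 nt at the 3' end); the upstream thresholds used by
any particular preprocessing pipeline are configuration, not constants.
Whether a contaminant-side high-quality definition should also demand
MAPQ ≥ 25 is data-dependent; both modes are exposed
(`ContaminantMode.ANY_HIT` vs `HQ_HIT`).
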