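# Methods

This note documents the models, conventions and numerical choices behind
`coralith`, in the order data flows through the pipeline, together with what
the synthetic-data generator does and does not emulate.

## Library model and read simulation

A sample is a pool of four amplicons (16S, 18S, 23S rDNA, *tufA*) built with
tailed locus primers. Each tailed primer is, 5′→3′, a 33 nt overhang tail
(the sequencing-primer binding site), a 0–3 nt random heterogeneity spacer,
and the locus primer. A read therefore begins with its own spacer and primer
and, when the amplicon is shorter than the read length, runs through the far
end into the reverse complement of the opposite primer followed by the
reverse complement of the tail and then adapter sequence.

The simulator reproduces this structure with one deliberate simplification:
the heterogeneity spacer appears only at each mate's own 5′ end, not in the
read-through copy of the opposite construct. The read-through segment is
then exactly `revcomp(tail + opposite_primer)`, which is also the pattern
the stripping step searches for — simulator and pipeline share one
well-defined chemistry. In real data the stripped pattern would be jittered
by 0–3 nt; the mismatch tolerance of the search (2 by default) absorbs small
perturbations but this jitter is not exercised by the generator.

Qualities follow a deterministic linear decay: Phred 38 at the 5′ base,
0.02 units lost per base, floored at 2. Sequencing errors are drawn per base
with probability 10^(−Q/10) (switchable off via `SimConfig.quality_errors`
for noise-free runs); template-level PCR substitutions are a separate
per-base rate (default 10⁻³). Chimeras are two-parent recombinants of
same-marker templates with a single uniform breakpoint at least 50 nt from
each end. Negative controls receive a fixed number of contaminant read pairs
(default 5) drawn uniformly from all templates.

Default per-sample depth is 2000 pairs. Real runs of this design produce
~160k reads per sample; desk-scale depths keep the suite fast and every
structural property (read-through, spacers, merging geometry, filter
arithmetic) is depth-independent. Amplicon lengths are set per marker
(290/380/410/450 nt including primers) so that 16S exercises the
read-through path while the other three exercise overlap merging.

What the generator does **not** emulate: indel sequencing errors, PCR
efficiency/length bias, index hopping at the sample level, quality jitter
around the decay line, and abundance-dependent chimera formation. Passing
tests therefore demonstrate correctness of the pipeline's logic and
arithmetic on structurally realistic reads, not robustness to every
real-world artifact.

## Demultiplexing and read preparation

Primer matching is IUPAC-aware with expansion-set intersection semantics
(an observed N is compatible with any code), scanning spacer offsets 0–3 and
choosing the offset with the fewest mismatches (ties → smallest offset).
A pair is assigned to a marker only if the forward primer matches read 1
*and* the reverse primer matches read 2, and to exactly one marker —
conflicting evidence goes to `unassigned`. This both-mates rule is
deliberately conservative; a panel is rejected at load time if any two
primers are within twice the mismatch tolerance of each other.

Read-through stripping only honours matches at or after position 30:
spacer (≤3) + primer (≥15) means no legitimate biological signal can start
earlier, and the guard prevents degenerate truncation. Partial signatures
at the 3′ end count if at least 10 pattern bases remain in the read.

Merging scans all overlaps ≥ 10 nt between read 1 and the reverse
complement of read 2, scores each by mismatch ratio, takes the minimum
(ties → longest overlap) and rejects above ratio 0.25 — the published
defaults of the classical overlap-merging approach. Consensus keeps the
higher-quality base; consensus quality is max(Q) at agreements and |Q1−Q2|
at disagreements. The 3′ trim is fixed-length (default 50 nt of 300),
config-exposed; a read trimmed below 30 nt is dropped. The mean-quality
keep rule is inclusive (mean Phred ≥ 35). Global primer trimming requires
the forward primer within 3 nt of the 5′ end and the reverse-complemented
reverse primer within 3 nt of the 3′ end (the trailing tolerance absorbs
the opposite spacer surviving in the merged sequence), removes both, and
enforces the per-marker minimum core length.

Every stage maintains a conservation ledger (input = kept + each rejection
class), checked by tests and reported in the run manifest.

## Identity, clustering and chimeras

Identity between amplicons is defined operationally: global alignment at
match +1 / mismatch −1 / gap open −2 / gap extend −1, identity = matching
columns over alignment columns excluding terminal-gap columns. Terminal
gaps are excluded so ragged amplicon ends (different merge extents) do not
depress identity; internal gaps count against it. Traceback ties are broken
deterministically (substitution > gap-in-second > gap-in-first, gaps closed
as early as possible), so identity is a pure function of the input pair.
The implementation is a vectorised Gotoh DP, pinned against an
independently written plain-Python DP in the tests.

Clustering is greedy and abundance-ordered: dereplicated sequences (sorted
by abundance, ties lexicographic) are recruited by the most similar centroid
at or above the marker threshold (ties → larger centroid, then earlier OTU),
otherwise chimera-screened, otherwise promoted. Centroids are never
re-centred, making output order-stable and deterministic. Read mapping back
onto centroids uses the marker's clustering threshold (the alternative — a
flat 97% for all markers — is a one-line config change).

The chimera verdict projects the query's global alignment against each
eligible parent (abundance ≥ 2× the query) onto query coordinates and asks
whether some breakpoint splits the query into a left segment ≥ 99% identical
to one parent and a right segment ≥ 99% identical to another, while no
single parent reaches > 97%. Within a run where both parents agree the
junction is unidentifiable, so the reported breakpoint is the centre of the
optimal plateau. Parameters (2× skew, 0.99/0.97) follow the published
de novo defaults and sit in `ChimeraParams`.

## Taxonomy

The classifier is the classical naive Bayes word model: words are 8-mers
counted presence/absence per sequence; the genus-conditional probability is
(m(w)+Pr(w))/(M+1) with corpus prior Pr(w)=(n(w)+0.5)/(N+1). Queries are
scored in log space over their full word set; 100 bootstrap trials rescore
a ⌈W/8⌉ random subsample (with replacement) and vote a genus. The
confidence at each rank is the fraction of votes agreeing with the
assignment's lineage at that rank, which is monotone from domain to genus
whenever the reference lineages are tree-consistent. Ranks below the 0.7
reporting threshold render as `unclassified_<deepest confident parent>`.

## OTU filters

Order is fixed: negative controls → per-sample minimum → dataset minimum.
The order matters (zeroing sub-threshold cells lowers row totals before the
dataset cut) and is pinned by a regression test. "Exceed N" is strict (> N)
by default; the inclusive (≥ N) reading is a flag. Negative-control hits
remove the OTU from the entire dataset rather than subtracting counts —
a control read marks the OTU as a contamination/tag-jump suspect, which is
not quantitative information.

## Trait evolution

The endolithic character is binary; the Mk transition matrix has gain rate
q01 and loss rate q10 (per million years on a dated tree), with the
closed-form 2×2 transition probability used throughout (no matrix
exponentials). The likelihood is Felsenstein's pruning recursion with
per-node rescaling; it is tested for exact equality against brute-force
enumeration over internal-state assignments on trees up to 8 tips.

Fitting maximises the likelihood over log₁₀-rates in [−8, 2]: bounded
scalar search for the equal-rates variant, Nelder–Mead for
all-rates-different. Monomorphic tip data returns the zero-rate boundary
with an explicit warning rather than a silent fit. The default root prior
is the model's stationary distribution (flat selectable); under a flat
prior the whole inference is symmetric under label swap, which is tested.

Stochastic maps are exact draws from the posterior over histories: node
states are sampled jointly (root from prior × partials, each child from the
parent-conditional times its partials), then each branch path is drawn from
the CTMC conditioned on its endpoints by uniformization — the number of
uniformized jumps is drawn from its exact conditional distribution, jump
times are uniform order statistics, virtual jumps collapse out. This has no
discretisation error at any rate; the zero-rate limit is handled explicitly
(constant path, or a named error if the endpoints are incompatible).

Origins are counted per map as the number of 0→1 segment boundaries summed
over branches, plus one if the root itself is in state 1 — the root origin
convention is a definition choice, documented here and pinned by tests.
Per-node ancestral probabilities are the fraction of maps with the node in
state 1; they converge to the analytic marginals from the up–down pruning
pass, and the test suite checks this agreement with exact binomial tails at
the 3σ family-wise level (a per-node Gaussian band is invalid for nodes
whose expected count over the map sample is below ~1).

Calibration problem sizes in the tests — 5000 maps on a 50-tip tree, rate
recovery as the mean of 20 maximum-likelihood estimates on 300-tip trees,
origin recovery over 50 simulated histories of 100 tips with 150 maps each —
were chosen as the smallest sizes at which the Monte-Carlo and estimator
noise is well inside the asserted bands.

## Synthetic phylogenies

Trees are birth–death simulations conditioned on the number of extant tips
via the general sampling approach (plain n-tip conditioning stops exactly at
a birth event and produces zero-length pendant edges). The character is
simulated forward along branches with exact exponential waiting times, and
every transition event is recorded so inference can be compared to truth.

## Determinism

Every random component takes a seed; compound workflows derive per-stage
seeds by SHA-256 hashing of the global seed with the stage name (always
< 2³¹), so adding a stage never shifts another stage's stream. Fixed seed
implies byte-identical FASTQ, tables, newick strings and map sets, which
the test suite asserts at file level.

## Known limitations

- No denoising/ASV inference; OTUs are identity clusters by design.
- The classifier has no organelle-specific reference curation; garbage
  references give confidently wrong assignments, as for any naive Bayes.
- Uniformization cost grows with rate × branch length; extremely high rates
  on long branches would be slow (not a regime a dated species tree visits).
- Tree inference, alignment to references and time calibration are out of
  scope: the evolution module consumes a finished dated tree.
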