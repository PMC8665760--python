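# Methods

This note documents the models, parameter choices and numerical decisions
behind `famscape`, and what the synthetic benchmarks do and do not show.

## Alignment model and statistics

Local alignment is Smith–Waterman/Gotoh with affine gaps under BLOSUM62.
A gap of length k costs `gap_open + k·gap_extend` (defaults 11/1, the
standard BLOSUM62 setting). Every alignment is internally a *profile*
alignment: a sequence is expanded to the matrix of its substitution-matrix
rows, so the identical dynamic program scores sequence–sequence and
PSSM–sequence comparisons. This makes the round-0 profile search reduce
exactly to pairwise alignment. Traceback tie-breaks are fixed (diagonal,
then gap in the first sequence, then gap in the second), so results are
deterministic. Ambiguous residues (B, Z, X, …) score 0 against everything.

Alignment `identity` counts identical residue pairs over all alignment
columns, gap columns included in the denominator; `coverage` is the aligned
span on the shorter sequence over that sequence's length. These are the
definitions commonly used by redundancy-filtering tools, to which the
filter thresholds refer. Where a "global-style" identity is needed (family
separation diagnostics), identical pairs are divided by the shorter
sequence's full length instead, since a short local alignment between
unrelated sequences otherwise reports a deceptively high identity.

Chance scores follow an extreme-value (Gumbel) law. `calibrate_evalue`
aligns n pairs of independent background-composition sequences (background:
the Robinson–Robinson average amino-acid frequencies) and fits location and
scale by maximum likelihood; then `λ = 1/scale` and
`K = exp(loc/scale)/(m·n)` with m·n the calibration search space, giving
`E = K·m·n'·e^{−λs}` and `P = 1 − e^{−E}` (pairwise mode `n' = len_b`,
database mode `n'` = total database residues). No analytic λ/K exists for
gapped alignment, hence the empirical fit. Because integer matrices put
scores on a unit lattice, a continuity correction places each observation at
its bin midpoint (+0.5) before fitting; without it the fitted location is
biased half a bin low. With the correction, P-values of fresh shuffled pairs
are uniform to a Kolmogorov–Smirnov statistic of ~0.02 at n = 2000, and the
fraction below 0.01 is 0.010 ± 0.003. Fitted values for 200-residue pairs
are λ ≈ 0.28, K ≈ 0.05, in line with published gapped BLOSUM62 statistics.

Profile searches recalibrate per profile (PSSM log-odds are not on the
matrix scale): 500 shuffled sequences of the database's median length, with
a seed derived deterministically from the run seed and the profile's seed
id, so reruns are bit-reproducible.

## Synthetic superfamilies

The generator emulates the statistical situation of a large database
containing one structural clan: families share a core fold carrying an
invariant catalytic motif — modelled on the Ntn-hydrolase active site
(Thr/Ser nucleophile at the core N-terminus, Asp, Lys, oxyanion-hole Gly;
default 0-based core positions 0/16/32/46 on a 180-residue core) — while
everything else diverges.

Evolution is a star topology. A family founder is the template ancestor
with family-specific insertions (at template-declared sites) and N-/C-
extensions, optionally pre-diverged from the template (`founder_divergence`,
default 0.3 so that two families drawn from one template are distinct
lineages). Members derive from the founder by independent per-site
substitution outside the motif; the substitution probability is solved from
the pairwise-identity model `r = f_motif + (1−f_motif)·(q² + (1−q²)·c)`
(q = per-site retention, c ≈ 0.059 the background coincidence probability)
and then refined in up to three calibration rounds against the realized
local-alignment identity of sampled member pairs, landing within ±0.02 of
the target in practice (the contract is ±0.05). Motif residues are never
mutated and member records carry their (insertion-shifted) motif
coordinates. There is no post-founding indel process and no phylogenetic
tree — deliberate simplifications; consequences below. Decoys are
background-composition sequences with lengths uniform over the member
length range, so length alone cannot separate them.

**Ancestor groups.** The discovery benchmark plants 8 families of 40
members (intra-family identity 0.35) in two groups: five families whose
founders derive from one group ancestor and three from an unrelated
ancestor (same motif), plus 50 decoys. The founder-from-group-ancestor
divergence is 0.5, chosen to place related families squarely in the
remote-homology regime: founder–founder identity ≈ 0.3, member–member
cross-family E-values 10³–10⁶ above the 1e-10 clustering cutoff (so
families stay separate components), while iterated 40-member PSSMs — which
approximately score against the family ancestor — cross family borders at
E ≤ 1. Seeds are single members of three group-A families; the remaining
two group-A families are then reachable only through profile chaining and
novelty re-seeding, and the group-B families are not. Because all families
share the catalytic motif, a rare chance hit at E ≤ 1 can legitimately
chain into the second group in some instances, exactly as the real protocol
would; cluster purity is unaffected. The profile-comparison benchmark uses
a shallower within-group divergence (0.35) and two groups of three
15-member families, emulating subfamily blocks.

## Search, screening and discovery

PSSMs use background-proportional pseudocounts of total weight β = 20 and
half-bit log-odds (`2·log2(freq/background)`), the BLOSUM scale, so the
substitution gap penalties stay applicable; with zero hits the PSSM is
exactly the seed's matrix rows. Hits enter the next PSSM at E ≤ 1 — the
published cutoff — provided they pass the motif screen: the residues
aligned to the seed's catalytic positions must match with at most one
mismatch (default 1, because the nucleophile position alternates Thr/Ser).
The screen is the automated stand-in for manual alignment inspection; no
structure-prediction fallback exists, so doubtful members are simply
rejected. Accepted sets are unions over rounds (monotone), and iteration
stops when the set stops growing or at 6 rounds.

The discovery loop follows the published protocol: per round, searches from
all pending seeds; pooling with exact-duplicate removal and fragment
removal (a record contained in a longer one at ≥ 0.95 identity over ≥ 0.95
of its length); greedy redundancy filtering (0.9 identity, 0.7 coverage;
0.7 identity is available for very large families); all-vs-all clustering
at P ≤ 1e-10 with a minimum cluster size of 10; novelty detection (a
cluster is novel iff it contains no node that has served as a seed) and
outlier detection ("few or no connections" quantified as a configurable
maximum link fraction, default zero); re-seeding with each novel cluster's
central member (highest summed −log10 P to co-members) and each unsearched
outlier. Termination: no new pool entries, or no pending seeds, or the
round cap (flagged unconverged).

## Cluster maps and layout

Clustering is connected components at the stated P cutoff — the
reproducible reading of transitive cluster usage; no interactive convex
clustering. Cluster ids are deterministic (size, then smallest member id).
The 2D force layout uses edge attraction proportional to
`min(−log10 P, 40)/40` times distance (P floored at 1e-40 to cap weights)
and pairwise `k/d` repulsion, with capped, cooled displacement steps from a
seeded random start; it is used for visualization only — no quantitative
result depends on coordinates beyond the planted-cluster separation check.
CLANS files are written in the text dialect (`sequences=`, `<seq>`, `<pos>`
with z = 0, `<hsp>` with `i j:p`), round-tripping byte-identically.

## Profile comparison

Family profiles are built from progressive MSAs (average-linkage guide tree
on pairwise identity; global affine profile alignment on expected
substitution scores). Columns with ≥ 50% gaps are dropped; the consensus is
the column majority (ties by fixed residue order) and the representative is
the member scoring highest against the consensus (ties by id). Pair scores
are a local DP over columns with the symmetrized log-odds·probability dot
product; significance comes from a Gumbel fit to 200 column-shuffled pairs
(shuffling permutes the precomputed score matrix, so nulls are cheap), and
results are reported as −log10 E floored at 0, with E ≥ 1 rendered as 0.
This is a deliberate simplification of HMM–HMM Viterbi comparison: the
contract is the *relative* similarity structure (self maximal, within-group
above between-group), not any external tool's absolute E-values.

## Problem sizes and limitations

Test and acceptance runs use desk-scale sizes chosen as the package's
standard conditions: the 370-record benchmark above, 50 mixed 30-record
sets for the filter contract, 40 random ≤ 12-node graphs for cluster
calling, 2000/5000 shuffled pairs for calibration, and an enumeration
oracle over all 4-letter pairs of length ≤ 2 plus a seeded sample of
length ≤ 5 pairs (full exhaustion of the length-≤ 5 space is ~10⁶ pairs
against an exponential-path oracle and adds nothing beyond the sample).

What passing these tests shows — and does not. The generator's families
are star topologies with uniform substitution and no post-founding indels,
so alignment within a family is essentially ungapped and MSA construction
is easier than for real families; recall and ARI numbers here are upper
bounds on real-data behavior. Real databases also contain compositionally
biased and repetitive sequences that the background model does not emulate,
so the decoy false-positive rates are optimistic. The E-value model fits a
single length regime per run (median database length) rather than
length-corrected statistics per pair. Structure prediction, taxonomy and
genomic-context analyses that a full family study would add are out of
scope.
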