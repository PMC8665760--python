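# famscape

Remote-homology discovery and cluster mapping for divergent protein
superfamilies.

Many protein families — the proteasome-like (Ntn-hydrolase) family is the
motivating case — consist of members whose pairwise sequence identity has
decayed to 20–35%, near or below the detection limit of direct pairwise
comparison. The classical way to expand such a family is *transitive*
searching: start from a few characterized seeds, run profile-iterated
searches (PSI-BLAST-style), pool and de-redundify the hits, cluster them in
a force-directed P-value map (CLANS-style), identify clusters that cannot be
traced to any seed plus unclustered outliers, use those as new seeds, and
repeat until the map stops growing. `famscape` implements that entire
protocol as a tested, reproducible library — together with a synthetic-data
generator that plants divergent families with known ground truth, so every
stage can be validated quantitatively without touching a sequence database.

## What is inside

- `famscape.synth` — superfamily simulator: a shared core fold with a pinned
  active-site motif (Thr/Ser nucleophile, Asp, Lys, oxyanion Gly), families
  diverged from founders by point substitution to a target identity,
  family-specific insertions/extensions, ancestor *groups* that create the
  remote-homology regime, and unrelated decoys.
- `famscape.align` — Smith–Waterman/Gotoh local alignment (BLOSUM62, affine
  gaps) with Karlin–Altschul-style statistics: the chance-score Gumbel
  `P(S ≥ s) ≈ 1 − exp(−K·m·n·e^{−λs})` is fitted by maximum likelihood on
  shuffled background sequences; `E = K·m·n'·e^{−λs}`, `P = 1 − e^{−E}`.
- `famscape.redundancy` — greedy longest-first identity/coverage filtering
  (the nr90/nr70 reductions: identity 0.9 or 0.7 at coverage 0.7).
- `famscape.psearch` — PSSM construction with background pseudocounts,
  profile-to-sequence search at E ≤ 1 with per-profile recalibration, an
  automated active-site motif screen, and iteration to convergence.
- `famscape.clustermap` — all-vs-all P-value graph, connected-component
  cluster calling (discovery at P ≤ 1e-10 with ≥ 10 members, maps at 1e-3),
  novel-cluster/outlier criteria, force-directed 2D layout, CLANS-format I/O.
- `famscape.discovery` — the orchestration loop with pooling, duplicate and
  fragment removal, provenance tracking and re-seeding.
- `famscape.profiles` — per-family progressive MSAs, consensus and
  representative (medoid) selection, and profile–profile comparison with a
  column-shuffle null, reported as negative E-value exponents (−log10 E).

A thin `famscape` CLI (`simulate`, `filter`, `search`, `discover`, `map`,
`heatmap`) wraps the library; `examples/` holds one narrative script per
capability.

## Worked example

`examples/04_discovery_and_map.py` runs the full protocol on the benchmark
database (8 families × 40 members at ~35% intra-family identity in two
ancestor groups, 50 decoys; seeds are single members of three families):

```
round 1: searched 3 seeds, pool 200, clusters 5, novel 2, outliers 0
round 2: searched 2 seeds, pool 200, clusters 5, novel 0, outliers 0
cluster 0: 40 members, truth ['famA1']
cluster 1: 40 members, truth ['famA2']
cluster 2: 40 members, truth ['famA3']
cluster 3: 40 members, truth ['famA4']
cluster 4: 40 members, truth ['famA5']
wrote discovery_map.clans
```

Round 1 searches from the three seeds already pull in the two unseeded
families of the same ancestor group through profile iteration; their
clusters contain no seed, are flagged *novel*, and their central members are
re-seeded. Round 2 adds nothing new, so the pool has reached its fixed
point. The five clusters coincide exactly with the planted families (the
three families of the unrelated ancestor group are not reachable and stay
absent); decoys never pass the E-value cutoff plus motif screen. The
resulting `discovery_map.clans` file can be opened in the CLANS viewer.

`examples/05_family_heatmap.py` prints the profile-comparison matrix for a
two-group simulation; exponents within an ancestor group average ~8 while
between-group pairs sit near 0 (E ~ 1) — the block structure expected for
subfamily groups.

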