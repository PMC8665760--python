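"""Simulate a labeled superfamily database and inspect its structure.

Builds the canonical benchmark: 8 families x 40 members at ~35% intra-family
identity in two ancestor groups, plus 50 unrelated decoys, every non-decoy
record carrying the Thr/Asp/Lys/Gly active-site motif at annotated
coordinates.
"""

import itertools

import numpy as np

from famscape import standard_benchmark, sw_align

bench = standard_benchmark(rng_seed=1)
records = bench.records
families: dict = {}
for rec in records:
    families.setdefault(rec.family, []).append(rec)

print(f"records: {len(records)}  families: {len(families) - 1}  decoys: {len(families['decoy'])}")
print(f"designated seeds: {', '.join(bench.seed_ids)}")
print(f"reachable families: {', '.join(bench.reachable_families)}")

rng = np.random.default_rng(0)
for fam in ("famA1", "famB1"):
    members = families[fam]
    pairs = list(itertools.combinations(members, 2))
    sample = [pairs[i] for i in rng.choice(len(pairs), 30, replace=False)]
    ident = np.mean([sw_align(a.seq, b.seq).identity for a, b in sample])
    print(f"{fam}: {len(members)} members, mean pairwise identity {ident:.2f}")

rec = families["famA1"][0]
print(f"motif check {rec.id}: positions {rec.motif_positions} -> "
      f"{''.join(rec.seq[p] for p in rec.motif_positions)}")
# Intra-family identity sits near the 0.35 design target; the motif string
# is TDKG in every non-decoy record.
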