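"""Leakage-free Bemis-Murcko scaffold splitting.

Groups molecules by their scaffold (ring systems plus linkers, side chains
removed) and fills train, then validation, then test greedily with whole
groups, so no scaffold ever spans two sets — a harder, more realistic
generalization test than random splitting.
"""

import molmpnn as mm

molecules = mm.gen_molecules(mm.FixtureSpec(n_molecules=100, seed=42))
split = mm.scaffold_split(molecules, ratios=(0.8, 0.1, 0.1))
print(f"sizes: train={len(split.train)} valid={len(split.valid)} "
      f"test={len(split.test)}")

scaffolds = [mm.murcko_scaffold(s) for s in molecules]
parts = [{scaffolds[i] for i in part}
         for part in (split.train, split.valid, split.test)]
leakage = (len(parts[0] & parts[1]) + len(parts[0] & parts[2])
           + len(parts[1] & parts[2]))
print(f"distinct scaffolds per set: {[len(p) for p in parts]}")
print(f"scaffolds shared between sets (leakage): {leakage}")
print("example test-set scaffold:", sorted(parts[2])[0] if parts[2] else "-")
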