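"""Frequent-itemset mining on five hand-written patient lists.

Each line is one patient's set of 3-character diagnosis categories over
the study window.  At a 60% minimum support threshold, a pattern must
appear in at least ceil(0.6 * 5) = 3 of the 5 lists.
"""

from morbidmine import MinerConfig, filter_multimorbidity, mine_frequent_itemsets

patients = [
    {"I10", "G47", "E78"},
    {"I10", "E78"},
    {"G47"},
    {"I10", "R06"},
    {"I10", "R06", "E78"},
]

patterns = mine_frequent_itemsets(patients, MinerConfig(min_support_fraction=0.60))
print("frequent patterns at 60% support:")
for p in patterns:
    print(f"  {'+'.join(p.items):12s} support={p.support_count}  prevalence={p.prevalence:.2f}")

multimorbidity = filter_multimorbidity(patterns)
print("\nmultimorbidity patterns (2+ conditions):")
for p in multimorbidity:
    print(f"  {'+'.join(p.items):12s} support={p.support_count}")

# Expected output: I10 (4/5), E78 (3/5 — exactly at the threshold, which is
# inclusive) and the pair E78+I10 (3/5); only the pair counts as
# multimorbidity.
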