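"""Bioactive GA/ABA ratios over imbibition.

Germination commitment tracks the balance of bioactive gibberellins
(GA4, GA7, GA1, GA3) against ABA.  With GA rising and ABA being
catabolized during imbibition, the GA/ABA ratio climbs several fold above
the dry-seed baseline; the pathway partition shows which hydroxylation
branch supplies the GAs.
"""

from seedtherm import HormoneProfile, bioactive_ga, ga_aba_ratio, \
    pathway_partition

profiles = [
    HormoneProfile("dry", {"GA4": 0.5, "GA7": 0.1, "GA1": 0.05, "GA3": 0.0,
                           "GA24": 8.0, "GA15": 5.0, "GA19": 0.4,
                           "GA44": 0.2, "ABA": 6.0}),
    HormoneProfile("8h", {"GA4": 1.2, "GA7": 0.3, "GA1": 0.1, "GA3": 0.0,
                          "GA24": 7.0, "GA15": 4.0, "GA19": 0.4,
                          "GA44": 0.2, "ABA": 3.0}),
    HormoneProfile("24h", {"GA4": 2.5, "GA7": 0.6, "GA1": 0.2, "GA3": 0.1,
                           "GA24": 5.0, "GA15": 3.0, "GA19": 0.3,
                           "GA44": 0.2, "ABA": 1.0}),
]

table = ga_aba_ratio(profiles, [0.0, 8.0, 24.0])
print(table[["sample", "time_h", "bioactive_ga", "aba", "ratio",
             "fold_vs_dry"]].to_string(index=False))
# fold_vs_dry > 1 means the balance has tipped towards germination.

part = pathway_partition(profiles[0])
print(f"\ndry seed GA branches: 13-non-hydroxylated {part.non_13oh:.2f} "
      f"vs 13-hydroxylated {part.oh13:.2f} -> dominant: {part.dominant}")
print("bioactive pool in dry seed:", bioactive_ga(profiles[0]))
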