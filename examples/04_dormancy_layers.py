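"""Decompose a treatment G_max ladder into dormancy layers.

Freshly harvested dormant black #1 seeds germinate to ~10% in water, ~60%
after GA (or after-ripening) and >90% under GA + ethephon + KNO3.  Taking
the full-release value as the viability ceiling, the ladder says 2/3 of
the viable population carries at most nondeep physiological dormancy and
1/3 a deeper layer needing ethylene + nitrate.
"""

from seedtherm import decompose_layers

ladder = {"water": 10.0, "ga": 60.0, "ga_e_kno3": 90.0}
d = decompose_layers(ladder)

print(f"treatment ladder: {ladder}")
print(f"viable fraction (ceiling):        {d.viable_fraction:.2f}")
print(f"non-dormant (water-germinating):  {d.f_nd:.3f}")
print(f"nondeep PD (GA/AR-releasable):    {d.f_npd:.3f}")
print(f"deeper PD (needs GA+E+KNO3):      {d.f_dpd:.3f}")
print(f"ND + nPD together:                {d.f_nd + d.f_npd:.3f}  (= 2/3)")
print(f"\nsame fractions over all seeds sown: {d.of_all_seeds}")
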