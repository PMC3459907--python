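"""Mixed Nash equilibrium of the inspector game.

The 2x2 game between a lazy employee (work/shirk) and an employer
(inspect at cost i / pass) has no pure equilibrium; the generic
indifference solver recovers the unique mixed one for any cost.
"""

import popgrad as pg

print("cost i   p_shirk  p_inspect  employee value  employer value")
for i in (0.1, 0.2, 0.3, 0.5, 0.7):
    nash = pg.inspector_mixed_nash(pg.InspectorConfig(i))
    print(f"  {i:.1f}     {nash['p_shirk']:.3f}    {nash['p_inspect']:.3f}"
          f"       {nash['v_employee']:.3f}           {nash['v_employer']:.3f}")

print("\nAt equilibrium the employee shirks exactly with probability i (the")
print("inspection cost) and the employer inspects half the time; the")
print("employee earns 0.5 per trial regardless of i, the employer 2 - 2i.")
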