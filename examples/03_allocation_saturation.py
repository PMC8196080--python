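"""Why access saturates against nets-per-capita.

Runs the net-to-household allocation mechanism at several misallocation
levels m and prints achieved population access against NPC. At m=0 (perfect
targeting) access follows the linear planning assumption; with misallocation
it plateaus, which is why procuring one net per 1.8 people (0.56 NPC) does
not deliver the predicted 0.9 access.
"""

import numpy as np

from itncover import allocation_curve, linear_access, procurement_npc
from itncover.synth import default_household_size_pmf

pmf = default_household_size_pmf()
print("NPC    linear    m=0.0    m=0.5    m=1.0")
curves = {m: allocation_curve(m, pmf, seed=1) for m in (0.0, 0.5, 1.0)}
for npc in (0.1, 0.2, 0.3, 0.4, 0.5, 0.56):
    row = [f"{np.interp(npc, c['npc'], c['access']):.3f}"
           for c in curves.values()]
    print(f"{npc:.2f}   {linear_access(npc):.3f}    " + "    ".join(row))

print(f"\nWHO procurement quantity: one net per 1.8 people = "
      f"{procurement_npc(1.8):.2f} NPC")
print("-> under the linear assumption 0.5 NPC yields 0.9 access; with "
      "misallocated nets the realised access falls visibly short.")
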