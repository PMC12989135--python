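"""Label decoy poses with DockQ against their native reference.

DockQ combines Fnat (recovered native contacts), iRMS (interface backbone
RMSD) and LRMS (ligand RMSD after receptor superposition) into one [0,1]
quality score; >= 0.8 counts as a native-like (positive) pose.
"""

import numpy as np

from poseqa import FixtureConfig, dockq, label_from_dockq
from poseqa.synthetic import make_native_complex, perturb_ig_side

native = make_native_complex(FixtureConfig(), seed=3)
rng = np.random.default_rng(0)

print(f"{'rot(deg)':>9} {'trans(A)':>9} {'Fnat':>6} {'iRMS':>6} {'LRMS':>7} "
      f"{'DockQ':>6} label")
for rot, trans in [(0, 0), (2, 0.4), (8, 1.5), (20, 5.0), (60, 20.0)]:
    decoy = perturb_ig_side(native, rot, trans, 0.0, rng)
    r = dockq(decoy, native)
    print(f"{rot:9.0f} {trans:9.1f} {r.fnat:6.2f} {r.irms:6.2f} {r.lrms:7.2f} "
          f"{r.dockq:6.3f} {label_from_dockq(r.dockq)}")
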