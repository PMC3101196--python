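"""Classify conformers in the (aperture angle, RMSD) plane.

Toy C-alpha scaffolds are generated at prescribed aperture angles (the angle
at a conserved active-site residue between the two domain anchors), rigidly
superposed on an open reference, and placed in open/intermediate/closed/
super-closed zones.
"""

from tightbind import (
    StateZoneConfig,
    aperture_angle,
    classify_state,
    generate_conformer,
    kabsch_superpose,
)
from tightbind.geometry import StateZone

zones = StateZoneConfig([
    StateZone("O", 90, 110, 0.0, 5.0),
    StateZone("I", 84, 90, 0.0, 5.0),
    StateZone("C", 74, 84, 0.0, 5.0),
    StateZone("S", 40, 74, 0.0, 5.0),
])

reference, markers = generate_conformer(target_delta_ap=97.0, seed=0)
for label, angle in [("open", 97.0), ("intermediate", 87.0),
                     ("closed", 79.0), ("super-closed", 65.0)]:
    model, _ = generate_conformer(target_delta_ap=angle, seed=3)
    delta = aperture_angle(model, markers)
    _, _, rmsd = kabsch_superpose(model, reference)
    state = classify_state(delta, rmsd, zones)
    print(f"{label:13s}: delta_ap = {delta:6.1f} deg, rmsd = {rmsd:5.2f} A -> {state}")

# Real zone boundaries must be calibrated on a real ensemble; the only
# anchored number is that independent open structures superpose below 0.25 A.
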