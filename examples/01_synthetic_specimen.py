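"""Generate a synthetic ungual and a fragmentary, noisy copy of it.

Builds the parametric claw shell (curved arc axis, tapering cross-section,
lateral blood grooves, ventral flexor tubercle), then degrades it the way
real fossils present: distal end missing, an excavation artefact punched
out, scanner noise along the surface normals. Writes both as OBJ.
"""
from pathlib import Path

import morphodist as md

out = Path("output_synthetic")
out.mkdir(exist_ok=True)

params = md.ClawParams(n_rings=24, n_theta=16)
intact = md.make_claw(params)
print(f"intact claw: {intact.n_vertices} vertices, {intact.n_faces} faces, "
      f"Euler characteristic {intact.euler_characteristic()} (closed shell)")

spec = md.DegradationSpec(distal_fraction_removed=0.35, hole_center=0.1,
                          hole_radius=2.0, noise_sd=0.05, seed=1)
fragment, report = md.degrade(intact, spec, params)
print(f"fragment: kept {report.kept} vertices "
      f"(removed {report.removed_distal} distal, {report.removed_hole} in the hole)")

md.write_mesh(intact, out / "intact.obj")
md.write_mesh(fragment, out / "fragment.obj")
print(f"wrote {out}/intact.obj and {out}/fragment.obj")
# The fragment is an open shell: only its surviving vertices will carry
# distance values in a later comparison, exactly like a trimmed scan.
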