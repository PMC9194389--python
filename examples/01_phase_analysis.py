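"""Phase analysis of a single synthetic gated polar map.

Builds a mildly dyssynchronous left ventricle, simulates its gated
count curves with Poisson noise, and runs the first-harmonic phase
analysis: per-sample contraction-onset phases, the global indices PSD
(phase standard deviation) and PBW (phase histogram bandwidth), scar
burden and wall thickening.
"""

import numpy as np

import spectpa as sp
from spectpa.simulate import default_archetype, gen_gated_counts, gen_phase_field, gen_scar_field

geometry = sp.PolarGeometry(n_rings=10, n_angles=36, n_frames=8)

# true contraction-onset phase field of a mild-pattern ventricle
spec = default_archetype(sp.PatternLabel.MILD)
field = gen_phase_field(spec, geometry, seed=42)
scar = gen_scar_field(geometry, spec.scar_fraction, seed=43)

# forward model: harmonic count modulation + Poisson counting noise
gated = gen_gated_counts(field, scar, a0=1000.0, seed=44)

pmap = sp.compute_phase_map(gated)
idx = sp.dyssynchrony_indices(pmap)
perf = sp.perfusion_map(gated)
scar_res = sp.scar_mask(perf)
thick = sp.compute_wall_thickening(gated, mask=~scar_res.scar_mask)

err = sp.circular_diff(pmap.phase_deg[pmap.valid_mask], field[pmap.valid_mask])
print(f"valid samples          : {int(pmap.valid_mask.sum())} / {geometry.n_samples}")
print(f"phase recovery RMSE    : {np.sqrt(np.mean(err**2)):.2f} deg (vs generating field)")
print(f"PSD                    : {idx.psd_deg:.2f} deg  (true field {spec.target_psd_deg} deg target)")
print(f"PBW                    : {idx.pbw_deg:.1f} deg")
print(f"scar burden            : {scar_res.scar_burden_pct:.1f} %")
print(f"median wall thickening : {thick.summary_pct:.1f} % (non-scar samples)")
print()
print("PSD/PBW are the global dyssynchrony indices; values at or below")
print("40.3/111.9 deg mark the mild dyssynchronous contraction pattern.")
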