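"""Contraction-pattern classification of the four archetypes.

Generates one noisy gated study per contraction pattern (mild
dyssynchronous, U-shaped, heterogeneous, homogeneous), runs the imaging
pipeline and prints the classified label with its evidence: block
lines, delayed-segment clusters and the segmental phase range.
"""

import logging

import spectpa as sp
from spectpa.pipeline import PipelineConfig, analyze_gated
from spectpa.simulate import default_archetype, gen_gated_counts, gen_labelled_field

logging.disable(logging.WARNING)

geometry = sp.PolarGeometry(10, 36, 8)
cfg = PipelineConfig()

print(f"{'truth':<14} {'label':<14} {'PSD':>6} {'PBW':>6} {'blocks':>6} {'clusters':>8} {'range':>6}")
for pattern in sp.PatternLabel:
    spec, field = gen_labelled_field(
        pattern, default_archetype(pattern).target_psd_deg, geometry, seed=7)
    gated = gen_gated_counts(field, None, a0=1000.0, a1_ratio=spec.a1_ratio, seed=8)
    res = analyze_gated(gated, cfg)
    idx, pat = res["indices"], res["pattern"]
    print(f"{pattern.value:<14} {pat.label.value:<14} {idx.psd_deg:6.1f} {idx.pbw_deg:6.1f} "
          f"{len(pat.block_lines):6d} {len(pat.delayed_clusters):8d} {pat.phase_range_deg:6.1f}")

print()
print("A block line is a >=90 deg phase jump between adjacent segments;")
print("a cluster is a connected group of segments contracting >=45 deg")
print("after the mean. Two clusters -> heterogeneous; one cluster behind")
print("a block -> U-shaped; a monotone septum-to-lateral ramp -> homogeneous.")
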