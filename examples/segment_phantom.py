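"""Segment a synthetic soil core with the five-step protocol and score it.

Builds a 96-cube phantom (three unconnected roots, mineral fill 0.5, organic
debris, one-voxel partial-volume blur), runs the protocol with example areas
sampled the way an operator would pick them, and compares the result with the
exact ground truth.
"""

import rootct as rc

spec = rc.PhantomSpec(shape=(96, 96, 96), seed=3)
volume, truth = rc.generate_phantom(spec)
soil_examples, root_examples = rc.example_coordinates(volume, truth, seed=1)

params = rc.ProtocolParams(soil_examples=soil_examples,
                           root_examples=root_examples,
                           min_component_voxels=2000)
result = rc.run_protocol(volume, params)
report = rc.evaluate(result, truth)

for step in result.step_log:
    print(f"step {step['step']} ({step['name']}): "
          f"{step['foreground_voxels']} foreground voxels")
print(f"root volume: {result.root_volume_mm3:.2f} mm^3 "
      f"(truth {truth.root_volume_mm3:.2f} mm^3)")
print(f"Dice {report.dice:.3f}  recall {report.recall:.3f}  "
      f"precision {report.precision:.3f}")
print(f"components found/true: {report.component_count_found}"
      f"/{report.component_count_true}")
# Dice near 1 and a matching component count mean the protocol recovered all
# root segments individually despite debris and partial-volume voxels.
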