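"""A catheter infusion into synthetic white matter, two tissue models.

Generates a uniform white-matter phantom (fibres along x, FA 0.7,
VF_ECS 0.30, 1 mm voxels), infuses 3 uL/min of tracer for 180 s through a
catheter at the centre, once with the constant-permeability DTI baseline and
once with the VF_ECS-dependent DTI-NODDI permeability, then compares the
two plumes.
"""

import numpy as np

import cedsim as cs

phantom = cs.generate_phantom(cs.PhantomSpec(shape=(32, 32, 32),
                                             voxel_size=1.0))
inputs = cs.CaseInputs(tensor=phantom.tensor, fa=phantom.fa,
                       noddi=phantom.noddi, mask=phantom.mask)
catheter = cs.CatheterSpec(tip_mm=(0.0, 0.0, 0.0), orientation=(1, 0, 0))
config = cs.SimulationConfig(dt=2.0)   # 180 s total, 0.01/min loss

results = {}
for mode in ("dti", "noddi"):
    res = cs.run_case(inputs, catheter, config, mode=mode)
    region = cs.infusion_region(res.final_concentration, catheter.c0)
    direction = cs.principal_direction(region)
    results[mode] = (res, region, direction)
    print(f"{mode:>5}: infusion volume {region.volume_mm3:5.1f} mm^3, "
          f"PCA axis {np.round(direction, 3)}, "
          f"L_max {cs.penetration_length(region, direction):.1f} mm, "
          f"peak c/c0 {res.final_concentration.data.max()/catheter.c0:.2f}")

(res_d, reg_d, dir_d) = results["dti"]
(res_n, reg_n, dir_n) = results["noddi"]
print(f"\nRMSD between models: "
      f"{100*cs.rmsd(res_d.final_concentration, res_n.final_concentration, catheter.c0):.1f}%")
print(f"angle between PCA axes: {cs.angle_between(dir_d, dir_n):.2f} deg")
print(f"volume overlap (Jaccard): "
      f"{cs.overlap_fraction(reg_d, reg_n):.0f}%")
print("\nBoth plumes elongate along the fibre axis (k_par >> k_perp), but")
print("the VF_ECS-dependent permeability changes how far and how sharply")
print("the tracer spreads — the quantity a surgeon would plan around.")
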