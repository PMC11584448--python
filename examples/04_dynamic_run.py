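"""Dynamic running simulation with validation metrics.

Drives the torso base with a synthetic 120 Hz clavicle trajectory
(filtered with the zero-lag 4th-order Butterworth at 6 Hz), integrates the
breast response with implicit Newmark dynamics from the gravity-loaded
state, extracts per-component kinematics at the gait events, and computes
the two validation statistics (RMAE against the driving signal at the
clavicle, surface-to-surface distance between two simulated surfaces).
"""

import numpy as np

import breastfem as bf

mesh = bf.build_anatomy(bf.AnatomyParams(mesh_size_fine=14.0,
                                         mesh_size_coarse=22.0))
materials = bf.material_table()
bcs = bf.BoundaryConditions.from_mesh(mesh)

raw = bf.build_synthetic_gait(duration=1.2, amp_y=30.0, amp_x=10.0,
                              noise_sd=0.5, seed=3, ramp_cycles=1.0)
traj = bf.butterworth_zero_lag(raw, fc=6.0)

model = bf.FEModel(mesh, materials)
static = bf.solve_static(mesh, materials, bcs, model=model)
dyn = bf.solve_dynamic(mesh, materials, bcs, traj, dt=0.005, n_steps=152,
                       static_prestate=static, model=model)

events = bf.detect_events(traj, half_cycle=0.38, index=1)
print("gait events (s):", {k: round(v, 3) for k, v in events.as_dict().items()})

kin = bf.extract_component_kinematics(dyn, mesh)
frames = events.frames(dyn.times)
for ev in ("t2", "t4"):
    snap = {c: round(float(k["displacement"][frames[ev]]), 2)
            for c, k in kin.items()}
    print(f"total displacement at {ev} (mm): {snap}")
print("Components farther from the chest wall travel farther: the nipple "
      "leads, the driven clavicle trails.")

# RMAE of the simulated clavicle against the (noisy) experimental signal
clav = mesh.node_sets["clavicle"][0]
sim_y = dyn.nodal_displacement[:, clav, 1]
exp_y = raw.resample(dyn.times)[:, 1]
r = bf.rmae(exp_y, sim_y, eps=0.5)
print(f"clavicle vertical RMAE vs raw signal: {100 * r:.2f} % "
      "(driven point reproduces the filtered input, so the error is the "
      "discarded noise)")

# surface distance between the deformed surface and a 1 mm-offset copy
seq = bf.SurfaceSequence.from_simulation(dyn, mesh, frame_stride=25)
offset_frames = [(verts + np.array([0.0, 0.0, 1.0]), tris)
                 for verts, tris in seq.frames]
ref = bf.SurfaceSequence(times=seq.times, frames=offset_frames)
d = bf.surface_distance(seq, ref)
print(f"surface-to-surface distance to a 1 mm offset copy: {d:.3f} mm "
      "(sanity check of the nearest point-to-triangle averaging)")
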