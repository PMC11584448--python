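"""Internal-stiffness sweep: how gland / ligament stiffness moves the
breast surface.

Re-runs the dynamic simulation over the five-level Young's modulus grids
(gland 5-15 kPa in 2.5 kPa steps; Cooper's ligaments 80-160 kPa in 20 kPa
steps), reads the nipple total displacement at the gait events t1..t4 of a
steady half-cycle, and fits displacement vs E per event by ordinary least
squares.  Writes a tidy CSV per sweep plus a JSON fit summary.
"""

import json
from pathlib import Path

import breastfem as bf

out = Path("scratch/sweeps")
out.mkdir(parents=True, exist_ok=True)

mesh = bf.build_anatomy(bf.AnatomyParams(mesh_size_fine=16.0,
                                         mesh_size_coarse=26.0))
materials = bf.material_table()
traj = bf.butterworth_zero_lag(bf.build_synthetic_gait(
    duration=1.2, amp_y=30.0, amp_x=10.0, noise_sd=0.5, seed=3,
    ramp_cycles=1.0))
config = bf.SweepConfig(mesh=mesh, materials=materials, trajectory=traj,
                        dt=0.005, n_steps=152, half_cycle=0.38,
                        event_index=1, event_window=0.095)

for component in ("gland", "ligament"):
    sweep = bf.stiffness_sweep(config, component, verbose=True)
    sweep.to_frame().to_csv(out / f"sweep_{component}.csv", index=False)
    (out / f"sweep_{component}_fit.json").write_text(
        json.dumps(sweep.fit_summary(), indent=2))
    print(f"{component}: slope (mm/kPa) per event "
          f"{ {k: round(v, 4) for k, v in sweep.slope.items()} }")
    print(f"{component}: Pearson r per event "
          f"{ {k: round(v, 3) for k, v in sweep.correlation.items()} }")

print("A negative slope means a stiffer internal component lets the nipple "
      "travel less at that event.  On this synthetic anatomy the trend is "
      "clearly negative at t4 (the braking extremum, where effective load "
      "peaks) and flat-to-positive at t2, where the torso's downward "
      "acceleration cancels most of gravity; see docs/methods.md.")
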