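# Scenario 1: fully sampled 3D EPI at 3 mm, 5 min run, single coil.
# Full scale (60 x 71 x 60); expect several minutes of compute.
phantom:
  shape: [60, 71, 60]
  voxel_size: [3.0, 3.0, 3.0]
paradigm: {on_s: 20.0, off_s: 20.0}
sequence: {TR_shot_ms: 50.0, TE_ms: 25.0, FA_deg: 12.0, Tobs_ms: 25.0}
trajectory: {kind: epi}
engine: {kind: t2s, snr_in: 1000.0, L: 1}
roi: {center_mm: [0.0, -60.0, 0.0], semi_axes_mm: [27.0, 27.0, 27.0], gm_threshold: 0.5}
recon: {method: adjoint}
analysis: {p: 0.001}
run: {length_s: 300.0, seed: 0}
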