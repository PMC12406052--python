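# Scenario 3: externally optimised 3D trajectory imported from file
# (set trajectory.path to a container written by write_trajectory).
phantom:
  shape: [64, 64, 64]
  voxel_size: [1.0, 1.0, 1.0]
paradigm: {on_s: 20.0, off_s: 20.0}
sequence: {TR_shot_ms: 50.0, TE_ms: 25.0, FA_deg: 12.0, Tobs_ms: 25.0}
trajectory: {kind: import, path: trajectory.ktraj}
engine: {kind: t2s, snr_in: 30.0, L: 32}
roi: {center_mm: [0.0, -20.0, 0.0], semi_axes_mm: [10.0, 10.0, 10.0], gm_threshold: 0.5}
recon: {method: cs, strategy: cold, mu: auto, max_iter: 100, tol: 1.0e-5}
analysis: {p: 0.001}
run: {length_s: 300.0, seed: 0}
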