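# Desk-scale fully sampled Cartesian scenario: 16^3 grid, 40 s run.
phantom:
  shape: [16, 16, 16]
  voxel_size: [3.0, 3.0, 3.0]
paradigm: {on_s: 10.0, off_s: 10.0}
sequence: {TR_shot_ms: 50.0, TE_ms: 25.0, FA_deg: 12.0, Tobs_ms: 25.0}
trajectory: {kind: epi}
engine: {kind: basic, snr_in: 1000.0, L: 1}
roi: {center_mm: [0.0, -12.0, 0.0], semi_axes_mm: [12.0, 12.0, 12.0], gm_threshold: 0.5}
recon: {method: adjoint}
analysis: {p: 0.001}
run: {length_s: 40.0, seed: 0}
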