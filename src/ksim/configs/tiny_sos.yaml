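# Desk-scale stack-of-spirals scenario: 16^3 grid, 4 shots per frame.
phantom:
  shape: [16, 16, 16]
  voxel_size: [3.0, 3.0, 3.0]
paradigm: {on_s: 2.0, off_s: 2.0}
sequence: {TR_shot_ms: 50.0, TE_ms: 25.0, FA_deg: 12.0, Tobs_ms: 30.0}
trajectory: {kind: stack_of_spirals, center_frac: 0.125, AF: 7, dynamic: false, n_samples: 256, n_turns: 6}
engine: {kind: t2s, snr_in: 1000.0, L: 2}
roi: {center_mm: [0.0, -12.0, 0.0], semi_axes_mm: [12.0, 12.0, 12.0], gm_threshold: 0.5}
recon: {method: cs, strategy: refined, mu: auto, max_iter: 15, tol: 1.0e-4}
analysis: {p: 0.001}
run: {length_s: 8.0, seed: 0}
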