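# Scenario 2: variable-density stack of spirals at 3 mm, 8 coils,
# ~10% centre planes always sampled, AF = 4 on the outer planes.
phantom:
  shape: [60, 60, 60]
  voxel_size: [3.0, 3.0, 3.0]
paradigm: {on_s: 20.0, off_s: 20.0}
sequence: {TR_shot_ms: 50.0, TE_ms: 25.0, FA_deg: 12.0, Tobs_ms: 30.0}
trajectory: {kind: stack_of_spirals, center_frac: 0.1, AF: 4, dynamic: true, n_samples: 3000, n_turns: 14}
engine: {kind: t2s, snr_in: 1000.0, L: 8}
roi: {center_mm: [0.0, -60.0, 0.0], semi_axes_mm: [27.0, 27.0, 27.0], gm_threshold: 0.5}
recon: {method: cs, strategy: refined, mu: auto, max_iter: 100, tol: 1.0e-5}
analysis: {p: 0.001}
run: {length_s: 300.0, seed: 0}
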