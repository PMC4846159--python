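# Default end-to-end run configuration.  Every tunable named here is the
# package default; CLI flags override individual entries.
construct: CP4-AB
sheet:
  n_strands: 3
  strand_spacing: 5.0        # Angstrom along X between adjacent strands
  flip: alternating          # alternating | literal-two-of-three
triad:
  cutoff: 5.0                # Angstrom, applied to all three pairs
  pair_mode: all             # all | bridge
  chain_mode: any            # any | intra | cross
trajectory:
  n_frames: 400
  frame_spacing_ps: 20.0
  jitter_sigma: 0.3          # Angstrom per coordinate
  window_ps: null            # null -> second half of the trajectory
  plant:
    enabled: true
    occupancy: 0.6
    # the dominant cross-chain triad: S1 and H10 of one chain with the
    # amyloid C-terminus of the adjacent chain
    hydroxyl: [A, 1]
    his: [A, 10]
    acid_cterm: [B, 19]
kinetics:
  noise_sigma_AU: null       # null -> fixture default
  duration_s: 1800.0
  dt_s: 5.0
  rate_window_s: 120.0
  endpoint_s: 1200.0
  reference_panel_id: 2
seed: 1
write_trajectory_pdb: false
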