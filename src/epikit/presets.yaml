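# Named sequence-parameter presets (3 T protocol: FOV 200 mm, TR/TE 2200/30 ms,
# grey-matter T2* 66 ms).  epi64: standard single-shot EPI, 64 phase-encode
# lines at 0.510 ms actual echo spacing.  epik96: EPI-with-keyhole, 96 lines,
# keyhole = one-fourth of k-space, 3 peripheral interleaves, 0.890 ms actual
# echo spacing (effective 0.445 ms/line).
epi64:
  scheme: EPI
  matrix_py: 64
  matrix_ro: 64
  fov_mm: 200.0
  te_ms: 30.0
  tr_ms: 2200.0
  echo_spacing_ms: 0.510
  keyhole_fraction: 1.0
  n_interleaves: 1
  t2star_ms: 66.0
epik96:
  scheme: EPIK
  matrix_py: 96
  matrix_ro: 96
  fov_mm: 200.0
  te_ms: 30.0
  tr_ms: 2200.0
  echo_spacing_ms: 0.890
  keyhole_fraction: 0.25
  n_interleaves: 3
  t2star_ms: 66.0
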