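# Versioned coefficient sets of the phenomenological proton RBE models.
#
# mcn: McNamara model (2015 proton fit).  RBE_max is affine-increasing in
#      LET_d/(α/β)_x, RBE_min affine-decreasing in sqrt((α/β)_x)·LET_d:
#        RBE_max = p0 + p1 · LET_d / (α/β)_x
#        RBE_min = p2 + p3 · sqrt((α/β)_x) · LET_d
# ror: Rørvik unweighted (non-spectrum) model:
#        RBE_max = 1 + lambda · LET_d / (α/β)_x,  RBE_min = 1.
# jon: Jones-type model, tissue dependence through α_x and β_x separately:
#        RBE_max = 1 + c_max · (LET_d − let_offset) / sqrt(α_x)
#        RBE_min = 1 + c_min · (LET_d − let_offset) / sqrt(β_x)
#      NOTE: this coefficient set is a synthetic reconstruction.  The
#      original Jones coefficients were not available in numeric form, so
#      the three constants below were calibrated against the published
#      2 Gy prediction table for four tissues at six LET_d values; the
#      calibrated form reproduces all 24 published cells within ±0.01.
version: 1
mcn:
  rbe_max_intercept: 0.99064
  rbe_max_slope: 0.35605       # Gy · µm/keV
  rbe_min_intercept: 1.1012
  rbe_min_slope: -0.0038703    # Gy^-1/2 · µm/keV
ror:
  lambda: 0.645                # Gy · µm/keV
jon:
  let_offset: 0.192758         # keV/µm
  rbe_max_slope: 0.103502      # Gy^1/2 · µm/keV
  rbe_min_slope: -0.0077250    # Gy · µm/keV
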