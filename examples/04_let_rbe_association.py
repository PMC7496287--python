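"""Test the LET_d–RBE association with linear regression and an F-test.

Derives experimental RBE at the 10% survival level for every proton
condition of two simulated cell lines (one radiosensitive high-(α/β)_x,
one radioresistant low-(α/β)_x) and regresses RBE on LET_d.
"""

import numpy as np

import rbekit as rk
from rbekit import study
from rbekit.lq import points_from_frame

rng = np.random.default_rng(3)
design = rk.AssayDesign()

for cell in ("FaDu", "Du145"):
    arch = rk.study_archetypes()[cell]
    fit_x = rk.fit_lq(points_from_frame(rk.compute_surviving_fractions(
        rk.simulate_assay(design, arch, study.XRAY_CONDITION, rng))))
    estimates = []
    for cond in study.PROTON_CONDITIONS:
        fit_p = rk.fit_lq(points_from_frame(rk.compute_surviving_fractions(
            rk.simulate_assay(design, arch, cond, rng))))
        estimates.append(rk.rbe_at_survival(fit_x, fit_p, 0.10, cond, cell))
    res = rk.fit_rbe_vs_letd(estimates)
    print(f"{cell}: slope = {res.slope:+.3f} ± {res.se_slope:.3f} RBE per keV/µm, "
          f"F(1,{res.n - 2}) = {res.f_stat:.2f}, p = {res.p_value:.4f}")

print("\nA small p-value indicates the RBE rises with LET_d; in the "
      "emulated study this association appears in the low-(α/β)_x line "
      "but not the high-(α/β)_x line.")
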