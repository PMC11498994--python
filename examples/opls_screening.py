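"""OPLS spectrum-effect models and the joint screening rule.

Fits one OPLS model per antioxidant index on the reference dataset
(relative areas as X, one orthogonal component, unit-variance scaling),
then applies the rule: a peak is a candidate when VIP > 1 with a
positive coefficient, and a core candidate when that holds for both
indices.
"""

import numpy as np

from specfx.io import load_fixture
from specfx.opls import OPLSConfig, fit_opls
from specfx.screening import report, screen

# coefficient signs of the reference study's published regression
# equations (fit with commercial software on its unpublished area matrix)
PUBLISHED_SIGNS = {
    "dpph_pct": [-1, 1, -1, -1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
    "t_aoc": [-1, -1, 1, 1, 1, -1, -1, 1, 1, 1, 1, -1, 1, 1, 1],
}

areas = load_fixture("table3").drop(columns="rsd_printed").T
activity = load_fixture("table5")[["dpph_pct", "t_aoc"]]

models = {}
for assay in activity.columns:
    m = fit_opls(areas, activity[assay], OPLSConfig(n_orthogonal=1))
    models[assay] = m
    agree = int(
        (np.sign(m.coefficients_scaled) == PUBLISHED_SIGNS[assay]).sum()
    )
    print(f"{assay}: R2Y = {m.r2y:.3f}; coefficient signs matching the "
          f"published equation: {agree}/15")

screening = screen(models, vip_threshold=1.0, near_miss_slack=0.1)
doc = report(screening, identities={"9": "vitexin", "11": "verbascoside",
                                    "15": "psoralen"})
print()
print(doc["markdown"])
print()
print("Core-set peaks are important (VIP > 1) for and positively associated\n"
      "with both antioxidant indices. On the *published relative* areas the\n"
      "fit finds mostly negative associations and an empty core: normalizing\n"
      "by peak 9 inverts the relationship whenever peak 9's absolute area\n"
      "itself tracks activity. The reference study's equations (peak 9\n"
      "nonzero despite a constant relative column) show they were fit on an\n"
      "unpublished raw-area matrix, which is why this input is a diagnostic,\n"
      "not a reproduction target. The constant reference-peak column is\n"
      "dropped at scaling and reports VIP 0.")
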