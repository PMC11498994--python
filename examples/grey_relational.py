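"""Grey relational analysis of the reference dataset.

Scores how closely each common peak's relative-area profile tracks the
two antioxidant indices across the 10 batches (Deng coefficients, mean
normalization, resolution coefficient 0.5).
"""

from specfx.gra import GRAConfig, grey_relational_analysis
from specfx.io import load_fixture

areas = load_fixture("table3").drop(columns="rsd_printed").T  # batches x peaks
activity = load_fixture("table5")[["dpph_pct", "t_aoc"]]

result = grey_relational_analysis(areas, activity, GRAConfig(rho=0.5))
table = result.degrees.round(3).copy()
table["dpph_rank"] = result.ranks["dpph_pct"]
table["taoc_rank"] = result.ranks["t_aoc"]
print(table.to_string())
print()
print(f"minimum degree: {result.degrees.min().min():.3f}")
print("All degrees exceed 0.5: every common peak co-varies with both\n"
      "antioxidant indices to some extent; the ranking, not the absolute\n"
      "level, is what feeds the screening discussion.")
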