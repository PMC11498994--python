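"""How reliably does the pipeline recover planted active peaks?

Generates datasets with 3 known active peaks (standardized effect 1.0,
activity noise at R^2 ~ 0.8, one y-orthogonal batch confounder) and
counts how often the screening core set equals the planted set, at two
batch counts.
"""

from specfx.io import PipelineConfig, run_spectrum_effect
from specfx.synthetic import SyntheticSpec, generate

N_REPS = 20
for n_batches in (30, 100):
    hits = 0
    for rep in range(N_REPS):
        spec = SyntheticSpec(n_batches=n_batches, seed=1000 + rep)
        tables, activity, truth = generate(spec)
        bundle = run_spectrum_effect(tables, activity, PipelineConfig())
        core = sorted(int(p) for p in bundle["screening"].core_set)
        hits += core == sorted(truth["active_set"])
    print(f"n_batches={n_batches:4d}: exact recovery in {hits}/{N_REPS} replicates")

print()
print("At 30 batches the VIP > 1 cut sits only ~1.7 null-SDs above zero, so\n"
      "spurious candidates slip into the core set in a sizeable fraction of\n"
      "datasets; with more batches the threshold separates cleanly. Treat\n"
      "small-n candidate lists as hypotheses to verify, not conclusions.")
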