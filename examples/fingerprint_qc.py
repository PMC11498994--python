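"""Fingerprint QC on the packaged 10-batch reference dataset.

Builds the common-peak matrix, expresses everything relative to the
reference peak (peak 9), and prints the per-peak RSDs and the
batch-vs-consensus similarity column.
"""

from specfx.fingerprint import fingerprint_summary
from specfx.io import fixture_common_peak_matrix

matrix = fixture_common_peak_matrix()
summary = fingerprint_summary(matrix, reference_peak_id="9")

print("Relative-area RSD per common peak (%):")
print(summary.relative_area_rsd.round(2).to_string())
print()
print("Similarity of each batch to the median consensus fingerprint:")
print(summary.similarity["Control"].drop("Control").round(3).to_string())
print()
print(
    "High area RSDs (~30-70%) with near-zero retention-time RSDs mean the\n"
    "batches share the same constituents at very different abundances —\n"
    "exactly the between-batch variation the spectrum-effect analysis needs."
)
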