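"""Apply the cfDNA somatic filter rules to candidate variants.

Builds a leukocyte-panel background error model, then evaluates each
candidate against all six rules (VAF, supporting reads, depth,
tumour/normal ratio, background error multiplier, read-end distance);
the verdict table shows which rule removed each failing candidate.
"""

import pandas as pd

import darcsign as ds
from darcsign.somatic_filters import verdicts_to_frame

# two leukocyte samples observed a low-level T artifact at 1:100
panel = pd.DataFrame({
    "sample": ["leuko1", "leuko2"],
    "chrom": ["1", "1"],
    "pos": [100, 100],
    "base": ["T", "T"],
    "alt_count": [1, 3],
    "depth": [400, 400],
})
error_model = ds.build_error_model(panel)
print(f"background error at 1:100 T: {error_model.rate('1', 100, 'T'):.4f}")

ctx = "ATCG" * 5 + "C" + "CGAT" * 5
candidates = [
    ds.VariantRecord("1", 100, "C", "T", 200, 30, 180, 0, 28.0, ctx),   # real
    ds.VariantRecord("1", 100, "C", "T", 600, 13, 180, 0, 28.0, ctx),   # error-level VAF
    ds.VariantRecord("1", 250, "C", "T", 200, 30, 180, 0, 4.0, ctx),    # read-end artifact
    ds.VariantRecord("1", 300, "C", "T", 200, 30, 180, 12, 28.0, ctx),  # germline leak
]
verdicts = ds.call_somatic(candidates, error_model)
print(verdicts_to_frame(verdicts).to_string(index=False))
print(
    "\n'pass' is True only when every rule holds; the per-rule columns "
    "make filter attrition auditable."
)
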