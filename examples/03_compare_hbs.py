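"""Intersect HBS sets across samples and between pre/post conditions.

Runs the full pipeline on a synthetic three-sample cohort and prints the
pairwise, three-way and cross-condition common HBS — the comparison that
identifies regulators shared by all tumors after therapy.
"""

import tempfile

from cnanet import make_end_to_end_fixture, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    make_end_to_end_fixture(tmp, profile="small", seed=3)
    result = run_pipeline(tmp)

for cond in ("pre", "post"):
    report = result.intersections[cond]
    print(f"condition {cond}:")
    for sid, size in sorted(report.sizes.items()):
        print(f"  {sid}: {size} HBS")
    for (a, b), members in sorted(report.pairwise.items()):
        print(f"  {a} & {b}: {len(members)} common")
    print(f"  all samples: {len(report.common)} common "
          f"({', '.join(report.common)})")

cross = result.cross_condition
print("pre & post per sample:",
      {s: len(m) for s, m in cross.per_sample.items()})
print(f"common to every sample and condition: {len(cross.global_common)} "
      f"({', '.join(cross.global_common)})")
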