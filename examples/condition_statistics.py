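"""Per-instance morphometry and a between-condition rank-sum comparison.

Emulates comparing organelle instances across two treatment conditions:
two synthetic populations with different intensity scales are segmented,
summarized per instance (voxel volume, mean LAC), and compared with the
two-sided Mann-Whitney U test.
"""

import pandas as pd

from sxtinstance import (
    PhantomSpec,
    assemble_dataset,
    compare_conditions,
    instance_statistics,
    segment_instances,
)


def stats_for(peaks, seed, tag):
    spec = PhantomSpec(morphology="sphere", intensity_peak_range=peaks, seed=seed)
    frames = []
    for i in range(3):  # three tomograms per condition
        ds = assemble_dataset(PhantomSpec(**{**spec.__dict__, "seed": seed + i}))
        inst = segment_instances(ds.tomogram, ds.semantic, "sphere").instance_mask
        frames.append(instance_statistics(ds.tomogram, inst, condition=tag))
    return pd.concat(frames, ignore_index=True)


low = stats_for((0.35, 0.40), seed=10, tag="0mM")
high = stats_for((0.40, 0.45), seed=20, tag="25mM")

print(pd.concat([low, high]).groupby("condition")[
    ["volume_voxels", "mean_intensity"]].describe().round(3).T.to_string())
p_int = compare_conditions(low, high, metric="intensity")
p_vol = compare_conditions(low, high, metric="volume")
print(f"\nMann-Whitney two-sided p (intensity): {p_int:.2e}")
print(f"Mann-Whitney two-sided p (volume):    {p_vol:.2e}")
print("a small intensity p-value flags a shift in per-instance mean LAC "
      "between conditions; volumes were drawn from the same range, so the "
      "volume comparison should stay non-significant.")
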