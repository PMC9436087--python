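"""Benchmark the tool against connected labeling and watershed baselines.

Generates seeded sphere datasets, runs all four methods on each, and prints
the average-precision table (three datasets here to keep the example quick;
the full benchmark uses ten).
"""

from sxtinstance import run_benchmark

table, _ = run_benchmark("sphere", n_datasets=3, seed=0)
print(table.round(1).to_string())
print()
print("connected labeling collapses every touching composite into one "
      "instance (mAP ~0); raw watershed over-segments the noisy interior; "
      "Gaussian pre-filtering recovers much of that; the blob-based tool "
      "resolves the contacts.")
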