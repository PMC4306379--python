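"""Time random vs deterministic patch evaluation.

Reproduces the shape of the classic comparison: one row per method, one
column per point count.  Absolute numbers depend on the machine and are
reported, never asserted; the stable observation is that the exact
inverse-transform samplers beat the deterministic Bézier evaluators, and the
gap widens as the number of points grows.
"""

from ellipatch.benchmark import benchmark_revolution, benchmark_sphere

for table in (benchmark_sphere(repeats=3, seed=0),
              benchmark_revolution(repeats=3, seed=0)):
    print(f"\n{table.shape} (seconds, median of 3 repeats):")
    print(table.format())
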