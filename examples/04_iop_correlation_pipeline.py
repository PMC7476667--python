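"""End-to-end pipeline run: rising-IOP phantom series -> segmentation ->
morphometry -> Pearson correlation of SC area with IOP.

Writes a measures CSV and a stats JSON into ./scratch/example_run and prints
the correlation block, whose negative r mirrors the physiological
compression of the outflow tissues as pressure rises.
"""

import numpy as np

from ubmseg import RunConfig, run_pipeline

config = RunConfig(
    iops=tuple(float(v) for v in np.linspace(12.0, 32.0, 10)),
    methods=("levelset",),
    reference="truth",
    output_dir="scratch/example_run",
    seed=5,
)
report = run_pipeline(config)

print(f"images processed: {report['n_pairs_processed']}, "
      f"excluded: {report['n_pairs_excluded']}")
block = report["stats"]["iop_correlation"]["levelset"]
for measure, res in block.items():
    print(
        f"{measure:12s} vs IOP: r = {res['r']:+.3f}, "
        f"slope = {res['slope']:+.3f} px per mm Hg, p = {res['p_value']:.2e}"
    )
# All four measures shrink with IOP by construction of the series; the
# pipeline recovers that as strongly negative correlations from the
# segmentations alone (no ground truth used in the regression).
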