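"""Run the whole desk-scale pipeline in one call.

Synthetic 4-class grating tiles -> spectral pseudo-backbone features at
three resolutions -> per-part DCT reduction -> fusion at half the
concatenated width -> ANOVA top-200 -> cubic SVM, with every intermediate
artifact written to the output directory.
"""

import tempfile
from pathlib import Path

from histospect import desk_config, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = desk_config(seed=1, output_dir=Path(tmp) / "run")
    reports = run_pipeline(cfg, experiment="exp4")
    for name, rep in reports.items():
        print(f"{name}: overall accuracy {rep.overall_accuracy:.3f}, "
              f"macro F1 {rep.macro['f1']['mean']:.3f}")
    produced = sorted(p.name for p in (Path(tmp) / "run").iterdir())
    print(f"artifacts: {produced}")

# The fused 928-wide representation (50% of the 1856 concatenated
# features) and the ANOVA-selected 200-wide subset both classify the
# held-out tiles essentially perfectly -- the texture classes are
# separable by design, which is what makes this a pipeline smoke test
# rather than a histology benchmark.
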