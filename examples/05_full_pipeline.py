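"""Generate a complete synthetic study and run every analysis stage on it.

Equivalent to `capsize run --demo --seed 1`; all reports land under
./capsize_demo/reports and the combined JSON is printed.
"""

import json

from capsize.pipeline import run_demo

combined = run_demo(seed=1, work_dir="capsize_demo")

print(json.dumps(combined, indent=1, sort_keys=True))
# shape:      20 batches classified against SF < 0.07
# tate:       pooled K_SF calibration and AAD/MAD of the diameter model
# mechanics:  per-curve surface modulus, crushing points, class ratio
# permeation: first-order uptake fits per class and their ordering
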