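"""Generate a synthetic calibration scan dataset with known ground truth.

Writes triplicate background/irradiated TIFF pairs for a 9-time exposure
schedule spanning the EBT3 usable dose range, plus a manifest CSV and the
generating truth as JSON. These scans stand in for the physical film
irradiations and let the whole analysis chain be exercised end to end.
"""

import tempfile
from pathlib import Path

from alphafilm.synthetic import default_truth, generate_calibration_dataset

out = Path(tempfile.mkdtemp(prefix="alphafilm_synth_"))
truth = default_truth("EBT3", "water", seed=42)
manifest = generate_calibration_dataset(truth, out)

print(f"truth: b = {truth.b_true} Gy, n = {truth.n_true}, rate = {truth.dose_rate_gy_min} Gy/min")
print(f"schedule (min): {truth.schedule_min}")
print(f"wrote {len(manifest)} scan pairs to {out}")
print(manifest.head(3).to_string(index=False))
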