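"""Monte-Carlo chance level for the object-location task.

Draws 10,000 uniform drop positions per object in each arena, forms 10,000
resampled means over the eight (session x environment x object) cells, and
reports the 5th percentile of that surrogate distribution — the drop-error
threshold separating good from bad trials.
"""

import json

from _cohort import RESULTS
from navrsa.behavior import chance_threshold

res = chance_threshold(seed=1)
print(f"chance threshold (5th percentile of surrogate means): "
      f"{res.threshold:.2f} vm")
for cell, mean in res.per_object_mean.items():
    print(f"  mean surrogate drop error {cell}: {mean:.2f} vm")

RESULTS.mkdir(exist_ok=True)
(RESULTS / "chance_level.json").write_text(json.dumps(res.to_dict(), indent=2))
print(f"wrote {RESULTS / 'chance_level.json'}")
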