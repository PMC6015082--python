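"""Degradation index of control versus treatment fields.

Renders ten control fields (30 degradation spots per cell) and ten
treatment fields at 40% of that density, counts spots with the LoG
detector, and normalizes the per-field spot-per-cell index so the
control mean is 100.  The treatment mean then reads directly as percent
of control activity: ~40, i.e. a ~60% reduction in pericellular
collagenolysis.
"""

import numpy as np

from endopolar import generate_degradation_field, run_degradation_experiment

rng = np.random.default_rng(5)
fields = []
for _ in range(10):
    img, _ = generate_degradation_field(5, 30.0, seed=rng)
    fields.append((img, 5, True))
for _ in range(10):
    img, _ = generate_degradation_field(5, 12.0, seed=rng)
    fields.append((img, 5, False))

table = run_degradation_experiment(fields)
ctrl = table[table.is_control].norm_index
treat = table[~table.is_control].norm_index
print(table.head(4).to_string(index=False))
print(f"control mean index: {ctrl.mean():.1f} (100 by construction)")
print(f"treatment mean index: {treat.mean():.1f}")
print(f"reduction: {100 - treat.mean():.1f}% (spot density was reduced by 60%)")
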