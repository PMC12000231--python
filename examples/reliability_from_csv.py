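"""Estimate the reliability of an AAT double-difference score from a CSV.

Builds a small synthetic approach-avoidance dataset, writes it to long
format, reads it back the way a user would read their own data, and computes
the stratified permutation-based split-half reliability.
"""

import tempfile
from pathlib import Path

import numpy as np

from permsplit import (
    SimParams,
    generate_dataset,
    permutation_splithalf,
    read_trials,
    true_reliability,
    write_trials,
)

params = SimParams(n_participants=40)  # 256 trials per participant
table = generate_dataset(params, np.random.default_rng(11))

path = Path(tempfile.gettempdir()) / "aat_example.csv"
write_trials(table, path)
data = read_trials(path, factors=("stimulus_type", "direction"))

spec = params.score_spec("mean")  # (avoid - approach) target minus control
est = permutation_splithalf(data, spec, n_splits=2000, rng=1)

print(est)
print(f"closed-form reliability of this design: {true_reliability(params, spec):.3f}")
print(
    "The point estimate aggregates 2,000 random stimulus-balanced split\n"
    "correlations (Olkin-Pratt) and projects the aggregate to full test\n"
    "length with the mirrored Spearman-Brown formula; the CI passes the\n"
    "2.5%/97.5% split-correlation quantiles through the same projection."
)
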