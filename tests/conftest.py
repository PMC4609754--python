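import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_balanced_design(
    n_per_group=4,
    within=("session", "trialtype"),
    seed=0,
    effects=None,
    noise_sd=1.0,
    subject_sd=1.0,
):
    """Balanced split-plot dataset: 2 groups x within 2-level factors.

    ``effects`` maps effect names (e.g. "session", "fitness_group * session")
    to the coded effect size on a +/-1 contrast scale; unspecified effects
    are zero.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    levels = {
        "fitness_group": ("lower", "higher"),
        "session": ("exercise", "rest"),
        "trialtype": ("Go", "NoGo"),
        "congruency": ("congruent", "incongruent"),
    }
    rows = []
    sid = 0
    for g in levels["fitness_group"]:
        for _ in range(n_per_group):
            sid += 1
            subj_eff = rng.normal(0, subject_sd)
            from itertools import product

            for combo in product(*(levels[f] for f in within)):
                row = {"participant": f"S{sid:02d}", "fitness_group": g}
                row.update(dict(zip(within, combo)))
                codes = {
                    f: (1.0 if row[f] == sorted(levels[f])[1] else -1.0)
                    for f in ("fitness_group", *within)
                }
                y = subj_eff + rng.normal(0, noise_sd)
                for name, size in effects.items():
                    parts = [p.strip() for p in name.split("*")]
                    y += size * np.prod([codes[p] for p in parts])
                row["y"] = y
                rows.append(row)
    return pd.DataFrame(rows)
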