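import numpy as np
import pandas as pd
import pytest

from mddskit import PullDirection, recommend_oks


@pytest.fixture
def golden_cohort() -> pd.DataFrame:
    """50-patient cohort mirroring the dominant-pull treatment group.

    33 motion-triggered / 17 non-motion-triggered patients; 36 improve
    immediately (72%).  Directions are assigned with backward pull most
    common; each patient receives the model-prescribed OKS.
    """
    rng = np.random.default_rng(20220131)
    n = 50
    dirs = (
        [PullDirection.BACK] * 26
        + [PullDirection.LEFT] * 8
        + [PullDirection.RIGHT] * 8
        + [PullDirection.FORWARD] * 5
        + [PullDirection.DOWN] * 2
        + [PullDirection.UP] * 1
    )
    improved = [True] * 36 + [False] * 14
    rows = []
    for i in range(n):
        d = dirs[i]
        rows.append(
            {
                "patient_id": f"G{i:03d}",
                "trigger": "MT" if i < 33 else "non_MT",
                "sex": "F" if i < 41 else "M",
                "pull_directions": frozenset({d.value}),
                "dominant_direction": d.value,
                "oks_given": recommend_oks(d).primary.value,
                "treatment_minutes": float(rng.integers(1, 60)),
                "response": "improved" if improved[i] else "no_change",
                "likert_before": int(rng.integers(3, 9)),
                "likert_after": int(rng.integers(0, 4)),
                "followup_improved": bool(improved[i] and rng.random() < 0.59),
            }
        )
    return pd.DataFrame(rows)
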