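"""Shared group-comparison helpers (Welch two-sample tables)."""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def welch_table(
    groups: Mapping[str, Sequence[float]],
    control: str,
) -> pd.DataFrame:
    """Per-group mean/SD/n plus a Welch two-sample p-value vs ``control``.

    Each group needs n >= 2 so that a within-group SD exists.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not among groups {list(groups)}")
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n={arr.size} < 2")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        arrays[name] = arr

    ctrl = arrays[control]
    rows = []
    for name, arr in arrays.items():
        if name == control:
            p = np.nan
        else:
            # Welch (unequal-variance) t test; identical samples give t=0, p=1.
            t, p = stats.ttest_ind(arr, ctrl, equal_var=False)
            if np.isnan(p) and np.allclose(arr, ctrl):
                p = 1.0
        rows.append(
            {
                "group": name,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "n": int(arr.size),
                "p_vs_control": float(p) if p == p else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
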