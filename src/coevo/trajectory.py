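"""Run output container shared by all model simulators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd


@dataclass
class Trajectory:
    """Per-round population summaries plus the final agent snapshot.

    data : DataFrame with one row per round and columns
        (t, p, y_mean, y_sd) — the frequency of the focal action and the
        mean/sd of attitudes after that round.
    final : DataFrame snapshot of every agent at the end of the run
        (agent_id, group_id, x, y and the psychological parameters).
    meta : config echo, seed and model tag; sufficient to re-run the
        simulation bit-exactly.
    """

    data: pd.DataFrame
    final: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)
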