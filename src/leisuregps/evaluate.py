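"""Evaluation of detected trips against a ground-truth manifest."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TripRecovery:
    n_truth: int
    n_detected: int
    n_matched: int
    mode_agreement: float      # fraction of matched pairs with equal mode

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


def match_trips(detected: pd.DataFrame, truth: pd.DataFrame,
                min_overlap_frac: float = 0.5) -> TripRecovery:
    """Greedy one-to-one matching of detected to true trips by temporal
    overlap within participant; a pair matches when the overlap covers at
    least ``min_overlap_frac`` of the shorter trip."""
    n_matched = 0
    mode_hits = 0
    for pid, tgrp in truth.groupby("participant_id"):
        dgrp = detected[detected["participant_id"] == pid]
        t_start = pd.to_datetime(tgrp["start"]).to_numpy()
        t_end = pd.to_datetime(tgrp["end"]).to_numpy()
        d_start = pd.to_datetime(dgrp["start"]).to_numpy()
        d_end = pd.to_datetime(dgrp["end"]).to_numpy()
        used = np.zeros(len(dgrp), dtype=bool)
        t_modes = tgrp["mode"].to_numpy()
        d_modes = dgrp["mode"].to_numpy()
        for i in range(len(tgrp)):
            ov = (np.minimum(t_end[i], d_end) - np.maximum(t_start[i], d_start)) / np.timedelta64(1, "s")
            shorter = np.minimum((t_end[i] - t_start[i]) / np.timedelta64(1, "s"),
                                 (d_end - d_start) / np.timedelta64(1, "s"))
            cand = np.flatnonzero((ov >= min_overlap_frac * shorter) & ~used & (shorter > 0))
            if cand.size == 0:
                continue
            j = cand[np.argmax(ov[cand])]
            used[j] = True
            n_matched += 1
            mode_hits += int(d_modes[j] == t_modes[i])
    return TripRecovery(
        n_truth=len(truth), n_detected=len(detected), n_matched=n_matched,
        mode_agreement=mode_hits / n_matched if n_matched else float("nan"),
    )
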