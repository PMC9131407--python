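"""Trial- and participant-level exclusion rules and per-condition
orientation profiles.

The RT analyses keep only correct responses with 150 ms <= RT <= 2000 ms
(trials strictly outside the window are removed); error-rate analyses keep
every responded trial.  Participants whose overall error proportion strictly
exceeds 20% are excluded before any analysis.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .design import MOVEMENTS, ORIENTATIONS

logger = logging.getLogger(__name__)

RT_MIN = 150.0
RT_MAX = 2000.0


@dataclasses.dataclass
class FilterResult:
    """Filtered trial streams plus a per-rule removal log."""

    rt_stream: pd.DataFrame      # correct trials with RT inside [150, 2000] ms
    error_stream: pd.DataFrame   # all responded trials
    log: dict

    def __post_init__(self):
        n = self.log
        assert n["n_input"] == (len(self.rt_stream) + n["n_no_response"]
                                + n["n_error"] + n["n_too_fast"] + n["n_too_slow"])


def filter_trials(trials: pd.DataFrame) -> FilterResult:
    """Split trials into the RT and error analysis streams.

    RT stream: responded, correct, and 150 <= rt_ms <= 2000 (boundaries
    inclusive).  Error stream: all responded trials.  The log reconciles
    exactly: input = retained + no-response + error + too-fast + too-slow.
    """
    if trials.empty:
        logger.warning("filter_trials received an empty trial table")
        log = dict(n_input=0, n_no_response=0, n_error=0, n_too_fast=0,
                   n_too_slow=0, n_retained_rt=0, n_error_stream=0)
        return FilterResult(trials.copy(), trials.copy(), log)

    responded = trials.rt_ms.notna()
    error_stream = trials[responded].copy()
    correct = responded & trials.correct.astype(bool)
    too_fast = correct & (trials.rt_ms < RT_MIN)
    too_slow = correct & (trials.rt_ms > RT_MAX)
    keep = correct & ~too_fast & ~too_slow
    rt_stream = trials[keep].copy()
    log = dict(
        n_input=len(trials),
        n_no_response=int((~responded).sum()),
        n_error=int((responded & ~trials.correct.astype(bool)).sum()),
        n_too_fast=int(too_fast.sum()),
        n_too_slow=int(too_slow.sum()),
        n_retained_rt=len(rt_stream),
        n_error_stream=len(error_stream),
    )
    return FilterResult(rt_stream, error_stream, log)


def exclude_participants(trials: pd.DataFrame, threshold: float = 0.20):
    """Exclude participants whose overall error proportion strictly exceeds
    ``threshold`` (computed on raw, untrimmed responded trials).

    Returns ``(retained_ids, report)`` where the report lists every
    participant's error rate and exclusion flag.
    """
    responded = trials[trials.rt_ms.notna()]
    rate = 1.0 - responded.groupby("participant_id").correct.mean()
    report = rate.rename("error_rate").reset_index()
    report["excluded"] = report.error_rate > threshold
    retained = report.loc[~report.excluded, "participant_id"].tolist()
    return retained, report


def orientation_profiles(stream: pd.DataFrame, measure: str = "rt_ms") -> pd.DataFrame:
    """Per-participant x condition orientation profiles.

    For ``measure='rt_ms'`` pass the RT stream; cell values are mean RTs.  For
    ``measure='error_rate'`` pass the error stream; cell values are error
    proportions.  Conditions are movement in {free, restricted, pooled} x
    location in {none, left, right}; the pooled profile is the average of the
    two movement-condition profiles.  Output is wide (one column per
    orientation) with a ``complete`` flag; incomplete profiles are kept but
    flagged, and downstream statistics skip them.
    """
    df = stream.copy()
    if measure == "rt_ms":
        df["value"] = df.rt_ms
    elif measure == "error_rate":
        df["value"] = 1.0 - df.correct.astype(float)
    else:
        raise ValueError(f"unknown measure {measure!r}")

    cell = (df.groupby(["participant_id", "movement", "person_location", "orientation_deg"],
                       observed=True)
              .value.mean()
              .unstack("orientation_deg")
              .reindex(columns=list(ORIENTATIONS)))
    pooled = cell.groupby(["participant_id", "person_location"], observed=True).mean()
    # pooled is valid only if both movement conditions contributed
    n_mov = cell.groupby(["participant_id", "person_location"], observed=True).size()
    pooled[n_mov < len(MOVEMENTS)] = np.nan
    pooled = pd.concat({"pooled": pooled}, names=["movement"])
    pooled = pooled.reorder_levels(["participant_id", "movement", "person_location"])

    out = pd.concat([cell, pooled]).reset_index()
    out.insert(3, "measure", measure)
    out["complete"] = out[list(ORIENTATIONS)].notna().all(axis=1)
    n_incomplete = int((~out.complete).sum())
    if n_incomplete:
        logger.info("%d incomplete orientation profiles flagged", n_incomplete)
    return out.sort_values(["participant_id", "movement", "person_location"]).reset_index(drop=True)


def profile_values(profiles: pd.DataFrame) -> np.ndarray:
    """The (n_profiles, 8) value matrix, ordered by ORIENTATIONS."""
    return profiles[list(ORIENTATIONS)].to_numpy(dtype=float)
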