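"""Deterministic scorers turning trial sequences into raw dependent measures.

Spatial Reversal
    Three measures: blocks completed under the 3-of-4 criterion (baseline
    block plus up to 3 reversal blocks, range 0-4), the single longest block
    in trials (range 4-20), and unused reversal trials remaining out of 20.
    A dog that never meets baseline criterion within 20 scored trials gets
    the worst possible score: 0 blocks, longest block 20, 0 trials remaining.

Delayed Search
    Proportion of correct first searches within each of five trial types
    (no delay; 10 s; 10 s, 20 s and 40 s with distraction).  A type with no
    scored trials is missing and is imputed downstream.  Four no-choice
    events discontinue the task.

Cylinder
    Proportion of the four inhibitory-control trials on which the dog
    obtained the reward without first touching the cylinder's exterior.
    Dogs responding on three or fewer trials are excluded.

No-choice / no-response administrations and their motivator trials do not
count toward trial caps or block lengths; the scored repeat replaces the
original administration.  All scorers are pure functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import data_model as dm
from .errors import ValidationError

SR_BASELINE_CAP = 20     # scored baseline trials before the task is stopped
SR_REVERSAL_CAP = 20     # scored reversal trials shared across blocks
SR_MAX_REVERSALS = 3
CRITERION_WINDOW = 4
CRITERION_REQUIRED = 3
DS_DISCONTINUE_NO_CHOICES = 4


@dataclass(frozen=True)
class SRMeasures:
    blocks_completed: Optional[int]
    longest_block: Optional[int]
    trials_remaining: Optional[int]
    baseline_failed: bool = False
    aborted: bool = False


@dataclass(frozen=True)
class DSMeasures:
    prop_by_type: tuple          # 5 entries, each float in [0,1] or None
    n_no_choice: int
    discontinued: bool
    aborted: bool = False


@dataclass(frozen=True)
class CylMeasure:
    prop_success: Optional[float]   # None when excluded
    n_responded: int

    @property
    def excluded(self) -> bool:
        return self.prop_success is None


def criterion_met(outcomes, window: int = CRITERION_WINDOW,
                  required: int = CRITERION_REQUIRED) -> Optional[int]:
    """First 1-based position at which the trailing-window criterion is met.

    Returns the smallest ``t >= window`` such that at least ``required`` of
    ``outcomes[t - window .. t - 1]`` are true, or ``None`` if the criterion
    is never met.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    if not (window >= required >= 1):
        raise ValueError("need window >= required >= 1")
    running = 0
    for t, outcome in enumerate(outcomes, start=1):
        running += bool(outcome)
        if t > window:
            running -= bool(outcomes[t - window - 1])
        if t >= window and running >= required:
            return t
    return None


def score_spatial_reversal(seq: dm.SRTrialSeq) -> SRMeasures:
    """Score one Spatial Reversal session."""
    dm.validate_sr_seq(seq)
    if seq.aborted:
        return SRMeasures(None, None, None, aborted=True)

    finals = seq.final_administrations()
    # scored trials: final administrations on which the dog chose a side
    baseline = [t for t in finals
                if t.phase == "baseline" and t.response in ("open", "closed")]
    reversal = [t for t in finals
                if t.phase == "reversal" and t.response in ("open", "closed")]

    if len(baseline) > SR_BASELINE_CAP:
        raise ValidationError("more than 20 scored baseline trials",
                              dog_id=seq.dog_id, timepoint=seq.timepoint)
    if len(reversal) > SR_REVERSAL_CAP:
        raise ValidationError("more than 20 scored reversal trials",
                              dog_id=seq.dog_id, timepoint=seq.timepoint)

    base_met = criterion_met([t.response == "open" for t in baseline]) \
        if baseline else None
    if base_met is None:
        # worst-score rule: baseline never passed within the 20 allotted trials
        if reversal:
            raise ValidationError(
                "reversal trials present although baseline criterion not met",
                dog_id=seq.dog_id, timepoint=seq.timepoint)
        return SRMeasures(0, 20, 0, baseline_failed=True)

    if len(baseline) > base_met:
        t = baseline[base_met]
        raise ValidationError(
            "scored baseline trials beyond the criterion-meeting trial",
            dog_id=seq.dog_id, timepoint=seq.timepoint, index=t.index)

    blocks_completed = 1
    block_lengths = [base_met]

    # replay the reversal phase: blocks are delimited by criterion detection
    pos = 0
    entered = 0
    while pos < len(reversal) and entered < SR_MAX_REVERSALS:
        entered += 1
        block = reversal[pos:]
        expect = entered  # block_index recorded in the data must agree
        met = None
        length = 0
        running = []
        for t in block:
            if t.block_index != expect:
                raise ValidationError(
                    "block_index inconsistent with criterion structure",
                    dog_id=seq.dog_id, timepoint=seq.timepoint, index=t.index)
            length += 1
            running.append(t.response == "open")
            m = criterion_met(running)
            if m is not None:
                met = length
                break
        if met is not None:
            blocks_completed += 1
            block_lengths.append(met)
            pos += met
        else:
            block_lengths.append(length)
            pos += length
            break

    if pos < len(reversal):
        t = reversal[pos]
        raise ValidationError(
            "scored reversal trials beyond 3 completed blocks",
            dog_id=seq.dog_id, timepoint=seq.timepoint, index=t.index)

    longest_block = max(block_lengths)
    trials_remaining = SR_REVERSAL_CAP - len(reversal)
    return SRMeasures(blocks_completed, longest_block, trials_remaining)


def score_delayed_search(trials: dm.DSTrialSet) -> DSMeasures:
    """Score one Delayed Search session."""
    dm.validate_ds_set(trials)
    n_no_choice = sum(1 for t in trials.trials if t.first_search == dm.NO_CHOICE)
    if trials.aborted:
        return DSMeasures((None,) * 5, n_no_choice, discontinued=False,
                          aborted=True)
    finals = trials.final_administrations()
    props = []
    for ttype in dm.DS_TRIAL_TYPES:
        scored = [t for t in finals
                  if t.trial_type == ttype and t.correct is not None]
        if not scored:
            props.append(None)
        else:
            props.append(sum(t.correct for t in scored) / len(scored))
    discontinued = n_no_choice >= DS_DISCONTINUE_NO_CHOICES
    return DSMeasures(tuple(props), n_no_choice, discontinued)


def score_cylinder(trials: dm.CylTrialSet) -> CylMeasure:
    """Score one Cylinder session."""
    dm.validate_cyl_set(trials)
    finals = trials.final_administrations()
    responded = [t for t in finals if t.responded]
    n_responded = len(responded)
    if n_responded <= dm.CYL_N_TRIALS - 1:
        return CylMeasure(None, n_responded)
    successes = sum(1 for t in responded if not t.touched_exterior)
    return CylMeasure(successes / dm.CYL_N_TRIALS, n_responded)


# ---------------------------------------------------------------------------
# Session collections -> measures table
# ---------------------------------------------------------------------------

def score_sessions(sr_sessions, ds_sessions, cyl_sessions) -> pd.DataFrame:
    """Score every session and assemble the long-format measures table.

    Keys of the three dicts are ``(dog_id, timepoint)``; a session absent
    from a task's dict yields missing measures for that task.
    """
    keys = sorted(set(sr_sessions) | set(ds_sessions) | set(cyl_sessions))
    rows = []
    for key in keys:
        dog_id, timepoint = key
        row = {"dog_id": dog_id, "timepoint": timepoint}
        flags = []
        if key in sr_sessions:
            m = score_spatial_reversal(sr_sessions[key])
            if m.aborted:
                flags.append("sr_aborted")
                row.update(sr_blocks=np.nan, sr_longest=np.nan, sr_remaining=np.nan)
            else:
                row.update(sr_blocks=float(m.blocks_completed),
                           sr_longest=float(m.longest_block),
                           sr_remaining=float(m.trials_remaining))
                if m.baseline_failed:
                    flags.append("sr_baseline_failed")
        else:
            row.update(sr_blocks=np.nan, sr_longest=np.nan, sr_remaining=np.nan)
        if key in ds_sessions:
            m = score_delayed_search(ds_sessions[key])
            if m.aborted:
                flags.append("ds_aborted")
            if m.discontinued:
                flags.append("ds_discontinued")
            for col, p in zip(dm.DS_PROP_COLUMNS, m.prop_by_type):
                row[col] = np.nan if p is None else p
        else:
            for col in dm.DS_PROP_COLUMNS:
                row[col] = np.nan
        if key in cyl_sessions:
            m = score_cylinder(cyl_sessions[key])
            if m.excluded:
                flags.append("cyl_excluded")
                row["cyl_prop"] = np.nan
            else:
                row["cyl_prop"] = m.prop_success
        else:
            row["cyl_prop"] = np.nan
        row["flags"] = ";".join(flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(dm.MEASURES_COLUMNS))
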