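"""Domain types, invariant checking and CSV readers/writers.

The battery produces long-format trial records for three tasks (Spatial
Reversal, Delayed Search, Cylinder) plus per-dog and per-session metadata.
All files are UTF-8 comma-separated with a mandatory header; missing values
are empty fields and booleans are lowercase ``true``/``false``.  Lines
starting with ``#`` are provenance comments and are ignored on read.

Trials that were administered again after a motivator trial (because the dog
made no choice / no response) carry a ``repeat_of`` column referencing the
original trial index; only the final administration of a trial slot is
scored.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

TIMEPOINTS = ("baseline", "m6", "m12")
SEXES = ("female", "male")
NEUTER_STATUSES = ("intact", "altered")
BREED_CLASSES = ("mixed", "purebred")
LOCATIONS = ("ACCC", "CC", "SSP")
#: Short location codes used in files, full site names used in reports.
LOCATION_NAMES = {
    "ACCC": "Arizona Canine Cognition Center",
    "CC": "Canine Companions",
    "SSP": "Sit! Stay! Play!",
}

DS_TRIAL_TYPES = ("no_delay", "d10", "d10_distract", "d20_distract", "d40_distract")
#: Number of scored trials of each type in a complete Delayed Search session.
DS_TYPE_COUNTS = {"no_delay": 4, "d10": 2, "d10_distract": 2, "d20_distract": 2, "d40_distract": 2}
DS_N_TRIALS = 12
DS_LOCATIONS = (1, 2, 3, 4)

CYL_N_TRIALS = 4

NO_CHOICE = "no_choice"
ABORT = "abort"

SCORES_COLUMNS = (
    "dog_id", "timepoint", "test_age_years", "sex", "location",
    "sr_score", "ds_score", "cyl_score", "overall_score",
    "sr_imputed", "ds_imputed", "cyl_imputed",
)

MEASURES_COLUMNS = (
    "dog_id", "timepoint",
    "sr_blocks", "sr_longest", "sr_remaining",
    "ds_p_nodelay", "ds_p_d10", "ds_p_d10x", "ds_p_d20x", "ds_p_d40x",
    "cyl_prop", "flags",
)

DS_PROP_COLUMNS = ("ds_p_nodelay", "ds_p_d10", "ds_p_d10x", "ds_p_d20x", "ds_p_d40x")
SR_MEASURE_COLUMNS = ("sr_blocks", "sr_longest", "sr_remaining")


# ---------------------------------------------------------------------------
# Trial-level domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SRTrial:
    """One Spatial Reversal trial administration."""

    index: int
    phase: str                     # baseline | reversal
    block_index: int               # 0 = baseline, 1..3 = reversal blocks
    open_side: str                 # left | right
    response: str                  # open | closed | no_choice | abort
    repeat_of: Optional[int] = None


@dataclass(frozen=True)
class DSTrial:
    """One Delayed Search trial administration."""

    index: int
    trial_type: str
    baited_location: int
    first_search: Union[int, str]  # 1..4 | no_choice | abort
    repeat_of: Optional[int] = None

    @property
    def correct(self) -> Optional[bool]:
        if self.first_search in (NO_CHOICE, ABORT):
            return None
        return self.first_search == self.baited_location


@dataclass(frozen=True)
class CylTrial:
    """One Cylinder inhibitory-control trial administration."""

    index: int
    responded: bool
    touched_exterior: Optional[bool]  # None when not responded
    repeat_of: Optional[int] = None


@dataclass
class TrialSeq:
    """Ordered trial administrations for one dog x timepoint session."""

    dog_id: str
    timepoint: str
    trials: list = field(default_factory=list)

    def __len__(self):
        return len(self.trials)

    @property
    def aborted(self) -> bool:
        return any(getattr(t, "response", getattr(t, "first_search", None)) == ABORT
                   for t in self.trials)

    def final_administrations(self) -> list:
        """Resolve motivator repeats: keep the last administration per slot.

        A slot is identified by the original trial index (``repeat_of`` when
        set, else the trial's own index).  Slots retain the original order.
        """
        last = {}
        order = []
        for t in self.trials:
            slot = t.repeat_of if t.repeat_of is not None else t.index
            if slot not in last:
                order.append(slot)
            last[slot] = t
        return [last[s] for s in order]


class SRTrialSeq(TrialSeq):
    pass


class DSTrialSet(TrialSeq):
    pass


class CylTrialSet(TrialSeq):
    pass


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check(cond, message, dog_id=None, timepoint=None, index=None):
    if not cond:
        raise ValidationError(message, dog_id=dog_id, timepoint=timepoint, index=index)


def validate_sr_seq(seq: SRTrialSeq) -> None:
    d, tp = seq.dog_id, seq.timepoint
    prev_index = 0
    originals = {}
    for t in seq.trials:
        _check(t.index > prev_index, "trial indices must be strictly increasing",
               d, tp, t.index)
        prev_index = t.index
        _check(t.response in ("open", "closed", NO_CHOICE, ABORT),
               f"invalid response {t.response!r}", d, tp, t.index)
        _check(t.phase in ("baseline", "reversal"),
               f"invalid phase {t.phase!r}", d, tp, t.index)
        if t.phase == "baseline":
            _check(t.block_index == 0, "baseline trials must have block_index 0",
                   d, tp, t.index)
        else:
            _check(1 <= t.block_index <= 3,
                   "reversal trials must have block_index in 1..3", d, tp, t.index)
        _check(t.open_side in ("left", "right"),
               f"invalid open_side {t.open_side!r}", d, tp, t.index)
        if t.repeat_of is not None:
            _check(t.repeat_of in originals,
                   f"repeat_of references unknown trial {t.repeat_of}", d, tp, t.index)
        else:
            originals[t.index] = t
    # open_side constant within a block, alternating between consecutive blocks
    side_by_block = {}
    block_order = []
    for t in seq.trials:
        if t.response == ABORT:
            continue
        if t.block_index not in side_by_block:
            side_by_block[t.block_index] = t.open_side
            block_order.append(t.block_index)
        else:
            _check(side_by_block[t.block_index] == t.open_side,
                   "open_side must be constant within a block", d, tp, t.index)
    for a, b in zip(block_order, block_order[1:]):
        _check(b == a + 1, "block indices must be consecutive", d, tp)
        _check(side_by_block[a] != side_by_block[b],
               "open_side must alternate between consecutive blocks", d, tp)
    if seq.aborted:
        _check(seq.trials[-1].response == ABORT,
               "abort must terminate the sequence", d, tp)


def validate_ds_set(seq: DSTrialSet) -> None:
    d, tp = seq.dog_id, seq.timepoint
    prev_index = 0
    originals = []
    by_index = {}
    for t in seq.trials:
        _check(t.index > prev_index, "trial indices must be strictly increasing",
               d, tp, t.index)
        prev_index = t.index
        _check(t.trial_type in DS_TRIAL_TYPES,
               f"invalid trial_type {t.trial_type!r}", d, tp, t.index)
        _check(t.baited_location in DS_LOCATIONS,
               f"invalid baited_location {t.baited_location!r}", d, tp, t.index)
        _check(t.first_search in DS_LOCATIONS or t.first_search in (NO_CHOICE, ABORT),
               f"invalid first_search {t.first_search!r}", d, tp, t.index)
        if t.repeat_of is not None:
            _check(t.repeat_of in by_index,
                   f"repeat_of references unknown trial {t.repeat_of}", d, tp, t.index)
            orig = by_index[t.repeat_of]
            _check(orig.trial_type == t.trial_type and
                   orig.baited_location == t.baited_location,
                   "repeat must preserve trial_type and baited_location",
                   d, tp, t.index)
        else:
            originals.append(t)
            by_index[t.index] = t
    _check(len(originals) <= DS_N_TRIALS,
           f"more than {DS_N_TRIALS} scored trials", d, tp)
    counts = {k: 0 for k in DS_TRIAL_TYPES}
    loc_counts = {k: 0 for k in DS_LOCATIONS}
    for a, b in zip(originals, originals[1:]):
        _check(a.baited_location != b.baited_location,
               "baited_location must differ on consecutive trials", d, tp, b.index)
    for t in originals:
        counts[t.trial_type] += 1
        loc_counts[t.baited_location] += 1
        _check(counts[t.trial_type] <= DS_TYPE_COUNTS[t.trial_type],
               f"too many {t.trial_type} trials", d, tp, t.index)
        _check(loc_counts[t.baited_location] <= 3,
               "each location may be baited at most 3 times", d, tp, t.index)
    if len(originals) == DS_N_TRIALS:
        _check(all(v == 3 for v in loc_counts.values()),
               "each location must be baited exactly 3 times in a complete session",
               d, tp)


def validate_cyl_set(seq: CylTrialSet) -> None:
    d, tp = seq.dog_id, seq.timepoint
    prev_index = 0
    originals = set()
    for t in seq.trials:
        _check(t.index > prev_index, "trial indices must be strictly increasing",
               d, tp, t.index)
        prev_index = t.index
        if t.responded:
            _check(t.touched_exterior is not None,
                   "touched_exterior required on responded trials", d, tp, t.index)
        else:
            _check(t.touched_exterior is None,
                   "touched_exterior must be empty on no-response trials",
                   d, tp, t.index)
        if t.repeat_of is not None:
            _check(t.repeat_of in originals,
                   f"repeat_of references unknown trial {t.repeat_of}", d, tp, t.index)
        else:
            originals.add(t.index)
    _check(len(originals) <= CYL_N_TRIALS,
           f"more than {CYL_N_TRIALS} scored trials", d, tp)


_VALIDATORS = {"sr": validate_sr_seq, "ds": validate_ds_set, "cyl": validate_cyl_set}
_SEQ_TYPES = {"sr": SRTrialSeq, "ds": DSTrialSet, "cyl": CylTrialSet}


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

_TRIAL_HEADERS = {
    "sr": ["dog_id", "timepoint", "index", "phase", "block_index",
           "open_side", "response", "repeat_of"],
    "ds": ["dog_id", "timepoint", "index", "trial_type", "baited_location",
           "first_search", "repeat_of"],
    "cyl": ["dog_id", "timepoint", "index", "responded", "touched_exterior",
            "repeat_of"],
}

DOGS_COLUMNS = ("dog_id", "sex", "neuter_status", "weight_kg", "breed_class")
SESSIONS_COLUMNS = ("dog_id", "timepoint", "test_age_years", "location",
                    "vision_pass", "hearing_pass")


def _read_rows(path, expected_header):
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.reader(io.StringIO("".join(lines)))
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError(f"{path}: empty file, header row is mandatory")
    missing = [c for c in expected_header if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    idx = {c: header.index(c) for c in expected_header}
    for row in reader:
        if not row:
            continue
        yield {c: row[idx[c]] for c in expected_header}


def _parse_int(value, what, optional=False):
    if value == "":
        if optional:
            return None
        raise FormatError(f"missing value for {what}")
    return int(value)


def _parse_bool(value, what, optional=False):
    if value == "":
        if optional:
            return None
        raise FormatError(f"missing value for {what}")
    v = value.strip().lower()
    if v not in ("true", "false"):
        raise FormatError(f"invalid boolean {value!r} for {what}")
    return v == "true"


def _row_to_trial(task, row):
    repeat_of = _parse_int(row["repeat_of"], "repeat_of", optional=True)
    if task == "sr":
        return SRTrial(index=_parse_int(row["index"], "index"),
                       phase=row["phase"],
                       block_index=_parse_int(row["block_index"], "block_index"),
                       open_side=row["open_side"],
                       response=row["response"],
                       repeat_of=repeat_of)
    if task == "ds":
        fs = row["first_search"]
        first_search = fs if fs in (NO_CHOICE, ABORT) else _parse_int(fs, "first_search")
        return DSTrial(index=_parse_int(row["index"], "index"),
                       trial_type=row["trial_type"],
                       baited_location=_parse_int(row["baited_location"],
                                                  "baited_location"),
                       first_search=first_search,
                       repeat_of=repeat_of)
    if task == "cyl":
        responded = _parse_bool(row["responded"], "responded")
        return CylTrial(index=_parse_int(row["index"], "index"),
                        responded=responded,
                        touched_exterior=_parse_bool(row["touched_exterior"],
                                                     "touched_exterior",
                                                     optional=True),
                        repeat_of=repeat_of)
    raise ValueError(f"unknown task {task!r}")


def read_trials(path, task):
    """Read and validate a trial CSV.

    Parameters
    ----------
    path : path-like
    task : {"sr", "ds", "cyl"}

    Returns
    -------
    dict mapping ``(dog_id, timepoint)`` to the task-specific trial sequence.
    """
    if task not in _TRIAL_HEADERS:
        raise ValueError(f"unknown task {task!r}")
    sessions: dict = {}
    for row in _read_rows(path, _TRIAL_HEADERS[task]):
        key = (row["dog_id"], row["timepoint"])
        if row["timepoint"] not in TIMEPOINTS:
            raise ValidationError(f"invalid timepoint {row['timepoint']!r}",
                                  dog_id=row["dog_id"])
        seq = sessions.setdefault(key, _SEQ_TYPES[task](dog_id=row["dog_id"],
                                                        timepoint=row["timepoint"]))
        seq.trials.append(_row_to_trial(task, row))
    for seq in sessions.values():
        _VALIDATORS[task](seq)
    return sessions


def trials_to_frame(sessions, task):
    """Flatten trial sequences back to a long-format DataFrame."""
    cols = _TRIAL_HEADERS[task]
    rows = []
    for (dog_id, timepoint), seq in sessions.items():
        for t in seq.trials:
            row = {"dog_id": dog_id, "timepoint": timepoint}
            for c in cols[2:]:
                row[c] = getattr(t, c)
            rows.append(row)
    # object dtype keeps optional int columns (repeat_of) from float coercion
    return pd.DataFrame(rows, columns=cols, dtype=object)


def write_trials(sessions, task, path, provenance=None):
    """Write trial sequences to CSV (inverse of :func:`read_trials`)."""
    frame = trials_to_frame(sessions, task)
    write_table(frame, path, _TRIAL_HEADERS[task], provenance=provenance)


# ---------------------------------------------------------------------------
# Dogs / sessions
# ---------------------------------------------------------------------------

def read_dogs(path) -> pd.DataFrame:
    rows = list(_read_rows(path, list(DOGS_COLUMNS)))
    df = pd.DataFrame(rows, columns=list(DOGS_COLUMNS))
    if df["dog_id"].duplicated().any():
        dup = df.loc[df["dog_id"].duplicated(), "dog_id"].iloc[0]
        raise ValidationError("dog_id must be unique", dog_id=dup)
    for col, allowed in (("sex", SEXES), ("neuter_status", NEUTER_STATUSES),
                         ("breed_class", BREED_CLASSES)):
        bad = ~df[col].isin(allowed) & (df[col] != "")
        if bad.any():
            raise ValidationError(
                f"invalid {col} {df.loc[bad, col].iloc[0]!r}",
                dog_id=df.loc[bad, "dog_id"].iloc[0])
    df["weight_kg"] = pd.to_numeric(df["weight_kg"].where(df["weight_kg"] != ""))
    if (df["weight_kg"] <= 0).any():
        bad = df.loc[df["weight_kg"] <= 0, "dog_id"].iloc[0]
        raise ValidationError("weight_kg must be positive", dog_id=bad)
    return df


def read_sessions(path) -> pd.DataFrame:
    rows = list(_read_rows(path, list(SESSIONS_COLUMNS)))
    df = pd.DataFrame(rows, columns=list(SESSIONS_COLUMNS))
    if df.duplicated(subset=["dog_id", "timepoint"]).any():
        bad = df.loc[df.duplicated(subset=["dog_id", "timepoint"])].iloc[0]
        raise ValidationError("at most one session per (dog_id, timepoint)",
                              dog_id=bad["dog_id"], timepoint=bad["timepoint"])
    bad = ~df["timepoint"].isin(TIMEPOINTS)
    if bad.any():
        raise ValidationError(f"invalid timepoint {df.loc[bad, 'timepoint'].iloc[0]!r}",
                              dog_id=df.loc[bad, "dog_id"].iloc[0])
    bad = ~df["location"].isin(LOCATIONS)
    if bad.any():
        raise ValidationError(f"invalid location {df.loc[bad, 'location'].iloc[0]!r}",
                              dog_id=df.loc[bad, "dog_id"].iloc[0])
    df["test_age_years"] = pd.to_numeric(df["test_age_years"])
    if (df["test_age_years"] <= 0).any():
        bad = df.loc[df["test_age_years"] <= 0, "dog_id"].iloc[0]
        raise ValidationError("test_age_years must be positive", dog_id=bad)
    for col in ("vision_pass", "hearing_pass"):
        df[col] = df[col].map({"true": True, "false": False})
        if df[col].isna().any():
            bad = df.loc[df[col].isna(), "dog_id"].iloc[0]
            raise ValidationError(f"invalid boolean in {col}", dog_id=bad)
    # vision failure is an exclusion criterion: no scored session may fail it
    if (~df["vision_pass"]).any():
        bad = df.loc[~df["vision_pass"], "dog_id"].iloc[0]
        raise ValidationError("vision_pass must be true for every scored session",
                              dog_id=bad)
    return df


def write_table(df, path, columns=None, provenance=None):
    """Write a generic table using the package CSV dialect.

    ``provenance`` (a string, e.g. package version and seed) is written as a
    leading ``#`` comment line, which readers ignore.
    """
    columns = list(columns) if columns is not None else list(df.columns)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        writer = csv.writer(fh)
        writer.writerow(columns)
        for row in df[columns].itertuples(index=False):
            writer.writerow([_format_value(v) for v in row])


def _format_value(v):
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isnan(v):
            return ""
        return repr(v)
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (np.floating,)):
        x = float(v)
        return "" if math.isnan(x) else repr(x)
    if isinstance(v, (np.integer,)):
        return str(int(v))
    if v is pd.NA or (isinstance(v, float) and math.isnan(v)):
        return ""
    return str(v)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

_SCORE_VALUE_COLUMNS = ("sr_score", "ds_score", "cyl_score", "overall_score")
_SCORE_FLAG_COLUMNS = ("sr_imputed", "ds_imputed", "cyl_imputed")


def validate_scores(df, sessions=None) -> None:
    """Check score-table invariants (optionally against a session table)."""
    missing = [c for c in SCORES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"score table missing column(s) {', '.join(missing)}")
    n_tasks = df[list(_SCORE_VALUE_COLUMNS[:3])].notna().sum(axis=1)
    bad = df["overall_score"].notna() & (n_tasks < 2)
    if bad.any():
        row = df.loc[bad].iloc[0]
        raise ValidationError(
            "overall_score requires at least 2 of 3 task scores",
            dog_id=row["dog_id"], timepoint=row["timepoint"])
    if sessions is not None:
        keys = set(zip(sessions["dog_id"], sessions["timepoint"]))
        for _, row in df.iterrows():
            if (row["dog_id"], row["timepoint"]) not in keys:
                raise ValidationError("score row has no matching session",
                                      dog_id=row["dog_id"],
                                      timepoint=row["timepoint"])


def write_scores(df, path, provenance=None) -> None:
    """Write a score table; round-trips exactly through :func:`read_scores`.

    A warning is logged when a score column's sample SD is implausibly far
    from 1 for standardized scores of that sample size; the file is still
    written.
    """
    validate_scores(df)
    for col in _SCORE_VALUE_COLUMNS:
        vals = df[col].dropna().to_numpy(dtype=float)
        n = len(vals)
        if n >= 3:
            sd = vals.std(ddof=1)
            if sd > 0 and abs(math.log(sd)) > 4.0 / math.sqrt(2 * (n - 1)):
                logger.warning(
                    "column %s has SD %.3g (n=%d); scores do not look standardized",
                    col, sd, n)
    write_table(df, path, SCORES_COLUMNS, provenance=provenance)


def read_scores(path) -> pd.DataFrame:
    rows = list(_read_rows(path, list(SCORES_COLUMNS)))
    df = pd.DataFrame(rows, columns=list(SCORES_COLUMNS))
    if len(df) == 0:
        df = df.astype({c: float for c in
                        ("test_age_years",) + _SCORE_VALUE_COLUMNS})
        for c in _SCORE_FLAG_COLUMNS:
            df[c] = df[c].astype(bool)
        return df
    df["test_age_years"] = pd.to_numeric(df["test_age_years"])
    for c in _SCORE_VALUE_COLUMNS:
        df[c] = pd.to_numeric(df[c].where(df[c] != ""))
    for c in _SCORE_FLAG_COLUMNS:
        df[c] = df[c].map({"true": True, "false": False})
        if df[c].isna().any():
            bad = df.loc[df[c].isna()].iloc[0]
            raise ValidationError(f"invalid boolean in {c}",
                                  dog_id=bad["dog_id"], timepoint=bad["timepoint"])
        df[c] = df[c].astype(bool)
    validate_scores(df)
    return df


def read_measures(path) -> pd.DataFrame:
    rows = list(_read_rows(path, list(MEASURES_COLUMNS)))
    df = pd.DataFrame(rows, columns=list(MEASURES_COLUMNS))
    num_cols = SR_MEASURE_COLUMNS + DS_PROP_COLUMNS + ("cyl_prop",)
    if len(df) == 0:
        return df.astype({c: float for c in num_cols})
    for c in num_cols:
        df[c] = pd.to_numeric(df[c].where(df[c] != ""))
    return df


def write_measures(df, path, provenance=None) -> None:
    write_table(df, path, MEASURES_COLUMNS, provenance=provenance)
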