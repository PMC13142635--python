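"""Independent reference implementations used only to check the scorers.

These replay trial sequences step by step with brute-force window scans,
written separately from the package scorers so the two can disagree.
"""

from canid import data_model as dm


def _finals(trials):
    last = {}
    order = []
    for t in trials:
        slot = t.index if t.repeat_of is None else t.repeat_of
        if slot not in last:
            order.append(slot)
        last[slot] = t
    return [last[s] for s in order]


def brute_force_criterion(outcomes, window=4, required=3):
    """Smallest t >= window whose trailing window holds >= required hits."""
    for t in range(window, len(outcomes) + 1):
        if sum(outcomes[t - window:t]) >= required:
            return t
    return None


def sr_oracle(seq):
    """Replay a Spatial Reversal session; returns a measures dict."""
    if any(t.response == dm.ABORT for t in seq.trials):
        return {"aborted": True}
    finals = _finals(seq.trials)
    base = [t.response == "open" for t in finals
            if t.phase == "baseline" and t.response != dm.NO_CHOICE]
    rev = [t.response == "open" for t in finals
           if t.phase == "reversal" and t.response != dm.NO_CHOICE]
    met = brute_force_criterion(base)
    if met is None:
        return {"aborted": False, "blocks": 0, "longest": 20, "remaining": 0,
                "baseline_failed": True}
    blocks = 1
    lengths = [met]
    remaining = list(rev)
    used = 0
    while remaining and blocks < 4:
        m = brute_force_criterion(remaining)
        if m is None:
            lengths.append(len(remaining))
            used += len(remaining)
            remaining = []
        else:
            blocks += 1
            lengths.append(m)
            used += m
            remaining = remaining[m:]
    return {"aborted": False, "blocks": blocks, "longest": max(lengths),
            "remaining": 20 - used, "baseline_failed": False}


def ds_oracle(seq):
    """Count correct first searches per trial type over final administrations."""
    if any(t.first_search == dm.ABORT for t in seq.trials):
        return {"aborted": True}
    finals = _finals(seq.trials)
    props = []
    for ttype in dm.DS_TRIAL_TYPES:
        scored = [t for t in finals
                  if t.trial_type == ttype and t.first_search != dm.NO_CHOICE]
        if not scored:
            props.append(None)
        else:
            props.append(sum(t.first_search == t.baited_location
                             for t in scored) / len(scored))
    n_nc = sum(t.first_search == dm.NO_CHOICE for t in seq.trials)
    return {"aborted": False, "props": tuple(props), "n_no_choice": n_nc,
            "discontinued": n_nc >= 4}


def cyl_oracle(seq):
    finals = _finals(seq.trials)
    responded = [t for t in finals if t.responded]
    if len(responded) <= 3:
        return {"prop": None, "n_responded": len(responded)}
    return {"prop": sum(not t.touched_exterior for t in responded) / 4,
            "n_responded": len(responded)}
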