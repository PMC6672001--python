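"""Behavioural indices from trial tables.

Implements the standard rodent-battery formulas:

* PPI% = 100 − 100·(mean startle on prepulse+pulse trials at one intensity) /
  (mean startle on the block-2 pulse-alone trials); negative values
  (facilitation) are allowed, and PPI is invariant under rescaling of all
  amplitudes.
* Novelty preference index = 100·T_novel/(T_novel + T_familiar); 50 = no
  preference.
* Spontaneous alternation = 100·(alternating triplets)/(visit triplets),
  where a sliding window of three consecutive arm visits alternates iff all
  three arms are distinct; 50% is chance for a 3-arm maze without
  self-transitions.
* Slip percentage = 100·slips/steps; marble percentage = 100·buried/total.
* Trial-resolved scores feed a two-way repeated-measures ANOVA
  (genotype x trial) with Šidák post-hoc per-trial comparisons, and the
  across-trial subject averages feed a two-sample t-test.
* Touchscreen criterion: first session closing a run of >= 3 consecutive
  sessions at >= 80% correct (inclusive boundary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .errors import ValidationError
from .io import TableSchema

__all__ = [
    "STARTLE_SCHEMA",
    "ppi_percent",
    "preference_index",
    "collapse_revisits",
    "alternation_score",
    "slip_percentage",
    "marble_percentage",
    "trial_summary",
    "criterion_session",
]

STARTLE_SCHEMA = TableSchema(
    required={"subject_id": str, "block": int, "trial_type": str,
              "prepulse_db": float, "amplitude": float},
)

PREPULSE_INTENSITIES_DB = (0.0, 3.0, 7.0, 11.0, 19.0)


def ppi_percent(startle: pd.DataFrame, subject: str) -> tuple[dict[float, float], float]:
    """Per-intensity PPI% and the across-intensity average for one subject.

    The denominator is the mean amplitude of the subject's block-2
    pulse-alone trials.  A zero denominator leaves every PPI undefined
    (NaN).  Returns ({prepulse dB above background: PPI%}, average).
    """
    sub = startle[startle.subject_id == subject]
    pa = sub[(sub.block == 2) & (sub.trial_type == "pulse_alone")]
    if len(pa) == 0:
        raise ValidationError(f"subject {subject!r}: no block-2 pulse-alone trials")
    denom = float(pa.amplitude.mean())
    pp = sub[sub.trial_type == "prepulse_pulse"]
    out: dict[float, float] = {}
    for level, grp in pp.groupby("prepulse_db"):
        if denom == 0.0:
            out[float(level)] = float("nan")
        else:
            out[float(level)] = 100.0 - (float(grp.amplitude.mean()) / denom) * 100.0
    if not out:
        raise ValidationError(f"subject {subject!r}: no prepulse trials")
    vals = np.array(list(out.values()))
    avg = float(vals.mean()) if np.all(np.isfinite(vals)) else float("nan")
    return out, avg


def preference_index(time_novel_s: float, time_familiar_s: float) -> float:
    """100·T_novel/(T_novel + T_familiar); NaN if both times are zero."""
    if time_novel_s < 0 or time_familiar_s < 0:
        raise ValidationError("times must be non-negative")
    total = time_novel_s + time_familiar_s
    if total == 0:
        return float("nan")
    return 100.0 * time_novel_s / total


def collapse_revisits(visits) -> list:
    """Collapse immediate re-entries into the same arm into one visit."""
    out = []
    for v in visits:
        if not out or out[-1] != v:
            out.append(v)
    return out


def alternation_score(visits) -> tuple[float, int]:
    """Spontaneous-alternation percentage and the entry count.

    Visits are collapsed (no self-transitions), then every sliding triplet
    of consecutive visits is scored: it alternates iff its three entries are
    distinct.  Score = 100·alternations/triplets.  Fewer than 3 visits ->
    NaN, flagged by the caller via the entry count.
    """
    seq = collapse_revisits(list(visits))
    n = len(seq)
    if n < 3:
        return float("nan"), n
    triplets = n - 2
    alternations = sum(len({seq[i], seq[i + 1], seq[i + 2]}) == 3
                       for i in range(triplets))
    return 100.0 * alternations / triplets, n


def slip_percentage(n_slips: int, n_steps: int) -> float:
    """100·slips/steps."""
    if n_steps <= 0:
        raise ValidationError("step count must be positive")
    if n_slips < 0 or n_slips > n_steps:
        raise ValidationError("slips must lie in [0, steps]")
    return 100.0 * n_slips / n_steps


def marble_percentage(n_buried: int, n_total: int = 20) -> float:
    """100·buried/total marbles (buried = at least two-thirds covered)."""
    if n_total <= 0:
        raise ValidationError("total must be positive")
    if n_buried < 0 or n_buried > n_total:
        raise ValidationError("buried must lie in [0, total]")
    return 100.0 * n_buried / n_total


def trial_summary(trials: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Trial-resolved group analysis of a latency/score table.

    ``trials`` has columns subject_id, group, trial, value.  Subjects with no
    trials are excluded (logged in the output).  Returns per-trial group
    means, the across-trial subject averages with their two-sample t-test,
    the two-way RM-ANOVA (genotype x trial) and Šidák post-hoc per-trial
    comparisons.  With a single trial the RM-ANOVA degenerates to the
    t-test alone.
    """
    required = {"subject_id", "group", "trial", "value"}
    if not required <= set(trials.columns):
        raise ValidationError(f"trial table needs columns {sorted(required)}")
    trials = trials.dropna(subset=["value"])
    per_trial = (trials.groupby(["group", "trial"])["value"]
                 .agg(mean="mean", sem="sem", n="count").reset_index())
    subj = (trials.groupby(["subject_id", "group"])["value"]
            .mean().reset_index(name="avg"))
    groups = sorted(subj.group.unique())
    if len(groups) != 2:
        raise ValidationError("trial_summary expects exactly 2 groups")
    a = subj.loc[subj.group == groups[0], "avg"].to_numpy()
    b = subj.loc[subj.group == groups[1], "avg"].to_numpy()
    ttest = stats.two_sample_t(a, b, alpha=alpha)
    out = {"per_trial": per_trial, "subject_averages": subj, "t_test": ttest}
    if trials["trial"].nunique() >= 2:
        fit = stats.two_way_rm_anova(trials["value"], trials["group"],
                                     trials["trial"], trials["subject_id"],
                                     alpha=alpha)
        out["rm_anova"] = fit.results
        out["posthoc"] = stats.sidak_posthoc(fit, alpha=alpha)
    else:
        out["rm_anova"] = None
        out["note"] = "single trial: repeated-measures ANOVA degenerates to the t-test"
    return out


def criterion_session(percent_correct, criterion: float = 80.0,
                      consecutive: int = 3) -> int | None:
    """First session (1-based) closing a run of >= ``consecutive`` sessions
    at >= ``criterion`` percent correct; None if never reached."""
    pc = list(percent_correct)
    if not pc:
        raise ValidationError("empty session record")
    run = 0
    for i, p in enumerate(pc, start=1):
        run = run + 1 if p >= criterion else 0
        if run >= consecutive:
            return i
    return None
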