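"""Behavioural score arithmetic.

Three scorers defined directly by their task arithmetic: Attention Network
Test (ANT) effect scores as differences of condition-mean reaction times,
theory-of-mind (ToM) scores as reaction-time differences between vignette
conditions, and symmetric-Likert questionnaire scoring with subscales (the
granular AQ convention).  All other instruments (SRS, EQ, SQ, SSQ, RMET,
COWA, Animal Names, FC-EFT, WASI) enter the pipeline as pre-computed numeric
scores in the behavioural table.

Trial tables are tidy data frames with columns ``subject, task, condition,
rt_ms, correct``; only correct trials enter any mean.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import pandas as pd

__all__ = [
    "ANT_CONDITIONS",
    "TRIAL_COLUMNS",
    "score_ant_effects",
    "score_tom_differences",
    "score_symmetric_likert",
    "SYMMETRIC_4POINT",
]

TRIAL_COLUMNS = ("subject", "condition", "rt_ms", "correct")

#: Condition labels the ANT scorer requires.  Cue conditions are means over
#: flanker types; the two no-cue x flanker cells define the conflict effect.
ANT_CONDITIONS = (
    "no_cue",
    "central_cue",
    "spatial_cue",
    "no_cue_congruent",
    "no_cue_incongruent",
)

#: Default symmetric 4-point Likert map: level -> score.
SYMMETRIC_4POINT = {1: -2, 2: -1, 3: 1, 4: 2}


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    if (trials["rt_ms"] <= 0).any():
        raise ValueError("reaction times must be positive")
    return trials[trials["correct"].astype(bool)]


def _condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean correct-trial RT for every condition (wide layout)."""
    return trials.groupby(["subject", "condition"])["rt_ms"].mean().unstack("condition")


def score_ant_effects(
    trials: pd.DataFrame,
    sign_convention: Literal["positive_cost", "as_printed"] = "positive_cost",
) -> pd.DataFrame:
    """ANT alerting, orienting, conflict and grand-mean scores (ms) per subject.

    ``as_printed`` follows the literal subtraction order (alerting = central
    cue minus no cue; orienting = spatial cue minus central cue), which makes
    cueing benefits negative; ``positive_cost`` (default) flips alerting and
    orienting so slower performance scores positive, matching the sign of the
    usual group-mean tables.  Conflict (no-cue incongruent minus no-cue
    congruent) is identical under both conventions.
    """
    if sign_convention not in ("positive_cost", "as_printed"):
        raise ValueError(f"unknown sign_convention {sign_convention!r}")
    correct = _validate_trials(trials)
    means = _condition_means(correct)
    absent = [c for c in ANT_CONDITIONS if c not in means.columns or means[c].isna().any()]
    if absent:
        raise ValueError(f"missing ANT condition(s): {absent}")
    alerting = means["central_cue"] - means["no_cue"]
    orienting = means["spatial_cue"] - means["central_cue"]
    conflict = means["no_cue_incongruent"] - means["no_cue_congruent"]
    if sign_convention == "positive_cost":
        alerting = -alerting
        orienting = -orienting
    grand_mean = correct.groupby("subject")["rt_ms"].mean()
    return pd.DataFrame(
        {
            "alerting": alerting,
            "orienting": orienting,
            "conflict": conflict,
            "grand_mean": grand_mean,
        }
    )


def score_tom_differences(
    trials: pd.DataFrame,
    contrast_spec: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Theory-of-mind scores (seconds) as condition-mean RT differences.

    ``contrast_spec`` maps each score name (e.g. second-order, egocentric and
    allocentric first-order ToM) to a pair ``(condition_a, condition_b)``;
    the score is mean RT(a) - mean RT(b) over correct trials, converted from
    ms to seconds.  The vignette-to-score pairing is study configuration, not
    package policy, so it is always injected.
    """
    correct = _validate_trials(trials)
    means = _condition_means(correct)
    out = {}
    for name, (cond_a, cond_b) in contrast_spec.items():
        for cond in (cond_a, cond_b):
            if cond not in means.columns:
                raise ValueError(f"contrast {name!r} references unknown condition {cond!r}")
        out[name] = (means[cond_a] - means[cond_b]) / 1000.0
    return pd.DataFrame(out)


def score_symmetric_likert(
    responses: pd.DataFrame,
    directions: Mapping[str, int],
    subscales: Mapping[str, str] | None = None,
    level_scores: Mapping[int, int] | None = None,
    composites: Mapping[str, Sequence[str]] | None = None,
    total_name: str = "total",
) -> pd.DataFrame:
    """Symmetric-Likert questionnaire scoring with subscales.

    ``responses`` is item x subject (index: item ids, columns: subjects) with
    integer levels; ``directions`` maps each item to +1 (agreement is keyed)
    or -1 (reverse keyed); ``level_scores`` maps levels to symmetric scores
    (default 4-point {1: -2, 2: -1, 3: +1, 4: +2}).  An item's score is
    ``direction * level_scores[response]``; the total is the sum over items
    and each subscale sums its own items.  ``composites`` optionally sums
    groups of subscales (e.g. a social composite over attention-switching,
    communication, imagination and social-skill subscales).

    Returns subjects x (total, subscales..., composites...).
    """
    level_scores = dict(level_scores or SYMMETRIC_4POINT)
    missing_dir = [item for item in responses.index if item not in directions]
    if missing_dir:
        raise ValueError(f"scoring key missing direction for item(s): {missing_dir}")
    bad_dir = {i: d for i, d in directions.items() if d not in (-1, 1)}
    if bad_dir:
        raise ValueError(f"item directions must be +1 or -1, got {bad_dir}")
    valid = set(level_scores)
    for item in responses.index:
        bad = set(responses.loc[item].dropna().unique()) - valid
        if bad:
            raise ValueError(f"item {item!r} has out-of-range response(s) {sorted(bad)}")

    mapped = responses.replace(level_scores).astype(float)
    signed = mapped.mul(pd.Series({i: directions[i] for i in responses.index}), axis=0)

    out = pd.DataFrame({total_name: signed.sum(axis=0)})
    if subscales is not None:
        unknown = [i for i in subscales if i not in responses.index]
        if unknown:
            raise ValueError(f"subscale map references unknown item(s): {unknown}")
        for name in dict.fromkeys(subscales.values()):
            items = [i for i, s in subscales.items() if s == name]
            out[name] = signed.loc[items].sum(axis=0)
    for name, parts in (composites or {}).items():
        absent = [p for p in parts if p not in out.columns]
        if absent:
            raise ValueError(f"composite {name!r} references unknown subscale(s): {absent}")
        out[name] = out[list(parts)].sum(axis=1)
    return out
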