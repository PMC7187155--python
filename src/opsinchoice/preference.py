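"""Dichotomous mate-choice scoring and repeatability.

In the dual-choice design a gravid female interacts with one blue and
one red male; every male courtship event (lateral display, LD, or
quiver, Q) receives a positive or negative female response.  A trial is
valid when 20 min of interaction time accrued within one hour of wall
clock and each male quivered at least three times.  The per-trial
preference index for behaviour b is

    pref_b = positive_red_b / total_red_b - positive_blue_b / total_blue_b

ranging from -1 (blue) to +1 (red).  Per-female means and the
among-female repeatability R (intraclass correlation from a one-way
variance decomposition) summarise repeated trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEHAVIOURS = ("LD", "Q")

MIN_INTERACTION_MIN = 20.0
MAX_WALL_CLOCK_MIN = 60.0
MIN_QUIVERS = 3


@dataclass(frozen=True)
class CourtshipEvent:
    elapsed_min: float
    male_species: str        # 'blue' | 'red'
    behaviour: str           # 'LD' | 'Q'
    response: str            # 'positive' | 'negative'


@dataclass
class CourtshipTrial:
    trial_id: str
    female_id: str
    observer_id: str
    test_light: str                       # 'shallow' | 'deep'
    male_ids: dict                        # species -> male id
    events: list
    total_interaction_minutes: float
    wall_clock_minutes: float

    def __post_init__(self):
        species = set(self.male_ids)
        if species != {"blue", "red"}:
            raise ValueError("trial needs exactly one blue and one red male")
        times = [e.elapsed_min for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be nondecreasing")
        if times and times[-1] > self.total_interaction_minutes + 1e-9:
            raise ValueError("event time exceeds total interaction time")


@dataclass
class TrialScore:
    trial_id: str
    female_id: str
    pref_LD: float | None
    pref_Q: float | None
    counts: dict                 # (species, behaviour) -> (total, positive)
    valid: bool
    reasons: list = field(default_factory=list)


def validate_trial(trial: CourtshipTrial):
    """Apply the trial-validity rule; returns (valid, reasons)."""
    reasons = []
    if trial.total_interaction_minutes < MIN_INTERACTION_MIN:
        reasons.append("interaction_time")
    if trial.wall_clock_minutes > MAX_WALL_CLOCK_MIN:
        reasons.append("wall_clock")
    for species in ("blue", "red"):
        n_q = sum(1 for e in trial.events
                  if e.male_species == species and e.behaviour == "Q")
        if n_q < MIN_QUIVERS:
            reasons.append("min_quivers")
            break
    return not reasons, reasons


def score_trial(trial: CourtshipTrial, require_valid: bool = True) -> TrialScore:
    """Compute the LD- and Q-based preference indices for one trial.

    A behaviour's score is undefined (None) when either male has no
    events of that behaviour; the other behaviour is unaffected.
    """
    valid, reasons = validate_trial(trial)
    counts = {(s, b): [0, 0] for s in ("blue", "red") for b in BEHAVIOURS}
    for e in trial.events:
        tot = counts[(e.male_species, e.behaviour)]
        tot[0] += 1
        if e.response == "positive":
            tot[1] += 1
    prefs = {}
    for b in BEHAVIOURS:
        t_red, p_red = counts[("red", b)]
        t_blue, p_blue = counts[("blue", b)]
        if t_red == 0 or t_blue == 0:
            prefs[b] = None
        else:
            prefs[b] = p_red / t_red - p_blue / t_blue
    if require_valid and not valid:
        prefs = {b: None for b in BEHAVIOURS}
    return TrialScore(trial.trial_id, trial.female_id,
                      prefs["LD"], prefs["Q"],
                      {k: tuple(v) for k, v in counts.items()},
                      valid, reasons)


def parse_trials(trials_df: pd.DataFrame, events_df: pd.DataFrame) -> list:
    """Assemble CourtshipTrial objects from the tabular event-log dialect.

    trials_df columns: trial_id, female_id, observer_id, test_light,
    blue_male_id, red_male_id, total_interaction_minutes,
    wall_clock_minutes.  events_df columns: trial_id, elapsed_min,
    male_species, behaviour, response.
    """
    ev_by_trial = {k: g for k, g in events_df.groupby("trial_id")}
    trials = []
    for _, row in trials_df.iterrows():
        tid = row["trial_id"]
        evs = ev_by_trial.get(tid)
        events = []
        if evs is not None:
            for _, e in evs.sort_values("elapsed_min").iterrows():
                events.append(CourtshipEvent(float(e["elapsed_min"]),
                                             str(e["male_species"]),
                                             str(e["behaviour"]),
                                             str(e["response"])))
        trials.append(CourtshipTrial(
            str(tid), str(row["female_id"]), str(row.get("observer_id", "")),
            str(row["test_light"]),
            {"blue": str(row["blue_male_id"]), "red": str(row["red_male_id"])},
            events,
            float(row["total_interaction_minutes"]),
            float(row["wall_clock_minutes"])))
    return trials


def score_trials(trials, trials_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Score a collection of trials into a tidy table."""
    meta = {}
    if trials_df is not None:
        meta = {str(r["trial_id"]): r for _, r in trials_df.iterrows()}
    rows = []
    for t in trials:
        s = score_trial(t)
        row = {"trial_id": s.trial_id, "female_id": s.female_id,
               "test_light": t.test_light, "observer_id": t.observer_id,
               "valid": s.valid, "reasons": ";".join(s.reasons),
               "pref_LD": np.nan if s.pref_LD is None else s.pref_LD,
               "pref_Q": np.nan if s.pref_Q is None else s.pref_Q}
        if s.trial_id in meta:
            for k, v in meta[s.trial_id].items():
                row.setdefault(k, v)
        rows.append(row)
    return pd.DataFrame(rows)


def mean_preference(scores: pd.DataFrame, by_test_light: bool = False) -> pd.DataFrame:
    """Per-female mean preference over valid trials with defined scores.

    Undefined per-trial scores are excluded from the mean rather than
    imputed as zero (zero would fabricate indifference).
    """
    df = scores[scores["valid"]].copy()
    keys = ["female_id"] + (["test_light"] if by_test_light else [])
    agg = df.groupby(keys).agg(
        mean_pref_LD=("pref_LD", "mean"),
        mean_pref_Q=("pref_Q", "mean"),
        n_trials=("trial_id", "count"),
        n_LD=("pref_LD", "count"),
        n_Q=("pref_Q", "count"),
    ).reset_index()
    return agg


@dataclass
class Repeatability:
    R: float
    var_among: float
    var_within: float
    n_groups: int
    n_obs: int


def repeatability(values, groups) -> Repeatability:
    """One-way ANOVA intraclass correlation (repeatability).

    R = s2_among / (s2_among + s2_within) with the variance components
    from the one-way random-intercept decomposition (unbalanced designs
    use the standard n0 coefficient); negative point estimates of the
    among-group component are truncated to zero.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    sizes = df.groupby("g").size()
    sizes = sizes[sizes >= 2]
    if len(sizes) < 2:
        raise ValueError("repeatability needs >= 2 groups with >= 2 trials each")
    df = df[df["g"].isin(sizes.index)]
    k = len(sizes)
    N = int(sizes.sum())
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ss_among = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (sizes ** 2).sum() / N) / (k - 1)
    var_among = max(0.0, (ms_among - ms_within) / n0)
    denom = var_among + ms_within
    r = var_among / denom if denom > 0 else 0.0
    return Repeatability(float(r), float(var_among), float(ms_within), k, N)
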