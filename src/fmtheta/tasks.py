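"""Executive-function battery: n-back, SART and local-global tasks.

Generators emit the trial structures used pre/post training (n-back:
280 letters from {A,B,C,D} per load, target = match `load` trials back;
SART: 250 digits 0-9 with no immediate repeats, no-go on 3; local-global:
200 trials of large H/T made of small H/T over 4 instruction sessions,
global/local alternating). Scoring treats each trial as a signal-detection
decision (hit / miss / false alarm / correct rejection) and summarizes
reaction times over correct response trials only. A parametric simulated
responder (d-prime + log-normal RTs) makes the group-level GLM analysis
testable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NBACK_LETTERS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class TaskTiming:
    """Stimulus timing defaults (ms)."""

    nback_stim: float = 1000.0
    nback_fixation: float = 500.0
    nback_window: float = 1500.0
    sart_stim: float = 400.0
    sart_isi: float = 2000.0
    localglobal_delay: float = 1000.0


@dataclass
class TrialRecord:
    task: str
    condition: str
    stimulus: str
    is_target: bool
    response: str | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        if (self.response is None) != (self.rt is None):
            raise ValueError("rt must be present iff a response is present")


# ---------------------------------------------------------- generators ----

def gen_nback(load: int, n_trials: int = 280,
              seed: int = 0) -> list[TrialRecord]:
    """n-back letter sequence; trial i is a target iff stimulus[i] equals
    stimulus[i - load] (the first ``load`` trials are never targets)."""
    if load not in (1, 2, 3):
        raise ValueError(f"load must be 1, 2 or 3, got {load}")
    rng = np.random.default_rng(seed)
    letters = rng.choice(NBACK_LETTERS, size=n_trials)
    trials = []
    for i, s in enumerate(letters):
        target = i >= load and s == letters[i - load]
        trials.append(TrialRecord("nback", f"{load}-back", str(s),
                                  bool(target)))
    return trials


def gen_sart(n_trials: int = 250, seed: int = 0,
             nogo_digit: int = 3) -> list[TrialRecord]:
    """SART digit sequence: digits 0-9, never the same digit twice in a
    row; no-go (response-withhold) trials are the digit 3."""
    rng = np.random.default_rng(seed)
    digits = np.empty(n_trials, dtype=int)
    prev = -1
    for i in range(n_trials):
        while True:
            d = int(rng.integers(0, 10))
            if d != prev:
                break
        digits[i] = d
        prev = d
    # go trials are the targets of the press response
    return [TrialRecord("sart", "nogo" if d == nogo_digit else "go",
                        str(d), d != nogo_digit) for d in digits]


def gen_localglobal(n_sessions: int = 4, trials_per: int = 50,
                    seed: int = 0) -> list[TrialRecord]:
    """Local-global trials: large H/T composed of small H/T; instruction is
    global for sessions 1 and 3, local for sessions 2 and 4. The correct
    response is the letter at the instructed level; ``is_target`` is unused
    (every trial requires a categorization) and set True."""
    rng = np.random.default_rng(seed)
    trials = []
    for s in range(1, n_sessions + 1):
        instruction = "global" if s % 2 == 1 else "local"
        for _ in range(trials_per):
            large = str(rng.choice(("H", "T")))
            small = str(rng.choice(("H", "T")))
            congruent = large == small
            cond = (f"{instruction}-"
                    f"{'congruent' if congruent else 'incongruent'}")
            trials.append(TrialRecord(
                "localglobal", cond, f"{large}of{small}", True))
    return trials


def correct_response(trial: TrialRecord) -> str | None:
    """The response (key) that counts as correct; None means withhold."""
    if trial.task in ("nback", "sart"):
        return "space" if trial.is_target else None
    if trial.task == "localglobal":
        large, small = trial.stimulus.split("of")
        level = trial.condition.split("-")[0]
        return large if level == "global" else small
    raise ValueError(f"unknown task {trial.task!r}")


# ------------------------------------------------------------- scoring ----

def score_task(trials: list[TrialRecord]) -> dict[str, float]:
    """Signal-detection summary of responded trials.

    hits: correct presses (or correct categorizations); misses: required
    response withheld/wrong; false_alarms: presses on withhold trials;
    correct_rejections: correctly withheld. RT statistics cover correct
    response trials only.
    """
    hits = misses = fas = crs = 0
    rts = []
    for t in trials:
        want = correct_response(t)
        if want is None:
            if t.response is None:
                crs += 1
            else:
                fas += 1
        else:
            if t.response == want:
                hits += 1
                if t.rt is not None:
                    rts.append(t.rt)
            else:
                misses += 1
    n = len(trials)
    correct = hits + crs
    return {
        "n_trials": n, "hits": hits, "misses": misses,
        "false_alarms": fas, "correct_rejections": crs,
        "n_correct": correct,
        "accuracy": correct / n if n else float("nan"),
        "mean_rt": float(np.mean(rts)) if rts else float("nan"),
        "median_rt": float(np.median(rts)) if rts else float("nan"),
    }


# -------------------------------------------------- simulated responder ----

def simulate_responder(trials: list[TrialRecord], dprime: float,
                       rt_mean: float = 500.0, rt_sd: float = 100.0,
                       seed: int = 0,
                       criterion: float = 0.0) -> list[TrialRecord]:
    """Attach responses from an equal-variance signal-detection model.

    Each trial draws evidence ~ N(d'/2, 1) when the correct action is to
    respond and N(-d'/2, 1) otherwise; a response is emitted when evidence
    exceeds ``criterion``. For categorization tasks (local-global) the
    emitted key is the correct one when evidence favors it, else the other
    key. RTs are log-normal with the requested mean/SD (ms).
    """
    if rt_sd <= 0:
        raise ValueError("rt_sd must be positive")
    dprime = min(dprime, 20.0)  # clamp: beyond this accuracy is exact
    rng = np.random.default_rng(seed)
    sigma2 = np.log(1.0 + (rt_sd / rt_mean) ** 2)
    mu = np.log(rt_mean) - sigma2 / 2.0
    out = []
    for t in trials:
        want = correct_response(t)
        evidence = rng.normal(dprime / 2.0 if want is not None
                              else -dprime / 2.0, 1.0)
        respond = evidence > criterion
        if t.task == "localglobal":
            # always responds; evidence decides which key
            keys = ("H", "T")
            other = keys[1 - keys.index(want)]
            key = want if respond else other
            rt = float(rng.lognormal(mu, np.sqrt(sigma2)))
            out.append(TrialRecord(t.task, t.condition, t.stimulus,
                                   t.is_target, key, rt))
        elif respond:
            rt = float(rng.lognormal(mu, np.sqrt(sigma2)))
            out.append(TrialRecord(t.task, t.condition, t.stimulus,
                                   t.is_target, "space", rt))
        else:
            out.append(TrialRecord(t.task, t.condition, t.stimulus,
                                   t.is_target, None, None))
    return out


# ----------------------------------------------------------- battery GLM ----

def battery_glm(summaries: pd.DataFrame, dv: str = "count"
                ) -> pd.DataFrame:
    """GLM F-table for the battery outcomes.

    ``summaries`` is long-format with columns ``subject``, ``group``,
    ``condition``, ``session`` (pre/post), ``response`` (hit vs correct
    rejection) and the dependent variable column ``dv``. The model is a
    fixed-effects least-squares fit with all main effects and interactions
    of group x condition x session x response plus subject nested in group,
    tested with Type-II F-tests (sum-to-zero coding).

    Returns a DataFrame indexed by term with columns F, p, df.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"subject", "group", "condition", "session", "response", dv}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = summaries.copy().reset_index(drop=True)
    # nested coding: sum-to-zero subject deviations *within* each group
    # (the last subject of a group carries -1), leaving the group main
    # effect estimable while absorbing between-subject variance
    nested_cols = []
    for g, sub in df.groupby("group"):
        subjects = pd.unique(sub["subject"])
        last = subjects[-1]
        for j, s in enumerate(subjects[:-1]):
            col = f"_subj_{g}_{j}"
            df[col] = np.where(
                df["subject"] == s, 1.0,
                np.where((df["subject"] == last) & (df["group"] == g),
                         -1.0, 0.0))
            nested_cols.append(col)
    factors = ["group", "condition", "session", "response"]
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    formula = f"{dv} ~ {terms} + " + " + ".join(nested_cols)
    model = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design; check the subject and "
                         "group columns")
    table = anova_lm(model, typ=2)
    table = table.rename(columns={"PR(>F)": "p"})
    # collapse the per-subject columns into one Subject(Group) row
    subj_rows = table.loc[table.index.isin(nested_cols)]
    table = table.drop(index=subj_rows.index)
    ss, dfree = subj_rows["sum_sq"].sum(), subj_rows["df"].sum()
    resid = table.loc["Residual"]
    ms_res = resid["sum_sq"] / resid["df"]
    from scipy import stats as _st

    f_subj = (ss / dfree) / ms_res
    p_subj = _st.f.sf(f_subj, dfree, resid["df"])
    table.loc["Subject(Group)"] = {
        "sum_sq": ss, "df": dfree, "F": f_subj, "p": p_subj}
    order = [i for i in table.index if i != "Residual"] + ["Residual"]
    return table.loc[order, ["F", "p", "df"]]


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """One row per trial, ready for CSV export."""
    return pd.DataFrame([{
        "task": t.task, "condition": t.condition, "stimulus": t.stimulus,
        "is_target": t.is_target, "response": t.response, "rt": t.rt,
    } for t in trials])
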