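"""Finger-tapping task scoring and clinical response classification.

The tapping task: 12 training runs of 30 s (correct-sequence counts) in the
evening, 3 test runs the next morning.  Training effect = mean of the last
three training runs minus the first run; consolidation effect = mean of the
three test runs minus the mean of the last three training runs.  Both
absolute and relative (divided by run 1 / by the last-three mean) variants
are produced; the relative variant is the group-statistics default.

Clinical response: at least a 50% reduction of the Hamilton depression
score (HAMD) between baseline and day 28.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TappingSession",
    "TappingScores",
    "ClinicalCourse",
    "score_tapping",
    "classify_responder",
    "read_tapping_sessions",
    "read_hamd_courses",
]

N_TRAINING_RUNS = 12
N_TEST_RUNS = 3


@dataclass
class TappingSession:
    training_runs: list[int]   # 12 correct-sequence counts
    test_runs: list[int]       # 3 counts, next morning

    def __post_init__(self):
        for name, runs, n in (("training", self.training_runs, N_TRAINING_RUNS),
                              ("test", self.test_runs, N_TEST_RUNS)):
            if len(runs) != n:
                raise ValueError(f"expected {n} {name} runs, got {len(runs)}")
            if any(r < 0 for r in runs):
                raise ValueError(f"negative {name} run count")


@dataclass
class TappingScores:
    baseline: float                       # run 1 count
    training_effect_abs: float
    training_effect_rel: float | None     # absent when run 1 = 0
    consolidation_abs: float
    consolidation_rel: float | None       # absent when last-3 mean = 0


@dataclass
class ClinicalCourse:
    hamd_baseline: float | None
    hamd_day7: float | None = None
    hamd_day28: float | None = None


def score_tapping(sess: TappingSession) -> TappingScores:
    baseline = float(sess.training_runs[0])
    last3 = float(np.mean(sess.training_runs[-3:]))
    test = float(np.mean(sess.test_runs))
    training_abs = last3 - baseline
    consolidation_abs = test - last3
    return TappingScores(
        baseline=baseline,
        training_effect_abs=training_abs,
        training_effect_rel=training_abs / baseline if baseline > 0 else None,
        consolidation_abs=consolidation_abs,
        consolidation_rel=consolidation_abs / last3 if last3 > 0 else None,
    )


def classify_responder(course: ClinicalCourse) -> bool | None:
    """True iff HAMD dropped by >= 50% from baseline to day 28; None when the
    day-28 score is missing."""
    if course.hamd_baseline is None or course.hamd_day28 is None:
        return None
    if course.hamd_baseline <= 0:
        raise ValueError("baseline HAMD must be positive")
    reduction = (course.hamd_baseline - course.hamd_day28) / course.hamd_baseline
    return bool(reduction >= 0.5)


def read_tapping_sessions(path) -> dict[str, TappingSession]:
    """Read TSV (subject_id, session_id, run_type, run_index, correct_count);
    returns one session per subject (missing runs are an error)."""
    df = pd.read_csv(path, sep="\t")
    sessions = {}
    for sid, grp in df.groupby("subject_id"):
        runs = {}
        for kind, n in (("train", N_TRAINING_RUNS), ("test", N_TEST_RUNS)):
            sub = grp[grp["run_type"] == kind].set_index("run_index")["correct_count"]
            missing = sorted(set(range(1, n + 1)) - set(sub.index))
            if missing:
                raise ValueError(f"subject {sid}: missing {kind} runs {missing}")
            runs[kind] = [int(sub[i]) for i in range(1, n + 1)]
        sessions[str(sid)] = TappingSession(training_runs=runs["train"],
                                            test_runs=runs["test"])
    return sessions


def read_hamd_courses(path) -> dict[str, ClinicalCourse]:
    """Read TSV (subject_id, timepoint_days, score) into per-subject courses
    (timepoints 0 / 7 / 28)."""
    df = pd.read_csv(path, sep="\t")
    courses = {}
    for sid, grp in df.groupby("subject_id"):
        by_day = dict(zip(grp["timepoint_days"].astype(int), grp["score"].astype(float)))
        courses[str(sid)] = ClinicalCourse(hamd_baseline=by_day.get(0),
                                           hamd_day7=by_day.get(7),
                                           hamd_day28=by_day.get(28))
    return courses
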