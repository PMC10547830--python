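"""Repeated k-fold cross-validation plans under four splitting schemes.

The four schemes differ in (a) the unit that is assigned to folds and
(b) the cropping overlap of the trial set they expect:

========  ========  ================
scheme    grouping  expected overlap
========  ========  ================
``sCV``   subject   0 (non-overlap)
``osCV``  subject   0.75
``tCV``   trial     0 (non-overlap)
``otCV``  trial     0.75
========  ========  ================

Subject grouping keeps all crops of a subject on one side of every split
(the honest design); trial grouping splits crops at random regardless of
subject, so crops of one recording appear in both training and test data —
the leakage the trial-grouped schemes are built to exhibit.  Every plan is
audited: the *contamination* of a fold is the fraction of test trials whose
subject also has at least one trial in the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .augment import TrialSet
from .errors import ConfigurationError, ContaminationError

SCHEME_NAMES = ("sCV", "osCV", "tCV", "otCV")


@dataclass(frozen=True)
class CVScheme:
    """One of the four named cross-validation strategies."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ConfigurationError(
                f"scheme name must be one of {SCHEME_NAMES}, got {self.name!r}"
            )

    @property
    def grouping(self) -> str:
        """'subject' for sCV/osCV, 'trial' for tCV/otCV."""
        return "subject" if self.name in ("sCV", "osCV") else "trial"

    @property
    def required_overlap(self) -> float:
        return 0.75 if self.name in ("osCV", "otCV") else 0.0

    @property
    def uses_voting(self) -> bool:
        """Subject-grouped schemes aggregate trial votes into one decision
        per subject; trial-grouped schemes are scored per trial."""
        return self.grouping == "subject"


def scheme(name: str) -> CVScheme:
    return CVScheme(name)


@dataclass
class CVPlan:
    """A repeated k-fold assignment of trial indices to train/test."""

    scheme: CVScheme
    k: int
    repeats: int
    seed: int
    n_trials: int
    #: folds[r][f] = (train_idx, test_idx) as int arrays
    folds: list[list[tuple[np.ndarray, np.ndarray]]] = field(repr=False)
    #: contamination[r][f] = fraction of test trials with a same-subject trial in train
    contamination: list[list[float]] = field(repr=False)
    degenerate_equal: bool = False  # one trial per subject: all schemes coincide
    stratified: bool = True

    def mean_contamination(self) -> float:
        return float(np.mean([c for rep in self.contamination for c in rep]))

    def to_json(self) -> str:
        return json.dumps({
            "scheme": self.scheme.name,
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "n_trials": self.n_trials,
            "degenerate_equal": self.degenerate_equal,
            "stratified": self.stratified,
            "folds": [[[tr.tolist(), te.tolist()] for tr, te in rep] for rep in self.folds],
            "contamination": self.contamination,
        })

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def from_json(cls, s: str) -> "CVPlan":
        d = json.loads(s)
        folds = [[(np.asarray(tr, dtype=int), np.asarray(te, dtype=int)) for tr, te in rep]
                 for rep in d["folds"]]
        return cls(scheme=CVScheme(d["scheme"]), k=d["k"], repeats=d["repeats"],
                   seed=d["seed"], n_trials=d["n_trials"], folds=folds,
                   contamination=d["contamination"],
                   degenerate_equal=d["degenerate_equal"], stratified=d["stratified"])

    @classmethod
    def load(cls, path: str | Path) -> "CVPlan":
        return cls.from_json(Path(path).read_text())


def _repeat_rng_state(seed: int, repeat: int) -> int:
    """Independent but reproducible sub-seed for one repetition."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(repeat,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_cv_plan(trialset: TrialSet, scheme: CVScheme, k: int = 10,
                 repeats: int = 10, seed: int = 0,
                 check_overlap: bool = True) -> CVPlan:
    """Build a repeated, label-stratified k-fold plan for a trial set.

    Subject grouping assigns whole subjects to folds (stratified by
    diagnosis so each fold's class ratio tracks the cohort's); all of a
    subject's trials follow its fold.  Trial grouping stratifies individual
    trials by label, ignoring subject identity.  The plan is a pure
    function of (trial manifest, scheme, k, repeats, seed).
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if check_overlap and trialset.params.overlap_fraction != scheme.required_overlap:
        raise ConfigurationError(
            f"scheme {scheme.name} expects overlap {scheme.required_overlap}, "
            f"trialset was cropped with overlap {trialset.params.overlap_fraction}"
        )
    subjects, subj_inverse = np.unique(trialset.subject_ids, return_inverse=True)
    subj_labels = np.array(
        [trialset.labels[subj_inverse == i][0] for i in range(subjects.size)])
    trials_per_subject = np.bincount(subj_inverse)
    if scheme.grouping == "subject" and subjects.size < k:
        raise ConfigurationError(
            f"subject-grouped CV needs at least k={k} subjects, got {subjects.size}"
        )

    folds: list[list[tuple[np.ndarray, np.ndarray]]] = []
    all_idx = np.arange(trialset.n_trials)
    for r in range(repeats):
        state = _repeat_rng_state(seed, r)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
        rep: list[tuple[np.ndarray, np.ndarray]] = []
        if scheme.grouping == "subject":
            for tr_s, te_s in splitter.split(np.zeros(subjects.size), subj_labels):
                te_mask = np.isin(subj_inverse, te_s)
                rep.append((all_idx[~te_mask], all_idx[te_mask]))
        else:
            for tr_i, te_i in splitter.split(np.zeros(trialset.n_trials), trialset.labels):
                rep.append((np.asarray(tr_i), np.asarray(te_i)))
        folds.append(rep)

    plan = CVPlan(scheme=scheme, k=k, repeats=repeats, seed=seed,
                  n_trials=trialset.n_trials, folds=folds, contamination=[],
                  degenerate_equal=bool(trials_per_subject.max() == 1))
    plan.contamination = _contamination_table(plan, trialset)
    return plan


def _contamination_table(plan: CVPlan, trialset: TrialSet) -> list[list[float]]:
    table = []
    for rep in plan.folds:
        row = []
        for tr, te in rep:
            if te.size and (tr.max(initial=-1) >= trialset.n_trials
                            or te.max(initial=-1) >= trialset.n_trials):
                raise ConfigurationError("plan indices out of range for trialset")
            train_subjects = set(trialset.subject_ids[tr])
            hits = np.fromiter((s in train_subjects for s in trialset.subject_ids[te]),
                               dtype=bool, count=te.size)
            row.append(float(hits.mean()) if te.size else 0.0)
        table.append(row)
    return table


@dataclass
class ContaminationReport:
    """Per-fold leakage audit of a CV plan."""

    per_fold: list[list[float]]
    mean: float
    #: (repeat, fold) pairs where a subject-grouped plan leaks — hard failures
    failures: list[tuple[int, int]]

    @property
    def ok(self) -> bool:
        return not self.failures


def audit_contamination(plan: CVPlan, trialset: TrialSet,
                        strict: bool = False) -> ContaminationReport:
    """Recompute contamination from scratch and flag leaking subject folds.

    With ``strict=True`` a contaminated subject-grouped fold raises
    :class:`ContaminationError` instead of merely being reported.
    """
    table = _contamination_table(plan, trialset)
    failures = []
    if plan.scheme.grouping == "subject":
        for r, row in enumerate(table):
            for f, c in enumerate(row):
                if c > 0:
                    failures.append((r, f))
    report = ContaminationReport(
        per_fold=table,
        mean=float(np.mean([c for row in table for c in row])),
        failures=failures,
    )
    if strict and failures:
        raise ContaminationError(
            f"{plan.scheme.name} plan leaks subjects in folds {failures[:5]}"
            + ("..." if len(failures) > 5 else "")
        )
    return report
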