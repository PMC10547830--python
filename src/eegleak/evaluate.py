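"""Experimental grid execution, voting aggregation and scheme comparison.

Trial-level predictions are turned into one diagnosis per subject with a
threshold voting rule (default 60%): a class must win at least the
threshold fraction of a subject's test-trial votes; if neither class
reaches it the subject abstains and is counted as incorrectly classified.
Voting applies only to subject-grouped schemes — trial-grouped schemes are
scored per trial, without voting.  Performance is balanced accuracy
(mean of sensitivity and specificity, in percent), robust to the 77/58
class imbalance.  Per-repetition accuracy pools the repetition's k folds
(each unit is tested exactly once per repetition); a grid cell reports
mean ± SD over repetitions.

Scheme differences are tested with a Friedman omnibus per window followed
by pairwise Wilcoxon tests with Bonferroni correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AugmentationParams, TrialSet, build_trialset
from .cohort import CONTROL, PATIENT, EEGRecording
from .cv import CVPlan, CVScheme, make_cv_plan
from .errors import ConfigurationError
from .models import ModelConfig, TrainedModel, train


@dataclass(frozen=True)
class VotingRule:
    """Threshold voting: a class wins a subject when it receives at least
    ``threshold`` of that subject's trial votes."""

    threshold: float = 0.6

    def __post_init__(self) -> None:
        if not (0.5 <= self.threshold < 1.0):
            raise ConfigurationError(
                f"voting threshold must be in [0.5, 1), got {self.threshold}"
            )


@dataclass(frozen=True)
class SubjectDecision:
    subject_id: str
    true_label: str
    predicted_label: Optional[str]  # None = abstain
    correct: bool
    vote_fraction: float  # fraction of votes for the winning class (max class)

    @property
    def abstained(self) -> bool:
        return self.predicted_label is None


def vote_subject(trial_predictions: Sequence[str], true_label: str,
                 rule: VotingRule = VotingRule(),
                 subject_id: str = "?") -> SubjectDecision:
    """Aggregate one subject's test-trial predictions into a decision.

    An abstention (no class reaches the threshold) counts as incorrect.
    """
    preds = list(trial_predictions)
    if not preds:
        raise ConfigurationError(f"subject {subject_id}: no trial predictions to vote on")
    frac_patient = sum(p == PATIENT for p in preds) / len(preds)
    frac = max(frac_patient, 1.0 - frac_patient)
    if frac_patient >= rule.threshold:
        predicted: Optional[str] = PATIENT
    elif (1.0 - frac_patient) >= rule.threshold:
        predicted = CONTROL
    else:
        predicted = None
    return SubjectDecision(subject_id=subject_id, true_label=true_label,
                           predicted_label=predicted,
                           correct=(predicted == true_label), vote_fraction=frac)


def balanced_accuracy(true_labels: Sequence[str],
                      predicted_labels: Sequence[str]) -> float:
    """100 * (sensitivity + specificity) / 2 over per-unit predictions."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    return balanced_accuracy_from_correct(t, t == p)


def balanced_accuracy_from_correct(true_labels: Sequence[str],
                                   correct: Sequence[bool]) -> float:
    """Balanced accuracy from per-unit correctness flags (abstentions enter
    as ``correct=False``)."""
    t = np.asarray(true_labels)
    c = np.asarray(correct, dtype=bool)
    pat = t == PATIENT
    ctl = t == CONTROL
    if not pat.any() or not ctl.any():
        raise ConfigurationError("both classes must be present in the true labels")
    sens = c[pat].mean()
    spec = c[ctl].mean()
    return float(100.0 * (sens + spec) / 2.0)


def null_accuracy_band(n_patients: int, n_controls: int,
                       trials_per_subject: int = 1,
                       threshold: float = 0.6,
                       alpha: float = 0.05) -> tuple[float, float]:
    """Chance band (percent) for subject-wise balanced accuracy under a
    label-independent classifier, accounting for the voting rule.

    Under the null the probability that a subject is scored correct
    depends on how coherent its trial votes are: fully coherent votes
    (crops of one subject classified identically, the typical regime when
    subjects carry spectral fingerprints) give 1/2; fully independent
    votes give ``P(Binom(m, 1/2) >= ceil(threshold * m))``, which is
    below 1/2 because abstentions count as incorrect.  Any intermediate
    coherence lies between these extremes, so the band spans the lower
    normal-approximation quantile at the independent-vote rate and the
    upper quantile at 1/2.
    """
    from scipy.stats import binom, norm

    m = trials_per_subject
    k_min = int(np.ceil(threshold * m - 1e-9))
    p_ind = float(binom.sf(k_min - 1, m, 0.5))
    z = float(norm.ppf(1 - alpha / 2))

    def sd(p: float) -> float:
        return float(np.sqrt(p * (1 - p) / 4 * (1 / n_patients + 1 / n_controls)))

    lo = 100.0 * (p_ind - z * sd(p_ind))
    hi = 100.0 * (0.5 + z * sd(0.5))
    return lo, hi


def _derive_seed(*parts: int) -> int:
    ss = np.random.SeedSequence(entropy=list(parts))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RepetitionResult:
    repeat: int
    accuracy: float  # balanced accuracy, percent
    abstain_rate: float  # subjects abstaining / subjects (0 for trial schemes)


def evaluate_plan(trialset: TrialSet, plan: CVPlan, model_config: ModelConfig,
                  voting: VotingRule = VotingRule(),
                  base_seed: int = 0) -> list[RepetitionResult]:
    """Train per fold and score each repetition per the scheme's unit.

    Subject-grouped schemes: vote per subject, balanced accuracy over
    subjects.  Trial-grouped schemes: balanced accuracy over trials.
    """
    results = []
    feats = None
    if model_config.family == "spectral_baseline":
        # Welch band powers are per-trial and model-independent: compute once
        from .models import baseline_features
        feats = baseline_features(trialset.trials, trialset.fs_hz)
    for r, rep_folds in enumerate(plan.folds):
        pred = np.empty(trialset.n_trials, dtype=object)
        tested = np.zeros(trialset.n_trials, dtype=bool)
        for f, (tr, te) in enumerate(rep_folds):
            cfg = model_config.with_seed(_derive_seed(base_seed, model_config.seed, r, f))
            if feats is not None:
                model = train(trialset.trials[tr], trialset.labels[tr], cfg,
                              trialset.fs_hz, features=feats[tr])
                proba = model.predict_proba_from_features(feats[te])
                labels = np.where(proba[:, 1] >= 0.5, PATIENT, CONTROL)
            else:
                model = train(trialset.trials[tr], trialset.labels[tr], cfg, trialset.fs_hz)
                _, labels = model.predict(trialset.trials[te])
            pred[te] = labels
            tested[te] = True
        if not tested.all():
            raise ConfigurationError("plan does not test every trial exactly once per repetition")
        if plan.scheme.uses_voting:
            decisions = []
            for sid in np.unique(trialset.subject_ids):
                m = trialset.subject_ids == sid
                decisions.append(vote_subject(pred[m].tolist(), trialset.labels[m][0],
                                              voting, subject_id=str(sid)))
            acc = balanced_accuracy_from_correct(
                [d.true_label for d in decisions], [d.correct for d in decisions])
            abstain = float(np.mean([d.abstained for d in decisions]))
        else:
            acc = balanced_accuracy(trialset.labels, pred.astype(str))
            abstain = 0.0
        results.append(RepetitionResult(repeat=r, accuracy=acc, abstain_rate=abstain))
    return results


@dataclass
class EvaluationReport:
    """Tidy per-repetition accuracies for every grid cell, plus metadata."""

    results: pd.DataFrame  # columns: model, scheme, window_s, repeat, accuracy, abstain_rate
    meta: dict = field(default_factory=dict)
    stats: Optional[pd.DataFrame] = None

    def summary(self) -> pd.DataFrame:
        g = self.results.groupby(["model", "scheme", "window_s"])["accuracy"]
        out = g.agg(["mean", "std"]).reset_index()
        out["std"] = out["std"].fillna(0.0)
        return out

    def leakage_gap(self) -> pd.DataFrame:
        """Mean accuracy inflation of trial-wise over subject-wise CV, in
        percentage points: tCV − sCV and otCV − osCV per (model, window)."""
        s = self.summary().set_index(["model", "scheme", "window_s"])["mean"]
        rows = []
        for (model, scheme_name, w) in s.index:
            if scheme_name != "tCV":
                continue
            rows.append({"model": model, "window_s": w, "pair": "tCV-sCV",
                         "gap_pp": s.get((model, "tCV", w), np.nan)
                         - s.get((model, "sCV", w), np.nan)})
        for (model, scheme_name, w) in s.index:
            if scheme_name != "otCV":
                continue
            rows.append({"model": model, "window_s": w, "pair": "otCV-osCV",
                         "gap_pp": s.get((model, "otCV", w), np.nan)
                         - s.get((model, "osCV", w), np.nan)})
        return pd.DataFrame(rows)

    def table_matrix(self) -> pd.DataFrame:
        """Accuracy table shaped (model × scheme) rows by window columns,
        entries 'mean ± sd'."""
        s = self.summary()
        s["cell"] = s.apply(lambda r: f"{r['mean']:.2f} ± {r['std']:.2f}", axis=1)
        return s.pivot_table(index=["model", "scheme"], columns="window_s",
                             values="cell", aggfunc="first")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.results.to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "meta": self.meta,
            "summary": self.summary().to_dict(orient="records"),
            "leakage_gap": self.leakage_gap().to_dict(orient="records"),
        }
        if self.stats is not None:
            payload["stats"] = self.stats.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path


def run_experiment(recordings: list[EEGRecording],
                   schemes: Sequence[CVScheme],
                   windows_s: Sequence[float],
                   models: Sequence[ModelConfig],
                   k: int = 10, repeats: int = 10, seed: int = 0,
                   voting: VotingRule = VotingRule()) -> EvaluationReport:
    """Run the full (scheme × window × model) grid on one cohort.

    Each cell builds its trial set (cropping overlap dictated by the
    scheme), draws a CV plan from a cell-specific seed derived from
    ``seed``, trains one model per fold, and scores per the scheme's unit.
    A failing cell is logged into the report and skipped, not fatal.
    """
    rows = []
    errors = []
    ts_cache: dict[tuple[float, float], TrialSet] = {}
    for mi, mcfg in enumerate(models):
        for si, scheme in enumerate(schemes):
            for wi, w in enumerate(windows_s):
                key = (float(w), scheme.required_overlap)
                if key not in ts_cache:
                    ts_cache[key] = build_trialset(
                        recordings, AugmentationParams(w, scheme.required_overlap))
                ts = ts_cache[key]
                cell_seed = _derive_seed(seed, si, wi)
                try:
                    plan = make_cv_plan(ts, scheme, k=k, repeats=repeats, seed=cell_seed)
                    reps = evaluate_plan(ts, plan, mcfg, voting,
                                         base_seed=_derive_seed(seed, mi, si, wi))
                except Exception as e:  # noqa: BLE001 — cell isolation by design
                    errors.append({"model": mcfg.family, "scheme": scheme.name,
                                   "window_s": w, "error": repr(e)})
                    continue
                for rr in reps:
                    rows.append({"model": mcfg.family, "scheme": scheme.name,
                                 "window_s": float(w), "repeat": rr.repeat,
                                 "accuracy": rr.accuracy,
                                 "abstain_rate": rr.abstain_rate})
    report = EvaluationReport(
        results=pd.DataFrame(rows),
        meta={"k": k, "repeats": repeats, "seed": seed,
              "voting_threshold": voting.threshold,
              "models": [m.family for m in models],
              "schemes": [s.name for s in schemes],
              "windows_s": [float(w) for w in windows_s],
              "errors": errors},
    )
    return report


def bonferroni(p: float, n_comparisons: int) -> float:
    return float(min(1.0, p * n_comparisons))


def compare_schemes(report: EvaluationReport,
                    wilcoxon: str = "ranksum") -> pd.DataFrame:
    """Friedman omnibus across schemes per (model, window), then pairwise
    Wilcoxon tests with Bonferroni adjustment.

    ``wilcoxon`` is ``'ranksum'`` (two-sample rank-sum, the default) or
    ``'signed_rank'`` (paired signed-rank over repetitions).
    """
    if wilcoxon not in ("ranksum", "signed_rank"):
        raise ConfigurationError(f"wilcoxon must be 'ranksum' or 'signed_rank', got {wilcoxon!r}")
    out = []
    df = report.results
    for (model, w), cell in df.groupby(["model", "window_s"]):
        cols = {name: grp.sort_values("repeat")["accuracy"].to_numpy()
                for name, grp in cell.groupby("scheme")}
        names = sorted(cols)
        if len(names) < 2:
            continue
        lens = {len(v) for v in cols.values()}
        if len(lens) != 1:
            raise ConfigurationError(
                f"unequal repetition counts across schemes for model={model}, window={w}"
            )
        if all(np.array_equal(cols[n], cols[names[0]]) for n in names):
            # fully tied table: no evidence of any difference
            fstat, fp = 0.0, 1.0
        elif len(names) >= 3:
            fstat, fp = stats.friedmanchisquare(*[cols[n] for n in names])
        else:
            fstat, fp = np.nan, np.nan
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        for a, b in pairs:
            x, y = cols[a], cols[b]
            if np.array_equal(x, y):
                praw = 1.0
            elif wilcoxon == "ranksum":
                praw = float(stats.ranksums(x, y).pvalue)
            else:
                d = x - y
                praw = 1.0 if np.all(d == 0) else float(stats.wilcoxon(x, y).pvalue)
            out.append({"model": model, "window_s": w,
                        "friedman_stat": float(fstat) if np.isfinite(fstat) else np.nan,
                        "friedman_p": float(fp) if np.isfinite(fp) else np.nan,
                        "pair": f"{a} vs {b}", "p_raw": praw,
                        "p_adj": bonferroni(praw, len(pairs))})
    stats_df = pd.DataFrame(out)
    report.stats = stats_df
    return stats_df
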