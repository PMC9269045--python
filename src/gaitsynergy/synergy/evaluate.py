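"""Leave-one-subject-out (LOSO) evaluation of synergy models.

Each subject in turn is held out; the model (PCA-CLME or LSTM) is
fitted on the remaining subjects — normalization statistics computed
from the training subjects only — and the held-out subject's target
series is estimated from their inputs.  Per-session RMSE, MAE, Pearson
correlation and R^2 are reported together with across-session means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ChannelSpec, SequenceDataset
from .lstm import LstmConfig, LstmSynergy
from .pca import PcaClme


def regression_metrics(truth: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    """RMSE, MAE, Pearson correlation and R^2 of a prediction."""
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise ValueError("prediction and truth differ in length")
    err = pred - truth
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((truth - truth.mean()) ** 2))
    r2 = float(1.0 - np.sum(err**2) / sst) if sst > 0 else float("nan")
    if np.std(truth) > 1e-12 and np.std(pred) > 1e-12:
        pearson = float(np.corrcoef(truth, pred)[0, 1])
    else:
        pearson = float("nan")
    return {"rmse": rmse, "mae": mae, "pearson": pearson, "r2": r2}


@dataclass
class EvaluationReport:
    """Per-session and mean metrics of one LOSO run."""

    sessions: pd.DataFrame  # index: held-out subject
    model_kind: str
    task: str

    @property
    def means(self) -> pd.Series:
        return self.sessions.mean(numeric_only=True)

    def summary(self) -> pd.DataFrame:
        out = self.sessions.copy()
        out.loc["mean"] = self.means
        out.index.name = f"{self.model_kind}:{self.task} (held-out subject)"
        return out

    def plot_sessions(self, metric: str = "rmse", ax=None):
        """Bar chart of one metric per held-out subject, plus the mean."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        vals = self.sessions[metric]
        ax.bar(list(vals.index) + ["mean"], list(vals) + [vals.mean()])
        ax.set_ylabel(f"{metric} (deg)" if metric in ("rmse", "mae") else metric)
        ax.set_title(f"{self.model_kind} / {self.task}: per-session {metric}")
        return ax


def loso_evaluate(
    dataset: SequenceDataset,
    model_kind: str,
    seed: int = 0,
    lstm_config: LstmConfig | None = None,
    variance_target: float = 0.95,
) -> EvaluationReport:
    """Run the inter-subject simulation: one session per subject.

    A master ``seed`` fans out one deterministic child seed per
    session, so the full report is reproducible.
    """
    if model_kind not in ("pca", "lstm"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    if dataset.normalized:
        raise ValueError(
            "pass an unnormalized dataset: LOSO computes normalization "
            "statistics from each session's training subjects"
        )
    subjects = dataset.subjects
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out evaluation needs at least 3 subjects")
    session_seeds = [
        int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(len(subjects))
    ]
    rows = {}
    for held_out, sess_seed in zip(subjects, session_seeds):
        train_subjects = [s for s in subjects if s != held_out]
        work = dataset.subset(subjects)
        work.fit_normalization(train_subjects)
        work.apply_normalization()
        train = work.subset(train_subjects)
        try:
            if model_kind == "pca":
                res = PcaClme(train, variance_target=variance_target).fit()
            else:
                res = LstmSynergy(train, lstm_config).fit(seed=sess_seed)
            pred = res.predict(work.inputs[held_out])
        except Exception as exc:  # noqa: BLE001 - re-raise with session context
            raise RuntimeError(f"LOSO session for subject {held_out!r} failed") from exc
        rows[held_out] = regression_metrics(dataset.targets[held_out], pred)
    report = pd.DataFrame.from_dict(rows, orient="index")
    return EvaluationReport(sessions=report, model_kind=model_kind, task=dataset.spec.task)
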