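"""Masked classification metrics and the experiment protocols.

Metrics are computed one-vs-rest per class from TP/FP/TN/FN counts and
macro-averaged ("the average over all classes"); prediction/truth pairs
whose true label is unknown are excluded from every count.  Evaluation of a
range forecast pools all users and all horizon days into one confusion
computation and also reports per-day-offset curves.

Protocols mirror the experimental grids the method is studied under:
an input-length sweep (35/30/25 input days with 19/17/12-day horizons), a
missing-ratio sweep (7.6/10/12/14% of input days blanked), and the
dimension/temporal-attention ablation grid, all under user-level k-fold
cross-validation.
"""

from __future__ import annotations

import dataclasses
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .attention_forecaster import AttentionForecaster, ModelConfig, ablate, train
from .chaos_forecaster import forecast_range_chaos
from .errors import EstimationError, InsufficientDataError, StresscastError
from .lyapunov import ChaosProfile, chaos_profile
from .sequence_io import UNKNOWN, LabelScheme, StressSequence, apply_label_scheme

__all__ = [
    "EvalReport",
    "masked_metrics",
    "range_evaluate",
    "estimate_consensus_profile",
    "crossval",
    "run_protocol",
    "LENGTH_SETTINGS",
    "MISSING_RATIOS",
]

#: (input length, horizon) pairs of the input-length sweep
LENGTH_SETTINGS = ((35, 19), (30, 17), (25, 12))
#: input missing ratios of the missing-data sweep
MISSING_RATIOS = (0.076, 0.10, 0.12, 0.14)


@dataclass
class EvalReport:
    """Macro-averaged one-vs-rest metrics over non-masked pairs."""

    num_class: int
    tp: np.ndarray  # per-class counts
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_evaluated: int
    n_masked: int
    per_day: list["EvalReport"] = field(default_factory=list, repr=False)

    @staticmethod
    def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        out = np.zeros_like(num, dtype=float)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        return out

    @property
    def per_class_accuracy(self) -> np.ndarray:
        return self._safe_div(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def per_class_precision(self) -> np.ndarray:
        return self._safe_div(self.tp, self.tp + self.fp)

    @property
    def per_class_recall(self) -> np.ndarray:
        return self._safe_div(self.tp, self.tp + self.fn)

    @property
    def per_class_f1(self) -> np.ndarray:
        p, r = self.per_class_precision, self.per_class_recall
        return self._safe_div(2 * p * r, p + r)

    @property
    def accuracy(self) -> float:
        """Macro accuracy: mean one-vs-rest accuracy over classes."""
        return float(self.per_class_accuracy.mean())

    @property
    def precision(self) -> float:
        return float(self.per_class_precision.mean())

    @property
    def recall(self) -> float:
        return float(self.per_class_recall.mean())

    @property
    def f1(self) -> float:
        return float(self.per_class_f1.mean())

    @property
    def micro_accuracy(self) -> float:
        """Pooled fraction of exact matches (equals macro accuracy for K=2)."""
        return float(self.tp.sum() / self.n_evaluated) if self.n_evaluated else 0.0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "micro_accuracy": self.micro_accuracy,
            "n_evaluated": self.n_evaluated,
            "n_masked": self.n_masked,
        }


def masked_metrics(
    pred: Sequence[int], truth: Sequence[int], num_class: int
) -> EvalReport:
    """Confusion counts over pairs with a known truth label.

    ``truth`` entries equal to the UNKNOWN sentinel (-1) are dropped before
    counting; the number dropped is reported as ``n_masked``.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    known = truth != UNKNOWN
    n_masked = int((~known).sum())
    pred, truth = pred[known], truth[known]
    if len(truth) == 0:
        raise EstimationError("all truth labels unknown; nothing to evaluate")
    classes = np.arange(num_class)
    tp = np.array([(pred[truth == c] == c).sum() for c in classes])
    fn = np.array([(pred[truth == c] != c).sum() for c in classes])
    fp = np.array([(pred[truth != c] == c).sum() for c in classes])
    tn = len(truth) - tp - fn - fp
    return EvalReport(
        num_class=num_class,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_evaluated=int(len(truth)),
        n_masked=n_masked,
    )


def range_evaluate(
    pairs: Sequence[tuple[Sequence[int], Sequence[int]]], num_class: int
) -> EvalReport:
    """Pool (predicted, truth) label arrays over users and horizon days.

    Each pair holds one user's m-day predictions and the matching true
    labels (UNKNOWN where unreported).  The pooled confusion is accompanied
    by per-day-offset reports; days where every truth is unknown yield a
    None placeholder in the per-day list.
    """
    preds = [np.asarray(p, dtype=int) for p, _ in pairs]
    truths = [np.asarray(t, dtype=int) for _, t in pairs]
    pooled = masked_metrics(
        np.concatenate(preds), np.concatenate(truths), num_class
    )
    horizon = max((len(p) for p in preds), default=0)
    per_day: list[EvalReport | None] = []
    for day in range(horizon):
        p = np.array([pr[day] for pr in preds if len(pr) > day])
        t = np.array([tr[day] for tr, pr in zip(truths, preds) if len(pr) > day])
        try:
            per_day.append(masked_metrics(p, t, num_class))
        except EstimationError:
            per_day.append(None)
    pooled.per_day = per_day
    return pooled


# ---------------------------------------------------------------------------
# cross-validation and protocols
# ---------------------------------------------------------------------------


def estimate_consensus_profile(
    sequences: Sequence[StressSequence], **profile_kwargs
) -> ChaosProfile:
    """Median (tau, d, l_max) over per-user chaos profiles.

    Users whose sequence defeats the estimate (degenerate neighbor sets,
    too-short series) are skipped with a warning; the horizon is recomputed
    from the median exponent.
    """
    profiles = []
    for seq in sequences:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                profiles.append(chaos_profile(seq, **profile_kwargs))
        except StresscastError:
            continue
    if not profiles:
        raise EstimationError("no sequence yields a chaos profile")
    if len(profiles) < len(sequences):
        warnings.warn(
            f"chaos profile failed for {len(sequences) - len(profiles)} "
            f"of {len(sequences)} users",
            stacklevel=2,
        )
    tau = int(statistics.median_low([p.tau for p in profiles]))
    d = int(statistics.median_low([p.d for p in profiles]))
    l_max = float(np.median([p.l_max for p in profiles]))
    m = max(1, int(np.floor(1.0 / l_max))) if l_max > 0 else None
    return ChaosProfile(tau=tau, d=d, l_max=l_max, m=m)


def _raise_missing_to(seq: StressSequence, ratio: float, seed: int) -> StressSequence:
    """Blank extra days so the total unknown count reaches round(ratio*n)."""
    n = seq.n
    target = int(np.floor(ratio * n + 0.5))
    known = [i for i, lv in enumerate(seq.levels) if lv != 0]
    extra = target - (n - len(known))
    if extra <= 0:
        return seq
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(known), size=min(extra, len(known)), replace=False)
    levels = np.asarray(seq.levels, dtype=int).copy()
    levels[np.asarray(known)[idx]] = 0
    return seq.with_levels(levels)


def _forecasts_for_method(
    method: str,
    train_seqs: list[StressSequence],
    test_inputs: list[StressSequence],
    scheme: LabelScheme,
    horizon: int,
    profile: ChaosProfile,
    config: ModelConfig,
    q: int,
) -> list[np.ndarray]:
    """Per-test-user arrays of predicted classes over the horizon."""
    if method == "chaos":
        return [
            np.asarray(
                forecast_range_chaos(s, profile, horizon, q=q, scheme=scheme).classes
            )
            for s in test_inputs
        ]
    if method in ("dl", "dl-chaos"):
        cfg = dataclasses.replace(
            config,
            num_class=scheme.num_class,
            use_phase_space=(method == "dl-chaos"),
            tau=profile.tau,
            d=profile.d,
        )
        model = train(train_seqs, scheme, cfg)
        return [
            np.asarray(model.forecast_range(s, horizon, scheme).classes)
            for s in test_inputs
        ]
    raise ValueError(f"unknown method {method!r}")


def crossval(
    sequences: Sequence[StressSequence],
    method: str,
    scheme: LabelScheme,
    folds: int = 5,
    seed: int = 0,
    n_input: int = 35,
    horizon: int | None = None,
    config: ModelConfig | None = None,
    q: int = 3,
    profile: ChaosProfile | None = None,
    missing_ratio: float | None = None,
) -> dict:
    """User-level k-fold cross-validation of range prediction.

    Users are partitioned once (seed-controlled) so each is tested exactly
    once; all of a user's data stays in a single fold.  Per fold, models
    train on the training users' sequences and each test user's first
    ``n_input`` days are forecast ``horizon`` days ahead; the horizon
    defaults to the consensus chaos estimate on that fold's training pool.
    ``missing_ratio`` optionally corrupts only the test inputs (truths are
    untouched).
    """
    sequences = list(sequences)
    if len(sequences) < folds:
        raise InsufficientDataError(f"{len(sequences)} users < {folds} folds")
    config = config or ModelConfig(seed=seed)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequences))
    fold_of = np.empty(len(sequences), dtype=int)
    for f, chunk in enumerate(np.array_split(order, folds)):
        fold_of[chunk] = f
    reports = []
    for f in range(folds):
        train_seqs = [s for s, ff in zip(sequences, fold_of) if ff != f]
        test_seqs = [
            s for s, ff in zip(sequences, fold_of) if ff == f and s.n > n_input
        ]
        if not test_seqs:
            continue
        prof = profile or estimate_consensus_profile(
            [s.prefix(n_input) for s in train_seqs]
        )
        h = horizon if horizon is not None else (prof.m or 1)
        h = min(h, min(s.n for s in test_seqs) - n_input)
        inputs = [s.prefix(n_input) for s in test_seqs]
        if missing_ratio is not None:
            inputs = [
                _raise_missing_to(s, missing_ratio, seed=seed * 7919 + i)
                for i, s in enumerate(inputs)
            ]
        preds = _forecasts_for_method(
            method, train_seqs, inputs, scheme, h, prof, config, q
        )
        truths = [
            apply_label_scheme(s, scheme)[n_input : n_input + h] for s in test_seqs
        ]
        reports.append(range_evaluate(list(zip(preds, truths)), scheme.num_class))
    pooled = EvalReport(
        num_class=scheme.num_class,
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports),
        fn=sum(r.fn for r in reports),
        n_evaluated=sum(r.n_evaluated for r in reports),
        n_masked=sum(r.n_masked for r in reports),
    )
    return {"folds": reports, "pooled": pooled, "fold_of": fold_of}


def run_protocol(
    sequences: Sequence[StressSequence],
    protocol: str,
    schemes: Sequence[LabelScheme],
    seed: int = 0,
    folds: int = 5,
    config: ModelConfig | None = None,
    q: int = 3,
    profile: ChaosProfile | None = None,
) -> pd.DataFrame:
    """Run one experimental grid; one row of pooled metrics per cell.

    ``length_sweep``: 3 methods x {(35,19),(30,17),(25,12)} x schemes.
    ``missing_sweep``: 3 methods x 4 input missing ratios x schemes at
    (35,19); only inputs are corrupted.
    ``ablation``: 4 attention variants of the phase-space model x schemes.
    """
    rows = []
    if protocol == "length_sweep":
        for method in ("chaos", "dl", "dl-chaos"):
            for n_input, horizon in LENGTH_SETTINGS:
                for scheme in schemes:
                    rep = crossval(
                        sequences, method, scheme, folds=folds, seed=seed,
                        n_input=n_input, horizon=horizon, config=config, q=q,
                        profile=profile,
                    )["pooled"]
                    rows.append(
                        {"method": method, "n_input": n_input, "horizon": horizon,
                         "num_class": scheme.num_class, **rep.as_dict()}
                    )
    elif protocol == "missing_sweep":
        n_input, horizon = LENGTH_SETTINGS[0]
        for method in ("chaos", "dl", "dl-chaos"):
            for ratio in MISSING_RATIOS:
                for scheme in schemes:
                    rep = crossval(
                        sequences, method, scheme, folds=folds, seed=seed,
                        n_input=n_input, horizon=horizon, config=config, q=q,
                        profile=profile, missing_ratio=ratio,
                    )["pooled"]
                    rows.append(
                        {"method": method, "missing_ratio": ratio,
                         "num_class": scheme.num_class, **rep.as_dict()}
                    )
    elif protocol == "ablation":
        base = config or ModelConfig(seed=seed)
        n_input, horizon = LENGTH_SETTINGS[0]
        variants = [
            ("with DA & TA", False, False),
            ("w/o DA", True, False),
            ("w/o TA", False, True),
            ("w/o DA & TA", True, True),
        ]
        for name, no_da, no_ta in variants:
            cfg = ablate(base, no_da=no_da, no_ta=no_ta)
            for scheme in schemes:
                rep = crossval(
                    sequences, "dl-chaos", scheme, folds=folds, seed=seed,
                    n_input=n_input, horizon=horizon, config=cfg, q=q,
                    profile=profile,
                )["pooled"]
                rows.append(
                    {"variant": name, "num_class": scheme.num_class,
                     **rep.as_dict()}
                )
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return pd.DataFrame(rows)
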