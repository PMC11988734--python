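"""Classifier evaluation: detection metrics, cost, and robustness protocols.

Detection metrics follow the standard confusion-matrix definitions with
the AF-positive decision at probability >= 0.5:

    TPR = TP/(TP+FN) x 100%,  TNR = TN/(TN+FP) x 100%,
    Acc = (TP+TN)/(TP+TN+FP+FN) x 100%.

AUROC uses the rank-based (Mann-Whitney) estimator with the tie
correction (tied pairs count one half) — identical in value to
trapezoidal integration of the ROC curve.  Rates whose denominator class
is absent are reported as undefined (NaN + flag), never as zero.

The robustness suite reproduces five protocols: (1) test accuracy vs
computational cost, (2) test-vs-validation accuracy drop across patients,
(3) per-lead accuracy drop, (4) shortened analysis intervals (10/20/30 s)
fed to 30 s-trained models without modification, and (5) sequential
full-length monitoring with majority labels and no exclusions.  Model
ranking then marks, per test, the models within a tolerance band of the
best ("top-rank") and of the worst ("worst-rank"); winners maximize
top-ranks subject to having no worst-rank.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .dataset import DatasetSplit, IntervalSample, full_length_segments, samples_to_images
from .ecg_io import ECGRecord

__all__ = [
    "EvalResult",
    "CostProfile",
    "confusion_metrics",
    "auroc",
    "inference_time_ratio",
    "evaluate_on_samples",
    "run_robustness_suite",
    "rank_models",
]


@dataclass
class EvalResult:
    tp: int
    tn: int
    fp: int
    fn: int
    auroc_score: float | None = None
    tags: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def tnr(self) -> float:
        denom = self.tn + self.fp
        return 100.0 * self.tn / denom if denom else float("nan")

    @property
    def acc(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else float("nan")

    def as_dict(self) -> dict:
        return dict(
            TP=self.tp, TN=self.tn, FP=self.fp, FN=self.fn, n=self.n,
            TPR=self.tpr, TNR=self.tnr, Acc=self.acc, AUROC=self.auroc_score,
            **{f"flag_{k}": v for k, v in self.flags.items()},
        )


@dataclass
class CostProfile:
    inference_time_ratio: float
    median_time_s: float
    total_params: int | None = None
    trainable_params: dict = field(default_factory=dict)


def confusion_metrics(labels, probs, threshold: float = 0.5) -> EvalResult:
    """Counts and percentage rates at a fixed decision threshold.

    Prediction is AF iff ``prob >= threshold``.  If one class is absent
    the corresponding rate is NaN and flagged undefined.
    """
    y = np.asarray(labels).ravel().astype(int)
    p = np.asarray(probs, dtype=float).ravel()
    if y.size == 0 or y.size != p.size:
        raise ValueError("labels and probs must be same nonzero length")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pred = p >= threshold
    res = EvalResult(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )
    res.flags["tpr_undefined"] = not np.any(y == 1)
    res.flags["tnr_undefined"] = not np.any(y == 0)
    if np.any(y == 1) and np.any(y == 0):
        res.auroc_score = auroc(y, p)
    return res


def auroc(labels, probs) -> float:
    """Rank-based AUROC with tie correction (ties count 0.5)."""
    y = np.asarray(labels).ravel().astype(int)
    p = np.asarray(probs, dtype=float).ravel()
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(p)  # mid-ranks implement the tie correction
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def inference_time_ratio(
    models: dict, probe_batch: int | dict = 8, repeats: int = 5
) -> dict[str, CostProfile]:
    """Median wall-clock inference time per model, normalized to the fastest.

    ``probe_batch`` is either a batch size (a random probe of each model's
    own input size is generated) or a mapping of model name to probe
    array.  Timing figures are inherently non-deterministic.
    """
    from .models import count_trainable_params

    rng = np.random.default_rng(0)
    times: dict[str, float] = {}
    for name, model in models.items():
        if isinstance(probe_batch, dict):
            batch = probe_batch[name]
        else:
            D = model.spec.D
            batch = rng.random((int(probe_batch), D, D, 3))
        model.predict(batch)  # warm-up
        samples = []
        for _ in range(max(int(repeats), 1)):
            t0 = time.perf_counter()
            model.predict(batch)
            samples.append(time.perf_counter() - t0)
        times[name] = float(np.median(samples))
    fastest = min(times.values())
    out = {}
    for name, model in models.items():
        out[name] = CostProfile(
            inference_time_ratio=times[name] / fastest,
            median_time_s=times[name],
            total_params=sum(l.n_params for l in model.network.layers),
            trainable_params={
                ph: count_trainable_params(model, ph) for ph in ("retrain", "fine_tune")
            },
        )
    return out


def evaluate_on_samples(
    model, samples: list[IntervalSample], records, threshold: float = 0.5, **tags
) -> EvalResult:
    """Render samples for this model's backbone, predict, and score."""
    X, y = samples_to_images(
        samples, records, D=model.spec.D, backbone_id=model.spec.backbone_id
    )
    res = confusion_metrics(y, model.predict(X), threshold=threshold)
    res.tags.update(tags)
    return res


def run_robustness_suite(
    models: dict,
    records: list[ECGRecord] | dict[str, ECGRecord],
    split: DatasetSplit,
    full_records: list[ECGRecord] | None = None,
    durations: tuple = (10.0, 20.0, 30.0),
) -> dict:
    """Run the five evaluation protocols for each trained model.

    Test 4 shortens each curated test interval to its leading 10/20 s
    (strict labels are unaffected: a subinterval of a pure interval is
    pure) and feeds the images to the 30 s-trained model unchanged.
    Test 5 requires ``full_records``; segments without any QRS are counted
    unscorable and excluded from the metrics.
    """
    if isinstance(records, list):
        records = {r.record_id: r for r in records}
    report: dict[str, dict] = {}
    costs = inference_time_ratio(models) if len(models) >= 1 else {}
    for name, model in models.items():
        entry: dict = {"cost": costs.get(name)}
        test1 = evaluate_on_samples(model, split.test, records, scope="test")
        entry["test1"] = {"Acc": test1.acc, "AUROC": test1.auroc_score, "result": test1}

        val = evaluate_on_samples(model, split.validation, records, scope="validation")
        entry["test2"] = {
            "val_Acc": val.acc, "test_Acc": test1.acc, "drop": val.acc - test1.acc,
        }

        leads = sorted({s.lead for s in split.test})
        per_lead = {}
        for lead in leads:
            subset = [s for s in split.test if s.lead == lead]
            if subset:
                per_lead[lead] = evaluate_on_samples(model, subset, records, lead=lead).acc
        entry["test3"] = {
            "per_lead_Acc": per_lead,
            "drop": (max(per_lead.values()) - min(per_lead.values())) if len(per_lead) > 1 else None,
        }

        by_duration = {}
        for dur in durations:
            shortened = []
            for s in split.test:
                rec = records[s.record_id]
                stop = s.start_sample + int(round(dur * rec.fs))
                qrs_ok = np.any((rec.qrs_idx >= s.start_sample) & (rec.qrs_idx < stop))
                if stop <= rec.n_samples and qrs_ok:
                    shortened.append(
                        IntervalSample(s.record_id, s.lead, s.start_sample, dur,
                                       s.label, s.af_coverage)
                    )
            if shortened:
                r = evaluate_on_samples(model, shortened, records, duration_s=dur)
                by_duration[dur] = {"AUROC": r.auroc_score, "Acc": r.acc, "n": r.n}
        entry["test4"] = by_duration

        if full_records:
            segments, n_unscorable = [], 0
            for rec in full_records:
                for lead in rec.leads:
                    for s in full_length_segments(rec, lead):
                        if s.unscorable:
                            n_unscorable += 1
                        else:
                            segments.append(s)
            full_map = {r.record_id: r for r in full_records}
            r5 = evaluate_on_samples(model, segments, full_map, scope="full_length")
            entry["test5"] = {
                "Acc": r5.acc, "AUROC": r5.auroc_score,
                "n_segments": r5.n, "n_unscorable": n_unscorable,
            }
        else:
            entry["test5"] = None
        report[name] = entry
    return report


def _test_scores(entry: dict) -> dict[str, float | None]:
    """Per-test scalar scores, oriented so that larger is better."""
    scores: dict[str, float | None] = {}
    scores["test1"] = entry["test1"]["Acc"]
    scores["test2"] = -entry["test2"]["drop"]
    drop3 = entry["test3"]["drop"]
    scores["test3"] = -drop3 if drop3 is not None else None
    t4 = entry["test4"]
    if t4:
        shortest, longest = min(t4, key=float), max(t4, key=float)
        scores["test4"] = -100.0 * (t4[longest]["AUROC"] - t4[shortest]["AUROC"])
    else:
        scores["test4"] = None
    scores["test5"] = entry["test5"]["Acc"] if entry.get("test5") else None
    return scores


def rank_models(reports: dict, epsilon: float = 0.1) -> dict:
    """Mark top- and worst-ranked models per test and select winners.

    A model is top-ranked in a test when its score is within ``epsilon``
    of the best score, worst-ranked when within ``epsilon`` of the worst
    (no worst-ranks are assigned in a test where best and worst already
    agree within ``epsilon``).  Winners are the models with the maximum
    number of top-ranks among those with no worst-rank; ties are all
    reported.
    """
    if len(reports) < 2:
        raise ValueError("ranking needs at least two model reports")
    complete = {
        name: _test_scores(entry)
        for name, entry in reports.items()
        if entry.get("test1") is not None
    }
    tests = sorted({t for sc in complete.values() for t, v in sc.items() if v is not None})
    table: dict[str, dict] = {
        name: {"top_ranks": 0, "worst_ranks": 0, "per_test": {}} for name in complete
    }
    for t in tests:
        vals = {n: sc[t] for n, sc in complete.items() if sc.get(t) is not None}
        if not vals:
            continue
        best, worst = max(vals.values()), min(vals.values())
        degenerate = best - worst <= epsilon
        for n, v in vals.items():
            mark = ""
            if best - v <= epsilon:
                table[n]["top_ranks"] += 1
                mark = "top"
            if not degenerate and v - worst <= epsilon:
                table[n]["worst_ranks"] += 1
                mark = "worst" if mark == "" else mark + "+worst"
            table[n]["per_test"][t] = {"score": v, "mark": mark}
    eligible = {n: e for n, e in table.items() if e["worst_ranks"] == 0}
    winners = []
    if eligible:
        m = max(e["top_ranks"] for e in eligible.values())
        winners = sorted(n for n, e in eligible.items() if e["top_ranks"] == m)
    return {"table": table, "winners": winners, "epsilon": epsilon}
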