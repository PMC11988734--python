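"""Curated and sequential datasets of labeled analysis intervals.

Curated datasets draw random 30 s (or 10/20 s) analysis intervals per
record and lead at a balanced 50:50 AF : non-AF ratio, labeling by strict
containment (an interval counts as AF only when it lies entirely inside an
annotated episode, non-AF only when entirely outside; intervals straddling
an episode boundary are excluded).  Full-length monitoring instead cuts
every sequential non-overlapping segment of a recording and labels by the
majority rule (AF iff at least half the samples are inside an episode); no
exclusion criteria are applied, so noisy or beat-free segments stay in,
the latter flagged unscorable.

Train/validation/test splitting is record-disjoint at the test boundary:
test records never contribute training or validation samples; within each
train/validation record, samples are shuffled and split 70:30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg_io import ECGRecord, episode_coverage

__all__ = [
    "IntervalSample",
    "DatasetSplit",
    "label_interval",
    "sample_balanced_intervals",
    "split_cohort",
    "full_length_segments",
    "samples_to_images",
]

AF = "AF"
NON_AF = "non-AF"
MIXED = "mixed"


@dataclass(frozen=True)
class IntervalSample:
    record_id: str
    lead: str
    start_sample: int
    duration_s: float
    label: str  # "AF" | "non-AF" | "mixed"
    af_coverage: float
    unscorable: bool = False  # no QRS in the segment (full-length scans only)

    @property
    def y(self) -> int:
        return 1 if self.label == AF else 0


@dataclass
class DatasetSplit:
    train: list[IntervalSample] = field(default_factory=list)
    validation: list[IntervalSample] = field(default_factory=list)
    test: list[IntervalSample] = field(default_factory=list)
    split_mode: str = "record_disjoint_test"

    def check_leakage(self) -> None:
        test_ids = {s.record_id for s in self.test}
        trainval_ids = {s.record_id for s in self.train} | {
            s.record_id for s in self.validation
        }
        if test_ids & trainval_ids:
            raise ValueError(f"record leakage across splits: {test_ids & trainval_ids}")

    def to_manifest(self) -> pd.DataFrame:
        rows = []
        for split_name in ("train", "validation", "test"):
            for s in getattr(self, split_name):
                rows.append(
                    dict(
                        record_id=s.record_id,
                        lead=s.lead,
                        start_sample=s.start_sample,
                        duration_s=s.duration_s,
                        label=s.label,
                        af_coverage=s.af_coverage,
                        split=split_name,
                    )
                )
        return pd.DataFrame(rows)


def label_interval(
    record: ECGRecord, start_sample: int, duration_s: float, mode: str = "strict"
) -> tuple[str, float]:
    """Label one analysis interval from the AF episode annotations.

    strict   : AF iff fully covered, non-AF iff untouched, else "mixed".
    majority : AF iff coverage >= 0.5 (used for full-length monitoring).
    """
    start = int(start_sample)
    stop = start + int(round(duration_s * record.fs))
    if start < 0 or stop > record.n_samples:
        raise ValueError("interval outside record")
    cov = episode_coverage(record.af_episodes, start, stop)
    if mode == "strict":
        label = AF if cov == 1.0 else NON_AF if cov == 0.0 else MIXED
    elif mode == "majority":
        label = AF if cov >= 0.5 else NON_AF
    else:
        raise ValueError(f"unknown labeling mode {mode!r}")
    return label, cov


def _valid_spans(record: ECGRecord, dur: int, want_af: bool) -> list[tuple[int, int]]:
    """Maximal spans in which every dur-long interval is strictly labeled."""
    n = record.n_samples
    edges = [0, n]
    for onset, offset in record.af_episodes:
        edges += [onset, offset]
    edges = sorted(set(edges))
    mask = record.af_mask()
    spans = []
    for a, b in zip(edges, edges[1:]):
        if b - a >= dur and bool(mask[a]) == want_af:
            spans.append((a, b))
    return spans


def sample_balanced_intervals(
    record: ECGRecord,
    lead: str,
    n_per_class: int,
    duration_s: float = 30.0,
    seed: int = 0,
    allow_overlap: bool = False,
) -> list[IntervalSample]:
    """Randomly place strict-labeled intervals, equal counts per class.

    Starts are drawn uniformly over all valid placements; with
    ``allow_overlap=False`` intervals are pairwise non-overlapping (random
    placement with a deterministic packing fallback).  When a record cannot
    supply ``n_per_class`` placements of both classes, the achievable
    maximum is returned equalized, with a warning.  A record with no valid
    placement of either class raises.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    dur = int(round(duration_s * record.fs))
    rng = np.random.default_rng(seed)
    picked: dict[str, list[int]] = {AF: [], NON_AF: []}

    for label, want_af in ((AF, True), (NON_AF, False)):
        spans = _valid_spans(record, dur, want_af)
        counts = np.array([b - a - dur + 1 for a, b in spans], dtype=np.float64)
        if not spans:
            continue
        taken = picked[AF] + picked[NON_AF]
        attempts = 0
        while len(picked[label]) < n_per_class and attempts < 200 * n_per_class:
            attempts += 1
            si = rng.choice(len(spans), p=counts / counts.sum())
            a, b = spans[si]
            start = int(rng.integers(a, b - dur + 1))
            if not allow_overlap and any(
                start < t + dur and t < start + dur for t in taken
            ):
                continue
            picked[label].append(start)
            taken.append(start)
        if len(picked[label]) < n_per_class and not allow_overlap:
            # deterministic packing fallback: tile the spans left to right
            for a, b in spans:
                t0 = a
                while t0 + dur <= b and len(picked[label]) < n_per_class:
                    if not any(t0 < t + dur and t < t0 + dur for t in taken):
                        picked[label].append(t0)
                        taken.append(t0)
                        t0 += dur
                    else:
                        t0 += 1

    if not picked[AF] and not picked[NON_AF]:
        raise ValueError(
            f"record {record.record_id}: no valid {duration_s} s placement of either class"
        )
    n_keep = min(len(picked[AF]), len(picked[NON_AF]))
    if n_keep < n_per_class:
        warnings.warn(
            f"record {record.record_id} lead {lead}: only {n_keep} samples per class "
            f"achievable (requested {n_per_class}); counts equalized",
            stacklevel=2,
        )
    samples = []
    for label in (AF, NON_AF):
        for start in sorted(picked[label][:n_keep]):
            lbl, cov = label_interval(record, start, duration_s, mode="strict")
            assert lbl == label
            samples.append(
                IntervalSample(record.record_id, lead, start, duration_s, lbl, cov)
            )
    return samples


def split_cohort(
    samples: list[IntervalSample],
    train_val_records: set[str] | list[str],
    test_records: set[str] | list[str],
    val_fraction: float = 0.3,
    seed: int = 0,
) -> DatasetSplit:
    """Partition pooled samples into a record-disjoint train/val/test split.

    Samples from each train/validation record are shuffled and split
    ``(1 - val_fraction) : val_fraction`` per record; test records
    contribute only test samples.
    """
    train_val_records, test_records = set(train_val_records), set(test_records)
    overlap = train_val_records & test_records
    if overlap:
        raise ValueError(f"records listed in both train_val and test sets: {overlap}")
    rng = np.random.default_rng(seed)
    split = DatasetSplit()
    by_record: dict[str, list[IntervalSample]] = {}
    for s in samples:
        by_record.setdefault(s.record_id, []).append(s)
    for rid in sorted(by_record):
        recs = by_record[rid]
        if rid in test_records:
            split.test.extend(recs)
        elif rid in train_val_records:
            order = rng.permutation(len(recs))
            n_val = int(round(val_fraction * len(recs)))
            val_idx = set(order[:n_val].tolist())
            for i, s in enumerate(recs):
                (split.validation if i in val_idx else split.train).append(s)
        # records in neither set are ignored
    split.check_leakage()
    return split


def full_length_segments(
    record: ECGRecord, lead: str, duration_s: float = 30.0
) -> list[IntervalSample]:
    """Every sequential non-overlapping segment, majority-labeled.

    Segments containing no QRS are emitted flagged ``unscorable`` rather
    than dropped, so monitoring summaries can count them explicitly.
    """
    dur = int(round(duration_s * record.fs))
    n_seg = record.n_samples // dur
    if n_seg < 1:
        raise ValueError(
            f"record {record.record_id} shorter than one {duration_s} s segment"
        )
    out = []
    for i in range(n_seg):
        start = i * dur
        label, cov = label_interval(record, start, duration_s, mode="majority")
        has_qrs = np.any((record.qrs_idx >= start) & (record.qrs_idx < start + dur))
        out.append(
            IntervalSample(
                record.record_id, lead, start, duration_s, label, cov,
                unscorable=not bool(has_qrs),
            )
        )
    return out


def samples_to_images(
    samples: list[IntervalSample],
    records: dict[str, ECGRecord] | list[ECGRecord],
    D: int,
    backbone_id: str | None = None,
    colormap=None,
):
    """Render samples to a (n, D, D, 3) tensor and 0/1 label vector.

    With ``backbone_id`` the tensor is passed through that backbone's input
    normalization; otherwise values stay in [0, 1].
    """
    from .echoview import echoview_image, preprocess_for_model

    if not isinstance(records, dict):
        records = {r.record_id: r for r in records}
    X = np.empty((len(samples), D, D, 3))
    y = np.empty(len(samples), dtype=np.int64)
    for i, s in enumerate(samples):
        img = echoview_image(
            records[s.record_id], s.lead, s.start_sample, s.duration_s, D=D,
            colormap=colormap,
        )
        x = img.rescaled
        if backbone_id is not None:
            x = preprocess_for_model(x, backbone_id)
        X[i] = x
        y[i] = s.y
    return X, y
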