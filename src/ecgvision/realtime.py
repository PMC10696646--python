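"""Streaming simulator and detector workflow.

A simulator pushes ECG samples into a fixed-capacity ring buffer at the
recording frequency (the inter-push period is scaled by a configurable
factor, 0.9 by default, to offset scheduling overhead that otherwise
stretches the run about 10% past real time).  A detector repeatedly
copies the buffer, optionally checks that a beat sits near the window
center, converts the copy to a binary image, classifies it and records
how many samples arrived — and were therefore dropped from its view —
while it was busy.

Two clocks are available.  *Wall-clock* mode runs a real producer
thread with ``time.sleep`` and measures stage times with
``perf_counter``.  *Virtual-time* mode advances a logical clock in
units of one sample period: each stage is assigned a cost in sample
periods and exactly that many samples are pushed while the stage
"runs", which makes the whole workflow deterministic and exactly
testable.  After every detector iteration (accepted or rejected) the
detector waits for at least one fresh sample before copying again, so
the loop always makes progress even at zero stage cost.
"""

from __future__ import annotations

import csv
import json
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ecg_io import EcgRecord
from .model import ClassifierModel, Prediction, predict
from .preprocess import BeatImage, signal_to_image

__all__ = [
    "RingBuffer", "StageCosts", "StreamRecord", "StreamReport",
    "StubClassifier", "check_center", "simulate_stream", "run_workflow",
]


class RingBuffer:
    """Fixed-capacity FIFO over the most recent stream samples."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._buf = np.zeros(capacity, dtype=float)
        self._start = 0
        self.total_pushed = 0

    def push(self, value: float) -> None:
        """Append; once full, the oldest sample is evicted."""
        self._buf[(self._start + min(self.total_pushed, self.capacity)) % self.capacity] = value
        if self.total_pushed >= self.capacity:
            self._start = (self._start + 1) % self.capacity
        self.total_pushed += 1

    @property
    def full(self) -> bool:
        return self.total_pushed >= self.capacity

    def __len__(self) -> int:
        return min(self.total_pushed, self.capacity)

    def snapshot(self) -> np.ndarray:
        """Copy of the current contents in arrival order."""
        k = len(self)
        idx = (self._start + np.arange(k)) % self.capacity
        return self._buf[idx].copy()


def check_center(samples: np.ndarray, tolerance: int | None = None) -> bool:
    """Accept a window iff its dominant deflection sits near the center.

    The "beat" is located as the sample of maximum absolute deviation
    from the window median; the window is accepted iff that index lies
    within ``tolerance`` (default ``n // 8``) of ``n // 2``.  Argmax
    ties break to the lowest index, so a flat window puts the peak at
    index 0 and is rejected for any window longer than ``2 * tolerance``
    samples.
    """
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    tol = n // 8 if tolerance is None else tolerance
    peak = int(np.argmax(np.abs(samples - np.median(samples))))
    return abs(peak - n // 2) <= tol


@dataclass(frozen=True)
class StageCosts:
    """Virtual-time cost of each detector stage, in sample periods."""

    check_center: int = 0
    image_conversion: int = 0
    classification: int = 0


@dataclass(frozen=True)
class StreamRecord:
    """One classification emitted by the detector."""

    id: int
    start: int                 # stream coordinates of the window: [start, end)
    end: int
    label: str
    confidence: float
    samples_missed: int        # pushes that occurred while the detector was busy
    missed_check: int = 0
    missed_conversion: int = 0
    missed_classification: int = 0
    check_seconds: float = 0.0
    conversion_seconds: float = 0.0
    classification_seconds: float = 0.0


@dataclass
class StreamReport:
    """All classifications from one streaming run, plus stream totals."""

    records: list[StreamRecord] = field(default_factory=list)
    total_pushed: int = 0
    rejected: int = 0
    period_seconds: float = 0.0

    def __len__(self) -> int:
        return len(self.records)

    def summary(self) -> dict:
        """Aggregate means mirroring the per-stage timing/miss report."""
        recs = self.records
        conf = np.array([r.confidence for r in recs]) if recs else np.array([])
        by_class: dict[str, list[float]] = {}
        for r in recs:
            by_class.setdefault(r.label, []).append(r.confidence)
        class_means = {k: float(np.mean(v)) for k, v in by_class.items()}
        return {
            "classifications": len(recs),
            "rejected_windows": self.rejected,
            "total_samples_pushed": self.total_pushed,
            "avg_classification_time_s": _mean([r.classification_seconds for r in recs]),
            "avg_conversion_time_s": _mean([r.conversion_seconds for r in recs]),
            "avg_check_center_time_s": _mean([r.check_seconds for r in recs]),
            "avg_samples_removed_during_classification": _mean(
                [r.missed_classification for r in recs]),
            "avg_samples_removed_during_conversion": _mean(
                [r.missed_conversion for r in recs]),
            "avg_samples_removed_during_check_center": _mean(
                [r.missed_check for r in recs]),
            "avg_samples_removed_total": _mean([r.samples_missed for r in recs]),
            # mean over beats, and the unweighted mean of per-class means
            "mean_confidence_beat_weighted": float(conf.mean()) if len(conf) else None,
            "mean_confidence_class_averaged": (
                float(np.mean(list(class_means.values()))) if class_means else None),
            "class_counts": {k: len(v) for k, v in by_class.items()},
        }

    def to_csv(self, path: str | Path) -> Path:
        """One row per classification: ID, Location, Classification, Confidence."""
        path = Path(path)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["ID", "Location", "Classification", "Confidence"])
            for r in self.records:
                w.writerow([r.id, f"{r.start}-{r.end}", r.label,
                            f"{100 * r.confidence:.2f}%"])
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.summary(), indent=2))
        return path


def _mean(values) -> float | None:
    return float(np.mean(values)) if len(values) else None


class StubClassifier:
    """Fixed-output classifier with a declared virtual-time cost.

    Used to test the streaming bookkeeping independently of any trained
    network: it always returns ``label`` with ``confidence`` and claims
    to take ``cost_samples`` sample periods per classification.
    """

    def __init__(self, width: int = 180, height: int = 64, label: str = "N",
                 confidence: float = 1.0, cost_samples: int = 0):
        from .ecg_io import CLASS_LABELS

        self.width, self.height = width, height
        self.cost_samples = cost_samples
        dist = np.full(len(CLASS_LABELS), (1.0 - confidence) / (len(CLASS_LABELS) - 1))
        k = CLASS_LABELS.index(label)
        dist[k] = confidence
        self._prediction_template = Prediction(k, confidence, dist)

    def classify(self, image: BeatImage) -> Prediction:
        return self._prediction_template


class _ModelAdapter:
    def __init__(self, model: ClassifierModel, cost_samples: int = 0):
        self.model = model
        self.width, self.height = model.width, model.height
        self.cost_samples = cost_samples

    def classify(self, image: BeatImage) -> Prediction:
        return predict(self.model, image)


def simulate_stream(
    record: EcgRecord,
    buffer: RingBuffer,
    channel: int = 0,
    period_factor: float = 0.9,
    *,
    virtual_time: bool = True,
    lock: threading.Lock | None = None,
    stop: threading.Event | None = None,
):
    """Push one channel of ``record`` into ``buffer``, one sample at a time.

    In virtual-time mode this is a generator the caller advances push by
    push (the logical clock).  In wall-clock mode it blocks, sleeping
    ``period_factor / fs`` seconds between pushes, until the record is
    exhausted or ``stop`` is set.
    """
    sig = record.signal[channel]
    period = period_factor / record.fs
    if virtual_time:
        def gen():
            for v in sig:
                buffer.push(float(v))
                yield buffer.total_pushed
        return gen()
    for v in sig:
        if stop is not None and stop.is_set():
            return None
        if lock is not None:
            with lock:
                buffer.push(float(v))
        else:
            buffer.push(float(v))
        time.sleep(period)
    return None


def run_workflow(
    record: EcgRecord,
    classifier,
    *,
    limits: tuple[float, float] | None = None,
    use_check_center: bool = True,
    center_tolerance: int | None = None,
    virtual_time: bool = True,
    stage_costs: StageCosts | None = None,
    period_factor: float = 0.9,
    channel: int = 0,
) -> StreamReport:
    """Stream ``record`` through the simulator/detector loop.

    ``classifier`` is a trained :class:`~ecgvision.model.ClassifierModel`
    or any object with ``width``/``height`` attributes, a
    ``classify(image) -> Prediction`` method, and (for virtual time) a
    ``cost_samples`` attribute.  The detector only ever works on a copy
    of the buffer — the live buffer is never read mid-task.
    """
    if isinstance(classifier, ClassifierModel):
        classifier = _ModelAdapter(classifier)
    n, h = classifier.width, classifier.height
    if limits is None:
        sig = record.signal[channel]
        limits = (float(sig.min()), float(sig.max()))
    if limits[1] <= limits[0]:
        raise ValueError(f"invalid conversion limits {limits}")
    if stage_costs is None:
        stage_costs = StageCosts(
            classification=getattr(classifier, "cost_samples", 0))
    if virtual_time:
        return _run_virtual(record, classifier, n, h, limits, use_check_center,
                            center_tolerance, stage_costs, period_factor, channel)
    return _run_wallclock(record, classifier, n, h, limits, use_check_center,
                          center_tolerance, period_factor, channel)


def _run_virtual(record, classifier, n, h, limits, use_check_center,
                 center_tolerance, costs, period_factor, channel) -> StreamReport:
    period = period_factor / record.fs
    n_total = record.n_samples
    buf = RingBuffer(n)
    stream = simulate_stream(record, buf, channel, period_factor, virtual_time=True)

    def advance(k: int) -> int:
        """Let the logical clock run k sample periods; returns pushes made."""
        pushed = 0
        for _ in range(k):
            if next(stream, None) is None:
                break
            pushed += 1
        return pushed

    report = StreamReport(period_seconds=period)
    exhausted = advance(n) < n
    while not exhausted:
        window = buf.snapshot()
        start_pushed = buf.total_pushed
        m_check = m_conv = m_cls = 0
        if use_check_center:
            accepted = check_center(window, center_tolerance)
            m_check = advance(costs.check_center)
            if not accepted:
                report.rejected += 1
                # wait for fresh data, then start over
                exhausted = advance(1) < 1 or buf.total_pushed >= n_total
                continue
        image = signal_to_image(window, limits[0], limits[1], h)
        m_conv = advance(costs.image_conversion)
        pred = classifier.classify(image)
        m_cls = advance(costs.classification)
        report.records.append(StreamRecord(
            id=len(report.records),
            start=start_pushed - n, end=start_pushed,
            label=pred.symbol, confidence=pred.confidence,
            samples_missed=m_check + m_conv + m_cls,
            missed_check=m_check, missed_conversion=m_conv,
            missed_classification=m_cls,
            check_seconds=costs.check_center * period if use_check_center else 0.0,
            conversion_seconds=costs.image_conversion * period,
            classification_seconds=costs.classification * period,
        ))
        # the detector stops once the simulator has no more samples
        exhausted = advance(1) < 1 or buf.total_pushed >= n_total
    report.total_pushed = buf.total_pushed
    return report


def _run_wallclock(record, classifier, n, h, limits, use_check_center,
                   center_tolerance, period_factor, channel) -> StreamReport:
    buf = RingBuffer(n)
    lock = threading.Lock()
    stop = threading.Event()
    done = threading.Event()

    def producer():
        simulate_stream(record, buf, channel, period_factor,
                        virtual_time=False, lock=lock, stop=stop)
        done.set()

    thread = threading.Thread(target=producer, daemon=True)
    report = StreamReport(period_seconds=period_factor / record.fs)
    thread.start()
    try:
        while not buf.full:
            if done.is_set():
                report.total_pushed = buf.total_pushed
                return report
            time.sleep(1e-4)
        last_seen = 0
        while True:
            with lock:
                window = buf.snapshot()
                start_pushed = buf.total_pushed
            t0 = time.perf_counter()
            accepted = check_center(window, center_tolerance) if use_check_center else True
            t1 = time.perf_counter()
            m_check = buf.total_pushed - start_pushed
            if not accepted:
                report.rejected += 1
                if done.is_set():
                    break
                last_seen = buf.total_pushed
                while buf.total_pushed == last_seen and not done.is_set():
                    time.sleep(1e-4)
                continue
            image = signal_to_image(window, limits[0], limits[1], h)
            t2 = time.perf_counter()
            m_conv = buf.total_pushed - start_pushed - m_check
            pred = classifier.classify(image)
            t3 = time.perf_counter()
            m_cls = buf.total_pushed - start_pushed - m_check - m_conv
            report.records.append(StreamRecord(
                id=len(report.records),
                start=start_pushed - n, end=start_pushed,
                label=pred.symbol, confidence=pred.confidence,
                samples_missed=m_check + m_conv + m_cls,
                missed_check=m_check, missed_conversion=m_conv,
                missed_classification=m_cls,
                check_seconds=(t1 - t0) if use_check_center else 0.0,
                conversion_seconds=t2 - t1,
                classification_seconds=t3 - t2,
            ))
            if done.is_set():
                break
            last_seen = buf.total_pushed
            while buf.total_pushed == last_seen and not done.is_set():
                time.sleep(1e-4)
    finally:
        stop.set()
        thread.join(timeout=5.0)
    report.total_pushed = buf.total_pushed
    return report
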