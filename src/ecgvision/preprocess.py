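"""Beat-window extraction and signal-to-image conversion.

The classifier consumes tiny binary raster images rather than raw
samples.  A window of ``n`` consecutive samples around an annotated beat
becomes an ``n``-column, ``h``-row image with exactly one lit pixel per
column: column ``c`` lights row ``r = floor((w_c - min) / d * h)`` where
``d = max - min`` is the fixed amplitude range.  Row 0 is the
minimum-amplitude row, so the raster is upside-down relative to the
usual plotting convention; it is kept that way deliberately — the
orientation is consistent between training and inference, which is all
the network needs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .ecg_io import CLASS_LABELS, EcgRecord

__all__ = [
    "BeatWindow",
    "BeatImage",
    "EmptyDatasetError",
    "extract_windows",
    "apply_skew",
    "signal_to_image",
    "image_to_signal",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]


class EmptyDatasetError(ValueError):
    """No usable beat windows could be extracted from the input records."""


@dataclass(frozen=True)
class BeatWindow:
    """``n`` consecutive samples cut around one annotated beat."""

    samples: np.ndarray
    label: str
    record_id: str
    center_index: int
    skew_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class BeatImage:
    """Binary raster with exactly one lit (255) pixel per column.

    ``grid`` has shape (height, width); ``grid[r, c]`` is the pixel in
    column ``c`` at row ``r``, row 0 being the minimum-amplitude row.
    """

    grid: np.ndarray
    limits: tuple[float, float]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    def lit_pixels(self) -> list[tuple[int, int]]:
        """Lit pixels as (column, row) pairs in column order."""
        rows = np.argmax(self.grid, axis=0)
        return [(c, int(r)) for c, r in enumerate(rows)]


def extract_windows(
    record: EcgRecord, n: int, channel: int = 0
) -> list[BeatWindow]:
    """Cut one ``n``-sample window centered on each annotated beat.

    Annotations closer than ``n/2`` samples to either record boundary
    are discarded (the window must lie fully inside the record).
    Non-beat (``Z``) annotations produce windows too — they are one of
    the 15 classes.
    """
    if n < 2 or n % 2:
        raise ValueError(f"window length must be even and >= 2, got {n}")
    if not 0 <= channel < record.n_channels:
        raise ValueError(f"channel {channel} outside record with {record.n_channels}")
    half = n // 2
    sig = record.signal[channel]
    out = []
    for ann in record.annotations:
        lo = ann.sample_index - half
        hi = ann.sample_index + half
        if lo < 0 or hi > len(sig):
            continue
        out.append(
            BeatWindow(
                samples=sig[lo:hi].copy(),
                label=ann.symbol,
                record_id=record.record_id,
                center_index=ann.sample_index,
            )
        )
    return out


def apply_skew(
    window: BeatWindow,
    record: EcgRecord,
    rng: np.random.Generator,
    channel: int = 0,
    max_retries: int = 10,
) -> BeatWindow:
    """Re-cut ``window`` at a random offset in ``[-n/4, +n/4]``.

    Emulates imperfect beat detection: the peak is no longer guaranteed
    to sit at the window center.  Offsets that would push the window
    past a record boundary are redrawn up to ``max_retries`` times, then
    fall back to offset 0.
    """
    n = window.n
    half, span = n // 2, n // 4
    sig = record.signal[channel]
    offset = 0
    for _ in range(max_retries):
        cand = int(rng.integers(-span, span + 1))
        lo = window.center_index + cand - half
        if 0 <= lo and lo + n <= len(sig):
            offset = cand
            break
    lo = window.center_index + offset - half
    return replace(
        window, samples=sig[lo : lo + n].copy(), skew_offset=offset
    )


def signal_to_image(
    samples: np.ndarray, min_limit: float, max_limit: float, h: int
) -> BeatImage:
    """Quantize an ``n``-sample window into an ``n``-column binary image.

    For each column ``c`` the lit row is ``floor((v - min) / d * h)``
    with ``d = max - min``, clamped into ``[0, h-1]``; samples outside
    the limits are clamped to the limits first.  Exactly one pixel per
    column is lit, at value 255.
    """
    if max_limit <= min_limit:
        raise ValueError(
            f"max_limit ({max_limit}) must exceed min_limit ({min_limit})"
        )
    if h < 1:
        raise ValueError(f"image height must be >= 1, got {h}")
    v = np.clip(np.asarray(samples, dtype=float).ravel(), min_limit, max_limit)
    d = max_limit - min_limit
    rows = np.floor((v - min_limit) / d * h).astype(int)
    np.clip(rows, 0, h - 1, out=rows)
    grid = np.zeros((h, len(v)), dtype=np.uint8)
    grid[rows, np.arange(len(v))] = 255
    return BeatImage(grid=grid, limits=(float(min_limit), float(max_limit)))


def image_to_signal(image: BeatImage) -> np.ndarray:
    """Decode an image back to per-column midpoint amplitudes.

    The inverse is lossy: each sample is recovered to the midpoint of
    its quantization bin, so the per-sample error is at most ``d / h``.
    """
    lo, hi = image.limits
    d = hi - lo
    rows = np.argmax(image.grid, axis=0)
    return lo + (rows + 0.5) * d / image.height


def _pooled_limits(records: list[EcgRecord], channel: int) -> tuple[float, float]:
    vals = np.concatenate([r.signal[channel] for r in records])
    return float(vals.min()), float(vals.max())


def build_dataset(
    records: list[EcgRecord],
    n: int = 180,
    h: int = 64,
    *,
    skewed: bool = False,
    split_fraction: float = 0.9,
    seed: int = 0,
    limits: tuple[float, float] | None = None,
    channel: int = 0,
) -> tuple[list[tuple[BeatImage, int]], list[tuple[BeatImage, int]]]:
    """Windows -> (optionally skewed) images -> shuffled train/test split.

    Quantization limits default to the pooled min/max of the chosen
    channel over all records — a fixed amplitude range, so relative beat
    amplitudes survive the encoding (per-window normalization would
    erase them).  Returns ``(train, test)`` lists of ``(image,
    class_index)`` pairs, split ``split_fraction : 1 - split_fraction``
    after a seeded global shuffle of the pooled windows.
    """
    rng = np.random.default_rng(seed)
    windows: list[tuple[BeatWindow, EcgRecord]] = []
    for rec in records:
        for w in extract_windows(rec, n, channel):
            windows.append((w, rec))
    if not windows:
        raise EmptyDatasetError(
            "no usable beat windows: records have no annotations far enough "
            "from the boundaries"
        )
    if skewed:
        windows = [(apply_skew(w, rec, rng, channel), rec) for w, rec in windows]
    if limits is None:
        limits = _pooled_limits(records, channel)
    pairs = [
        (signal_to_image(w.samples, limits[0], limits[1], h),
         CLASS_LABELS.index(w.label))
        for w, _ in windows
    ]
    order = rng.permutation(len(pairs))
    n_train = int(len(pairs) * split_fraction)
    train = [pairs[i] for i in order[:n_train]]
    test = [pairs[i] for i in order[n_train:]]
    return train, test


# --- dataset persistence (PNG + CSV manifest) ------------------------------

def save_dataset(
    pairs: list[tuple[BeatImage, int]], directory: str | Path, split: str = "train"
) -> Path:
    """Write images as 8-bit grayscale PNGs plus a CSV manifest."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    new = not manifest.exists()
    with manifest.open("a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(
                ["filename", "label", "class_index", "min_limit", "max_limit", "split"]
            )
        for i, (img, idx) in enumerate(pairs):
            name = f"{split}_{i:06d}.png"
            Image.fromarray(img.grid, mode="L").save(directory / name)
            writer.writerow(
                [name, CLASS_LABELS[idx], idx, img.limits[0], img.limits[1], split]
            )
    return manifest


def load_dataset(
    directory: str | Path, split: str = "train"
) -> list[tuple[BeatImage, int]]:
    from PIL import Image

    directory = Path(directory)
    out = []
    with (directory / "manifest.csv").open() as fh:
        for row in csv.DictReader(fh):
            if row["split"] != split:
                continue
            grid = np.asarray(Image.open(directory / row["filename"]), dtype=np.uint8)
            img = BeatImage(
                grid=grid,
                limits=(float(row["min_limit"]), float(row["max_limit"])),
            )
            out.append((img, int(row["class_index"])))
    return out
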