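"""Reading and writing WFDB-dialect ECG records and beat annotations.

A record is the triplet ``<id>.hea`` (plain-text header), ``<id>.dat``
(binary signal, format 16 or 212) and optionally ``<id>.atr`` (binary
annotations in the MIT annotation format).  Raw single-character
annotation symbols are mapped onto a fixed 15-symbol classification
vocabulary: 14 beat classes plus ``Z`` for everything that is not a
heartbeat (rhythm changes, signal-quality markers, waveform boundaries,
comments).  Beat symbols outside the 14 named classes collapse to ``Q``,
the unclassifiable-beat class.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "BeatAnnotation",
    "EcgRecord",
    "FormatError",
    "ValidationError",
    "class_labels",
    "group_symbol",
    "read_record",
    "write_record",
]

#: The ordered classification vocabulary.  The index of a symbol in this
#: tuple is the integer class index used by the classifier everywhere.
CLASS_LABELS: tuple[str, ...] = (
    "N", "L", "R", "V", "A", "f", "F", "j", "a", "E", "J", "Q", "e", "S", "Z",
)


class FormatError(ValueError):
    """A header, signal or annotation file could not be parsed."""


class ValidationError(ValueError):
    """A parsed record violates a structural invariant."""


# --- annotation symbol vocabulary -----------------------------------------
# MIT annotation-type codes <-> display symbols, following the WFDB
# annotation standard.  Codes 59..63 are pseudo-annotations (SKIP, NUM,
# SUB, CHN, AUX) handled separately by the binary reader/writer.
_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE: dict[str, int] = {s: c for c, s in _CODE_TO_SYMBOL.items()}

#: Symbols the WFDB standard flags as heartbeats (QRS annotations).
BEAT_SYMBOLS: frozenset[str] = frozenset("NLRBAaJSVrFejnE/fQ?")

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _load_group_table() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("ecgvision").joinpath("data/symbol_groups.txt").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        raw, grouped = line.split()
        table[raw] = grouped
    return table


_GROUP_TABLE = _load_group_table()


def class_labels() -> list[str]:
    """Return the ordered 15-symbol vocabulary (class index = list index)."""
    return list(CLASS_LABELS)


def group_symbol(raw_symbol: str, is_beat: bool | None = None) -> str:
    """Map a raw annotation symbol onto the 15-class vocabulary.

    Beat symbols among the 14 named classes pass through unchanged; beat
    symbols outside them map to ``Q``; every non-beat symbol maps to
    ``Z``.  Total on any character: unknown symbols are treated as
    non-beat unless ``is_beat`` says otherwise.
    """
    grouped = _GROUP_TABLE.get(raw_symbol)
    if grouped is not None:
        return grouped
    if is_beat or raw_symbol in BEAT_SYMBOLS:
        return raw_symbol if raw_symbol in CLASS_LABELS[:-1] else "Q"
    return "Z"


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated sample: position in the record and grouped symbol."""

    sample_index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.symbol not in CLASS_LABELS:
            raise ValidationError(
                f"annotation symbol {self.symbol!r} outside the 15-class vocabulary"
            )


@dataclass
class EcgRecord:
    """A multi-channel ECG recording with beat annotations.

    ``signal`` is a (channels, samples) float array in physical units
    (millivolts when read from a gain-bearing header).  ``annotations``
    carry grouped symbols; the raw (ungrouped) symbols are preserved
    side-by-side in ``raw_symbols``.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    channel_names: list[str]
    annotations: list[BeatAnnotation] = field(default_factory=list)
    raw_symbols: list[str] = field(default_factory=list)
    units: str = "mV"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        n = self.signal.shape[1]
        for ann in self.annotations:
            if not 0 <= ann.sample_index < n:
                raise ValidationError(
                    f"annotation at sample {ann.sample_index} outside record "
                    f"of length {n}"
                )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


# --- header ----------------------------------------------------------------

_GAIN_RE = re.compile(
    r"^(?P<gain>-?[\d.]+)(\((?P<baseline>-?\d+)\))?(/(?P<units>\S+))?$"
)


def _parse_header(path: Path):
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header file: {path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed record line in {path}: {lines[0]!r}")
    record_id = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samp = int(head[3])
    except ValueError as exc:
        raise FormatError(f"malformed record line in {path}: {lines[0]!r}") from exc
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed signal line in {path}: {ln!r}")
        fmt = tok[1].split("x")[0]
        gain, baseline, units = 200.0, None, "mV"
        if len(tok) > 2:
            m = _GAIN_RE.match(tok[2])
            if not m:
                raise FormatError(f"malformed gain field in {path}: {tok[2]!r}")
            gain = float(m.group("gain")) or 200.0
            if m.group("baseline") is not None:
                baseline = int(m.group("baseline"))
            if m.group("units"):
                units = m.group("units")
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[9:]) if len(tok) > 9 else f"ch{len(signals)}"
        signals.append(
            {"file": tok[0], "fmt": fmt, "gain": gain, "baseline": baseline,
             "units": units, "desc": desc}
        )
    if len(signals) != n_sig:
        raise FormatError(f"header {path} declares {n_sig} signals, found {len(signals)}")
    return record_id, fs, n_samp, signals


# --- signal ----------------------------------------------------------------

def _read_dat(path: Path, fmt: str, n_sig: int, n_samp: int) -> np.ndarray:
    raw = path.read_bytes()
    total = n_sig * n_samp
    if fmt == "16":
        data = np.frombuffer(raw, dtype="<i2", count=total).astype(np.int64)
    elif fmt == "212":
        need = (total + 1) // 2 * 3
        if len(raw) < need:
            raise FormatError(f"signal file {path} truncated for format 212")
        b = np.frombuffer(raw, dtype=np.uint8, count=need).reshape(-1, 3).astype(np.int64)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        pairs = np.empty(2 * len(b), dtype=np.int64)
        pairs[0::2], pairs[1::2] = first, second
        pairs[pairs > 2047] -= 4096  # 12-bit two's complement
        data = pairs[:total]
    else:
        raise FormatError(f"unsupported signal format {fmt!r} in {path}")
    if data.size < total:
        raise FormatError(f"signal file {path} holds {data.size} samples, need {total}")
    return data.reshape(n_samp, n_sig).T


def _write_dat(path: Path, digital: np.ndarray, fmt: str) -> None:
    flat = digital.T.reshape(-1)  # interleave channels per sample frame
    if fmt == "16":
        path.write_bytes(flat.astype("<i2").tobytes())
    elif fmt == "212":
        if flat.size % 2:
            flat = np.concatenate([flat, [0]])
        pairs = flat.reshape(-1, 2) & 0xFFF
        b = np.empty((len(pairs), 3), dtype=np.uint8)
        b[:, 0] = pairs[:, 0] & 0xFF
        b[:, 1] = ((pairs[:, 0] >> 8) & 0x0F) | (((pairs[:, 1] >> 8) & 0x0F) << 4)
        b[:, 2] = pairs[:, 1] & 0xFF
        path.write_bytes(b.tobytes())
    else:
        raise FormatError(f"unsupported signal format {fmt!r}")


# --- annotations -----------------------------------------------------------

def _read_annotations(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw):
        (word,) = struct.unpack_from("<H", raw, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:
            break  # end of annotation stream
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", raw, i)
            (lo,) = struct.unpack_from("<H", raw, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code == _AUX:
            i += delta + (delta & 1)  # aux string, padded to even length
            continue
        if code in (_NUM, _SUB, _CHN):
            continue  # parsed but ignored
        t += delta + pending_skip
        pending_skip = 0
        symbol = _CODE_TO_SYMBOL.get(code)
        if symbol is None:
            raise FormatError(f"unknown annotation type code {code} in {path}")
        out.append((t, symbol))
    return out


def _write_annotations(path: Path, anns: list[tuple[int, str]]) -> None:
    buf = bytearray()
    prev = 0
    for idx, symbol in sorted(anns):
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise FormatError(f"symbol {symbol!r} has no annotation type code")
        delta = idx - prev
        if delta < 0:
            raise ValidationError("annotation indices must be non-decreasing")
        if delta >= 1024:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = idx
    buf += struct.pack("<H", 0)
    path.write_bytes(bytes(buf))


# --- public API ------------------------------------------------------------

def read_record(
    path: str | Path,
    annotation_extension: str = "atr",
    *,
    validate: bool = True,
) -> EcgRecord:
    """Read a WFDB-dialect record (``path`` without extension).

    The annotation file is optional; when present, raw symbols are kept
    in :attr:`EcgRecord.raw_symbols` and the grouped 15-class symbols in
    :attr:`EcgRecord.annotations`.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header file not found: {hea}")
    record_id, fs, n_samp, signals = _parse_header(hea)
    fmts = {s["fmt"] for s in signals}
    files = {s["file"] for s in signals}
    if len(fmts) != 1 or len(files) != 1:
        raise FormatError(f"multi-file or mixed-format records unsupported: {hea}")
    digital = _read_dat(path.parent / signals[0]["file"], fmts.pop(), len(signals), n_samp)
    gains = np.array([s["gain"] for s in signals])[:, None]
    baselines = np.array([s["baseline"] for s in signals])[:, None]
    physical = (digital - baselines) / gains

    annotations: list[BeatAnnotation] = []
    raw_symbols: list[str] = []
    ann_path = path.with_suffix(f".{annotation_extension}")
    if ann_path.exists():
        for idx, symbol in _read_annotations(ann_path):
            if validate and not 0 <= idx < n_samp:
                raise ValidationError(
                    f"annotation at sample {idx} outside record of length {n_samp}"
                )
            raw_symbols.append(symbol)
            annotations.append(BeatAnnotation(idx, group_symbol(symbol)))

    return EcgRecord(
        record_id=record_id,
        signal=physical,
        fs=fs,
        channel_names=[s["desc"] for s in signals],
        annotations=annotations,
        raw_symbols=raw_symbols,
        units=signals[0]["units"],
    )


def write_record(
    record: EcgRecord,
    directory: str | Path,
    *,
    fmt: str = "16",
    gain: float = 200.0,
    annotation_extension: str = "atr",
) -> Path:
    """Write ``record`` as WFDB-dialect files; returns the header path.

    Samples are quantized to integers at ``gain`` ADC units per physical
    unit, so the round-trip amplitude error is at most half an LSB
    (``0.5 / gain``).  Raw symbols are written when present, otherwise
    the grouped symbols (both re-group to the same vocabulary on read).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    digital = np.rint(record.signal * gain).astype(np.int64)
    lim = 2047 if fmt == "212" else 32767
    digital = np.clip(digital, -lim - 1, lim)

    lines = [f"{record.record_id} {record.n_channels} {record.fs:g} {record.n_samples}"]
    for ch in range(record.n_channels):
        first = digital[ch, 0] if record.n_samples else 0
        cksum = int(np.sum(digital[ch], dtype=np.int64) & 0xFFFF)
        if cksum >= 0x8000:
            cksum -= 0x10000
        res = 12 if fmt == "212" else 16
        lines.append(
            f"{record.record_id}.dat {fmt} {gain:g}(0)/{record.units} {res} 0 "
            f"{first} {cksum} 0 {record.channel_names[ch]}"
        )
    (directory / f"{record.record_id}.hea").write_text("\n".join(lines) + "\n")
    _write_dat(directory / f"{record.record_id}.dat", digital, fmt)

    symbols = record.raw_symbols or [a.symbol for a in record.annotations]
    anns = [(a.sample_index, s) for a, s in zip(record.annotations, symbols)]
    _write_annotations(directory / f"{record.record_id}.{annotation_extension}", anns)
    return directory / f"{record.record_id}.hea"
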