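"""Reading and writing the formats the pipeline touches.

Recordings travel as EDF+ (16-bit European Data Format with annotations):
one signal per channel, trial markers as EDF+ annotations with onsets in
seconds. Reading goes through MNE's EDF reader; writing is implemented
here against the published EDF+C layout. Electrode positions use
``.sfp``-style whitespace-delimited text (``label x y z`` per line), and
tabular results go to TSV or JSON.

Channel kinds are inferred from labels: a leading ``E``/``EEG`` means EEG,
``EMG`` means EMG and ``FORCE`` means force, unless an explicit override
map is supplied.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Recording, TRIAL_END, TRIAL_START
from .errors import ClassificationError, CmcError, FormatError, UsageError
from .montage import Montage

_META_PREFIX = "meta:"
_ANNOT_LABEL = "EDF Annotations"


# ---------------------------------------------------------------------------
# channel-kind inference


def infer_kind(label: str) -> str:
    """Map a channel label to a kind using the standard prefix rules."""
    up = label.upper()
    if up.startswith("EMG"):
        return "EMG"
    if up.startswith("FORCE"):
        return "FORCE"
    if up.startswith(("EEG", "E")):
        return "EEG"
    raise ClassificationError(
        f"cannot infer channel kind from label {label!r}; "
        "provide an explicit channel_kinds override"
    )


# ---------------------------------------------------------------------------
# EDF+ writing

_HEADER_FIXED = 256
_PER_SIGNAL = 256


def _fit8(value: float) -> str:
    """Render a float into at most 8 ASCII characters (EDF numeric field)."""
    for prec in range(7, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    raise FormatError(f"cannot encode {value} in an 8-character EDF field")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF field overflow: {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _physical_range(x: np.ndarray) -> tuple[float, float]:
    """Physical min/max with 5% headroom; degenerate channels span [-1, 1]."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = hi - lo
    if span == 0.0:
        return lo - 1.0, hi + 1.0
    return lo - 0.05 * span, hi + 0.05 * span


def _annotation_payloads(rec: Recording, n_records: int, record_s: float) -> list[bytes]:
    """Per-record TAL byte strings (timestamp TAL + event TALs)."""
    fs = rec.fs
    events_by_record: dict[int, list[bytes]] = {}
    annots: list[tuple[float, str]] = [
        (idx / fs, code) for idx, code in rec.events
    ]
    if rec.meta:
        annots.append((0.0, _META_PREFIX + json.dumps(rec.meta, sort_keys=True)))
    for onset, text in annots:
        r = min(int(onset // record_s), n_records - 1)
        tal = f"+{onset:.6f}\x14{text}\x14\x00".encode("utf-8")
        events_by_record.setdefault(r, []).append(tal)
    payloads = []
    for r in range(n_records):
        head = f"+{r * record_s:.6f}\x14\x14\x00".encode("ascii")
        payloads.append(head + b"".join(events_by_record.get(r, [])))
    return payloads


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a Recording as a 16-bit EDF+C file.

    One EDF signal per channel (µV for EEG/EMG, N for force); per-channel
    physical range is taken from the data extrema with 5% headroom, so the
    quantisation step stays far below the noise floor. Trial markers and a
    JSON metadata sidecar annotation are stored as EDF+ annotations.
    Recordings whose length is not a whole number of 1-s records are
    zero-padded to the record boundary.
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    if rec.fs != int(rec.fs):
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(rec.fs)
    n_chan = len(rec.channels)
    record_s = 1.0
    n_records = max(1, math.ceil(rec.n_samples / fs))

    payloads = _annotation_payloads(rec, n_records, record_s)
    annot_bytes = max(max(len(p) for p in payloads) + 2, 32)
    annot_samples = (annot_bytes + 1) // 2  # 2 bytes per 16-bit sample

    ns = n_chan + 1
    phys: list[tuple[float, float]] = []
    labels16, dims = [], []
    for (label, kind), row in zip(rec.channels, rec.data):
        lo_s = _fit8(_physical_range(row)[0])
        hi_s = _fit8(_physical_range(row)[1])
        # use the values as they will be parsed back, so scaling round-trips
        phys.append((float(lo_s), float(hi_s)))
        labels16.append(label)
        dims.append("N" if kind == "FORCE" else "uV")

    dig_lo, dig_hi = -32768, 32767
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(_HEADER_FIXED + _PER_SIGNAL * ns), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad(_fit8(record_s), 8),
            _pad(str(ns), 4),
        ]
    )

    def field_block(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    header += field_block(labels16 + [_ANNOT_LABEL], 16)
    header += field_block([""] * ns, 80)  # transducer
    header += field_block(dims + [""], 8)
    header += field_block([_fit8(lo) for lo, _ in phys] + ["-1"], 8)
    header += field_block([_fit8(hi) for _, hi in phys] + ["1"], 8)
    header += field_block([str(dig_lo)] * ns, 8)
    header += field_block([str(dig_hi)] * ns, 8)
    header += field_block([""] * ns, 80)  # prefiltering
    header += field_block([str(fs)] * n_chan + [str(annot_samples)], 8)
    header += field_block([""] * ns, 32)  # reserved

    # digitise once, zero-padded to the record boundary
    total = n_records * fs
    digital = np.zeros((n_chan, total), dtype="<i2")
    for i, ((lo, hi), row) in enumerate(zip(phys, rec.data)):
        padded = np.zeros(total)
        padded[: row.size] = row
        scale = (dig_hi - dig_lo) / (hi - lo)
        d = np.rint((padded - lo) * scale + dig_lo)
        digital[i] = np.clip(d, dig_lo, dig_hi).astype("<i2")

    try:
        fh = open(path, "wb")
    except OSError as exc:
        raise IOError(f"cannot open {path} for writing: {exc}") from exc
    with fh:
        fh.write(header)
        for r in range(n_records):
            sl = slice(r * fs, (r + 1) * fs)
            for i in range(n_chan):
                fh.write(digital[i, sl].tobytes())
            fh.write(payloads[r].ljust(2 * annot_samples, b"\x00"))


# ---------------------------------------------------------------------------
# EDF reading (MNE) with a pre-flight structural check


def _preflight_edf(path: str | os.PathLike) -> dict[str, str]:
    """Validate gross EDF structure; return per-signal dimension fields."""
    try:
        with open(path, "rb") as fh:
            fixed = fh.read(_HEADER_FIXED)
            if len(fixed) < _HEADER_FIXED:
                raise FormatError("file shorter than the fixed EDF header")
            try:
                header_bytes = int(fixed[184:192].decode("ascii").strip())
                n_records = int(fixed[236:244].decode("ascii").strip())
                ns = int(fixed[252:256].decode("ascii").strip())
            except ValueError as exc:
                raise FormatError(f"unparseable EDF header field: {exc}") from exc
            sig = fh.read(header_bytes - _HEADER_FIXED)
            if len(sig) < _PER_SIGNAL * ns:
                raise FormatError("signal header truncated (field: number of signals)")
            labels = [
                sig[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
                for i in range(ns)
            ]
            off = 16 * ns + 80 * ns
            dims = [
                sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii", "replace").strip()
                for i in range(ns)
            ]
            off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
            spr = [
                int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
                for i in range(ns)
            ]
            record_bytes = 2 * sum(spr)
            fh.seek(0, os.SEEK_END)
            actual = fh.tell() - header_bytes
            if actual < n_records * record_bytes:
                raise FormatError(
                    "file truncated: header field 'number of data records' "
                    f"promises {n_records} records "
                    f"({n_records * record_bytes} bytes) but only "
                    f"{actual} data bytes are present"
                )
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    return dict(zip(labels, dims))


def read_recording(
    path: str | os.PathLike,
    channel_kinds: dict[str, str] | None = None,
) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    Channel kinds come from the label prefix rules unless overridden via
    ``channel_kinds``. EEG/EMG samples are returned in µV, force in N;
    trial markers are recovered from the EDF+ annotations.
    """
    import mne

    dims = _preflight_edf(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    channels: list[tuple[str, str]] = []
    for label in raw.ch_names:
        if channel_kinds and label in channel_kinds:
            kind = channel_kinds[label]
            if kind not in ("EEG", "EMG", "FORCE"):
                raise ClassificationError(f"unknown kind override {kind!r}")
        else:
            kind = infer_kind(label)
        channels.append((label, kind))

    data = raw.get_data()
    # MNE rescales dimensioned channels to SI units; undo to µV
    for i, label in enumerate(raw.ch_names):
        if dims.get(label, "").lower() in ("uv", "µv"):
            data[i] = data[i] * 1e6

    events: list[tuple[int, str]] = []
    meta: dict = {}
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in (TRIAL_START, TRIAL_END):
            events.append((int(round(onset * fs)), desc))
        elif desc.startswith(_META_PREFIX):
            meta = json.loads(desc[len(_META_PREFIX):])
    return Recording(fs=fs, channels=channels, data=data, events=events, meta=meta)


# ---------------------------------------------------------------------------
# montage I/O


def read_montage(path: str | os.PathLike, reference_label: str = "Cz") -> Montage:
    """Read an ``.sfp``-style position file (``label x y z`` per line).

    Positions are renormalised onto the unit sphere; line order is kept.
    """
    labels: list[str] = []
    vecs: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'label x y z', "
                    f"got {len(tokens)} tokens"
                )
            try:
                xyz = [float(t) for t in tokens[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            labels.append(tokens[0])
            vecs.append(xyz)
    pos = np.asarray(vecs, dtype=float)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise FormatError(f"{path}: zero-length position vector")
    pos = pos / norms[:, None]
    return Montage(labels=labels, positions=pos, reference_label=reference_label)


def write_montage(mont: Montage, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for label, (x, y, z) in zip(mont.labels, mont.positions):
            fh.write(f"{label} {x:.17g} {y:.17g} {z:.17g}\n")


# ---------------------------------------------------------------------------
# result tables

_COLUMNS = ("key", "frequency", "value", "units")


@dataclass
class ResultTable:
    """Long-format result rows: (key, frequency-or-band, value, units)."""

    rows: list[tuple[str, object, float, str]] = field(default_factory=list)

    def add(self, key: str, frequency: object, value: float, units: str) -> None:
        if isinstance(frequency, (int, float)) and frequency < 0:
            raise CmcError("frequencies must be non-negative")
        if units == "coherence" and not (0.0 <= value <= 1.0):
            raise CmcError(f"coherence value {value} outside [0, 1]")
        self.rows.append((key, frequency, float(value), units))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=_COLUMNS)


def write_results(table: ResultTable, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a result table as TSV or JSON (full float precision)."""
    if format == "tsv":
        table.to_frame().to_csv(path, sep="\t", index=False)
    elif format == "json":
        records = [dict(zip(_COLUMNS, row)) for row in table.rows]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise UsageError(f"unknown result format {format!r}; use 'tsv' or 'json'")


def read_results(path: str | os.PathLike, format: str = "tsv") -> ResultTable:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        rows = [tuple(r) for r in df.itertuples(index=False)]
    elif format == "json":
        with open(path) as fh:
            rows = [tuple(d[c] for c in _COLUMNS) for d in json.load(fh)]
    else:
        raise UsageError(f"unknown result format {format!r}")
    table = ResultTable()
    table.rows = [(k, f, float(v), u) for k, f, v, u in rows]
    return table
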