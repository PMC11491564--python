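"""Multichannel record data model and readers/writers.

A :class:`MultichannelRecord` is a synchronized set of named signal channels
sampled at a fixed rate, with amplitudes in millivolts everywhere inside the
package; readers convert units at the boundary.  Records can carry one of the
five diagnostic superclass labels (NORM, MI, STTC, CD, HYP) used by the
PTB-XL corpus, or no label.

Supported on-disk formats:

* WFDB header/signal pairs (``.hea`` + ``.dat``, 16-bit format) — the format
  PhysioNet ECG corpora such as PTB-XL ship in.  A minimal reader/writer is
  implemented here covering single-segment format-16 records.
* Delimited text (CSV/TSV), samples x channels, optional header row of lead
  names.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

CLASS_LABELS = ("NORM", "MI", "STTC", "CD", "HYP")

#: Conversion factors into millivolts for the amplitude units WFDB headers use.
_UNIT_TO_MV = {"mV": 1.0, "uV": 1e-3, "V": 1e3, "mv": 1.0, "uv": 1e-3}

DEFAULT_SAMPLING_RATE_HZ = 500.0


@dataclass(frozen=True)
class MultichannelRecord:
    """A synchronized multichannel signal in mV.

    Parameters
    ----------
    channel_names
        Ordered, unique lead labels, one per data column.
    data
        Real matrix of shape ``(n_samples, n_channels)``, amplitudes in mV.
    sampling_rate_hz
        Positive sampling rate; time of sample ``i`` is ``i / rate``.
    label
        Optional diagnostic class tag (one of NORM, MI, STTC, CD, HYP).
    """

    channel_names: tuple[str, ...]
    data: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ContractError(f"data must be 2-D (samples x channels), got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        if data.shape[1] != len(self.channel_names):
            raise ContractError(
                f"{data.shape[1]} data columns but {len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ContractError(f"channel names are not distinct: {self.channel_names}")
        if not self.sampling_rate_hz > 0:
            raise ContractError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        if data.shape[0] < 2:
            raise ContractError(f"record needs at least 2 samples, got {data.shape[0]}")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ContractError(f"unknown class label {self.label!r}; expected one of {CLASS_LABELS}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ContractError(
                f"channel {name!r} not in record (has {', '.join(self.channel_names)})"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's samples as a 1-D array (a view)."""
        return self.data[:, self.channel_index(name)]

    def subset(self, names: Sequence[str]) -> "MultichannelRecord":
        """Record restricted to ``names`` in the given order."""
        idx = [self.channel_index(n) for n in names]
        return replace(self, channel_names=tuple(names), data=self.data[:, idx])

    def with_label(self, label: str | None) -> "MultichannelRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class RecordCollection:
    """A sequence of records sharing channel order and sampling rate."""

    records: tuple[MultichannelRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if self.records:
            ref = self.records[0]
            for k, rec in enumerate(self.records):
                if rec.channel_names != ref.channel_names:
                    raise ContractError(
                        f"record {k} channel names {rec.channel_names} differ from "
                        f"record 0 {ref.channel_names}"
                    )
                if rec.sampling_rate_hz != ref.sampling_rate_hz:
                    raise ContractError(
                        f"record {k} sampling rate {rec.sampling_rate_hz} differs from "
                        f"record 0 {ref.sampling_rate_hz}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def channel_names(self) -> tuple[str, ...]:
        if not self.records:
            raise ContractError("empty collection has no channel names")
        return self.records[0].channel_names

    @property
    def labels(self) -> tuple[str | None, ...]:
        return tuple(r.label for r in self.records)

    def filter_label(self, label: str) -> "RecordCollection":
        """Sub-collection with the given class label (e.g. healthy-only NORM)."""
        return RecordCollection(tuple(r for r in self.records if r.label == label))


def concatenate(collection: RecordCollection | Iterable[MultichannelRecord]) -> MultichannelRecord:
    """Concatenate all records of a collection along time into one record.

    Pooling samples this way sharpens the empirical bin histograms that the
    entropy estimates are built from.  Channel order is preserved; the class
    label is dropped (a pooled record has no single diagnosis).
    """
    if not isinstance(collection, RecordCollection):
        collection = RecordCollection(tuple(collection))
    if len(collection) == 0:
        raise ContractError("cannot concatenate an empty collection")
    if len(collection) == 1:
        return collection[0].with_label(None)
    ref = collection[0]
    data = np.concatenate([r.data for r in collection], axis=0)
    return MultichannelRecord(ref.channel_names, data, ref.sampling_rate_hz, label=None)


# ---------------------------------------------------------------------------
# Delimited text I/O
# ---------------------------------------------------------------------------

def read_delimited(
    path: str | Path,
    name_row: bool = True,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    delimiter: str | None = None,
    label: str | None = None,
) -> MultichannelRecord:
    """Read a samples-x-channels table (CSV/TSV) into a record.

    Parameters
    ----------
    name_row
        If True the first row holds channel names; otherwise names are
        generated as ``ch1..chN``.
    sampling_rate_hz
        The table carries no rate, so it is supplied here (default 500 Hz).
    delimiter
        Explicit delimiter; autodetected between ``,``, tab and ``;`` if None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if delimiter is None:
        first = text.lstrip().splitlines()[0]
        delimiter = max(",\t;", key=first.count)
        if first.count(delimiter) == 0:
            delimiter = ","
    rows = [line.split(delimiter) for line in text.strip().splitlines()]
    start = 0
    if name_row:
        names = tuple(c.strip() for c in rows[0])
        start = 1
        if len(rows) == start:
            raise FormatError(f"{path}: header but no data rows")
    else:
        names = tuple(f"ch{i + 1}" for i in range(len(rows[0])))
    width = len(names)
    data = np.empty((len(rows) - start, width), dtype=float)
    for r, row in enumerate(rows[start:], start=start):
        if len(row) != width:
            raise FormatError(f"{path}: row {r} has {len(row)} fields, expected {width}")
        try:
            data[r - start] = [float(c) for c in row]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row {r}: {exc}") from None
    return MultichannelRecord(names, data, sampling_rate_hz, label=label)


def write_delimited(record: MultichannelRecord, path: str | Path, delimiter: str = ",") -> None:
    """Write a record as delimited text with a channel-name header row."""
    df = pd.DataFrame(record.data, columns=list(record.channel_names))
    df.to_csv(path, sep=delimiter, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# WFDB I/O (minimal: single-segment, format 16)
# ---------------------------------------------------------------------------

def read_wfdb(path: str | Path) -> MultichannelRecord:
    """Read a WFDB record (``.hea`` header + format-16 ``.dat`` signal).

    ``path`` may point at the header file or at the record name without
    extension.  Amplitudes are converted to mV using each signal's gain,
    baseline and units; only units convertible to mV (V, mV, uV) are
    accepted.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no such WFDB header: {hea}")
    lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"{hea}: record line needs 'name nsig fs nsamples'")
    try:
        n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    except ValueError:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}") from None
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise FormatError(f"{hea}: header declares {n_sig} signals, found {len(sig_lines)} lines")

    names, gains, baselines, units, dat_files = [], [], [], [], []
    for k, ln in enumerate(sig_lines):
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"{hea}: signal line {k} too short: {ln!r}")
        dat_files.append(tok[0])
        if tok[1].split("x")[0] not in ("16",):
            raise FormatError(f"{hea}: unsupported WFDB format {tok[1]!r} (only 16)")
        gain, base, unit = 200.0, 0, "mV"  # WFDB defaults: 200 adu/mV, ADC units
        if len(tok) > 2:
            spec = tok[2]
            if "/" in spec:
                spec, unit = spec.split("/", 1)
            if "(" in spec:
                spec, base_s = spec.rstrip(")").split("(")
                base = int(base_s)
            gain = float(spec)
            if gain == 0:
                gain = 200.0
        names.append(tok[-1] if len(tok) >= 9 else f"ch{k + 1}")
        gains.append(gain)
        baselines.append(base)
        units.append(unit)
    for unit in units:
        if unit not in _UNIT_TO_MV:
            raise FormatError(f"{hea}: amplitude unit {unit!r} not convertible to mV")
    if len(set(dat_files)) != 1:
        raise FormatError(f"{hea}: multi-file signals not supported")

    dat = hea.parent / dat_files[0]
    if not dat.exists():
        raise FileNotFoundError(f"no such WFDB signal file: {dat}")
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise FormatError(
            f"{dat}: expected {n_sig * n_samp} samples ({n_sig} sig x {n_samp}), got {raw.size}"
        )
    adc = raw.reshape(n_samp, n_sig).astype(float)
    mv = (adc - np.asarray(baselines)) / np.asarray(gains)
    mv *= np.array([_UNIT_TO_MV[u] for u in units])
    return MultichannelRecord(tuple(names), mv, fs)


def write_wfdb(
    record: MultichannelRecord,
    path: str | Path,
    gain_adu_per_mv: float = 1000.0,
) -> None:
    """Write a record as a WFDB header/format-16 signal pair (mV units)."""
    path = Path(path)
    stem = path.with_suffix("")
    adc = np.round(record.data * gain_adu_per_mv)
    if np.abs(adc).max(initial=0) > 32767:
        raise ContractError("amplitudes overflow int16 at this gain; lower gain_adu_per_mv")
    n_samp, n_sig = record.data.shape
    dat_name = stem.name + ".dat"
    lines = [f"{stem.name} {n_sig} {record.sampling_rate_hz:g} {n_samp}"]
    for name in record.channel_names:
        lines.append(f"{dat_name} 16 {gain_adu_per_mv:g}(0)/mV 16 0 0 0 0 {name}")
    stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    with open(stem.with_suffix(".dat"), "wb") as fh:
        fh.write(adc.astype("<i2").tobytes())


def _parse_simple_config(text: str) -> dict:
    """Parse ``key=value`` / ``key: value`` config lines (a YAML subset)."""
    out: dict[str, object] = {}
    for ln in text.splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        sep = "=" if "=" in ln else ":"
        if sep not in ln:
            raise FormatError(f"config line without '=' or ':': {ln!r}")
        key, val = (s.strip() for s in ln.split(sep, 1))
        try:
            out[key] = float(val) if "." in val or "e" in val.lower() else int(val)
        except ValueError:
            out[key] = val
    return out


def load_config(path: str | Path) -> dict:
    """Load a config file: YAML if parseable, else key=value lines."""
    text = Path(path).read_text()
    try:
        import yaml

        parsed = yaml.safe_load(text)
        if isinstance(parsed, dict):
            return parsed
    except Exception:
        pass
    return _parse_simple_config(text)
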