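"""Record I/O, AAMI label mapping and the inter-patient record split.

Reads MIT-BIH-style WFDB records (.hea / .dat format 212 / .atr) as well as
the plain-text dialect written by :mod:`focalbeat.synthetic_ecg` (a one-column
CSV signal plus a JSON annotation list).  Beat annotations are mapped onto the
four AAMI classes used for modelling (N, SVEB, VEB, F); unknown/paced beats
(Q, f, /) are excluded rather than modelled.

The DS1/DS2 split follows the de Chazal inter-patient protocol: the four
paced records (102, 104, 107, 217) are removed and the remaining 44 records
are partitioned into two fixed sets of 22 so that no patient contributes
beats to both training and test data.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AAMIClass",
    "EcgRecord",
    "load_record",
    "map_annotation_symbol",
    "split_inter_patient",
    "summarize_counts",
    "prepare_dataset",
    "DS1_RECORDS",
    "DS2_RECORDS",
    "PACED_RECORDS",
]


class AAMIClass(IntEnum):
    """AAMI beat class with the fixed index order used everywhere.

    The index order (N=0, SVEB=1, VEB=2, F=3) is shared by loss targets,
    network outputs and confusion-matrix axes.  The AAMI Q class is never a
    model class here; excluded beats are represented by ``None``.
    """

    N = 0
    SVEB = 1
    VEB = 2
    F = 3


#: MIT-BIH beat symbol -> AAMI class; ``None`` marks an excluded beat.
SYMBOL_TO_CLASS: dict[str, AAMIClass | None] = {
    # N: normal, bundle-branch block and escape beats
    "N": AAMIClass.N,
    "L": AAMIClass.N,
    "R": AAMIClass.N,
    "e": AAMIClass.N,
    "j": AAMIClass.N,
    # SVEB: supraventricular ectopic beats
    "A": AAMIClass.SVEB,
    "a": AAMIClass.SVEB,
    "J": AAMIClass.SVEB,
    "S": AAMIClass.SVEB,
    # VEB: ventricular ectopic beats
    "V": AAMIClass.VEB,
    "E": AAMIClass.VEB,
    # F: fusion of ventricular and normal
    "F": AAMIClass.F,
    # Q group: unknown / paced / fusion-of-paced -- excluded from modelling
    "Q": None,
    "f": None,
    "/": None,
}

#: Records with paced beats, removed per AAMI recommended practice.
PACED_RECORDS = ("102", "104", "107", "217")

#: Canonical inter-patient training split (22 records).
DS1_RECORDS = (
    "101", "106", "108", "109", "112", "114", "115", "116", "118", "119",
    "122", "124", "201", "203", "205", "207", "208", "209", "215", "220",
    "223", "230",
)

#: Canonical inter-patient test split (22 records).
DS2_RECORDS = (
    "100", "103", "105", "111", "113", "117", "121", "123", "200", "202",
    "210", "212", "213", "214", "219", "221", "222", "228", "231", "232",
    "233", "234",
)


@dataclass
class EcgRecord:
    """One patient's single-lead ECG with beat annotations.

    Attributes
    ----------
    record_id : str
        Record name (e.g. ``"100"`` or a synthetic id).
    sampling_rate_hz : float
        Sampling frequency, 360 Hz for MIT-BIH.
    signal : np.ndarray
        One lead's amplitude samples in mV (1-D float array).
    annotations : list of (int, str)
        Beat annotations as (sample index, MIT-BIH symbol), strictly
        increasing sample indices, all within the signal.
    """

    record_id: str
    sampling_rate_hz: float
    signal: np.ndarray
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional (a single lead)")
        if self.sampling_rate_hz <= 0:
            raise ValueError(f"sampling_rate_hz must be > 0, got {self.sampling_rate_hz}")
        idx = [s for s, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation sample indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.signal.size):
            raise ValueError("annotation sample indices must lie within the signal")

    @property
    def r_indices(self) -> np.ndarray:
        return np.asarray([s for s, _ in self.annotations], dtype=np.int64)

    @property
    def symbols(self) -> list[str]:
        return [sym for _, sym in self.annotations]


def map_annotation_symbol(symbol: str) -> AAMIClass | None:
    """Map an MIT-BIH beat symbol to its AAMI class (``None`` = excluded).

    Total function: symbols outside the mapping table are excluded with a
    logged warning rather than raising, so auxiliary annotation codes that
    slip through upstream filtering never abort a run.
    """
    if symbol in SYMBOL_TO_CLASS:
        return SYMBOL_TO_CLASS[symbol]
    logger.warning("unknown annotation symbol %r treated as excluded", symbol)
    return None


def split_inter_patient(record_ids: Iterable[str]) -> tuple[list[str], list[str]]:
    """Partition record ids into the canonical DS1 (train) / DS2 (test) sets.

    Paced records (102, 104, 107, 217) land in neither set.  Unknown ids are
    reported in a warning and also placed in neither set.  Input order is
    preserved within each returned list.
    """
    ds1_set, ds2_set = set(DS1_RECORDS), set(DS2_RECORDS)
    paced = set(PACED_RECORDS)
    ds1: list[str] = []
    ds2: list[str] = []
    unknown: list[str] = []
    for rid in record_ids:
        rid = str(rid)
        if rid in ds1_set:
            ds1.append(rid)
        elif rid in ds2_set:
            ds2.append(rid)
        elif rid in paced:
            logger.info("record %s is paced and excluded from both splits", rid)
        else:
            unknown.append(rid)
    if unknown:
        logger.warning("record ids not in the canonical split: %s", ", ".join(unknown))
    return ds1, ds2


def summarize_counts(
    labeled_beats: Iterable[tuple[str, AAMIClass]],
) -> pd.DataFrame:
    """Tabulate per-split, per-class beat counts.

    Parameters
    ----------
    labeled_beats
        Iterable of (record_id, AAMIClass) pairs with excluded beats already
        removed.

    Returns
    -------
    DataFrame with rows DS1, DS2, Total and columns N, SVEB, VEB, F, Total.
    """
    cols = [c.name for c in AAMIClass]
    table = pd.DataFrame(0, index=["DS1", "DS2", "Total"], columns=cols + ["Total"])
    ds1_set, ds2_set = set(DS1_RECORDS), set(DS2_RECORDS)
    for rid, cls in labeled_beats:
        rid = str(rid)
        if rid in ds1_set:
            row = "DS1"
        elif rid in ds2_set:
            row = "DS2"
        else:
            continue
        table.loc[row, AAMIClass(cls).name] += 1
    table.loc["Total", cols] = table.loc["DS1", cols] + table.loc["DS2", cols]
    table["Total"] = table[cols].sum(axis=1)
    return table


# ---------------------------------------------------------------------------
# WFDB reading (header, format-212 signals, MIT annotation files)
# ---------------------------------------------------------------------------

# WFDB annotation type codes that denote beats (QRS annotations).  Non-beat
# codes (rhythm changes, signal quality, waveform boundaries...) are dropped
# on load.
_WFDB_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_WFDB_BEAT_CODES = frozenset(
    {1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41}
)


def _parse_header(hea_path: Path) -> tuple[float, int, list[dict]]:
    """Parse a WFDB .hea file -> (fs, n_samples, per-signal field dicts)."""
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain, baseline_str = gain_str.split("(")
            baseline: int | None = int(baseline_str.rstrip(")"))
        else:
            gain, baseline = gain_str, None
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        signals.append(
            {
                "file": fname,
                "format": fmt,
                "gain": float(gain) if float(gain) != 0 else 200.0,
                "baseline": baseline if baseline is not None else adc_zero,
                "description": parts[8] if len(parts) > 8 else f"sig{len(signals)}",
            }
        )
    return fs, n_samples, signals


def _read_dat_212(dat_path: Path, n_sig: int, n_samples: int) -> np.ndarray:
    """Decode a format-212 .dat file -> int array of shape (n_samples, n_sig).

    Format 212 packs two 12-bit two's-complement samples into 3 bytes; for
    multi-signal files samples are interleaved frame by frame.
    """
    raw = np.frombuffer(dat_path.read_bytes(), dtype=np.uint8)
    n_total = n_samples * n_sig
    n_triplets = (n_total + 1) // 2
    raw = raw[: 3 * n_triplets].reshape(-1, 3).astype(np.int64)
    first = raw[:, 0] | ((raw[:, 1] & 0x0F) << 8)
    second = raw[:, 2] | ((raw[:, 1] & 0xF0) << 4)
    samples = np.empty(2 * raw.shape[0], dtype=np.int64)
    samples[0::2] = first
    samples[1::2] = second
    samples = samples[:n_total]
    samples[samples > 2047] -= 4096
    return samples.reshape(-1, n_sig)


def _read_atr(atr_path: Path) -> list[tuple[int, str]]:
    """Decode an MIT-format annotation file -> [(sample, symbol), ...].

    Only beat annotations are returned; NUM/SUB/CHN/AUX modifier pseudo-
    annotations are consumed and dropped, SKIP pseudo-annotations adjust the
    running sample time.
    """
    data = atr_path.read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code, count = word >> 10, word & 0x3FF
        if code == 0 and count == 0:  # end of file
            break
        if code == 59:  # SKIP: 4-byte time interval, high word first
            if i + 3 >= n:
                break
            hi = struct.unpack_from("<H", data, i)[0]
            lo = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            delta = (hi << 16) | lo
            if delta >= 1 << 31:
                delta -= 1 << 32
            time += delta
            continue
        if code == 63:  # AUX: `count` bytes of text, padded to even length
            i += count + (count & 1)
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        time += count
        if code in _WFDB_BEAT_CODES:
            out.append((time, _WFDB_CODE_TO_SYMBOL.get(code, "?")))
    return out


def _load_wfdb_record(base: Path, lead_name: str) -> EcgRecord:
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header at {hea}")
    fs, n_samples, signals = _parse_header(hea)
    names = [s["description"] for s in signals]
    if lead_name not in names:
        raise ValueError(
            f"lead {lead_name!r} not in record {base.name}; available leads: {names}"
        )
    chan = names.index(lead_name)
    sig = signals[chan]
    if sig["format"] != "212":
        raise NotImplementedError(f"unsupported WFDB signal format {sig['format']!r}")
    adc = _read_dat_212(base.parent / sig["file"], len(signals), n_samples)
    physical = (adc[:, chan] - sig["baseline"]) / sig["gain"]
    atr = base.with_suffix(".atr")
    annotations = _read_atr(atr) if atr.exists() else []
    annotations = [(s, sym) for s, sym in annotations if 0 <= s < physical.size]
    return EcgRecord(base.name, fs, physical, annotations)


def _load_synthetic_record(csv_path: Path) -> EcgRecord:
    """Read the text dialect written by synthetic_ecg: <id>.csv + <id>.ann.json."""
    fs = 360.0
    values: list[float] = []
    for ln in csv_path.read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            if "sampling_rate_hz=" in ln:
                fs = float(ln.split("sampling_rate_hz=")[1])
            continue
        values.append(float(ln))
    ann_path = csv_path.with_suffix("").with_suffix(".ann.json")
    if not ann_path.exists():
        ann_path = Path(str(csv_path)[: -len(".csv")] + ".ann.json")
    annotations: list[tuple[int, str]] = []
    if ann_path.exists():
        for entry in json.loads(ann_path.read_text()):
            annotations.append((int(entry["sample"]), str(entry["symbol"])))
    record_id = csv_path.name[: -len(".csv")]
    return EcgRecord(record_id, fs, np.asarray(values), annotations)


def load_record(path: str | Path, lead_name: str = "MLII") -> EcgRecord:
    """Load one ECG record (WFDB or the synthetic CSV/JSON dialect).

    ``path`` is the record base name: ``DIR/100`` loads ``100.hea/.dat/.atr``;
    ``DIR/syn00001`` (or ``DIR/syn00001.csv``) loads the synthetic dialect.
    Only beat annotations are kept.  Requesting a lead the record does not
    have raises with the list of available leads.
    """
    path = Path(path)
    if path.suffix == ".csv":
        return _load_synthetic_record(path)
    if path.with_suffix(".csv").exists():
        return _load_synthetic_record(path.with_suffix(".csv"))
    if path.with_suffix(".hea").exists():
        return _load_wfdb_record(path, lead_name)
    raise FileNotFoundError(f"no record found at {path} (.hea or .csv)")


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def prepare_dataset(records: Sequence[EcgRecord]) -> dict[str, np.ndarray]:
    """Turn records into aligned model-ready arrays.

    For each record: estimate and subtract the baseline wander, cut the
    200-sample segment around every beat whose AAMI class is not excluded,
    and attach the four normalized RR features.  RR intervals are computed
    over *all* beat annotations of the record (excluded beats still carry a
    real R peak), and the per-record mean RR used for normalization is the
    mean over all of the record's intervals — no information crosses records.

    Returns a dict with keys ``segments`` (n, 200), ``rr`` (n, 4),
    ``labels`` (n,), ``record_ids`` (n,), ``n_dropped`` (scalar count of
    beats lost to record edges).
    """
    from . import preprocess, rr_features  # local import to avoid cycles

    seg_rows, rr_rows, label_rows, rid_rows = [], [], [], []
    n_dropped = 0
    for rec in records:
        r_idx = rec.r_indices
        if r_idx.size < 2:
            logger.warning("record %s has <2 beats; skipped", rec.record_id)
            continue
        corrected = preprocess.remove_baseline(rec.signal, rec.sampling_rate_hz)
        rr_all = rr_features.record_rr_features(r_idx, rec.sampling_rate_hz)
        keep = [
            (pos, cls)
            for pos, (_, sym) in enumerate(rec.annotations)
            if (cls := map_annotation_symbol(sym)) is not None
        ]
        labeled = [(int(r_idx[pos]), cls) for pos, cls in keep]
        segments, dropped = preprocess.segment_heartbeats(
            corrected, labeled, record_id=rec.record_id
        )
        n_dropped += dropped
        kept_r = {seg.r_index for seg in segments}
        for (pos, cls), r in zip(keep, (int(r_idx[p]) for p, _ in keep)):
            if r not in kept_r:
                continue
            rr_rows.append(rr_all[pos])
            label_rows.append(int(cls))
            rid_rows.append(rec.record_id)
        seg_rows.extend(seg.samples for seg in segments)
    return {
        "segments": np.asarray(seg_rows, dtype=float).reshape(-1, 200),
        "rr": np.asarray(rr_rows, dtype=float).reshape(-1, 4),
        "labels": np.asarray(label_rows, dtype=np.int64),
        "record_ids": np.asarray(rid_rows, dtype=object),
        "n_dropped": np.int64(n_dropped),
    }
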