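"""Minimal WFDB writers used only to round-trip-test the package's reader.

Encodes the documented on-disk formats independently of the reader under
test: .hea headers, format-212 packed 12-bit signals, and MIT-format .atr
annotation files (including SKIP pseudo-annotations for inter-beat gaps
longer than 1023 samples).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np


def write_header(
    base: Path, fs: float, n_samples: int, sig_names: list[str],
    gain: float = 200.0, baseline: int = 1024,
) -> None:
    lines = [f"{base.name} {len(sig_names)} {fs:g} {n_samples}"]
    for name in sig_names:
        lines.append(
            f"{base.name}.dat 212 {gain:g}({baseline})/mV 11 {baseline} 0 0 0 {name}"
        )
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")


def write_dat_212(base: Path, adc: np.ndarray) -> None:
    """adc: (n_samples, n_sig) integer array of 12-bit ADC values."""
    flat = np.asarray(adc, dtype=np.int64).reshape(-1).copy()
    if flat.size % 2:
        flat = np.append(flat, 0)
    flat[flat < 0] += 4096  # 12-bit two's complement
    first, second = flat[0::2], flat[1::2]
    out = np.empty((first.size, 3), dtype=np.uint8)
    out[:, 0] = first & 0xFF
    out[:, 1] = ((first >> 8) & 0x0F) | (((second >> 8) & 0x0F) << 4)
    out[:, 2] = second & 0xFF
    base.with_suffix(".dat").write_bytes(out.tobytes())


_SYMBOL_TO_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8, "S": 9,
    "E": 10, "j": 11, "/": 12, "Q": 13, "~": 14, "|": 16, "+": 28, "e": 34,
    "n": 35, "f": 38, '"': 22,
}


def write_atr(base: Path, samples: list[int], symbols: list[str]) -> None:
    """MIT annotation format: (code << 10 | delta) words, SKIP for big gaps."""
    buf = bytearray()
    prev = 0
    for sample, symbol in zip(samples, symbols):
        delta = sample - prev
        prev = sample
        if not 0 <= delta <= 1023:
            buf += struct.pack("<H", 59 << 10)  # SKIP, count 0
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (_SYMBOL_TO_CODE[symbol] << 10) | delta)
    buf += struct.pack("<H", 0)  # end marker
    base.with_suffix(".atr").write_bytes(bytes(buf))


def write_record(
    base: Path, signal_mv: np.ndarray, fs: float, sig_names: list[str],
    ann_samples: list[int], ann_symbols: list[str],
    gain: float = 200.0, baseline: int = 1024,
) -> None:
    """Write a full .hea/.dat/.atr triple from physical (mV) signals."""
    signal_mv = np.atleast_2d(np.asarray(signal_mv, dtype=float))
    if signal_mv.shape[0] < signal_mv.shape[1]:
        signal_mv = signal_mv.T
    adc = np.clip(np.round(signal_mv * gain + baseline), -2048, 2047).astype(np.int64)
    write_header(base, fs, signal_mv.shape[0], sig_names, gain, baseline)
    write_dat_212(base, adc)
    write_atr(base, ann_samples, ann_symbols)
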