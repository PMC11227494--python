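"""Lossless 8-bit grayscale AVI read/write.

Videos are stored as uncompressed device-independent bitmaps ('DIB ')
inside a standard RIFF/AVI container with a 256-entry grayscale palette,
so every frame round-trips bit-exactly.  Only the subset of the container
needed for single-stream 8-bit video is implemented: one 'vids' stream,
'00db' frame chunks, and an idx1 index so mainstream players can seek.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi"]

_AVIF_HASINDEX = 0x00000010
_AVIIF_KEYFRAME = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    pad = b"\x00" if len(payload) % 2 else b""
    return fourcc + struct.pack("<I", len(payload)) + payload + pad


def _list(list_type: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", list_type + payload)


def _row_stride(width: int) -> int:
    return (width + 3) & ~3  # DIB rows pad to 4-byte boundaries


def write_avi(path: str | Path, frames: np.ndarray, fps: float = 30.0) -> None:
    """Write a (T, H, W) uint8 stack as an uncompressed grayscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"expected (T, H, W) frames, got shape {frames.shape}")
    if frames.dtype != np.uint8:
        if frames.min() < 0 or frames.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")
        frames = frames.astype(np.uint8)
    t, h, w = frames.shape
    stride = _row_stride(w)
    frame_bytes = stride * h

    # stream format: BITMAPINFOHEADER + grayscale palette
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 0)
    palette = bytes(bytearray(v for i in range(256) for v in (i, i, i, 0)))
    strf = _chunk(b"strf", bmih + palette)

    rate = max(1, int(round(fps * 1000)))
    strh = _chunk(b"strh", struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0, 1000, rate, 0, t,
        frame_bytes, 0, 0, 0, 0, w, h))
    strl = _list(b"strl", strh + strf)

    avih = _chunk(b"avih", struct.pack(
        "<IIIIIIIIIIIIII",
        int(round(1e6 / max(fps, 1e-9))), frame_bytes * int(round(fps)), 0,
        _AVIF_HASINDEX, t, 0, 1, frame_bytes, w, h, 0, 0, 0, 0))
    hdrl = _list(b"hdrl", avih + strl)

    movi_payload = bytearray()
    index = bytearray()
    for frame in frames:
        dib = np.empty((h, stride), dtype=np.uint8)
        dib[:, :w] = frame[::-1]  # DIB stores rows bottom-up
        dib[:, w:] = 0
        offset = 4 + len(movi_payload)  # from the 'movi' fourcc
        movi_payload += _chunk(b"00db", dib.tobytes())
        index += struct.pack("<4sIII", b"00db", _AVIIF_KEYFRAME, offset, frame_bytes)
    movi = _list(b"movi", bytes(movi_payload))
    idx1 = _chunk(b"idx1", bytes(index))

    riff = _chunk(b"RIFF", b"AVI " + hdrl + movi + idx1)
    Path(path).write_bytes(riff)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos:pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 8-bit grayscale AVI -> ((T, H, W) uint8, fps)."""
    buf = Path(path).read_bytes()
    if buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise ValueError(f"{path}: not an AVI file")

    width = height = None
    bitcount = None
    fps = 30.0
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount, fps
        for fourcc, data_pos, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(data_pos + 4, data_pos + size)
            elif fourcc == b"strh" and buf[data_pos:data_pos + 4] == b"vids":
                scale, rate = struct.unpack_from("<II", buf, data_pos + 20)
                if scale:
                    fps = rate / scale / 1000.0 if rate > 1000 * scale else rate / scale
            elif fourcc == b"strf" and width is None:
                _, w, h, _, bits = struct.unpack_from("<IiiHH", buf, data_pos)
                width, height, bitcount = w, abs(h), bits
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames.append(np.frombuffer(buf, np.uint8, size, data_pos).copy())

    walk(12, len(buf))
    if width is None or not frames:
        raise ValueError(f"{path}: no decodable video stream")
    if bitcount != 8:
        raise ValueError(f"{path}: only 8-bit uncompressed AVI is supported "
                         f"(got {bitcount}-bit)")
    stride = _row_stride(width)
    out = np.empty((len(frames), height, width), dtype=np.uint8)
    for i, raw in enumerate(frames):
        dib = raw[: stride * height].reshape(height, stride)
        out[i] = dib[::-1, :width]
    return out, fps
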