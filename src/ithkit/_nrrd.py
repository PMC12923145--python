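"""Minimal NRRD0004 reader/writer (raw encoding, little-endian).

Covers exactly what the package emits: 2D/3D scalar grids with per-axis
spacings.  Not a general NRRD implementation.
"""

from __future__ import annotations

import numpy as np

_DTYPES = {
    "uint8": np.uint8,
    "int16": np.int16,
    "int32": np.int32,
    "float": np.float32,
    "double": np.float64,
}
_NAMES = {np.dtype(v): k for k, v in _DTYPES.items()}


def write_nrrd(path, array: np.ndarray, spacing=None) -> None:
    arr = np.ascontiguousarray(array)
    if arr.dtype not in _NAMES:
        arr = arr.astype(np.float64)
    if spacing is None:
        spacing = (1.0,) * arr.ndim
    header = [
        "NRRD0004",
        f"type: {_NAMES[arr.dtype]}",
        f"dimension: {arr.ndim}",
        "sizes: " + " ".join(str(s) for s in arr.shape),
        "spacings: " + " ".join(repr(float(s)) for s in spacing),
        "endian: little",
        "encoding: raw",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(arr.astype(arr.dtype.newbyteorder("<"), copy=False).tobytes())


def read_nrrd(path):
    """Return ``(array, spacing)`` from a raw-encoded NRRD file."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if not text or text.startswith("#"):
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.strip()
        if fields.get("encoding", "raw") != "raw":
            raise ValueError(f"{path}: only raw encoding is supported")
        dtype = np.dtype(_DTYPES[fields["type"]])
        if fields.get("endian", "little") == "little":
            dtype = dtype.newbyteorder("<")
        else:
            dtype = dtype.newbyteorder(">")
        shape = tuple(int(s) for s in fields["sizes"].split())
        data = np.frombuffer(fh.read(), dtype=dtype).reshape(shape)
    if "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    else:
        spacing = (1.0,) * len(shape)
    return np.asarray(data), spacing
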