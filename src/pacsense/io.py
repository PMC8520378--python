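"""File formats: delimited-text signals, .npy containers, CSV profiles.

Signals travel as plain text (one sample per line, ``#`` comments and
blank lines ignored) or as numpy's binary ``.npy`` container for lossless
round-trips.  Sparsity profiles are CSV tables with threshold rows and
basis columns, matching the layout in which basis-comparison tables are
conventionally printed.  Every writer embeds provenance (seeds,
parameters) as ``#`` header comments or JSON fields so artifacts can be
regenerated bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SignalIOError
from .signals import Signal1D
from .sparsity import SparsityProfile


def read_signal(path, format: str | None = None) -> Signal1D:
    """Load a signal from delimited text or a binary .npy container.

    The format is inferred from the suffix when not given (.npy binary,
    anything else text).  Malformed text lines raise an error naming the
    line number; an empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"signal file not found: {path}")
    fmt = format or ("binary_container" if path.suffix == ".npy" else "delimited_text")
    if fmt == "binary_container":
        arr = np.load(path)
        if arr.size == 0:
            raise SignalIOError(f"empty signal container: {path}")
        return Signal1D(arr, label=path.stem)

    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise SignalIOError(
                    f"{path}: cannot parse line {lineno}: {line.strip()!r}"
                ) from None
    if not values:
        raise SignalIOError(f"no samples found in {path}")
    return Signal1D(np.asarray(values), label=path.stem)


def write_signal(signal: Signal1D, path, format: str | None = None,
                 header: dict | None = None) -> None:
    """Write a signal as text (with '#' provenance header) or .npy."""
    path = Path(path)
    fmt = format or ("binary_container" if path.suffix == ".npy" else "delimited_text")
    if fmt == "binary_container":
        np.save(path, signal.samples)
        return
    lines = [f"# pacsense signal: {signal.label}"]
    for key, value in (header or {}).items():
        lines.append(f"# {key}: {value}")
    lines.extend(repr(float(v)) for v in signal.samples)
    path.write_text("\n".join(lines) + "\n")


def read_matrix(path) -> np.ndarray:
    """Load a dense matrix from whitespace-delimited text."""
    return np.loadtxt(path, comments="#", ndmin=2)


def write_matrix(matrix: np.ndarray, path, header: dict | None = None) -> None:
    """Write a dense matrix as whitespace-delimited text with '#' header."""
    head = "\n".join(f"{k}: {v}" for k, v in (header or {}).items())
    np.savetxt(path, np.asarray(matrix), header=head, fmt="%.17g")


def write_profile(profile: SparsityProfile, path) -> None:
    """Serialize a sparsity profile as CSV: threshold rows, basis columns."""
    if profile.table.empty:
        raise SignalIOError("refusing to write an empty sparsity profile")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# signal: {profile.signal_label}\n")
        fh.write(f"# threshold_mode: {profile.threshold_mode}\n")
        profile.table.to_csv(fh)


def read_profile(path) -> SparsityProfile:
    """Read back a CSV sparsity profile written by :func:`write_profile`."""
    path = Path(path)
    label, mode = "", "relative"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() == "signal":
                label = value.strip()
            elif key.strip() == "threshold_mode":
                mode = value.strip()
    table = pd.read_csv(path, comment="#", index_col=0)
    table.index = table.index.astype(float)
    table.index.name = "c"
    return SparsityProfile(signal_label=label, table=table.astype(int),
                           threshold_mode=mode)


def write_json(obj: dict, path) -> None:
    """Write a JSON run summary (numpy scalars coerced to Python types)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
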