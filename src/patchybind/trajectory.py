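"""Extended-XYZ trajectory writing and re-reading.

One frame per sampling interval: the first line holds the atom count, the
comment line carries ``time=... box="lx ly lz" energy=...`` and each body
line is ``<species label> x y z``.  Values round-trip to better than 1e-9
(written with 17 significant digits); bit-exactness is not promised.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Frame", "write_frames", "read_frames", "XYZWriter"]


@dataclass
class Frame:
    time: float
    box: tuple[float, float, float]
    energy: float
    labels: list[str]
    positions: np.ndarray  # (N, 3)


def _write_frame(fh: io.TextIOBase, frame: Frame) -> None:
    n = len(frame.labels)
    if frame.positions.shape != (n, 3):
        raise ValueError("labels/positions length mismatch")
    fh.write(f"{n}\n")
    bx, by, bz = (float(v) for v in frame.box)
    fh.write(
        f'time={float(frame.time)!r} box="{bx!r} {by!r} {bz!r}" '
        f"energy={float(frame.energy)!r}\n"
    )
    for lab, row in zip(frame.labels, frame.positions):
        fh.write(
            f"{lab} {float(row[0])!r} {float(row[1])!r} {float(row[2])!r}\n"
        )


class XYZWriter:
    """Incremental writer; usable as a context manager."""

    def __init__(self, path: str | Path) -> None:
        self._fh = open(path, "w")

    def write(self, frame: Frame) -> None:
        _write_frame(self._fh, frame)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "XYZWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_frames(path: str | Path, frames: list[Frame]) -> None:
    with XYZWriter(path) as w:
        for frame in frames:
            w.write(frame)


def _parse_comment(line: str) -> tuple[float, tuple[float, float, float], float]:
    time = 0.0
    box = (0.0, 0.0, 0.0)
    energy = float("nan")
    rest = line.strip()
    while rest:
        key, _, rest = rest.partition("=")
        key = key.strip()
        rest = rest.lstrip()
        if rest.startswith('"'):
            value, _, rest = rest[1:].partition('"')
        else:
            value, _, rest = rest.partition(" ")
        if key == "time":
            time = float(value)
        elif key == "box":
            parts = value.split()
            box = (float(parts[0]), float(parts[1]), float(parts[2]))
        elif key == "energy":
            energy = float(value)
        rest = rest.lstrip()
    return time, box, energy


def read_frames(path: str | Path) -> list[Frame]:
    """Read every frame of an extended-XYZ trajectory file."""
    frames: list[Frame] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            time, box, energy = _parse_comment(fh.readline())
            labels = []
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(Frame(time, box, energy, labels, pos))
    return frames
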