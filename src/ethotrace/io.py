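"""Bout log file format.

The recorder reduces each one-minute video bout to a small tab-separated
text file: one header line with the acquisition metadata and cage layout,
then one line per frame with the frame index, time offset, 3D position
(mm, 3 decimals) and a single-letter behavior code (``-`` while
unclassified).  The format round-trips bit-exactly at the serialized
precision.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

from .core import (
    UNSET,
    Bout,
    CageGeometry,
    LABEL_LETTERS,
    LETTER_LABELS,
    BehaviorLabel,
    Position3D,
    ValidationError,
)

__all__ = ["write_bout_log", "read_bout_log", "read_bout_logs", "BoutLogError"]

_MAGIC = "#ethotrace-bout"


class BoutLogError(ValueError):
    """A bout log file could not be parsed."""


def _fmt_point(p: Position3D) -> str:
    return f"{p.x:.3f},{p.y:.3f},{p.z:.3f}"


def _parse_point(text: str) -> Position3D:
    return Position3D(*(float(v) for v in text.split(",")))


def write_bout_log(bout: Bout, sink) -> int:
    """Serialize *bout* to *sink* (path or text file object).

    Returns the number of data lines written (one per frame).
    """
    bout.validate()
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            return write_bout_log(bout, fh)
    g = bout.geometry
    header = "\t".join(
        [
            _MAGIC,
            f"fly={bout.fly_id}",
            f"cage={bout.cage_id}",
            f"start={bout.start.isoformat()}",
            f"rate_hz={bout.rate_hz:g}",
            f"duration_s={bout.duration_s:g}",
            f"cage_mm={g.width:g},{g.depth:g},{g.height:g}",
            f"food={_fmt_point(g.food_center)}",
            f"water={_fmt_point(g.water_center)}",
            f"top={g.top_fraction:g}",
        ]
    )
    sink.write(header + "\n")
    period = bout.frame_period_s
    n = 0
    for i in range(bout.n_frames):
        x, y, z = bout.positions[i]
        code = int(bout.labels[i])
        letter = "-" if code == UNSET else LABEL_LETTERS[BehaviorLabel(code)]
        sink.write(f"{i}\t{i * period:.1f}\t{x:.3f}\t{y:.3f}\t{z:.3f}\t{letter}\n")
        n += 1
    return n


def read_bout_log(source) -> Bout:
    """Parse a single-bout log produced by :func:`write_bout_log`.

    Raises :class:`BoutLogError` naming the line number on malformed input
    and :class:`ValidationError` if the frame count disagrees with the
    header.
    """
    bouts = read_bout_logs(source)
    if len(bouts) != 1:
        raise BoutLogError(f"expected exactly one bout in the log, found {len(bouts)}")
    return bouts[0]


def read_bout_logs(source) -> list[Bout]:
    """Parse a log holding one or more concatenated bout records (e.g. a
    daily log file)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_bout_logs(fh)
    bouts: list[Bout] = []
    header = source.readline().rstrip("\n")
    lineno = 1
    while header:
        bout, header, lineno = _read_one(source, header, lineno)
        bouts.append(bout)
    if not bouts:
        raise BoutLogError("line 1: missing bout log header")
    return bouts


def _read_one(source, header: str, header_lineno: int) -> tuple[Bout, str, int]:
    """Parse one bout starting at *header*; returns (bout, next header or
    empty string, next line number)."""
    fields = header.split("\t")
    if not fields or fields[0] != _MAGIC:
        raise BoutLogError(f"line {header_lineno}: missing bout log header")
    try:
        meta = dict(f.split("=", 1) for f in fields[1:])
        w, d, h = (float(v) for v in meta["cage_mm"].split(","))
        geometry = CageGeometry(
            width=w,
            depth=d,
            height=h,
            food_center=_parse_point(meta["food"]),
            water_center=_parse_point(meta["water"]),
            top_fraction=float(meta["top"]),
        )
        fly_id = meta["fly"]
        cage_id = int(meta["cage"])
        start = datetime.fromisoformat(meta["start"])
        rate_hz = float(meta["rate_hz"])
        duration_s = float(meta["duration_s"])
    except (KeyError, ValueError) as exc:
        raise BoutLogError(f"line {header_lineno}: malformed header ({exc})") from exc

    positions = []
    labels = []
    lineno = header_lineno
    next_header = ""
    for line in source:
        lineno += 1
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(_MAGIC):
            next_header = line
            break
        parts = line.split("\t")
        if len(parts) != 6:
            raise BoutLogError(f"line {lineno}: expected 6 tab-separated fields, got {len(parts)}")
        try:
            positions.append([float(parts[2]), float(parts[3]), float(parts[4])])
            letter = parts[5]
            labels.append(UNSET if letter == "-" else int(LETTER_LABELS[letter]))
        except (ValueError, KeyError) as exc:
            raise BoutLogError(f"line {lineno}: malformed data line ({exc})") from exc

    n_expected = int(round(rate_hz * duration_s))
    if len(positions) != n_expected:
        raise ValidationError(
            f"bout log has {len(positions)} data lines but header implies {n_expected}"
        )
    bout = Bout(
        fly_id,
        cage_id,
        start,
        rate_hz,
        duration_s,
        np.asarray(positions, dtype=float),
        np.asarray(labels, dtype=np.int8),
        geometry,
    )
    return bout, next_header, lineno
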