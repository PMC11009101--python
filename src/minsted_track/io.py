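"""Delimited-text reader/writer for localization traces.

A trace file is a TSV with '#'-prefixed header lines carrying JSON
metadata (scan/E-PSF configuration, duration, ground-truth reference),
followed by a column-name line and one row per photon:

    index  t_s  beta_rad  x_center_nm  y_center_nm  radius_nm  is_background  is_warmup

Times are formatted to 1 ns, positions and radii to 0.001 nm, so a
write/read/write cycle is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .epsf import EPSF, ScanConfig
from .simulate import Trace

__all__ = ["write_trace", "read_trace"]

_COLUMNS = ["index", "t_s", "beta_rad", "x_center_nm", "y_center_nm",
            "radius_nm", "is_background", "is_warmup"]
_FORMAT_NAME = "minsted-trace"
_FORMAT_VERSION = 1


def _scan_to_dict(scan: ScanConfig) -> dict:
    return {
        "radius": scan.radius, "alpha": scan.alpha, "rate": scan.rate,
        "circling_freq": scan.circling_freq,
        "termination_window": scan.termination_window,
        "power_label": scan.power_label,
    }


def write_trace(trace: Trace, path) -> None:
    """Write a trace as TSV with a JSON metadata header."""
    header = {
        "format": _FORMAT_NAME,
        "version": _FORMAT_VERSION,
        "scan": _scan_to_dict(trace.scan),
        "epsf": {"sigma_e": trace.epsf.sigma_e},
        "duration": trace.duration,
        "meta": trace.meta,
    }
    lines = ["# " + json.dumps(header, sort_keys=True)]
    lines.append("\t".join(_COLUMNS))
    for i in range(trace.n):
        lines.append(
            f"{i}\t{trace.t[i]:.9f}\t{trace.beta[i]:.9f}\t{trace.x[i]:.3f}\t"
            f"{trace.y[i]:.3f}\t{trace.radius[i]:.3f}\t"
            f"{int(trace.is_background[i])}\t{int(trace.is_warmup[i])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    text = Path(path).read_text().splitlines()
    header = None
    body_start = None
    for lineno, line in enumerate(text, start=1):
        if line.startswith("#"):
            if header is None:
                try:
                    header = json.loads(line.lstrip("#").strip())
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: line {lineno}: bad JSON header: {exc}") from exc
        elif line.strip():
            body_start = lineno
            break
    if header is None or header.get("format") != _FORMAT_NAME:
        raise ValueError(f"{path}: missing or unrecognized trace header")
    if body_start is None:
        raise ValueError(f"{path}: missing column line")

    cols = text[body_start - 1].split("\t")
    if cols != _COLUMNS:
        raise ValueError(f"{path}: line {body_start}: expected columns {_COLUMNS}, got {cols}")

    rows = []
    for lineno, line in enumerate(text[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise ValueError(f"{path}: line {lineno}: expected {len(_COLUMNS)} columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc

    data = np.array(rows, dtype=float).reshape(len(rows), len(_COLUMNS))
    scan = ScanConfig(**header["scan"])
    epsf = EPSF(**header["epsf"])
    return Trace(
        t=data[:, 1], beta=data[:, 2], x=data[:, 3], y=data[:, 4],
        radius=data[:, 5],
        is_background=data[:, 6].astype(bool),
        is_warmup=data[:, 7].astype(bool),
        scan=scan, epsf=epsf,
        duration=float(header["duration"]),
        meta=header.get("meta", {}),
    )
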