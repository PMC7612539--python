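"""Wave CSV and dataset directory formats.

Wave files are two-column CSV with the exact header ``time_s,value``; time in
seconds, value in mmHg or mL/s, strictly increasing and uniformly spaced to
within 1e-6 s (non-uniform grids are resampled on read with a logged
warning). A dataset directory holds one sub-directory per subject
(``q_in.csv``, ``cbp.csv``, ``truth.json``) plus a top-level
``manifest.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import WaveIOError
from .virtual_population import Dataset, VirtualSubject
from .waveforms import MIN_SAMPLES, UniformWave, WaveKind

log = logging.getLogger("cbpkit")

HEADER = "time_s,value"

#: tolerated deviation from uniform sample spacing (s)
SPACING_TOL = 1e-6


def write_wave(w: UniformWave, path) -> None:
    """Write a wave to CSV (full float precision, lossless round trip)."""
    path = Path(path)
    t = w.times
    with path.open("w") as fh:
        fh.write(HEADER + "\n")
        for ti, vi in zip(t, w.values):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_wave(path, kind: WaveKind = "pressure") -> UniformWave:
    """Read a wave from CSV, validating header, length and uniform spacing."""
    path = Path(path)
    try:
        lines = path.read_text().strip().splitlines()
    except OSError as exc:
        raise WaveIOError(f"cannot read {path}: {exc}")
    if not lines or lines[0].strip() != HEADER:
        got = lines[0].strip() if lines else "<empty file>"
        raise WaveIOError(f"{path}:1: expected header {HEADER!r}, got {got!r}")
    t, v = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise WaveIOError(f"{path}:{i}: expected two comma-separated fields")
        try:
            t.append(float(parts[0]))
            v.append(float(parts[1]))
        except ValueError:
            raise WaveIOError(f"{path}:{i}: non-numeric value in {line!r}")
    t = np.asarray(t)
    v = np.asarray(v)
    if t.size < MIN_SAMPLES:
        raise WaveIOError(f"{path}: {t.size} samples < minimum {MIN_SAMPLES}")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise WaveIOError(f"{path}: time column must be strictly increasing")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > SPACING_TOL:
        log.warning("%s: non-uniform sampling (max dev %.2e s); resampling",
                    path, float(np.max(np.abs(dts - dt))))
        n = t.size
        tu = np.linspace(t[0], t[-1], n)
        v = np.interp(tu, t, v)
        dt = float(tu[1] - tu[0])
        t = tu
    return UniformWave(float(t[0]), dt, v, kind)


def write_dataset(dataset: Dataset, outdir) -> None:
    """Write a virtual population to a directory tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(dataset.manifest, indent=2))
    for s in dataset.subjects:
        d = outdir / f"subject_{s.id:06d}"
        d.mkdir(exist_ok=True)
        meta = {
            "id": s.id,
            "truth": s.truth,
            "excluded": s.excluded,
            "exclusion_reasons": s.exclusion_reasons,
        }
        (d / "truth.json").write_text(json.dumps(meta, indent=2))
        if s.q_in is not None:
            write_wave(s.q_in, d / "q_in.csv")
        if s.cbp is not None:
            write_wave(s.cbp, d / "cbp.csv")


def read_dataset(indir) -> Dataset:
    """Read a virtual population written by :func:`write_dataset`."""
    indir = Path(indir)
    manifest_path = indir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    subjects = []
    for d in sorted(indir.glob("subject_*")):
        meta = json.loads((d / "truth.json").read_text())
        q = read_wave(d / "q_in.csv", "flow") if (d / "q_in.csv").exists() else None
        p = read_wave(d / "cbp.csv", "pressure") if (d / "cbp.csv").exists() else None
        subjects.append(VirtualSubject(
            id=meta["id"], truth=meta["truth"], q_in=q, cbp=p,
            excluded=meta.get("excluded", False),
            exclusion_reasons=meta.get("exclusion_reasons", []),
        ))
    return Dataset(subjects=subjects, manifest=manifest)
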