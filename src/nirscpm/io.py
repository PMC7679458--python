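"""Plain-text readers/writers for recordings and cohort tables.

Per-participant time series are stored as tab-delimited text: one column
per channel-wavelength (``chNN_695``/``chNN_830``) for intensity data or
per channel-chromophore (``chNN_hbo``/``chNN_hbr``) for hemoglobin data,
a header row with those ids, and a leading comment line carrying the
sampling rate. This keeps every artifact diffable and dependency-free.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .optics import HemoSeries, IntensityRecording

_RATE_RE = re.compile(r"#\s*sampling_rate_hz\s*=\s*([0-9.eE+-]+)")


def _write_frame(path: Path, frame: pd.DataFrame, sampling_rate: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={sampling_rate:g}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _read_frame(path: Path) -> tuple[pd.DataFrame, float]:
    with open(path) as fh:
        first = fh.readline()
        m = _RATE_RE.match(first)
        if not m:
            raise InputError(f"{path}: missing '# sampling_rate_hz=' header line")
        frame = pd.read_csv(fh, sep="\t")
    return frame, float(m.group(1))


def write_intensity(rec: IntensityRecording, path) -> None:
    rec.validate()
    cols = {}
    for c in range(rec.n_channels):
        cols[f"ch{c + 1:02d}_695"] = rec.od_695[c]
        cols[f"ch{c + 1:02d}_830"] = rec.od_830[c]
    _write_frame(Path(path), pd.DataFrame(cols), rec.sampling_rate)


def read_intensity(path, participant_id: str | None = None) -> IntensityRecording:
    path = Path(path)
    frame, rate = _read_frame(path)
    w695 = sorted(c for c in frame.columns if c.endswith("_695"))
    w830 = sorted(c for c in frame.columns if c.endswith("_830"))
    if not w695 or len(w695) != len(w830):
        raise InputError(f"{path}: expected matched chNN_695/chNN_830 columns")
    rec = IntensityRecording(
        participant_id=participant_id or path.stem,
        od_695=frame[w695].to_numpy(float).T,
        od_830=frame[w830].to_numpy(float).T,
        sampling_rate=rate,
    )
    rec.validate()
    return rec


def write_hemoglobin(series: HemoSeries, path) -> None:
    series.validate()
    cols = {}
    for c in range(series.n_channels):
        cols[f"ch{c + 1:02d}_hbo"] = series.hbo[c]
        cols[f"ch{c + 1:02d}_hbr"] = series.hbr[c]
    _write_frame(Path(path), pd.DataFrame(cols), series.sampling_rate)


def read_hemoglobin(path, participant_id: str | None = None) -> HemoSeries:
    path = Path(path)
    frame, rate = _read_frame(path)
    hbo = sorted(c for c in frame.columns if c.endswith("_hbo"))
    hbr = sorted(c for c in frame.columns if c.endswith("_hbr"))
    if not hbo or len(hbo) != len(hbr):
        raise InputError(f"{path}: expected matched chNN_hbo/chNN_hbr columns")
    series = HemoSeries(
        participant_id=participant_id or path.stem,
        hbo=frame[hbo].to_numpy(float).T,
        hbr=frame[hbr].to_numpy(float).T,
        sampling_rate=rate,
    )
    series.validate()
    return series


def write_cohort(recordings, phenotypes: pd.DataFrame, meta: pd.DataFrame, outdir) -> Path:
    """Write a whole simulated/ingested cohort as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        if isinstance(rec, IntensityRecording):
            write_intensity(rec, outdir / f"{rec.participant_id}_intensity.tsv")
        else:
            write_hemoglobin(rec, outdir / f"{rec.participant_id}_hemo.tsv")
    phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    meta.to_csv(outdir / "channels.tsv", sep="\t", index=False)
    return outdir


def read_cohort_recordings(indir) -> list:
    """Load every per-participant series (intensity or hemoglobin) in a directory."""
    indir = Path(indir)
    recs = []
    for path in sorted(indir.glob("*_intensity.tsv")):
        recs.append(read_intensity(path, path.stem.replace("_intensity", "")))
    for path in sorted(indir.glob("*_hemo.tsv")):
        recs.append(read_hemoglobin(path, path.stem.replace("_hemo", "")))
    if not recs:
        raise InputError(f"no *_intensity.tsv or *_hemo.tsv files under {indir}")
    return recs
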