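"""Reading and writing recordings and cohort metadata.

Recordings are exchanged either as EDF (16-bit, physical units µV) or as
delimited numeric matrices with a samples-per-second header line.  EDF
reading goes through MNE; EDF writing uses a small built-in encoder for the
plain EDF variant (continuous recording, one data record per second).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording, normalize_channel_label
from .synthetic import SubjectMeta

__all__ = [
    "write_edf",
    "read_recording",
    "write_delimited_recording",
    "read_delimited_recording",
    "write_cohort",
    "read_metadata_table",
]


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a recording as a plain EDF file (int16, physical units µV).

    Uses one data record per second; the recording is truncated to a whole
    number of seconds (EDF stores an integer number of fixed-length
    records).
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * spr]
    ns = rec.n_channels

    phys_max = float(np.max(np.abs(data)))
    phys_max = max(np.ceil(phys_max), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (2 * phys_max)
    digital = np.round((data + phys_max) * scale + dig_min).astype("<i2")

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b.ljust(width)

    header = b"".join(
        [
            f("0", 8),                                   # version
            f(rec.subject_id, 80),                       # patient id
            f("synthetic resting-state EEG", 80),        # recording id
            f("01.01.20", 8), f("00.00.00", 8),          # start date/time
            f(str(256 * (ns + 1)), 8),                   # header bytes
            f("", 44),                                   # reserved
            f(str(n_records), 8),
            f("1", 8),                                   # record duration, s
            f(str(ns), 4),
        ]
    )
    labels = b"".join(f(ch, 16) for ch in rec.channels)
    transducer = b"".join(f("AgAgCl electrode", 80) for _ in range(ns))
    dim = b"".join(f("uV", 8) for _ in range(ns))
    pmin = b"".join(f(f"{-phys_max:g}", 8) for _ in range(ns))
    pmax = b"".join(f(f"{phys_max:g}", 8) for _ in range(ns))
    dmin = b"".join(f(str(dig_min), 8) for _ in range(ns))
    dmax = b"".join(f(str(dig_max), 8) for _ in range(ns))
    prefilter = b"".join(f("", 80) for _ in range(ns))
    nsamp = b"".join(f(str(spr), 8) for _ in range(ns))
    reserved = b"".join(f("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + pmin + pmax + dmin + dmax
                 + prefilter + nsamp + reserved)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(struct.pack(f"<{ns * spr}h", *block.ravel().tolist()))


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    channels = tuple(normalize_channel_label(c) for c in raw.ch_names)
    data_uv = raw.get_data() * 1e6  # MNE loads EEG in volts
    return Recording(path.stem, data_uv, float(raw.info["sfreq"]), channels)


def write_delimited_recording(path: str | Path, rec: Recording) -> None:
    """Write a recording as TSV: '# fs=<Hz>' line, channel header, samples as rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        fh.write("\t".join(rec.channels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.4f", delimiter="\t")


def read_delimited_recording(path: str | Path) -> Recording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "fs=" not in first:
            raise ValueError(f"{path}: missing '# fs=<Hz>' header line")
        fs = float(first.split("fs=")[1])
        channels = tuple(
            normalize_channel_label(c) for c in fh.readline().strip().split("\t")
        )
        data = np.loadtxt(fh, delimiter="\t")
    return Recording(path.stem, data.T, fs, channels)


def read_recording(path: str | Path) -> Recording:
    """Read an EDF or delimited recording, dispatching on file extension."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return read_delimited_recording(path)


def metadata_to_frame(metas: list[SubjectMeta]) -> pd.DataFrame:
    rows = []
    for m in metas:
        row = {
            "subject_id": m.subject_id,
            "group": m.group,
            "age": m.age,
            "sex": m.sex,
            "education_years": m.education,
            "apoe4": int(m.apoe4),
        }
        row.update(m.cognitive_scores)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    out_dir: str | Path,
    cohort: list[tuple[Recording, SubjectMeta]],
    fmt: str = "edf",
) -> Path:
    """Write per-subject recordings plus a cohort metadata TSV.

    Returns the path of the metadata table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, meta in cohort:
        if fmt == "edf":
            write_edf(out_dir / f"{meta.subject_id}.edf", rec)
        elif fmt == "tsv":
            write_delimited_recording(out_dir / f"{meta.subject_id}.tsv", rec)
        else:
            raise ValueError(f"unknown recording format {fmt!r}")
    meta_path = out_dir / "metadata.tsv"
    metadata_to_frame([m for _, m in cohort]).to_csv(meta_path, sep="\t", index=False)
    return meta_path


def read_metadata_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata table must contain columns {required}")
    return df
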