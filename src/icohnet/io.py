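"""File interfaces: EDF export/import, labeled matrices, cohort manifests.

EDF export writes plain (continuous) EDF with one data record per trial, so an
epoched recording round-trips exactly through record boundaries.  Samples are
stored as 16-bit integers against a per-signal physical range, the format's
native encoding; reading back therefore quantizes amplitudes to ~1/65536 of
the channel range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int) -> bytes:
    for prec in range(width - 2, -1, -1):
        s = f"{x:.{prec}f}"
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(path: str | Path, e: EpochSet, patient_id: str = "X", recording_id: str = "synthetic") -> Path:
    """Write an :class:`EpochSet` as plain EDF, one data record per trial."""
    path = Path(path)
    n_sig = e.n_channels
    n_rec = e.n_trials
    rec_dur = e.n_samples / e.fs
    data = np.asarray(e.data, dtype=float)
    phys_max = float(max(np.abs(data).max() * 1.01, 1e-6))
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient_id, 80),
            _ascii(recording_id, 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_sig), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _fmt_float(rec_dur, 8),
            _ascii(n_sig, 4),
        ]
    )
    blocks: list[bytes] = [header]
    blocks.append(b"".join(_ascii(c[:16], 16) for c in e.ch_names))
    blocks.append(b"".join(_ascii("EEG electrode", 80) for _ in range(n_sig)))
    blocks.append(b"".join(_ascii("uV", 8) for _ in range(n_sig)))
    blocks.append(b"".join(_fmt_float(phys_min, 8) for _ in range(n_sig)))
    blocks.append(b"".join(_fmt_float(phys_max, 8) for _ in range(n_sig)))
    blocks.append(b"".join(_ascii(dig_min, 8) for _ in range(n_sig)))
    blocks.append(b"".join(_ascii(dig_max, 8) for _ in range(n_sig)))
    blocks.append(b"".join(_ascii("", 80) for _ in range(n_sig)))
    blocks.append(b"".join(_ascii(e.n_samples, 8) for _ in range(n_sig)))
    blocks.append(b"".join(_ascii("", 32) for _ in range(n_sig)))

    digital = np.clip(
        np.round((data - phys_min) * scale) + dig_min, dig_min, dig_max
    ).astype("<i2")
    with open(path, "wb") as f:
        f.write(b"".join(blocks))
        for rec in range(n_rec):
            f.write(digital[rec].tobytes())  # channel-blocked within the record
    return path


def read_edf_epochs(path: str | Path, tmin: float) -> EpochSet:
    """Read an EDF written by :func:`write_edf` back into an :class:`EpochSet`.

    Uses MNE's EDF reader; the one-record-per-trial layout is recovered from
    the record duration in the header.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    with open(path, "rb") as f:
        hdr = f.read(256)
    n_rec = int(hdr[236:244].decode())
    rec_dur = float(hdr[244:252].decode())
    n_samples = int(round(rec_dur * fs))
    data = raw.get_data(units="uV")  # (ch, total samples)
    data = data[:, : n_rec * n_samples].reshape(len(raw.ch_names), n_rec, n_samples)
    return EpochSet(
        data=np.transpose(data, (1, 0, 2)), fs=fs, ch_names=list(raw.ch_names), tmin=tmin
    )


def write_cohort(records, out_dir: str | Path) -> Path:
    """One EDF per subject plus a delimited subject manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}.edf"
        write_edf(out_dir / fname, rec.epochs, patient_id=rec.subject_id)
        rows.append(
            {
                "subject": rec.subject_id,
                "group": rec.group,
                "hand": rec.hand,
                "ul_fma": rec.ul_fma,
                "edf": fname,
                "fs": rec.epochs.fs,
                "tmin": rec.epochs.tmin,
                "n_trials": rec.epochs.n_trials,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path):
    """Read a cohort written by :func:`write_cohort`; returns SubjectRecord list."""
    from .synthdata import SubjectRecord

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    records = []
    for _, row in df.iterrows():
        epochs = read_edf_epochs(manifest_path.parent / row["edf"], tmin=float(row["tmin"]))
        records.append(
            SubjectRecord(
                subject_id=str(row["subject"]),
                group=str(row["group"]),
                hand=str(row["hand"]),
                ul_fma=float(row["ul_fma"]),
                epochs=epochs,
            )
        )
    return records


def save_epochs_npz(path: str | Path, e: EpochSet) -> Path:
    """Internal binary round-trip format (lossless), for tests and pipelines."""
    path = Path(path)
    np.savez_compressed(
        path, data=e.data, fs=e.fs, ch_names=np.array(e.ch_names), tmin=e.tmin
    )
    return path


def load_epochs_npz(path: str | Path) -> EpochSet:
    z = np.load(path, allow_pickle=False)
    return EpochSet(
        data=z["data"], fs=float(z["fs"]), ch_names=[str(c) for c in z["ch_names"]], tmin=float(z["tmin"])
    )


def write_labeled_matrix(path: str | Path, m: np.ndarray, labels: list[str]) -> Path:
    """Connectivity matrix as a labeled delimited table."""
    path = Path(path)
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path, sep="\t")
    return path


def read_labeled_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), list(df.columns)
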