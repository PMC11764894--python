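"""Trial and report input/output.

Two trial-store layouts are supported:

* array-container: one HDF5 file with root attributes ``fs``, ``dimension``
  and ``channels`` and one ``(n_channels, n_samples)`` dataset per trial
  under ``/trials``, each carrying a ``rating`` attribute;
* delimited-text: a directory with a ``manifest.csv`` (comment lines
  ``# fs=...`` and ``# dimension=...``, then ``trial_id,file,rating`` rows)
  pointing at per-trial CSV files whose header row names the channels.

Numeric text output is deterministic: '.' decimal, comma delimiter,
'#'-prefixed comments, floats at 6 significant digits.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import h5py
import numpy as np

from .brem import MONTAGE_32
from .classify import (EvaluationReport, PairRecord, Trial, TrialSet,
                       accuracy, label_from_rating)
from .rhythms import EEGSignal

__all__ = ["read_trials", "write_trials", "write_report", "read_report",
           "read_series", "write_matrix", "read_matrix"]

_FLOAT_FMT = "%.6g"


def _fmt(value: float) -> str:
    return _FLOAT_FMT % value


# ---------------------------------------------------------------- trials

def _check_channels(labels: list[str], where: str) -> list[str]:
    known = [ch for ch in labels if ch in MONTAGE_32]
    unknown = [ch for ch in labels if ch not in MONTAGE_32]
    if unknown:
        warnings.warn(f"{where}: skipping unknown channel labels {unknown}",
                      stacklevel=3)
    if not known:
        raise ValueError(f"{where}: no valid montage channel labels")
    return known


def _read_trials_h5(path: Path) -> TrialSet:
    with h5py.File(path, "r") as f:
        for attr in ("fs", "dimension", "channels"):
            if attr not in f.attrs:
                raise ValueError(f"trial store missing attribute {attr!r}")
        fs = float(f.attrs["fs"])
        dimension = str(f.attrs["dimension"])
        labels = [str(c) for c in f.attrs["channels"]]
        keep = _check_channels(labels, str(path))
        subject = str(f.attrs.get("subject", path.stem))
        if "trials" not in f:
            raise ValueError("trial store has no /trials group")
        trials = []
        group = f["trials"]
        order = sorted(group, key=lambda k: int(group[k].attrs["index"]))
        for tid in order:
            ds = group[tid]
            if "rating" not in ds.attrs:
                raise ValueError(f"trial {tid!r} missing rating attribute")
            rating = float(ds.attrs["rating"])
            data = np.asarray(ds)
            chans = {
                ch: EEGSignal(samples=data[i], fs=fs, channel=ch,
                              trial_id=tid)
                for i, ch in enumerate(labels) if ch in keep
            }
            trials.append(Trial(trial_id=tid, channels=chans,
                                label=label_from_rating(rating),
                                rating=rating))
    return TrialSet(subject=subject, trials=trials, dimension=dimension)


def _read_manifest_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, newline="") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_series(path: Path | str) -> tuple[list[str], np.ndarray]:
    """Read a delimited-text trial: header of channel labels, one column
    per channel.  Returns ``(labels, samples[channel, time])``."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    try:  # headerless single column of numbers is also accepted
        float(header[0])
        header = [f"col{i}" for i in range(len(rows[0]))]
        data_rows = rows
    except ValueError:
        data_rows = rows[1:]
    data = np.array([[float(v) for v in row] for row in data_rows])
    return header, data.T


def _read_trials_text(path: Path) -> TrialSet:
    manifest = path / "manifest.csv" if path.is_dir() else path
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest at {manifest}")
    meta = _read_manifest_header(manifest)
    if "fs" not in meta:
        raise ValueError("manifest missing '# fs=' header")
    fs = float(meta["fs"])
    dimension = meta.get("dimension", "arousal")
    subject = meta.get("subject", manifest.parent.name)
    with open(manifest, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].lstrip().startswith("#")]
    if not rows or [c.strip() for c in rows[0]] != ["trial_id", "file", "rating"]:
        raise ValueError(
            "manifest must have header 'trial_id,file,rating'"
            + ("" if rows else " (file empty)"))
    trials = []
    for tid, fname, rating_s in rows[1:]:
        try:
            rating = float(rating_s)
        except ValueError:
            raise ValueError(f"trial {tid!r}: bad rating {rating_s!r}") from None
        labels, data = read_series(manifest.parent / fname.strip())
        keep = _check_channels(labels, fname)
        chans = {ch: EEGSignal(samples=data[i], fs=fs, channel=ch,
                               trial_id=tid)
                 for i, ch in enumerate(labels) if ch in keep}
        trials.append(Trial(trial_id=tid.strip(), channels=chans,
                            label=label_from_rating(rating), rating=rating))
    return TrialSet(subject=subject, trials=trials, dimension=dimension)


def read_trials(path: Path | str, format: str | None = None) -> TrialSet:
    """Load a :class:`TrialSet` from an array-container (HDF5) or
    delimited-text store; ratings map to labels via the >= 5 rule."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = ("array-container"
                  if path.suffix in (".h5", ".hdf5") else "delimited-text")
    if format == "array-container":
        return _read_trials_h5(path)
    if format == "delimited-text":
        return _read_trials_text(path)
    raise ValueError(f"unknown format {format!r}")


def write_trials(trials: TrialSet, path: Path | str) -> None:
    """Write a :class:`TrialSet` as an HDF5 array container."""
    path = Path(path)
    channels = sorted({ch for t in trials.trials for ch in t.channels},
                      key=lambda c: (MONTAGE_32.index(c)
                                     if c in MONTAGE_32 else 99, c))
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = trials.fs
        f.attrs["dimension"] = trials.dimension
        f.attrs["subject"] = trials.subject
        f.attrs["channels"] = channels
        group = f.create_group("trials")
        for k, trial in enumerate(trials.trials):
            data = np.stack([trial.channels[ch].samples for ch in channels])
            ds = group.create_dataset(trial.trial_id, data=data)
            ds.attrs["index"] = k
            ds.attrs["rating"] = (trial.rating if trial.rating is not None
                                  else (7.0 if trial.label == "positive"
                                        else 3.0))


# ---------------------------------------------------------------- reports

def write_report(report: EvaluationReport, path: Path | str) -> None:
    """Write the per-pair table (CSV) plus a JSON summary next to it.

    A round-trip through :func:`read_report` reproduces every confusion
    count exactly.
    """
    if not report.records:
        raise ValueError("report must contain at least one pair")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# per-template-pair LOOCV records\n")
        writer = csv.writer(fh)
        writer.writerow(["pos_template_id", "neg_template_id",
                         "TP", "FP", "FN", "TN", "accuracy", "ties"])
        for r in report.records:
            writer.writerow([r.pos_template_id, r.neg_template_id,
                             r.tp, r.fp, r.fn, r.tn,
                             _fmt(r.accuracy), r.ties])
    summary = {
        "mean_accuracy": float(_fmt(report.mean_accuracy)),
        "sd_accuracy": float(_fmt(report.sd_accuracy)),
        "n_pairs": report.n_pairs,
        "tie_count": report.tie_count,
        "config": report.config,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: Path | str) -> EvaluationReport:
    """Inverse of :func:`write_report` (counts exact, floats at 6 s.d.)."""
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].lstrip().startswith("#")]
    records = []
    for pos_id, neg_id, tp, fp, fn, tn, _acc, ties in rows[1:]:
        tp, fp, fn, tn = int(tp), int(fp), int(fn), int(tn)
        records.append(PairRecord(
            pos_template_id=pos_id, neg_template_id=neg_id,
            tp=tp, fp=fp, fn=fn, tn=tn,
            accuracy=accuracy(tp, fp, fn, tn), ties=int(ties)))
    with open(path.with_suffix(".json")) as fh:
        summary = json.load(fh)
    accs = np.array([r.accuracy for r in records])
    return EvaluationReport(
        records=records, mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        n_pairs=len(records),
        tie_count=int(summary["tie_count"]), config=summary["config"])


# ---------------------------------------------------------------- matrices

def write_matrix(values: np.ndarray, path: Path | str,
                 row_labels: list[str], col_labels: list[str]) -> None:
    """Write a labeled matrix as CSV (rhythm rows, entropy columns)."""
    values = np.asarray(values)
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(col_labels))
        for label, row in zip(row_labels, values):
            writer.writerow([label] + [_fmt(v) for v in row])


def read_matrix(path: Path | str) -> tuple[np.ndarray, list[str], list[str]]:
    with open(Path(path), newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].lstrip().startswith("#")]
    col_labels = rows[0][1:]
    row_labels = [r[0] for r in rows[1:]]
    values = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return values, row_labels, col_labels
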