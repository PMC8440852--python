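"""Readers and writers for the pipeline's on-disk artifacts.

Raw channels travel as CSV (columns ``time_s,value``) with a per-subject
events CSV (``onset_s,level``), or bundled per cohort in one HDF5 file.
Segment datasets, model checkpoints and training curves use HDF5/CSV.
"""

from __future__ import annotations

import csv
import json

import h5py
import numpy as np

from .preprocess import Recording, SegmentDataset

_STR = None  # h5py string dtype, created lazily


def _str_dtype():
    global _STR
    if _STR is None:
        _STR = h5py.string_dtype(encoding="utf-8")
    return _STR


# -- CSV ---------------------------------------------------------------------

def write_channel_csv(path, rec: Recording):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for i, v in enumerate(rec.samples):
            w.writerow([f"{i / rec.rate:.6f}", f"{v:.9g}"])


def read_channel_csv(path, subject_id, modality, events=()) -> Recording:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = data[:, 0], data[:, 1]
    rate = (len(t) - 1) / float(t[-1] - t[0])
    if abs(rate - round(rate)) < 1e-2:  # absorb timestamp rounding
        rate = float(round(rate))
    return Recording(subject_id, modality, v, rate, tuple(events))


def write_events_csv(path, events):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "level"])
        for onset, level in events:
            w.writerow([f"{onset:.6f}", level])


def read_events_csv(path):
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return tuple((float(o), int(l)) for o, l in data)


# -- cohort HDF5 -------------------------------------------------------------

def write_cohort_h5(path, recordings, attrs: dict | None = None):
    with h5py.File(path, "w") as f:
        if attrs:
            f.attrs.update(attrs)
        for rec in recordings:
            g = f.require_group(f"{rec.subject_id}/{rec.modality}")
            g.create_dataset("samples", data=rec.samples)
            g.attrs["rate"] = rec.rate
            ev = f[rec.subject_id]
            if "events" not in ev:
                ev.create_dataset(
                    "events",
                    data=np.array([(o, l) for o, l in rec.events]),
                )


def read_cohort_h5(path) -> list:
    out = []
    with h5py.File(path, "r") as f:
        for subject in sorted(f):
            grp = f[subject]
            events = tuple(
                (float(o), int(l)) for o, l in grp["events"][()]
            ) if "events" in grp else ()
            for mod in sorted(grp):
                if mod == "events":
                    continue
                g = grp[mod]
                out.append(Recording(subject, mod, g["samples"][()],
                                     float(g.attrs["rate"]), events))
    return out


# -- segment datasets --------------------------------------------------------

def write_segments_h5(path, ds: SegmentDataset, attrs: dict | None = None):
    with h5py.File(path, "w") as f:
        if attrs:
            f.attrs.update(attrs)
        xg = f.create_group("X")
        xg.attrs["order"] = json.dumps(list(ds.X))
        for mod, x in ds.X.items():
            xg.create_dataset(mod, data=x)
        f.create_dataset("y", data=np.asarray(ds.y, dtype=float))
        f.create_dataset("subject", data=ds.subject.astype(object),
                         dtype=_str_dtype())
        f.create_dataset("shift", data=np.asarray(ds.shift, dtype=int))
        f.create_dataset("provenance", data=ds.provenance.astype(object),
                         dtype=_str_dtype())


def read_segments_h5(path) -> SegmentDataset:
    with h5py.File(path, "r") as f:
        order = json.loads(f["X"].attrs.get("order", "null")) or sorted(f["X"])
        X = {mod: f["X"][mod][()] for mod in order}
        y = f["y"][()]
        if np.allclose(y, np.round(y)):
            y = y.astype(int)
        return SegmentDataset(
            X=X, y=y,
            subject=np.array([s.decode() for s in f["subject"][()]],
                             dtype=object),
            shift=f["shift"][()],
            provenance=np.array([s.decode() for s in f["provenance"][()]],
                                dtype=object),
        )


# -- checkpoints and curves --------------------------------------------------

def save_checkpoint(path, model, extra: dict | None = None):
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(_config_json(model.cfg))
        if model.classes_ is not None:
            f.create_dataset("classes", data=np.asarray(model.classes_,
                                                        dtype=float))
        if extra:
            f.attrs.update({k: json.dumps(v) for k, v in extra.items()})
        g = f.create_group("params")
        for name, arr in model.state_dict().items():
            g.create_dataset(name, data=arr)


def load_checkpoint(path, model):
    """Load parameters into an already-built model of matching config."""
    with h5py.File(path, "r") as f:
        state = {name: f["params"][name][()] for name in f["params"]}
        model.load_state_dict(state)
        if "classes" in f:
            classes = f["classes"][()]
            if np.allclose(classes, np.round(classes)):
                classes = classes.astype(int)
            model.classes_ = classes
    return model


def _config_json(cfg) -> dict:
    from dataclasses import asdict
    return asdict(cfg)


def write_curves_csv(path, history):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "loss"])
        for row in history:
            w.writerow([row["epoch"], f"{row['loss']:.9g}"])


def write_metrics_csv(path, fold_results):
    names = sorted(fold_results[0].metrics)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["test_subject"] + names)
        for fr in fold_results:
            w.writerow([fr.test_subject]
                       + [f"{fr.metrics[n]:.9g}" for n in names])


def read_metrics_csv(path) -> dict:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    out = {k: np.array([float(r[k]) for r in rows])
           for k in rows[0] if k != "test_subject"}
    out["test_subject"] = np.array([r["test_subject"] for r in rows])
    return out
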