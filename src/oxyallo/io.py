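"""HDF5 container for synthetic experiments and derived results.

Layout::

    /recording/{swim,resp,po2_brain,po2_bath}   (fs attributes)
    /fluo/{F,coords}                            (frame_rate attribute)
    /schedule                                   epoch table
    /truth                                      manifest JSON string
    /events/{bouts,resp_times}                  ground-truth behavior
    /fluo/{Fslow,dff}, /clusters/{L,A,labels}, /maps/...   (derived, optional)
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .paradigm import Epoch, Paradigm
from .synthdata import FluorescenceSet, Recording, SyntheticExperiment

__all__ = ["save_experiment", "load_experiment", "save_decomposition",
           "load_decomposition"]


def save_experiment(path: str, exp: SyntheticExperiment) -> None:
    rec = exp.recording
    with h5py.File(path, "w") as f:
        g = f.create_group("recording")
        for name, data, fs in (
            ("swim", rec.swim, rec.fs),
            ("resp", rec.resp, rec.fs),
            ("po2_brain", rec.po2_brain, rec.po2_fs),
            ("po2_bath", rec.po2_bath, rec.po2_fs),
        ):
            d = g.create_dataset(name, data=data, compression="gzip")
            d.attrs["fs"] = fs
        gf = f.create_group("fluo")
        gf.create_dataset("F", data=exp.fluo.F, compression="gzip")
        gf.create_dataset("coords", data=exp.fluo.coords)
        gf.attrs["frame_rate"] = exp.fluo.frame_rate
        if exp.fluo.cell_archetype is not None:
            gf.create_dataset(
                "cell_archetype",
                data=np.asarray(exp.fluo.cell_archetype, dtype="S"),
            )
        sched = np.array(
            [
                (e.label.encode(), e.start, e.end, e.bath_o2)
                for e in rec.schedule.epochs
            ],
            dtype=[("label", "S16"), ("start", "f8"), ("end", "f8"),
                   ("bath_o2", "f8")],
        )
        ds = f.create_dataset("schedule", data=sched)
        ds.attrs["mixing_tau"] = rec.schedule.mixing_tau
        f.create_dataset("truth", data=json.dumps(exp.manifest))
        ge = f.create_group("events")
        ge.create_dataset(
            "bouts", data=exp.bouts[["onset_s", "offset_s", "vigor"]].values
        )
        ge.create_dataset("resp_times", data=exp.resp_events)


def load_experiment(path: str) -> SyntheticExperiment:
    with h5py.File(path, "r") as f:
        sched_rows = f["schedule"][()]
        schedule = Paradigm(
            epochs=tuple(
                Epoch(r["label"].decode(), float(r["start"]), float(r["end"]),
                      float(r["bath_o2"]))
                for r in sched_rows
            ),
            mixing_tau=float(f["schedule"].attrs["mixing_tau"]),
        )
        rec = Recording(
            swim=f["recording/swim"][()],
            resp=f["recording/resp"][()],
            po2_brain=f["recording/po2_brain"][()],
            po2_bath=f["recording/po2_bath"][()],
            fs=float(f["recording/swim"].attrs["fs"]),
            po2_fs=float(f["recording/po2_brain"].attrs["fs"]),
            schedule=schedule,
        )
        labels = (
            np.char.decode(f["fluo/cell_archetype"][()].astype("S"))
            if "cell_archetype" in f["fluo"]
            else None
        )
        fluo = FluorescenceSet(
            F=f["fluo/F"][()],
            coords=f["fluo/coords"][()],
            frame_rate=float(f["fluo"].attrs["frame_rate"]),
            cell_archetype=labels,
        )
        bouts = pd.DataFrame(
            f["events/bouts"][()], columns=["onset_s", "offset_s", "vigor"]
        )
        manifest = json.loads(f["truth"][()])
        resp_events = f["events/resp_times"][()]
    return SyntheticExperiment(
        recording=rec, bouts=bouts, resp_events=resp_events, fluo=fluo,
        manifest=manifest,
    )


def save_decomposition(path: str, fslow: np.ndarray, dff: np.ndarray) -> None:
    with h5py.File(path, "a") as f:
        for name, data in (("Fslow", fslow), ("dff", dff)):
            if f"fluo/{name}" in f:
                del f[f"fluo/{name}"]
            f.create_dataset(f"fluo/{name}", data=data, compression="gzip")


def load_decomposition(path: str) -> tuple[np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        return f["fluo/Fslow"][()], f["fluo/dff"][()]
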