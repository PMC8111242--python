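"""HDF5 / CSV / JSON persistence for cohorts and analysis artifacts.

Cohort layout: ``/subjects/<id>/task`` and (optionally) ``/rest`` groups,
each with a ``data`` dataset (samples x parcels) and, for synthetic
cohorts, the true ``states`` path; sampling rate and parcel names are
stored as attributes.  Trial structure travels as a separate events CSV
(trial_id, baseline_onset_s, stim_onset_s, trial_end_s) per subject, and
planted ground truth as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .hmm import HMMParameters
from .preprocess import ConcatenatedData, ParcelTimeSeries
from .simulate import Cohort, CohortConfig, GroundTruth, SubjectRecordings
from .spectra import BandPowerMap, StateSpectra

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_concat",
    "read_concat",
    "write_hmm",
    "read_hmm",
    "LoadedHMM",
    "write_spectra",
    "read_spectra",
    "band_map_to_frame",
]


def _events_path(h5_path: Path) -> Path:
    return h5_path.with_suffix(".events.csv")


def _truth_path(h5_path: Path) -> Path:
    return h5_path.with_suffix(".truth.json")


def write_cohort(cohort: Cohort, h5_path: str | Path) -> None:
    """Write recordings, per-subject events CSV and ground-truth JSON.

    Events go to ``<stem>.events.csv`` (with a subject_id column), ground
    truth to ``<stem>.truth.json``.
    """
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as f:
        f.attrs["fs"] = cohort.config.fs
        f.attrs["roi_parcels"] = list(cohort.config.roi_parcels)
        f.attrs["K_true"] = cohort.config.K_true
        f.attrs["enhancing_state"] = cohort.config.enhancing_state
        f.attrs["seed"] = cohort.config.seed
        f.attrs["parcel_names"] = cohort.config.parcel_names()
        subs = f.create_group("subjects")
        for sub in cohort.subjects:
            g = subs.create_group(sub.subject_id)
            gt = g.create_group("task")
            gt.create_dataset("data", data=sub.task.data, compression="gzip")
            states = cohort.ground_truth.state_paths_task.get(sub.subject_id)
            if states is not None:
                gt.create_dataset("states", data=states)
            if sub.rest is not None:
                gr = g.create_group("rest")
                gr.create_dataset("data", data=sub.rest.data, compression="gzip")
                rstates = cohort.ground_truth.state_paths_rest.get(sub.subject_id)
                if rstates is not None:
                    gr.create_dataset("states", data=rstates)
    ev = pd.concat(
        [sub.events.assign(subject_id=sub.subject_id) for sub in cohort.subjects],
        ignore_index=True,
    )
    ev.to_csv(_events_path(h5_path), index=False)
    _truth_path(h5_path).write_text(cohort.ground_truth.to_json())


def read_cohort(h5_path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    h5_path = Path(h5_path)
    ev_all = pd.read_csv(_events_path(h5_path))
    truth_file = _truth_path(h5_path)
    subjects: list[SubjectRecordings] = []
    with h5py.File(h5_path, "r") as f:
        fs = float(f.attrs["fs"])
        roi = tuple(int(p) for p in f.attrs["roi_parcels"])
        names = [str(x) for x in f.attrs["parcel_names"]]
        state_paths_task, state_paths_rest = {}, {}
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            task = ParcelTimeSeries(g["task/data"][()], fs, sid, parcel_names=names)
            rest = None
            if "rest" in g:
                rest = ParcelTimeSeries(g["rest/data"][()], fs, sid, parcel_names=names)
                if "states" in g["rest"]:
                    state_paths_rest[sid] = g["rest/states"][()]
            if "states" in g["task"]:
                state_paths_task[sid] = g["task/states"][()]
            ev = (
                ev_all[ev_all.subject_id == sid]
                .drop(columns="subject_id")
                .reset_index(drop=True)
            )
            subjects.append(SubjectRecordings(sid, rest, task, ev))
        n_parcels = subjects[0].task.n_parcels
        K = int(f.attrs["K_true"])
        cfg = CohortConfig(
            n_subjects=max(len(subjects), 2),
            n_parcels=n_parcels,
            fs=fs,
            K_true=K,
            n_trials=len(subjects[0].events),
            roi_parcels=roi,
            enhancing_state=int(f.attrs["enhancing_state"]),
            seed=int(f.attrs["seed"]),
        )
    if truth_file.exists():
        raw = json.loads(truth_file.read_text())
        gt = GroundTruth(
            enhancing_state=raw["enhancing_state"],
            state_paths_task={k: np.asarray(v) for k, v in raw["state_paths_task"].items()},
            state_paths_rest={k: np.asarray(v) for k, v in raw["state_paths_rest"].items()},
            fo_baseline={k: np.asarray(v) for k, v in raw["fo_baseline"].items()},
            fo_rest={k: np.asarray(v) for k, v in raw["fo_rest"].items()},
            prestim_state={k: np.asarray(v) for k, v in raw["prestim_state"].items()},
            planted_amplitude={k: np.asarray(v) for k, v in raw["planted_amplitude"].items()},
            subject_amplitude=raw["subject_amplitude"],
            peak_freq=raw["peak_freq"],
            transitions={k: np.asarray(v) for k, v in raw["transitions"].items()},
        )
    else:
        gt = GroundTruth(0, state_paths_task, state_paths_rest, {}, {}, {}, {}, {}, {}, {})
    return Cohort(cfg, subjects, gt)


def write_concat(concat: ConcatenatedData, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = concat.fs
        f.create_dataset("data", data=concat.data, compression="gzip")
        g = f.create_group("index")
        for col in ("subject_id", "label"):
            g.create_dataset(col, data=concat.index[col].astype(str).to_numpy(dtype="S"))
        for col in ("segment_id", "start", "stop"):
            g.create_dataset(col, data=concat.index[col].to_numpy())


def read_concat(path: str | Path) -> ConcatenatedData:
    with h5py.File(path, "r") as f:
        index = pd.DataFrame(
            {
                "subject_id": [s.decode() for s in f["index/subject_id"][()]],
                "segment_id": f["index/segment_id"][()],
                "label": [s.decode() for s in f["index/label"][()]],
                "start": f["index/start"][()],
                "stop": f["index/stop"][()],
            }
        )
        return ConcatenatedData(f["data"][()], float(f.attrs["fs"]), index)


@dataclasses.dataclass
class LoadedHMM:
    """Fitted HMM read back from disk (parameters, posteriors, diagnostics)."""

    params: HMMParameters
    gamma: np.ndarray
    valid_mask: np.ndarray
    lags: list[int]
    loglik_trace: np.ndarray
    converged: bool

    @property
    def n_states(self) -> int:
        return self.params.n_states


def write_hmm(results, path: str | Path) -> None:
    """Persist a fitted TDE-HMM (works for TDEHMMResults and LoadedHMM)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("initial", data=results.params.initial)
        f.create_dataset("transition", data=results.params.transition)
        f.create_dataset("covariances", data=results.params.covariances)
        f.create_dataset("gamma", data=results.gamma, compression="gzip")
        f.create_dataset("valid_mask", data=results.valid_mask)
        f.create_dataset("loglik_trace", data=results.loglik_trace)
        lags = results.model.lags if hasattr(results, "model") else results.lags
        f.attrs["lags"] = lags
        f.attrs["converged"] = bool(results.converged)
        pca = getattr(results, "pca", None)
        if pca is not None:
            g = f.create_group("pca")
            g.create_dataset("components", data=pca.components_)
            g.create_dataset("mean", data=pca.mean_)


def read_hmm(path: str | Path) -> LoadedHMM:
    with h5py.File(path, "r") as f:
        params = HMMParameters(
            f["initial"][()], f["transition"][()], f["covariances"][()]
        )
        return LoadedHMM(
            params,
            f["gamma"][()],
            f["valid_mask"][()].astype(bool),
            [int(l) for l in f.attrs["lags"]],
            f["loglik_trace"][()],
            bool(f.attrs["converged"]),
        )


def write_spectra(spectra: StateSpectra, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=spectra.power, compression="gzip")
        if spectra.coherence is not None:
            f.create_dataset("coherence", data=spectra.coherence, compression="gzip")
        f.create_dataset("freqs", data=spectra.freqs)
        f.attrs["n_tapers"] = spectra.n_tapers
        f.attrs["window_s"] = spectra.window_s
        f.attrs["overlap"] = spectra.overlap


def read_spectra(path: str | Path) -> StateSpectra:
    with h5py.File(path, "r") as f:
        return StateSpectra(
            f["power"][()],
            f["coherence"][()] if "coherence" in f else None,
            f["freqs"][()],
            int(f.attrs["n_tapers"]),
            float(f.attrs["window_s"]),
            float(f.attrs["overlap"]),
        )


def band_map_to_frame(
    bmap: BandPowerMap, parcel_names: list[str] | None = None
) -> pd.DataFrame:
    """Long-format (state, parcel, band, value) table for export/plotting."""
    K, P, _ = bmap.values.shape
    if parcel_names is None:
        parcel_names = [f"parcel_{p:02d}" for p in range(P)]
    rows = []
    for k in range(K):
        for p in range(P):
            for b, name in enumerate(bmap.band_names):
                rows.append(
                    {
                        "state": k,
                        "parcel": parcel_names[p],
                        "band": name,
                        "value": bmap.values[k, p, b],
                    }
                )
    return pd.DataFrame(rows)
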