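"""File formats: TSV spike lists, JSON session metadata and sidecars, HDF5
raw traces, and YAML/JSON configuration.

All analysis products are plain text (diff-able); HDF5 is used only for raw
multi-channel traces, whose volume demands a binary container.  Times are
printed with six decimal places (microsecond precision at the 25 kHz
acquisition scale) and round-trip exactly at that printed precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import yaml

from .types import RawRecording, SessionRecord, SpikeTrain

SPIKE_HEADER = "electrode_id\ttime_s"
TIME_FMT = "{:.6f}"


def write_spike_table(trains: Sequence[SpikeTrain], path: str | Path) -> None:
    """Write trains as a two-column TSV (electrode_id, time_s)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(SPIKE_HEADER + "\n")
        for tr in trains:
            for t in tr.times_s:
                fh.write(f"{tr.electrode_id}\t{TIME_FMT.format(t)}\n")


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Read a spike TSV, validating monotonicity per electrode.

    Electrodes appear in order of first occurrence; rows of one electrode
    must be strictly increasing in time.
    """
    path = Path(path)
    by_electrode: dict[str, list[float]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if header != SPIKE_HEADER:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: unparseable row {line!r}")
            eid, t_raw = parts
            try:
                t = float(t_raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad time {t_raw!r}") from exc
            by_electrode.setdefault(eid, []).append(t)
    trains = []
    for eid, times in by_electrode.items():
        arr = np.asarray(times)
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError(f"{path}: non-monotone spike times on electrode {eid!r}")
        trains.append(SpikeTrain(eid, arr))
    return trains


def write_session(session: SessionRecord, spikes_path: str | Path,
                  meta_path: str | Path) -> None:
    """Write one session as a spike TSV plus a JSON metadata sidecar.

    The sidecar carries the full electrode list (silent electrodes do not
    appear in the TSV) and the session labels.
    """
    write_spike_table(session.trains, spikes_path)
    meta = {
        "assembloid_id": session.assembloid_id,
        "genotype": session.genotype,
        "condition": session.condition,
        "duration_s": session.duration_s,
        "electrode_ids": list(session.electrode_ids),
    }
    write_json(meta, meta_path)


def read_session(spikes_path: str | Path, meta_path: str | Path) -> SessionRecord:
    meta = read_json(meta_path)
    trains = {tr.electrode_id: tr for tr in read_spike_table(spikes_path)}
    unknown = set(trains) - set(meta["electrode_ids"])
    if unknown:
        raise ValueError(f"spike table has electrodes absent from metadata: {sorted(unknown)}")
    full = tuple(
        trains.get(eid, SpikeTrain(eid, np.empty(0))) for eid in meta["electrode_ids"]
    )
    return SessionRecord(
        assembloid_id=meta["assembloid_id"],
        genotype=meta["genotype"],
        condition=meta["condition"],
        duration_s=float(meta["duration_s"]),
        trains=full,
    )


def write_raw(raw: RawRecording, path: str | Path) -> None:
    """Write a raw recording to HDF5 (dataset ``traces`` int16 + attributes)."""
    if raw.traces.dtype != np.int16:
        raise ValueError("raw traces must be int16 for acquisition-format export")
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("traces", data=raw.traces, dtype="int16")
        ds.attrs["sampling_rate_hz"] = float(raw.sampling_rate_hz)
        ds.attrs["duration_s"] = float(raw.duration_s)
        ds.attrs["electrode_ids"] = [eid.encode() for eid in raw.electrode_ids]


def read_raw(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as fh:
        if "traces" not in fh:
            raise ValueError(f"{path}: missing 'traces' dataset")
        ds = fh["traces"]
        if ds.dtype != np.int16:
            raise ValueError(f"{path}: traces dtype {ds.dtype} is not signed 16-bit")
        if "sampling_rate_hz" not in ds.attrs:
            raise ValueError(f"{path}: missing sampling_rate_hz attribute")
        rate = float(ds.attrs["sampling_rate_hz"])
        traces = ds[()]
        ids = [
            e.decode() if isinstance(e, bytes) else str(e)
            for e in ds.attrs.get("electrode_ids", [f"E{i:02d}" for i in range(traces.shape[0])])
        ]
        duration = float(ds.attrs.get("duration_s", traces.shape[1] / rate))
    return RawRecording(traces=traces, sampling_rate_hz=rate,
                        electrode_ids=tuple(ids), duration_s=duration)


def write_json(obj, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    with Path(path).open() as fh:
        return json.load(fh)


def read_config(path: str | Path) -> dict:
    """Load a configuration mapping from YAML or JSON by extension."""
    path = Path(path)
    with path.open() as fh:
        if path.suffix.lower() in (".yml", ".yaml"):
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: configuration must be a mapping")
    return dict(cfg)


def write_ground_truth(truth, spikes_path: str | Path, sidecar_path: str | Path) -> None:
    """Export ground truth: TSV spike list plus a JSON sidecar with the
    coupling matrix and the injected network-burst intervals."""
    trains = [SpikeTrain(eid, times) for eid, times in truth.spike_times.items()]
    write_spike_table(trains, spikes_path)
    write_json(
        {
            "coupling_matrix": truth.coupling_matrix,
            "nb_intervals": [list(iv) for iv in truth.nb_intervals],
            "nb_participants": [list(p) for p in truth.nb_participants],
            "condition_scalar": truth.condition_scalar,
            "n_source_spikes": int(truth.source_times_s.size),
        },
        sidecar_path,
    )
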