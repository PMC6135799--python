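"""Session-bundle data model and on-disk interchange format.

A session bundle is one recording session: the tracked trajectory, one
spike train per sorted unit (with waveform summary statistics), the
light-pulse event train when the session is a stimulation session, and
any number of LFP channels.  Bundles are stored as a directory of
plain-text CSV files plus a versioned JSON manifest; LFP may optionally
be stored in HDF5 for size.

A recording *day* is the ordered triple baseline1 / stimulation /
baseline2 with a consistent unit population, which is what the
classification stages operate on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import LfpSignal, StimTrain, Trajectory

FORMAT_VERSION = "1.0"
ROLES = ("baseline1", "stimulation", "baseline2")

__all__ = [
    "SpikeTrain",
    "SessionBundle",
    "DayRecord",
    "write_session",
    "read_session",
    "validate_day",
    "ValidationError",
]


class ValidationError(ValueError):
    """A session bundle violates the format's invariants."""


@dataclass
class SpikeTrain:
    """Sorted spike timestamps of one unit plus waveform summaries."""

    cell_id: str
    times: np.ndarray
    mean_rate: float = 0.0
    peak_valley_ratio: float = 2.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValidationError(f"unit {self.cell_id}: spike times not sorted")
        if len(self.times) and self.times[0] < 0:
            raise ValidationError(f"unit {self.cell_id}: negative spike time")
        if self.mean_rate < 0:
            raise ValidationError(f"unit {self.cell_id}: negative mean rate")


@dataclass
class SessionBundle:
    session_id: str
    role: str
    trajectory: Trajectory
    units: list[SpikeTrain]
    stim: StimTrain | None = None
    lfp: list[LfpSignal] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"invalid role {self.role!r}; expected one of {ROLES}")
        if (self.stim is not None) != (self.role == "stimulation"):
            raise ValidationError("stim train must be present iff role is 'stimulation'")
        dur = self.duration
        for u in self.units:
            if len(u.times) and (u.times[0] < 0 or u.times[-1] > dur):
                raise ValidationError(
                    f"unit {u.cell_id}: spike times outside [0, {dur:.3f}] s"
                )
        if self.stim is not None and len(self.stim.onsets):
            if self.stim.onsets[0] < 0 or self.stim.onsets[-1] > dur:
                raise ValidationError("stim onsets outside the session")

    @property
    def duration(self) -> float:
        return float(self.metadata.get("duration_s") or self.trajectory.duration)

    def unit(self, cell_id: str) -> SpikeTrain:
        for u in self.units:
            if u.cell_id == cell_id:
                return u
        raise KeyError(cell_id)


@dataclass
class DayRecord:
    """The validated baseline1 / stimulation / baseline2 triple."""

    baseline1: SessionBundle
    stimulation: SessionBundle
    baseline2: SessionBundle

    @property
    def sessions(self) -> tuple[SessionBundle, SessionBundle, SessionBundle]:
        return (self.baseline1, self.stimulation, self.baseline2)

    @property
    def cell_ids(self) -> list[str]:
        return [u.cell_id for u in self.baseline1.units]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_POS_HEADER = "# t [s], x [cm], y [cm], hd [deg]\n"
_SPK_HEADER = "# t [s]\n"
_EVT_HEADER = "# onset [s]\n"


def write_session(
    bundle: SessionBundle,
    path: str | Path,
    overwrite: bool = False,
    lfp_format: str = "hdf5",
) -> Path:
    """Write a bundle to ``path`` and return the manifest path."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    path.mkdir(parents=True, exist_ok=True)

    tr = bundle.trajectory
    with open(path / "position.csv", "w") as fh:
        fh.write(_POS_HEADER)
        pd.DataFrame({"t": tr.t, "x": tr.x, "y": tr.y, "hd": tr.hd}).to_csv(
            fh, index=False, float_format="%.9g"
        )
    for u in bundle.units:
        with open(path / f"spikes_{u.cell_id}.csv", "w") as fh:
            fh.write(_SPK_HEADER)
            pd.DataFrame({"t": u.times}).to_csv(fh, index=False, float_format="%.9g")
    if bundle.stim is not None:
        with open(path / "events.csv", "w") as fh:
            fh.write(_EVT_HEADER)
            pd.DataFrame({"onset": bundle.stim.onsets}).to_csv(
                fh, index=False, float_format="%.9g"
            )

    lfp_entries = []
    for sig in bundle.lfp:
        if lfp_format == "hdf5":
            import h5py

            fname = f"lfp_{sig.channel_id}.h5"
            with h5py.File(path / fname, "w") as h5:
                ds = h5.create_dataset("samples", data=sig.samples)
                ds.attrs["fs"] = sig.fs
        elif lfp_format == "csv":
            fname = f"lfp_{sig.channel_id}.csv"
            np.savetxt(path / fname, sig.samples, fmt="%.6g", header="uV")
        else:
            raise ValueError("lfp_format must be 'hdf5' or 'csv'")
        lfp_entries.append({"channel_id": sig.channel_id, "fs": sig.fs, "file": fname})

    manifest = {
        "format_version": FORMAT_VERSION,
        "session_id": bundle.session_id,
        "role": bundle.role,
        "box_size_cm": tr.box_size_cm,
        "duration_s": bundle.duration,
        "units": [
            {
                "cell_id": u.cell_id,
                "file": f"spikes_{u.cell_id}.csv",
                "n_spikes": int(len(u.times)),
                "mean_rate": u.mean_rate,
                "peak_valley_ratio": u.peak_valley_ratio,
            }
            for u in bundle.units
        ],
        "stim": (
            {
                "file": "events.csv",
                "frequency_hz": bundle.stim.frequency_hz,
                "pulse_width_ms": bundle.stim.pulse_width_ms,
            }
            if bundle.stim is not None
            else None
        ),
        "lfp": lfp_entries,
        "metadata": bundle.metadata,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing file {path.name}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as e:
        raise ValidationError(f"{path.name}: unreadable CSV ({e})") from e
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    try:
        df = df[columns].apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as e:
        raise ValidationError(f"{path.name}: non-numeric values ({e})") from e
    if df.isna().any().any():
        raise ValidationError(f"{path.name}: missing values")
    return df


def read_session(path: str | Path) -> SessionBundle:
    """Read and fully validate a session bundle directory."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json under {path}")
    with open(manifest_path) as fh:
        man = json.load(fh)
    if man.get("format_version") != FORMAT_VERSION:
        raise ValidationError(f"unsupported format_version {man.get('format_version')!r}")

    pos = _read_csv(path / "position.csv", ["t", "x", "y", "hd"])
    try:
        traj = Trajectory(
            t=pos["t"].to_numpy(),
            x=pos["x"].to_numpy(),
            y=pos["y"].to_numpy(),
            hd=pos["hd"].to_numpy() % 360.0,
            box_size_cm=float(man["box_size_cm"]),
        )
    except ValueError as e:
        raise ValidationError(f"position.csv: {e}") from e

    units = []
    for entry in man["units"]:
        df = _read_csv(path / entry["file"], ["t"])
        units.append(
            SpikeTrain(
                cell_id=entry["cell_id"],
                times=df["t"].to_numpy(),
                mean_rate=float(entry["mean_rate"]),
                peak_valley_ratio=float(entry["peak_valley_ratio"]),
            )
        )

    stim = None
    if man.get("stim") is not None:
        df = _read_csv(path / man["stim"]["file"], ["onset"])
        stim = StimTrain(
            onsets=df["onset"].to_numpy(),
            pulse_width_ms=float(man["stim"]["pulse_width_ms"]),
            frequency_hz=float(man["stim"]["frequency_hz"]),
        )

    lfps = []
    for entry in man.get("lfp", []):
        f = path / entry["file"]
        if not f.exists():
            raise ValidationError(f"missing LFP file {entry['file']}")
        if f.suffix == ".h5":
            import h5py

            with h5py.File(f, "r") as h5:
                samples = h5["samples"][:]
        else:
            samples = np.loadtxt(f)
        lfps.append(
            LfpSignal(fs=float(entry["fs"]), samples=samples, channel_id=entry["channel_id"])
        )

    return SessionBundle(
        session_id=man["session_id"],
        role=man["role"],
        trajectory=traj,
        units=units,
        stim=stim,
        lfp=lfps,
        metadata=man.get("metadata", {}),
    )


def validate_day(bundles: list[SessionBundle]) -> DayRecord:
    """Group >= 3 sessions into a validated day record.

    Requires exactly one session per role in baseline1 / stimulation /
    baseline2 order and an identical unit-id set across the three.
    """
    if len(bundles) < 3:
        raise ValidationError(f"a day needs >= 3 sessions, got {len(bundles)}")
    by_role: dict[str, SessionBundle] = {}
    for b in bundles:
        if b.role in by_role:
            raise ValidationError(f"duplicate role {b.role!r}")
        by_role[b.role] = b
    missing = [r for r in ROLES if r not in by_role]
    if missing:
        raise ValidationError(f"missing session roles: {missing}")
    id_sets = [tuple(u.cell_id for u in by_role[r].units) for r in ROLES]
    common = set(id_sets[0]) & set(id_sets[1]) & set(id_sets[2])
    for r, ids in zip(ROLES, id_sets):
        odd = set(ids) - common
        if odd:
            raise ValidationError(
                f"units {sorted(odd)} not present in all three sessions (role {r})"
            )
    return DayRecord(
        baseline1=by_role["baseline1"],
        stimulation=by_role["stimulation"],
        baseline2=by_role["baseline2"],
    )
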