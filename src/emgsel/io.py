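"""Reading and writing trial datasets as plain-text files.

A dataset on disk is a YAML manifest plus one delimited-text signal file per
trial (one row per sample, one column per channel).  Text formats keep
fixtures diff-able and avoid any proprietary acquisition container.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dataset import (
    CHANNEL_GROUPS,
    MOTION_CLASSES,
    WRIST_POSITIONS,
    ChannelLayout,
    Trial,
)


class DatasetError(RuntimeError):
    """Raised for malformed manifests or inconsistent trial files."""


def write_dataset(trials: Sequence[Trial], out_dir: str | os.PathLike) -> Path:
    """Write trials and a manifest under ``out_dir``; returns the manifest path.

    Signal values are written with 17 significant digits so a
    write/load round trip is exact.
    """
    if not trials:
        raise ValueError("no trials to write")
    out = Path(out_dir)
    (out / "trials").mkdir(parents=True, exist_ok=True)
    layout = trials[0].layout
    entries = []
    for t in trials:
        if t.layout != layout:
            raise DatasetError("all trials in a dataset must share one layout")
        fname = (
            f"trials/{t.subject_id}_{t.motion_class}_{t.wrist_position}"
            f"_r{t.repetition}.txt"
        )
        np.savetxt(out / fname, t.signal.T, fmt="%.17g")
        entries.append(
            {
                "subject": t.subject_id,
                "motion_class": t.motion_class,
                "wrist_position": t.wrist_position,
                "repetition": int(t.repetition),
                "file": fname,
            }
        )
    manifest = {
        "sampling_rate": float(layout.sampling_rate),
        "channels": [
            {"id": cid, "group": grp}
            for cid, grp in zip(layout.channel_ids, layout.groups)
        ],
        "trials": entries,
    }
    path = out / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def load_dataset(manifest_path: str | os.PathLike) -> list[Trial]:
    """Load all trials listed in a dataset manifest.

    Validates labels against the closed motion-class / wrist-position sets
    and enforces a single shared channel layout.
    """
    path = Path(manifest_path)
    if path.is_dir():
        path = path / "manifest.yaml"
    if not path.exists():
        raise DatasetError(f"manifest not found: {path}")
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    try:
        fs = float(manifest["sampling_rate"])
        channels = manifest["channels"]
        trial_entries = manifest["trials"]
    except (KeyError, TypeError) as exc:
        raise DatasetError(f"manifest {path} is missing required keys") from exc
    for ch in channels:
        if ch.get("group") not in CHANNEL_GROUPS:
            raise DatasetError(
                f"channel {ch.get('id')!r} has invalid group {ch.get('group')!r}"
            )
    layout = ChannelLayout(
        channel_ids=tuple(str(ch["id"]) for ch in channels),
        groups=tuple(str(ch["group"]) for ch in channels),
        sampling_rate=fs,
    )
    base = path.parent
    trials = []
    for entry in trial_entries:
        name = (
            f"{entry.get('subject')}/{entry.get('motion_class')}/"
            f"{entry.get('wrist_position')}/rep{entry.get('repetition')}"
        )
        if entry.get("motion_class") not in MOTION_CLASSES:
            raise DatasetError(
                f"trial {name}: motion_class {entry.get('motion_class')!r} "
                f"not in {MOTION_CLASSES}"
            )
        if entry.get("wrist_position") not in WRIST_POSITIONS:
            raise DatasetError(
                f"trial {name}: wrist_position {entry.get('wrist_position')!r} "
                f"not in {WRIST_POSITIONS}"
            )
        fpath = base / entry["file"]
        if not fpath.exists():
            raise DatasetError(f"trial {name}: signal file missing: {fpath}")
        sig = np.loadtxt(fpath, ndmin=2).T
        if sig.shape[0] != layout.n_channels:
            raise DatasetError(
                f"trial {name}: {sig.shape[0]} signal columns but layout has "
                f"{layout.n_channels} channels"
            )
        trials.append(
            Trial(
                subject_id=str(entry["subject"]),
                motion_class=entry["motion_class"],
                wrist_position=entry["wrist_position"],
                repetition=int(entry["repetition"]),
                signal=sig,
                layout=layout,
            )
        )
    return trials
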