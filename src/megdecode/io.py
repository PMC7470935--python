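"""Portable serialization: NPZ array containers with JSON sidecars.

Feature arrays and evoked responses travel as NPZ bundles carrying axis
metadata; static vectors can be exported to CSV; evaluation results land in
a tidy CSV plus a JSON run manifest. An optional adapter reads standard MEG
FIF evoked files when the ``mne`` package is importable.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .neural import EvokedResponse


def save_features_npz(path, arrays: dict, metadata: dict | None = None):
    """Save named feature arrays plus a JSON-encoded metadata entry."""
    payload = {k: np.asarray(v) for k, v in arrays.items()}
    payload["__metadata__"] = np.array(
        json.dumps(metadata or {}), dtype=object)
    np.savez(path, **payload, allow_pickle=True)


def load_features_npz(path):
    with np.load(path, allow_pickle=True) as z:
        metadata = json.loads(str(z["__metadata__"][()]))
        arrays = {k: z[k] for k in z.files if k != "__metadata__"}
    return arrays, metadata


def export_static_csv(path, values: np.ndarray, item_ids, prefix="f"):
    """Write one static feature vector per row to CSV."""
    df = pd.DataFrame(np.atleast_2d(values),
                      columns=[f"{prefix}{k}" for k in
                               range(np.atleast_2d(values).shape[1])])
    df.insert(0, "item_id", list(item_ids))
    df.to_csv(path, index=False)


def save_evoked(path, responses):
    """Evoked dataset -> NPZ (item x channel x time) + JSON sidecar."""
    path = Path(path)
    values = np.stack([r.values for r in responses])
    np.savez(path, values=values, times=responses[0].times)
    sidecar = {
        "item_ids": [r.item_id for r in responses],
        "channel_ids": list(responses[0].channel_ids),
        "times_ms": [float(t) for t in responses[0].times],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_evoked(path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        values, times = z["values"], z["times"]
    return [EvokedResponse(iid, values[i], times,
                           list(sidecar["channel_ids"]))
            for i, iid in enumerate(sidecar["item_ids"])]


def read_evoked_fif(path):
    """Read evoked responses from a FIF file via mne, when installed."""
    try:
        import mne
    except ImportError as exc:     # pragma: no cover
        raise ImportError("reading FIF files requires the mne package"
                          ) from exc
    out = []
    for ev in mne.read_evokeds(path, verbose="error"):
        out.append(EvokedResponse(ev.comment or "evoked",
                                  ev.data, 1000.0 * ev.times,
                                  list(ev.ch_names)))
    return out


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def write_results(out_dir, results_df: pd.DataFrame, manifest: dict):
    """Tidy results CSV + JSON run manifest (config hash, seeds, versions)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results_df.to_csv(out_dir / "results.csv", index=False)
    manifest = dict(manifest)
    manifest.setdefault("versions", {})
    manifest["versions"].update({
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    return out_dir / "results.csv"
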