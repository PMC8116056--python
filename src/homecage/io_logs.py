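"""Event-log readers and writers.

The canonical on-disk format is JSON Lines, one object per trial or fixation
event, appended after each event so a run can resume from the last complete
record (emulating the controller's per-trial SD-card updates).  CSV mirrors
are a lossy convenience export.  A run manifest ties logs to the seed and
configuration hashes that fully determine the simulated outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .headfix_protocol import FixationEvent
from .trial_engine import TrialRecord

__all__ = [
    "SchemaError",
    "RunManifest",
    "write_jsonl",
    "read_trials",
    "read_fixations",
    "resume_index",
    "trials_to_csv",
    "config_hash",
]

SCHEMA_VERSION = 1

TRIAL_REQUIRED = {
    "trial_index", "trial_type", "pole_position", "contingency", "stage",
    "delay_duration", "lick_events", "choice", "outcome",
}
FIXATION_REQUIRED = {
    "start_time", "end_time", "scheduled_duration", "release_type",
    "thresholds_at_release",
}


class SchemaError(ValueError):
    """A record is missing required fields or is out of order."""


@dataclass
class RunManifest:
    mouse_id: str
    seed: int
    protocol_config_hash: str = ""
    agent_config_hash: str = ""
    start_iso: str = ""
    end_iso: str = ""
    log_paths: dict = field(default_factory=dict)
    software_version: str = "homecage 0.1.0"
    schema_version: int = SCHEMA_VERSION

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _validate(d: dict, required: set, lineno: int) -> None:
    missing = required - d.keys()
    if missing:
        raise SchemaError(f"line {lineno}: missing fields {sorted(missing)}")


def write_jsonl(
    records: Iterable[Union[TrialRecord, FixationEvent, dict]],
    path: Union[str, Path],
    append: bool = False,
) -> int:
    """Append-only JSON Lines writer; returns the number of records written.

    With ``append=True`` and an existing file, writing resumes after the
    last complete record: records whose index falls at or before the resume
    point are skipped, and a trailing partial line (truncated write) is
    discarded first.
    """
    path = Path(path)
    start_after = resume_index(path) if (append and path.exists()) else None
    mode = "a" if (append and path.exists()) else "w"
    n = 0
    with open(path, mode) as fh:
        for rec in records:
            d = rec.to_dict() if hasattr(rec, "to_dict") else dict(rec)
            if start_after is not None and d.get("trial_index") is not None \
                    and d["trial_index"] <= start_after:
                continue
            fh.write(json.dumps(d) + "\n")
            n += 1
    return n


def resume_index(path: Union[str, Path]) -> Optional[int]:
    """Index of the last complete trial record in a JSONL file, if any.

    Truncated trailing lines (interrupted writes) are repaired by dropping
    them; the file is rewritten only when a partial line is found.
    """
    path = Path(path)
    if not path.exists():
        return None
    text = path.read_text()
    lines = text.split("\n")
    complete, bad_tail = [], False
    for line in lines:
        if not line.strip():
            continue
        try:
            complete.append(json.loads(line))
        except json.JSONDecodeError:
            bad_tail = True
            break
    if bad_tail:
        path.write_text("".join(json.dumps(d) + "\n" for d in complete))
    if not complete:
        return None
    return complete[-1].get("trial_index")


def _read_records(path: Union[str, Path], required: set) -> list[dict]:
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError:
                if lineno == sum(1 for _ in open(path)):
                    break  # tolerate a truncated final line
                raise SchemaError(f"line {lineno}: invalid JSON")
            _validate(d, required, lineno)
            out.append(d)
    return out


def read_trials(path: Union[str, Path]) -> list[TrialRecord]:
    """Read and validate a trial log; trial indices must be non-decreasing."""
    dicts = _read_records(path, TRIAL_REQUIRED)
    last = -1
    for lineno, d in enumerate(dicts, start=1):
        if d["trial_index"] < last:
            raise SchemaError(f"line {lineno}: trial_index {d['trial_index']} "
                              f"out of order (after {last})")
        last = d["trial_index"]
    return [TrialRecord.from_dict(d) for d in dicts]


def read_fixations(path: Union[str, Path]) -> list[FixationEvent]:
    dicts = _read_records(path, FIXATION_REQUIRED)
    return [FixationEvent.from_dict(d) for d in dicts]


def trials_to_csv(trials: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    """Lossy CSV mirror of a trial log (lick events as counts, not times)."""
    rows = []
    for t in trials:
        d = t.to_dict()
        d["n_licks"] = len(d.pop("lick_events"))
        d["photostim_epoch"] = (d["photostim"] or {}).get("epoch")
        d["photostim_intensity"] = (d.pop("photostim") or {}).get("intensity_mw_mm2")
        d["autoassist_flags"] = ";".join(d["autoassist_flags"])
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)
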