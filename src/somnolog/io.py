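"""On-disk formats for annotations, surveys and configuration.

Annotations travel as JSONL (one interval per line with ISO-8601
offset-carrying timestamps) or as CSV with the same four columns
(participant_id, start, end, state); surveys as long-format CSV
(participant_id, week, event_time, instrument, item, value).  Generator
configuration round-trips through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from somnolog.synthetic_data import GeneratorConfig

__all__ = [
    "write_annotations_jsonl",
    "read_annotations_jsonl",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_surveys_csv",
    "read_surveys_csv",
    "load_config",
    "dump_config",
]


def write_annotations_jsonl(annotations: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, r in annotations.iterrows():
            fh.write(
                json.dumps(
                    {
                        "participant_id": r["participant_id"],
                        "start": r["start"].isoformat(),
                        "end": r["end"].isoformat(),
                        "state": r["state"],
                    }
                )
                + "\n"
            )


def read_annotations_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    df = pd.DataFrame(rows, columns=["participant_id", "start", "end", "state"])
    for c in ("start", "end"):
        df[c] = pd.to_datetime(df[c])
    return df


def write_annotations_csv(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    for c in ("start", "end"):
        out[c] = out[c].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_annotations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("start", "end"):
        df[c] = pd.to_datetime(df[c])
    return df


def write_surveys_csv(surveys: pd.DataFrame, path) -> None:
    out = surveys.copy()
    out["event_time"] = out["event_time"].map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_surveys_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["event_time"] = pd.to_datetime(df["event_time"])
    return df


def load_config(path) -> GeneratorConfig:
    """Read a generator configuration from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file must hold a mapping, got {type(raw).__name__}")
    if "effect_sizes" in raw:
        raw["effect_sizes"] = {
            k: (v[0], float(v[1])) for k, v in dict(raw["effect_sizes"]).items()
        }
    for key in ("phq_weeks", "psqi_weeks"):
        if key in raw:
            raw[key] = tuple(raw[key])
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "n_participants" not in raw:
        raise ValueError("missing config key: n_participants")
    return GeneratorConfig(**raw)


def dump_config(config: GeneratorConfig, path) -> None:
    data = {k: getattr(config, k) for k in GeneratorConfig.__dataclass_fields__}
    data["phq_weeks"] = list(data["phq_weeks"])
    data["psqi_weeks"] = list(data["psqi_weeks"])
    data["effect_sizes"] = {k: [v[0], float(v[1])] for k, v in dict(data["effect_sizes"]).items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
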