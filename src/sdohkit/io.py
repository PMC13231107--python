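"""JSONL readers/writers and run manifests shared by all pipeline stages.

Record schemas carry a ``schema_version`` field; readers reject unknown
major versions so prediction sidecar files stay forward-compatible.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .schema import GoldAnnotation, LabelSet, Segment

__all__ = [
    "SCHEMA_VERSION",
    "read_gold",
    "read_jsonl",
    "read_notes",
    "read_predictions",
    "read_segments",
    "write_gold",
    "write_jsonl",
    "write_manifest",
    "write_predictions",
    "write_segments",
]

SCHEMA_VERSION = "1.0"


def _check_version(rec: Mapping, path: Path) -> None:
    v = str(rec.get("schema_version", SCHEMA_VERSION))
    if v.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(f"{path}: unsupported schema_version {v!r}")


def read_jsonl(path: str | Path) -> Iterator[dict]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: bad JSON: {exc}") from exc
            _check_version(rec, path)
            yield rec


def write_jsonl(records: Iterable[Mapping], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(
                {"schema_version": SCHEMA_VERSION, **rec}, sort_keys=True
            ) + "\n")


def read_notes(path: str | Path) -> list[dict]:
    """Notes JSONL: patient_id, note_id, text."""
    return [
        {"patient_id": r["patient_id"], "note_id": r["note_id"], "text": r["text"]}
        for r in read_jsonl(path)
    ]


def read_segments(path: str | Path) -> list[Segment]:
    return [Segment.from_record(r) for r in read_jsonl(path)]


def write_segments(segments: Sequence[Segment], path: str | Path) -> None:
    write_jsonl((s.to_record() for s in segments), path)


def read_gold(path: str | Path) -> list[GoldAnnotation]:
    return [GoldAnnotation.from_record(r) for r in read_jsonl(path)]


def write_gold(gold: Sequence[GoldAnnotation], path: str | Path) -> None:
    write_jsonl((g.to_record() for g in gold), path)


def read_predictions(path: str | Path) -> list[tuple[str, LabelSet]]:
    return [
        (r["segment_id"], LabelSet.from_record(r)) for r in read_jsonl(path)
    ]


def write_predictions(
    pred: Sequence[tuple[str, LabelSet]], path: str | Path, system: str = ""
) -> None:
    write_jsonl(
        (
            {"segment_id": sid, "system": system, **ls.to_record()}
            for sid, ls in pred
        ),
        path,
    )


def write_manifest(path: str | Path, config: Mapping, seed: int | None,
                   artifacts: Mapping[str, str | Path]) -> dict:
    """Write a stage manifest: config hash, seed, versions, artifact digests.

    Deterministic stages re-run with an identical config produce an
    identical manifest, so artifacts are reconstructible from it alone.
    """
    import sdohkit

    digests = {}
    for name, p in artifacts.items():
        data = Path(p).read_bytes()
        digests[name] = hashlib.sha256(data).hexdigest()
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": dict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(dict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "sdohkit_version": sdohkit.__version__,
        "python_version": platform.python_version(),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "artifact_sha256": digests,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
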