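"""Config-file round-tripping (YAML/JSON) for subjects and regimens."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .params import SubjectParameters
from .pk import Regimen


def _load_doc(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_doc(obj: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(obj, indent=2))
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def load_subject(path) -> SubjectParameters:
    return SubjectParameters.model_validate(_load_doc(path))


def save_subject(subject: SubjectParameters, path) -> None:
    _dump_doc(subject.model_dump(mode="json"), path)


def load_regimen(path) -> Regimen:
    return Regimen.model_validate(_load_doc(path))


def save_regimen(regimen: Regimen, path) -> None:
    _dump_doc(regimen.model_dump(mode="json"), path)
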