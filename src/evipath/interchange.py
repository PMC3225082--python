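"""JSON interchange for evidence paths (the CLI's ``paths.json`` format)."""

from __future__ import annotations

import json
from typing import Iterable, List

from .kg import Binding, Term, Triple, literal
from .rules import EvidencePath

__all__ = ["paths_to_json", "paths_from_json"]


def _term_to_obj(t: Term) -> dict:
    if t.is_iri:
        return {"type": "iri", "value": t.value}
    obj = {"type": "literal", "value": t.value}
    if t.datatype:
        obj["datatype"] = t.datatype
    return obj


def _term_from_obj(obj: dict) -> Term:
    if obj["type"] == "iri":
        return Term("iri", obj["value"])
    return literal(obj["value"], obj.get("datatype"))


def _triple_to_obj(t: Triple) -> list:
    return [_term_to_obj(t.subject), _term_to_obj(t.predicate),
            _term_to_obj(t.object)]


def _triple_from_obj(obj: list) -> Triple:
    return Triple(*(_term_from_obj(x) for x in obj))


def paths_to_json(paths: Iterable[EvidencePath]) -> str:
    ordered = sorted(paths, key=lambda p: (
        p.rule_id, tuple((k, v.value) for k, v in p.binding.items())))
    doc = [{
        "rule": p.rule_id,
        "binding": {k: _term_to_obj(v) for k, v in p.binding.items()},
        "grounded_body": [_triple_to_obj(t) for t in p.grounded_body],
        "inferred": [_triple_to_obj(t) for t in p.inferred],
    } for p in ordered]
    return json.dumps(doc, indent=2) + "\n"


def paths_from_json(text: str) -> List[EvidencePath]:
    doc = json.loads(text)
    return [EvidencePath(
        rule_id=entry["rule"],
        binding=Binding({k: _term_from_obj(v)
                         for k, v in entry["binding"].items()}),
        grounded_body=tuple(_triple_from_obj(t)
                            for t in entry["grounded_body"]),
        inferred=tuple(_triple_from_obj(t) for t in entry["inferred"]),
    ) for entry in doc]
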