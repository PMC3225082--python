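"""Lightweight structural JSON validation.

Implements the subset of JSON Schema used by the shipped result schema:
``type`` (including type lists), ``properties`` / ``required`` /
``additionalProperties``, ``items``, ``enum`` and ``minimum``.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any, List


class SchemaError(ValueError):
    """Instance does not conform to the schema; message carries the path."""


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def _type_ok(value: Any, typename: str) -> bool:
    if typename == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if typename == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    return isinstance(value, _TYPES[typename])


def validate_instance(instance: Any, schema: dict, path: str = "$") -> None:
    """Raise :class:`SchemaError` at the first violation."""
    stype = schema.get("type")
    if stype is not None:
        names = stype if isinstance(stype, list) else [stype]
        if not any(_type_ok(instance, n) for n in names):
            raise SchemaError(f"{path}: expected {'/'.join(names)}, "
                              f"got {type(instance).__name__}")
    if "enum" in schema and instance not in schema["enum"]:
        raise SchemaError(f"{path}: {instance!r} not in {schema['enum']!r}")
    if "minimum" in schema and isinstance(instance, (int, float)) \
            and not isinstance(instance, bool) and instance < schema["minimum"]:
        raise SchemaError(f"{path}: {instance!r} < minimum {schema['minimum']!r}")
    if isinstance(instance, dict):
        props = schema.get("properties", {})
        for name in schema.get("required", []):
            if name not in instance:
                raise SchemaError(f"{path}: missing required field {name!r}")
        if schema.get("additionalProperties") is False:
            extra = sorted(set(instance) - set(props))
            if extra:
                raise SchemaError(f"{path}: unexpected fields {extra!r}")
        for name, sub in props.items():
            if name in instance:
                validate_instance(instance[name], sub, f"{path}.{name}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            validate_instance(item, schema["items"], f"{path}[{i}]")


def load_packaged_schema(name: str) -> dict:
    """Load a schema file shipped under ``evipath/schemas``."""
    text = resources.files("evipath").joinpath("schemas", name).read_text("utf-8")
    return json.loads(text)


def schema_errors(instance: Any, schema: dict) -> List[str]:
    try:
        validate_instance(instance, schema)
    except SchemaError as exc:
        return [str(exc)]
    return []
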