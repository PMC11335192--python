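"""Report-JSON schema and a small validator.

Every machine-readable JSON the package writes is wrapped in a common
envelope; :func:`validate_report` checks any produced document against
:data:`REPORT_SCHEMA` (a self-contained subset of JSON Schema: ``type``,
``required``, ``properties``, ``items``, ``enum``, ``const``).
"""

from __future__ import annotations

from .errors import FormatError

REPORT_KINDS = ("simulate", "pss", "dose", "compete", "efflux", "ground_truth")

REPORT_SCHEMA = {
    "type": "object",
    "required": ["format", "version", "kind", "payload"],
    "properties": {
        "format": {"const": "gatkin-report"},
        "version": {"type": "number"},
        "kind": {"type": "string", "enum": list(REPORT_KINDS)},
        "seed": {"type": ["number", "null"]},
        "config_hash": {"type": ["string", "null"]},
        "payload": {"type": "object"},
    },
}

_TYPES = {
    "object": dict, "array": list, "string": str,
    "number": (int, float), "boolean": bool, "null": type(None),
}


def _check(obj, schema, path):
    if "const" in schema and obj != schema["const"]:
        raise FormatError(f"{path}: expected constant {schema['const']!r}, got {obj!r}")
    if "type" in schema:
        types = schema["type"] if isinstance(schema["type"], list) else [schema["type"]]
        pytypes = tuple(t for name in types for t in
                        (_TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)))
        if isinstance(obj, bool) and "boolean" not in types:
            raise FormatError(f"{path}: expected {types}, got boolean")
        if not isinstance(obj, pytypes):
            raise FormatError(f"{path}: expected {types}, got {type(obj).__name__}")
    if "enum" in schema and obj not in schema["enum"]:
        raise FormatError(f"{path}: {obj!r} not one of {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise FormatError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check(obj[key], sub, f"{path}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            _check(item, schema["items"], f"{path}[{i}]")


def validate_report(obj: dict, schema: dict = REPORT_SCHEMA) -> None:
    """Raise :class:`FormatError` if ``obj`` does not satisfy ``schema``."""
    _check(obj, schema, "$")
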