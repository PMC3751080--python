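"""Model I/O: SBML (legacy COBRA notes dialect), COBRA Toolbox MAT structs,
and a plain JSON dialect used for packaged fixtures.

:func:`read_model` / :func:`write_model` dispatch on file extension
(.xml/.sbml -> SBML, .mat -> Toolbox struct, .json -> JSON).
"""

from __future__ import annotations

import os

from .jsonio import read_json, write_json
from .matio import read_cobra_struct, write_cobra_struct
from .sbml import read_sbml, write_sbml

__all__ = [
    "read_json",
    "write_json",
    "read_sbml",
    "write_sbml",
    "read_cobra_struct",
    "write_cobra_struct",
    "read_model",
    "write_model",
    "infer_format",
]

_EXTENSIONS = {
    ".xml": "sbml",
    ".sbml": "sbml",
    ".mat": "mat",
    ".json": "json",
}

_READERS = {"sbml": read_sbml, "mat": read_cobra_struct, "json": read_json}
_WRITERS = {"sbml": write_sbml, "mat": write_cobra_struct, "json": write_json}


def infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext not in _EXTENSIONS:
        raise ValueError(
            f"cannot infer model format from extension {ext!r}; "
            f"known: {sorted(_EXTENSIONS)}"
        )
    return _EXTENSIONS[ext]


def read_model(path: str, format: str | None = None):
    fmt = format or infer_format(path)
    if fmt not in _READERS:
        raise ValueError(f"unknown format {fmt!r}; known: {sorted(_READERS)}")
    return _READERS[fmt](path)


def write_model(model, path: str, format: str | None = None) -> None:
    fmt = format or infer_format(path)
    if fmt not in _WRITERS:
        raise ValueError(f"unknown format {fmt!r}; known: {sorted(_WRITERS)}")
    _WRITERS[fmt](model, path)
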