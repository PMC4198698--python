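"""Append-only audit log.

Every mutating operation on the registry and the coordinator appends one
entry, so that all users and requests can be traced after the fact.  Entries
are plain dicts; the log can be mirrored to a JSON-lines file.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Callable


def _digest(args: Any) -> str:
    blob = json.dumps(args, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class AuditLog:
    """In-memory append-only log, optionally mirrored to a JSON-lines file.

    ``clock`` is injectable so that fixture generation stays deterministic.
    """

    def __init__(self, path: str | Path | None = None,
                 clock: Callable[[], float] = time.time) -> None:
        self.entries: list[dict] = []
        self.path = Path(path) if path is not None else None
        self._clock = clock

    def append(self, user: str, op: str, args: Any = None) -> dict:
        entry = {
            "timestamp": self._clock(),
            "user": user,
            "op": op,
            "args_digest": _digest(args),
        }
        self.entries.append(entry)
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(json.dumps(entry) + "\n")
        return entry

    def __len__(self) -> int:
        return len(self.entries)
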