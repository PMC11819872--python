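"""Deterministic seed fan-out.

A single user-facing seed is expanded into independent per-stage child seeds
by hashing the stage name path with SHA-256.  Adding a new stage therefore
never perturbs the random streams of existing stages, and every child seed
fits in a signed 32-bit integer.
"""

from __future__ import annotations

import hashlib

__all__ = ["child_seed"]


def child_seed(seed: int, *path: str | int) -> int:
    """Derive a child seed from ``seed`` and a stage-name path.

    Parameters
    ----------
    seed:
        The parent (typically global) seed.
    path:
        One or more stage names or indices, e.g. ``("cohort", 12)``.

    Returns
    -------
    int
        A deterministic seed in ``[0, 2**31)``.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for part in path:
        h.update(b"/")
        h.update(str(part).encode())
    return int.from_bytes(h.digest()[:8], "big") % (2**31)
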