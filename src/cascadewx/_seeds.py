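"""Deterministic seed derivation.

Every stochastic stage (fold splitting, network initialisation,
simulation) draws its seed from a single master seed plus a stage name,
so a whole pipeline run is reproducible from one integer.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *names: object) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and stage names."""
    msg = ":".join([str(int(master)), *[str(n) for n in names]]).encode()
    return int.from_bytes(hashlib.sha256(msg).digest()[:4], "little") % (2**31)
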