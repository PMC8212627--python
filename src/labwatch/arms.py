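"""Trial-arm assignment by patient-id parity.

Odd trailing integers map to the control arm, even ones to the
intervention arm.  Non-numeric ids are hashed to a stable integer first
(SHA-256 of the UTF-8 id) so the split stays deterministic across runs.
"""

from __future__ import annotations

import hashlib
import re
from enum import Enum

__all__ = ["Arm", "assign_arm"]


class Arm(Enum):
    CONTROL = "CONTROL"
    INTERVENTION = "INTERVENTION"


_TRAILING_INT = re.compile(r"(\d+)\s*$")


def _stable_int(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode("utf-8")).digest()[:8], "big")


def assign_arm(patient_id: str) -> Arm:
    """Deterministically assign a patient to CONTROL (odd) or INTERVENTION (even)."""
    if not patient_id or not patient_id.strip():
        raise ValueError("patient_id must be non-empty")
    match = _TRAILING_INT.search(patient_id)
    n = int(match.group(1)) if match else _stable_int(patient_id)
    return Arm.CONTROL if n % 2 else Arm.INTERVENTION
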