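"""Preoperative postural guidance from the anatomical localization.

Posture follows the primary zone: supine for superior detachment, sitting
for inferior, lateral decubitus on the matching side for the right/left
zones.  Posterior-pole involvement overrides the zone rule: supine plus an
urgent referral.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

__all__ = ["PostureAdvice", "posture_for", "guidance_record", "record_to_json",
           "record_from_json"]

_ZONE_POSTURE = {
    "superior": "supine",
    "inferior": "sitting",
    "right": "right_lateral",
    "left": "left_lateral",
}


@dataclass(frozen=True)
class PostureAdvice:
    posture: str
    urgent_referral: bool
    primary_zone: str
    posterior_involved: bool
    laterality: str


def posture_for(primary: Optional[str], posterior: bool, laterality: str) -> PostureAdvice:
    """Total, deterministic posture map over (zone, posterior, laterality)."""
    if primary not in _ZONE_POSTURE:
        raise ValueError(f"undefined primary zone: {primary!r}")
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be OD or OS")
    if posterior:
        posture = "supine"
    else:
        posture = _ZONE_POSTURE[primary]
    return PostureAdvice(
        posture=posture,
        urgent_referral=bool(posterior),
        primary_zone=primary,
        posterior_involved=bool(posterior),
        laterality=laterality,
    )


def guidance_record(
    image_id: str,
    probability: float,
    is_rd: bool,
    partitions,
    primary_zone: Optional[str],
    posterior: bool,
    laterality: str,
    landmark_source: str = "sidecar",
    model_version: str = "rdmap-0.1.0",
    threshold: float = 0.5,
) -> dict:
    """One structured per-image report record (JSON-serializable)."""
    if is_rd and primary_zone is None:
        raise ValueError("detachment-positive record requires a primary zone")
    rec = {
        "image_id": image_id,
        "probability": float(probability),
        "is_rd": bool(is_rd),
        "partitions": "".join(str(int(b)) for b in partitions),
        "primary_zone": primary_zone,
        "posterior_involved": bool(posterior),
        "laterality": laterality,
        "provenance": {
            "model_version": model_version,
            "threshold": float(threshold),
            "landmark_source": landmark_source,
        },
    }
    if is_rd and primary_zone is not None:
        advice = posture_for(primary_zone, posterior, laterality)
        rec["posture"] = advice.posture
        rec["urgent_referral"] = advice.urgent_referral
    else:
        rec["posture"] = None
        rec["urgent_referral"] = False
        rec["note"] = "no lesion, no postural advice"
    return rec


def record_to_json(record: dict) -> str:
    return json.dumps(record, sort_keys=True)


def record_from_json(line: str) -> dict:
    return json.loads(line)
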