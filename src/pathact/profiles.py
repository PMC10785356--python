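"""Pathway activity profiles: the universal method output.

A profile is a pathways x samples matrix plus per-pathway provenance (the
member genes actually used, how many survived the DEG filter, and the method
tag).  Profiles are written as headered TSV with a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PathwayActivityProfile", "write_profile", "read_profile"]


@dataclass
class PathwayActivityProfile:
    """Pathways x samples activity matrix with per-pathway provenance."""

    activity: pd.DataFrame
    method: str
    provenance: dict[str, dict] = field(default_factory=dict)
    dropped: dict[str, str] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in self.activity.index if p not in self.provenance]
        if missing:
            raise ValueError(f"pathways without provenance: {missing[:3]}...")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.activity.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity.columns)


def write_profile(profile: PathwayActivityProfile, tsv_stream, sidecar_stream=None) -> None:
    out = profile.activity.copy()
    out.index.name = "pathway"
    out.to_csv(tsv_stream, sep="\t")
    if sidecar_stream is not None:
        json.dump(
            {
                "method": profile.method,
                "parameters": profile.parameters,
                "provenance": profile.provenance,
                "dropped": profile.dropped,
            },
            sidecar_stream,
            indent=1,
            sort_keys=True,
        )


def read_profile(tsv_stream, sidecar_stream=None) -> PathwayActivityProfile:
    df = pd.read_csv(tsv_stream, sep="\t", index_col=0)
    meta = {"method": "unknown", "parameters": {}, "provenance": {}, "dropped": {}}
    if sidecar_stream is not None:
        meta.update(json.load(sidecar_stream))
    provenance = meta["provenance"] or {p: {} for p in df.index}
    return PathwayActivityProfile(
        df, meta["method"], provenance, meta["dropped"], meta["parameters"]
    )
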