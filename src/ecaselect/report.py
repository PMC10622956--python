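"""Textual 10-20 position report for a selected channel subset.

Maps each electrode name to its scalp region by the 10-20 naming convention:
a leading ``F`` (F, Fp, AF, FC, FT) marks frontal sites, a leading ``C``
(C, CP) central sites, and a leading ``P`` or ``PO`` parietal sites; ``T``
and ``O`` sites are temporal and occipital.  Names that do not parse are
listed under ``unmapped``.
"""

from __future__ import annotations

import json
import re

__all__ = ["scalp_region", "describe_subset"]

_REGIONS = {
    "FP": "frontal",
    "AF": "frontal",
    "F": "frontal",
    "FC": "frontal",
    "FT": "frontal",
    "C": "central",
    "CP": "central",
    "T": "temporal",
    "TP": "temporal",
    "P": "parietal",
    "PO": "parietal",
    "O": "occipital",
}


def scalp_region(name: str) -> str | None:
    """Scalp-region tag for a 10-20 electrode name, or None if unknown."""
    m = re.match(r"^([A-Za-z]+?)(z|\d+)?$", name.strip())
    if not m:
        return None
    return _REGIONS.get(m.group(1).upper())


def describe_subset(channels: list[str]) -> dict:
    """Per-channel 10-20 label and region tag, plus region counts.

    Returns a dict with ``channels`` (list of {name, region}), ``regions``
    (tag -> count) and ``unmapped`` (names with no 10-20 parse).
    """
    rows, unmapped, counts = [], [], {}
    for name in channels:
        region = scalp_region(name)
        if region is None:
            unmapped.append(name)
            continue
        rows.append({"name": name, "region": region})
        counts[region] = counts.get(region, 0) + 1
    return {"channels": rows, "regions": counts, "unmapped": unmapped}


def format_report(channels: list[str]) -> str:
    rep = describe_subset(channels)
    lines = ["channel  region", "-------  ------"]
    for row in rep["channels"]:
        lines.append(f"{row['name']:<7}  {row['region']}")
    if rep["regions"]:
        lines.append("")
        lines.append(
            "regions: " + ", ".join(f"{k}={v}" for k, v in sorted(rep["regions"].items()))
        )
    if rep["unmapped"]:
        lines.append("unmapped: " + ", ".join(rep["unmapped"]))
    return "\n".join(lines)


def report_json(channels: list[str]) -> str:
    return json.dumps(describe_subset(channels), indent=1)
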