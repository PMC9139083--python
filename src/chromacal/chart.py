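"""Reference-chart model, sample screening, and nearest-color matching.

The workflow screens chart samples before fitting: samples whose device
channels railed at 0 or 255 carry irrecoverable clipping (under/over-
exposure) and are discarded, and pairs whose color difference from the
reference exceeds the just-noticeable-difference threshold are treated as
inaccurate.  Matching assigns an arbitrary color to its nearest chart
entry, by CIEDE2000 in Lab (or Euclidean RGB as a config alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import colorspace as cs
from .colorspace import DeltaEParams
from .correction import ColorPairSet, JND_DELTA_E

__all__ = [
    "ChartEntry",
    "ReferenceChart",
    "ScreeningResult",
    "screen_saturation",
    "screen_accuracy",
    "nearest_entry",
]


@dataclass(frozen=True)
class ChartEntry:
    entry_id: str
    rgb: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.entry_id:
            raise ValueError("entry_id must be nonempty")
        if len(self.rgb) != 3 or any(not (0 <= int(v) <= 255) for v in self.rgb):
            raise ValueError(f"invalid RGB8 triple for {self.entry_id!r}: {self.rgb}")


@dataclass
class ReferenceChart:
    """Ordered collection of named reference colors (RAL-style id -> RGB)."""

    entries: list[ChartEntry]
    name: str = "chart"

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a chart needs at least one entry")
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate chart ids: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.entry_id for e in self.entries]

    @property
    def rgb_array(self) -> np.ndarray:
        return np.array([e.rgb for e in self.entries], dtype=float)

    def subset(self, keep_ids) -> "ReferenceChart":
        keep = set(keep_ids)
        return ReferenceChart(
            [e for e in self.entries if e.entry_id in keep], name=self.name
        )


@dataclass
class ScreeningResult:
    """Partition of screened samples: kept / saturated / inaccurate."""

    kept: list[str]
    rejected_saturated: list[tuple[str, list[str]]] = field(default_factory=list)
    rejected_inaccurate: list[tuple[str, float]] = field(default_factory=list)

    @property
    def rejected_ids(self) -> list[str]:
        return [i for i, _ in self.rejected_saturated] + [
            i for i, _ in self.rejected_inaccurate
        ]

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "rejected_saturated": [
                {"id": i, "channels": ch} for i, ch in self.rejected_saturated
            ],
            "rejected_inaccurate": [
                {"id": i, "delta_e": v} for i, v in self.rejected_inaccurate
            ],
        }


def _saturated_channels(rgb: np.ndarray) -> list[str]:
    return [name for name, v in zip("RGB", rgb) if v == 0 or v == 255]


def screen_saturation(data: ReferenceChart | ColorPairSet) -> ScreeningResult:
    """Reject every sample with any channel exactly 0 or exactly 255.

    For a :class:`ColorPairSet` the rule is applied to the device-measured
    colors (the side where clipping happens); for a chart, to the entries.
    """
    if isinstance(data, ReferenceChart):
        ids, colors = data.ids, data.rgb_array
    else:
        ids, colors = data.ids, data.measured
    kept, rejected = [], []
    for sid, rgb in zip(ids, colors):
        bad = _saturated_channels(rgb)
        if bad:
            rejected.append((sid, bad))
        else:
            kept.append(sid)
    return ScreeningResult(kept=kept, rejected_saturated=rejected)


def screen_accuracy(
    pairs: ColorPairSet,
    threshold: float = JND_DELTA_E,
    params: DeltaEParams = DeltaEParams(),
) -> ScreeningResult:
    """Reject pairs whose CIEDE2000 difference is >= ``threshold``.

    The boundary is inclusive: a pair sitting exactly at the threshold is
    considered inaccurate and discarded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    lab_m = cs.srgb_to_lab(pairs.measured)
    lab_r = cs.srgb_to_lab(pairs.reference)
    de = np.atleast_1d(cs.delta_e_2000(lab_m, lab_r, params))
    kept, rejected = [], []
    for sid, d in zip(pairs.ids, de):
        if d >= threshold:
            rejected.append((sid, float(d)))
        else:
            kept.append(sid)
    return ScreeningResult(kept=kept, rejected_inaccurate=rejected)


def nearest_entry(
    chart: ReferenceChart,
    rgb,
    params: DeltaEParams = DeltaEParams(),
    metric: str = "de2000",
) -> tuple[ChartEntry, float]:
    """Match a color to the chart entry minimizing the color difference.

    ``metric`` is "de2000" (CIEDE2000 in Lab under ``params``; the default,
    consistent with the evaluation metric) or "rgb" (Euclidean distance in
    encoded RGB).  Ties are broken by chart order (first entry wins).
    """
    rgb = np.asarray(rgb, dtype=float)
    if metric == "de2000":
        lab_c = cs.srgb_to_lab(rgb)
        lab_entries = cs.srgb_to_lab(chart.rgb_array)
        dist = np.atleast_1d(cs.delta_e_2000(lab_entries, lab_c, params))
    elif metric == "rgb":
        dist = np.linalg.norm(chart.rgb_array - rgb, axis=1)
    else:
        raise ValueError(f"metric must be 'de2000' or 'rgb', got {metric!r}")
    idx = int(np.argmin(dist))  # argmin returns the first minimum: chart order
    return chart.entries[idx], float(dist[idx])
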