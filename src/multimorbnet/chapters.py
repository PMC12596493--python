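"""ICD-10 chapter attribution of pattern frequencies and rank trajectories.

Each accepted pattern's co-occurrence frequency is attributed to the
chapter of each of its two endpoint diseases — once per distinct chapter,
so a within-chapter pattern counts once (dual attribution).  Percentages
are taken against the network's total pattern frequency, which means the
per-chapter percentages can sum past 100 across chapters; they are
reported as-is.  A half-credit mode splits cross-chapter patterns 50/50
instead.

Chapters are ranked by descending percentage (rank 1 = highest), ties
broken by ascending chapter number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .icd10 import chapter_of
from .netbuild import MultimorbidityNetwork
from .profiles import pct

__all__ = ["ChapterFrequency", "chapter_frequencies", "rank_trajectories"]


@dataclass(frozen=True, slots=True)
class ChapterFrequency:
    chapter: int
    freq: float
    pct: float
    rank: int


def chapter_frequencies(
    net: MultimorbidityNetwork,
    attribution: Literal["dual", "half"] = "dual",
) -> list[ChapterFrequency]:
    """Pattern frequency aggregated to chapters, ranked by share.

    Only chapters actually touched by an accepted pattern appear; the list
    is ordered by rank.
    """
    totals: dict[int, float] = {}
    for e in net.edges:
        cx, cy = chapter_of(e.x), chapter_of(e.y)
        if cx == cy:
            totals[cx] = totals.get(cx, 0.0) + e.frequency
        elif attribution == "dual":
            totals[cx] = totals.get(cx, 0.0) + e.frequency
            totals[cy] = totals.get(cy, 0.0) + e.frequency
        elif attribution == "half":
            totals[cx] = totals.get(cx, 0.0) + e.frequency / 2
            totals[cy] = totals.get(cy, 0.0) + e.frequency / 2
        else:
            raise ValueError(f"unknown attribution mode {attribution!r}")
    denom = net.total_pattern_frequency
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        ChapterFrequency(chapter=ch, freq=f, pct=pct(f, denom), rank=r)
        for r, (ch, f) in enumerate(ordered, start=1)
    ]


def rank_trajectories(
    nets_by_band: Mapping[str, MultimorbidityNetwork],
    attribution: Literal["dual", "half"] = "dual",
) -> list[dict]:
    """Long-format chapter-rank table across age bands (for line charts).

    One row per (band, chapter) over the union of chapters observed in any
    band; a chapter absent from a band gets rank/pct/freq recorded as NaN
    rather than being pushed to the bottom rank.
    """
    per_band = {
        band: {cf.chapter: cf for cf in chapter_frequencies(net, attribution)}
        for band, net in nets_by_band.items()
    }
    all_chapters = sorted({ch for cfs in per_band.values() for ch in cfs})
    rows: list[dict] = []
    for band in nets_by_band:
        for ch in all_chapters:
            cf = per_band[band].get(ch)
            rows.append(
                {
                    "band": band,
                    "chapter": ch,
                    "freq": cf.freq if cf else math.nan,
                    "pct": cf.pct if cf else math.nan,
                    "rank": cf.rank if cf else math.nan,
                }
            )
    return rows
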