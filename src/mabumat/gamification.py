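"""Reward mechanics: levels, groups and the leaderboard.

The practitioner starts at Level 0 and gains one level for every full 10 s
the stance was held correctly.  Levels are grouped as beginner (0-6),
intermediate (7-12), veteran (13-18) and expert (19 and up).  The
leaderboard ranks completed sessions by total held duration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

LEVEL_SECONDS = 10.0
GROUPS = ("beginner", "intermediate", "veteran", "expert")


def level_for_duration(duration_s: float) -> int:
    """Level reached after holding the stance for ``duration_s`` seconds.

    One level per full 10 s, starting at Level 0; exactly 10.0 s already
    awards Level 1 (floor convention).
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    return int(math.floor(duration_s / LEVEL_SECONDS))


def group_for_level(level: int) -> str:
    """Group association for a level: 0-6 beginner, 7-12 intermediate,
    13-18 veteran, >= 19 expert."""
    if level < 0:
        raise ValueError("level must be >= 0")
    if level <= 6:
        return "beginner"
    if level <= 12:
        return "intermediate"
    if level <= 18:
        return "veteran"
    return "expert"


@dataclass(frozen=True)
class LeaderboardEntry:
    participant_id: str
    total_duration_s: float
    final_level: int
    group: str
    rank: int
    recorded_at_ms: int

    def to_dict(self) -> dict:
        return {"participant_id": self.participant_id,
                "total_duration_s": self.total_duration_s,
                "final_level": self.final_level, "group": self.group,
                "rank": self.rank, "recorded_at_ms": self.recorded_at_ms}


def update_leaderboard(board: list[LeaderboardEntry], record) -> list[LeaderboardEntry]:
    """Insert a completed session and re-rank.

    ``record`` needs ``participant_id``, ``good_duration_s``, ``state`` and
    ``recorded_at_ms`` attributes (a :class:`~mabumat.monitor.SessionRecord`
    fits).  Entries sort by duration descending, ties broken by earlier
    recording; a returning participant keeps only their best run.
    """
    if getattr(record, "state", "BROKEN") != "BROKEN":
        raise ValueError("only completed (BROKEN) sessions enter the leaderboard")
    duration = record.good_duration_s
    level = level_for_duration(duration)
    candidate = LeaderboardEntry(
        participant_id=record.participant_id,
        total_duration_s=duration,
        final_level=level,
        group=group_for_level(level),
        rank=0,
        recorded_at_ms=getattr(record, "recorded_at_ms", 0),
    )
    entries = [e for e in board if e.participant_id != candidate.participant_id]
    previous = [e for e in board if e.participant_id == candidate.participant_id]
    if previous:
        best = max(previous, key=lambda e: (e.total_duration_s, -e.recorded_at_ms))
        if (best.total_duration_s, -best.recorded_at_ms) >= (
                candidate.total_duration_s, -candidate.recorded_at_ms):
            candidate = best
    entries.append(candidate)
    entries.sort(key=lambda e: (-e.total_duration_s, e.recorded_at_ms, e.participant_id))
    return [LeaderboardEntry(e.participant_id, e.total_duration_s, e.final_level,
                             e.group, i + 1, e.recorded_at_ms)
            for i, e in enumerate(entries)]


def save_leaderboard(board: list[LeaderboardEntry], path: str | Path) -> None:
    Path(path).write_text(json.dumps([e.to_dict() for e in board], indent=2) + "\n")


def load_leaderboard(path: str | Path) -> list[LeaderboardEntry]:
    path = Path(path)
    if not path.exists():
        return []
    return [LeaderboardEntry(**d) for d in json.loads(path.read_text())]
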