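"""Event-sourced counting sessions.

A :class:`CountSession` records one sample's count as an ordered action log
(count events, track increments, a single rare-mode switch, on-the-fly taxon
additions).  All derived state — per-phase tallies, track counters, the
current mode — is a pure function of the initial taxa list plus that log, so
a session can be replayed, checkpointed to disk and resumed exactly.

Two counting phases exist.  In the *full* phase every specimen encountered
is recorded.  After the observer switches to the *rare* phase a frozen set
of excluded (common) taxa is no longer counted — attempting to do so is a
hard :class:`~raricount.errors.RareModeViolation` — while observational
effort keeps accruing on a separate rare-phase track counter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .config_io import TaxonConfig
from .errors import (
    CheckpointError,
    DuplicateTaxonError,
    RareModeViolation,
    StateError,
    UndoError,
    UnknownTaxonError,
)

__all__ = ["CountEvent", "CountSession", "TallyTable", "CHECKPOINT_FORMAT", "CHECKPOINT_VERSION"]

FULL = "full"
RARE = "rare"

CHECKPOINT_FORMAT = "raricount-checkpoint"
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class CountEvent:
    """One recorded specimen: sequence number, taxon, and counting phase."""

    seq: int
    taxon_id: str
    phase: str


class TallyTable:
    """Per-taxon raw counts split by phase."""

    def __init__(self, n_full: dict[str, int], n_rare: dict[str, int]):
        self.n_full = dict(n_full)
        self.n_rare = dict(n_rare)

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "TallyTable":
        """A tally with all counts attributed to the full phase."""
        return cls(dict(counts), {k: 0 for k in counts})

    @property
    def N_full(self) -> int:
        return sum(self.n_full.values())

    @property
    def N_rare(self) -> int:
        return sum(self.n_rare.values())

    def total(self, taxon_id: str) -> int:
        return self.n_full.get(taxon_id, 0) + self.n_rare.get(taxon_id, 0)

    def taxon_ids(self) -> list[str]:
        return list(self.n_full)

    def __eq__(self, other):
        if not isinstance(other, TallyTable):
            return NotImplemented
        return self.n_full == other.n_full and self.n_rare == other.n_rare


class CountSession:
    """Event-sourced state of one sample's count."""

    def __init__(
        self,
        taxa: Sequence[TaxonConfig] = (),
        sample_metadata: dict | None = None,
    ):
        self.sample_metadata: dict[str, str] = dict(sample_metadata or {})
        self._initial_taxa: list[TaxonConfig] = list(taxa)
        self.taxa: list[TaxonConfig] = list(taxa)
        self._taxon_ids: set[str] = {t.taxon_id for t in self.taxa}
        if len(self._taxon_ids) != len(self.taxa):
            raise DuplicateTaxonError("initial taxa list contains duplicate ids")
        self.actions: list[tuple] = []
        self.events: list[CountEvent] = []
        self.tracks_full: int = 0
        self.tracks_rare: int = 0
        self.mode: str = FULL
        self.exclusions: frozenset[str] = frozenset()

    # -- actions ---------------------------------------------------------

    def record_count(self, taxon_id: str) -> "CountSession":
        if taxon_id not in self._taxon_ids:
            raise UnknownTaxonError(f"unknown taxon: {taxon_id!r}")
        if self.mode == RARE and taxon_id in self.exclusions:
            raise RareModeViolation(
                f"{taxon_id!r} is excluded in rare count mode"
            )
        self.events.append(CountEvent(len(self.events) + 1, taxon_id, self.mode))
        self.actions.append(("count", taxon_id))
        return self

    def increment_track(self) -> "CountSession":
        if self.mode == FULL:
            self.tracks_full += 1
        else:
            self.tracks_rare += 1
        self.actions.append(("track", self.mode))
        return self

    def enter_rare_mode(self, exclusions: Iterable[str]) -> "CountSession":
        if self.mode == RARE:
            raise StateError("rare mode may be entered only once per session")
        exclusions = frozenset(exclusions)
        unknown = exclusions - self._taxon_ids
        if unknown:
            raise UnknownTaxonError(f"unknown taxa in exclusions: {sorted(unknown)}")
        tally = self.tally()
        never_seen = sorted(t for t in exclusions if tally.n_full.get(t, 0) == 0)
        if never_seen:
            raise StateError(
                f"cannot exclude taxa never seen in full mode: {never_seen}"
            )
        self.mode = RARE
        self.exclusions = exclusions
        self.actions.append(("rare", sorted(exclusions)))
        return self

    def add_taxon(self, taxon: TaxonConfig) -> "CountSession":
        if taxon.taxon_id in self._taxon_ids:
            raise DuplicateTaxonError(f"taxon already present: {taxon.taxon_id!r}")
        self.taxa.append(taxon)
        self._taxon_ids.add(taxon.taxon_id)
        self.actions.append(("add", taxon.to_dict()))
        return self

    def undo_last(self) -> "CountSession":
        """Exact inverse of the most recent count or track action.

        Rare-mode entry and taxon additions are barriers: undo stops there
        rather than silently un-entering a mode or removing a taxon.
        """
        if not self.actions:
            raise UndoError("nothing to undo")
        kind = self.actions[-1][0]
        if kind == "count":
            self.actions.pop()
            self.events.pop()
        elif kind == "track":
            _, phase = self.actions.pop()
            if phase == FULL:
                self.tracks_full -= 1
            else:
                self.tracks_rare -= 1
        else:
            raise UndoError(f"cannot undo a {kind!r} action")
        return self

    # -- derived state ---------------------------------------------------

    def tally(self) -> TallyTable:
        n_full = {t.taxon_id: 0 for t in self.taxa}
        n_rare = {t.taxon_id: 0 for t in self.taxa}
        for ev in self.events:
            if ev.phase == FULL:
                n_full[ev.taxon_id] += 1
            else:
                n_rare[ev.taxon_id] += 1
        return TallyTable(n_full, n_rare)

    @property
    def taxon_ids(self) -> frozenset[str]:
        return frozenset(self._taxon_ids)

    def __eq__(self, other):
        if not isinstance(other, CountSession):
            return NotImplemented
        return (
            self.sample_metadata == other.sample_metadata
            and self._initial_taxa == other._initial_taxa
            and self.actions == other.actions
        )

    # -- replay / persistence -------------------------------------------

    @classmethod
    def replay(
        cls,
        taxa: Sequence[TaxonConfig],
        actions: Iterable[tuple],
        sample_metadata: dict | None = None,
    ) -> "CountSession":
        """Rebuild a session from its initial taxa and action log."""
        session = cls(taxa, sample_metadata)
        for action in actions:
            kind = action[0]
            if kind == "count":
                session.record_count(action[1])
            elif kind == "track":
                session.increment_track()
            elif kind == "rare":
                session.enter_rare_mode(action[1])
            elif kind == "add":
                session.add_taxon(TaxonConfig.from_dict(action[1]))
            else:
                raise CheckpointError(f"unknown action kind {kind!r}")
        return session

    def checkpoint(self, path) -> None:
        """Save the session as versioned structured text (internal format).

        This is deliberately *not* the SOD output format: it is a temporary
        file meant only for suspend/resume of a partial count.
        """
        payload = {
            "format": CHECKPOINT_FORMAT,
            "version": CHECKPOINT_VERSION,
            "sample_metadata": self.sample_metadata,
            "taxa": [t.to_dict() for t in self._initial_taxa],
            "actions": [list(a) for a in self.actions],
        }
        Path(path).write_text(
            json.dumps(payload, indent=1, sort_keys=False) + "\n", encoding="utf-8"
        )

    @classmethod
    def resume(cls, path) -> "CountSession":
        path = Path(path)
        if not path.exists():
            raise CheckpointError(f"no such checkpoint: {path}")
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise CheckpointError(f"corrupt checkpoint {path}: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("format") != CHECKPOINT_FORMAT:
            raise CheckpointError(f"{path} is not a raricount checkpoint")
        if payload.get("version") != CHECKPOINT_VERSION:
            raise CheckpointError(
                f"checkpoint version {payload.get('version')!r} not supported"
            )
        taxa = [TaxonConfig.from_dict(d) for d in payload["taxa"]]
        actions = []
        for raw in payload["actions"]:
            kind = raw[0]
            if kind == "track":
                actions.append((kind, raw[1]))
            elif kind in ("count",):
                actions.append((kind, raw[1]))
            elif kind == "rare":
                actions.append((kind, list(raw[1])))
            elif kind == "add":
                actions.append((kind, raw[1]))
            else:
                raise CheckpointError(f"unknown action kind {kind!r}")
        return cls.replay(taxa, actions, payload.get("sample_metadata"))
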