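"""Cohort design (kindred pairings) and the per-variant filter ledger."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .calls import VariantKey
from .errors import ConfigurationError

RELATIONSHIPS = ("brothers", "half-brothers", "cousins", "uncle-nephew")

RETAIN = "retain"
REJECT = "reject"
RESCUE = "rescue"


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str = "male"
    batch: str = ""


@dataclass
class CohortDesign:
    """Sample roster with declared kindred pairings and library batches.

    Every sample appears either in exactly one pair or in the sporadic list.
    """

    samples: list[SampleInfo]
    pairs: list[tuple[str, str, str]]
    sporadic: list[str]
    _kin: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample ids in design")
        id_set = set(ids)
        seen: set[str] = set()
        kin: dict[str, str] = {}
        for a, b, rel in self.pairs:
            if a == b:
                raise ConfigurationError(f"pair members must be distinct: {a}")
            if rel not in RELATIONSHIPS:
                raise ConfigurationError(f"unknown relationship {rel!r}")
            for s in (a, b):
                if s not in id_set:
                    raise ConfigurationError(f"pair sample {s} not in roster")
                if s in seen:
                    raise ConfigurationError(f"sample {s} declared more than once")
                seen.add(s)
            kin[a] = b
            kin[b] = a
        for s in self.sporadic:
            if s not in id_set:
                raise ConfigurationError(f"sporadic sample {s} not in roster")
            if s in seen:
                raise ConfigurationError(f"sample {s} declared more than once")
            seen.add(s)
        if seen != id_set:
            missing = sorted(id_set - seen)
            raise ConfigurationError(f"samples missing from pairs/sporadic: {missing}")
        self._kin = kin

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def batch_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.batch
        raise KeyError(sample_id)

    def kin_of(self, sample_id: str) -> str | None:
        """Declared kindred partner, or None for a sporadic sample."""
        return self._kin.get(sample_id)

    def are_kin(self, a: str, b: str) -> bool:
        return self._kin.get(a) == b

    def relationship_of(self, sample_id: str) -> str | None:
        for a, b, rel in self.pairs:
            if sample_id in (a, b):
                return rel
        return None

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for s in self.samples:
            kin = self._kin.get(s.sample_id, "-")
            rel = self.relationship_of(s.sample_id) or "-"
            rows.append((s.sample_id, kin, rel, s.batch))
        pd.DataFrame(rows, columns=["sample_id", "kin_id", "relationship", "batch"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortDesign":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
        samples = [SampleInfo(r.sample_id, batch=r.batch) for r in df.itertuples()]
        pairs: list[tuple[str, str, str]] = []
        sporadic: list[str] = []
        done: set[str] = set()
        for r in df.itertuples():
            if r.kin_id == "-":
                sporadic.append(r.sample_id)
            elif r.sample_id not in done:
                pairs.append((r.sample_id, r.kin_id, r.relationship))
                done.update((r.sample_id, r.kin_id))
        return cls(samples=samples, pairs=pairs, sporadic=sporadic)


@dataclass(frozen=True, slots=True)
class LedgerEntry:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    stage: str
    decision: str
    reason: str

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


class FilterLedger:
    """Per-variant, per-sample provenance of every retain/reject/rescue decision."""

    def __init__(self, entries: Iterable[LedgerEntry] = ()) -> None:
        self.entries: list[LedgerEntry] = list(entries)

    def add(
        self,
        sample_id: str,
        key: VariantKey,
        stage: str,
        decision: str,
        reason: str = "-",
    ) -> None:
        if decision not in (RETAIN, REJECT, RESCUE):
            raise ValueError(f"unknown decision {decision!r}")
        self.entries.append(LedgerEntry(sample_id, key[0], key[1], key[2], key[3], stage, decision, reason))

    def extend(self, entries: Iterable[LedgerEntry]) -> None:
        self.entries.extend(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LedgerEntry]:
        return iter(self.entries)

    def select(
        self,
        stage: str | None = None,
        decision: str | None = None,
        reason: str | None = None,
        sample_id: str | None = None,
    ) -> list[LedgerEntry]:
        out = []
        for e in self.entries:
            if stage is not None and e.stage != stage:
                continue
            if decision is not None and e.decision != decision:
                continue
            if reason is not None and e.reason != reason:
                continue
            if sample_id is not None and e.sample_id != sample_id:
                continue
            out.append(e)
        return out

    def rescued_keys(self) -> set[VariantKey]:
        return {e.key for e in self.entries if e.decision == RESCUE}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.sample_id, e.chrom, e.pos, e.ref, e.alt, e.stage, e.decision, e.reason)
                for e in self.entries
            ],
            columns=["sample_id", "chrom", "pos", "ref", "alt", "stage", "decision", "reason"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FilterLedger":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int})
        return cls(
            LedgerEntry(r.sample_id, r.chrom, int(r.pos), r.ref, r.alt, r.stage, r.decision, str(r.reason))
            for r in df.itertuples()
        )
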