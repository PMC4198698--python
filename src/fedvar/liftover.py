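"""Coordinate conversion between genome builds via UCSC chain files.

Chain files are 0-based half-open; every public function here speaks
1-based inclusive and converts at the boundary.  Records from samples
aligned to different builds are harmonized onto one target build before
aggregation; positions that fall into chain gaps are routed to a drop
report, never silently lost.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigurationError, ValidationError
from .genotyper import SiteRecord


@dataclass(frozen=True)
class ChainBlock:
    """One gapless aligned segment of a chain (0-based half-open)."""

    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int  # in strand coordinates, as in the chain file
    strand: str        # target strand, '+' or '-'
    target_size: int

    def map_offset(self, source_pos0: int) -> tuple[str, int]:
        """Map a 0-based source position inside this block."""
        offset = source_pos0 - self.source_start
        strand_pos = self.target_start + offset
        if self.strand == "+":
            return self.target_chrom, strand_pos
        return self.target_chrom, self.target_size - strand_pos - 1


@dataclass(frozen=True)
class Unmapped:
    reason: str  # "gap" | "chrom_absent"

    def __bool__(self) -> bool:
        return False


UNMAPPED_GAP = Unmapped("gap")
UNMAPPED_CHROM = Unmapped("chrom_absent")


class LiftoverMap:
    """Binary-searchable block index for one (from_build, to_build) pair."""

    def __init__(self, from_build: str = "", to_build: str = "") -> None:
        self.from_build = from_build
        self.to_build = to_build
        self._blocks: dict[str, list[ChainBlock]] = {}
        self._starts: dict[str, list[int]] = {}

    def add_block(self, block: ChainBlock) -> None:
        self._blocks.setdefault(block.source_chrom, []).append(block)

    def freeze(self) -> "LiftoverMap":
        for chrom, blocks in self._blocks.items():
            blocks.sort(key=lambda b: b.source_start)
            self._starts[chrom] = [b.source_start for b in blocks]
        return self

    @property
    def n_blocks(self) -> int:
        return sum(len(b) for b in self._blocks.values())

    def lookup(self, chrom: str, pos0: int) -> ChainBlock | None:
        blocks = self._blocks.get(chrom)
        if not blocks:
            return None
        idx = bisect_right(self._starts[chrom], pos0) - 1
        if idx < 0:
            return None
        block = blocks[idx]
        return block if pos0 < block.source_end else None


def load_chain(chain_text: str, from_build: str = "",
               to_build: str = "") -> LiftoverMap:
    """Parse UCSC chain format into a liftover map.

    The chain's tName side is the source build, qName the target (matching
    UCSC's <from>To<To>.over.chain naming).  Block arithmetic is validated
    against the header's declared end coordinates; inconsistencies raise
    with the offending line number.
    """
    lift = LiftoverMap(from_build, to_build)
    lines = chain_text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] != "chain" or len(fields) < 12:
            raise ValidationError(f"line {i}: expected chain header, "
                                  f"got {line!r}")
        (_, _, t_name, _, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end) = fields[:12]
        if t_strand != "+":
            raise ValidationError(f"line {i}: source strand must be '+'")
        if q_strand not in "+-":
            raise ValidationError(f"line {i}: bad target strand {q_strand!r}")
        t_cursor, q_cursor = int(t_start), int(q_start)
        q_size_i = int(q_size)
        while i < len(lines):
            data = lines[i].strip()
            i += 1
            if not data:
                break
            parts = data.split()
            try:
                size = int(parts[0])
                dt, dq = (int(parts[1]), int(parts[2])) if len(parts) == 3 \
                    else (0, 0)
            except (ValueError, IndexError):
                raise ValidationError(
                    f"line {i}: malformed alignment line {data!r}") from None
            if size > 0:
                lift.add_block(ChainBlock(
                    t_name, t_cursor, t_cursor + size,
                    q_name, q_cursor, q_strand, q_size_i))
            t_cursor += size + dt
            q_cursor += size + dq
            if len(parts) == 1:  # final line of the chain
                break
        if t_cursor != int(t_end) or q_cursor != int(q_end):
            raise ValidationError(
                f"line {i}: chain block arithmetic does not reach declared "
                f"ends (source {t_cursor}!={t_end} or "
                f"target {q_cursor}!={q_end})")
    return lift.freeze()


def load_chain_file(path: str | Path, from_build: str = "",
                    to_build: str = "") -> LiftoverMap:
    return load_chain(Path(path).read_text(), from_build, to_build)


def lift_position(lift: LiftoverMap, chrom: str,
                  pos_1based: int) -> tuple[str, int] | Unmapped:
    """Lift one 1-based position; Unmapped carries the failure reason."""
    if chrom not in lift._blocks:
        return UNMAPPED_CHROM
    block = lift.lookup(chrom, pos_1based - 1)
    if block is None:
        return UNMAPPED_GAP
    target_chrom, pos0 = block.map_offset(pos_1based - 1)
    return target_chrom, pos0 + 1


@dataclass
class DropEntry:
    chrom: str
    pos: int
    system_sample_id: str
    reason: str


def harmonize_record(record: SiteRecord, target_build: str,
                     maps: Mapping[tuple[str, str], LiftoverMap],
                     ) -> SiteRecord | DropEntry:
    """Rewrite one record onto the target build (genotype data untouched).

    Records already on the target build pass through unchanged;
    ``source_build`` stays on the record as provenance either way.
    """
    if record.source_build == target_build:
        return record
    lift = maps.get((record.source_build, target_build))
    if lift is None:
        raise ConfigurationError(
            f"no chain configured for {record.source_build} -> {target_build}")
    lifted = lift_position(lift, record.chrom, record.pos)
    if isinstance(lifted, Unmapped):
        return DropEntry(record.chrom, record.pos, record.system_sample_id,
                         lifted.reason)
    chrom, pos = lifted
    return replace(record, chrom=chrom, pos=pos)


def harmonize_batch(records: Iterable[SiteRecord], target_build: str,
                    maps: Mapping[tuple[str, str], LiftoverMap],
                    ) -> tuple[list[SiteRecord], list[DropEntry]]:
    """Harmonize a batch; len(in) == len(out) + len(dropped) always."""
    kept: list[SiteRecord] = []
    dropped: list[DropEntry] = []
    for record in records:
        result = harmonize_record(record, target_build, maps)
        if isinstance(result, DropEntry):
            dropped.append(result)
        else:
            kept.append(result)
    return kept, dropped


def write_drop_report(drops: Iterable[DropEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "sample", "reason"])
        for d in drops:
            writer.writerow([d.chrom, d.pos, d.system_sample_id, d.reason])
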