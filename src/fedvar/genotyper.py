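"""Per-center query engine: pileups in, VCF-like genotype records out.

The built-in caller is the classical site-independent diploid model.  For a
read carrying base ``b`` with phred quality ``Q`` and error probability
``e = 10**(-Q/10)``::

    P(b | allele a)      = 1 - e        if b == a else e / 3
    P(b | genotype a1a2) = (P(b|a1) + P(b|a2)) / 2

The site likelihood of a genotype is the product over reads, and PLs are the
phred-scaled likelihoods normalized so the best genotype scores 0.  A
pluggable hook lets deployments substitute an external caller that produces
the same record schema (see :func:`run_center_query`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .errors import NoDataError, ValidationError

BASES = ("A", "C", "G", "T")
GQ_CAP = 99
QUAL_CAP = 999.0

GT_HOM_REF = "0/0"
GT_HET = "0/1"
GT_HOM_ALT = "1/1"
GT_NO_CALL = "./."


# ---------------------------------------------------------------------------
# pileup extraction


@dataclass
class PileupColumn:
    """Stack of observed base calls over one 1-based genomic position."""

    chrom: str
    pos: int
    ref_base: str
    bases: list[str]
    quals: list[int]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValidationError("bases and quals must be the same length")
        if any(q < 0 for q in self.quals):
            raise ValidationError("base qualities must be >= 0")

    @property
    def depth(self) -> int:
        return len(self.bases)


class TsvPileupSource:
    """Pileup fixture dialect: one TSV per sample.

    Columns: chrom, pos, ref, bases, quals.  ``bases`` is a string of base
    characters ('.' when the position has no coverage), ``quals`` the
    matching comma-separated phred integers.
    """

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self._columns: dict[tuple[str, int], tuple[str, str, list[int]]] = {}
        self.contigs: set[str] = set()
        with self.path.open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                chrom = row["chrom"]
                bases = row["bases"]
                if bases == ".":
                    bases, quals = "", []
                else:
                    quals = [int(q) for q in row["quals"].split(",")]
                self.contigs.add(chrom)
                self._columns[(chrom, int(row["pos"]))] = (
                    row["ref"], bases, quals)

    def column(self, chrom: str, pos: int) -> tuple[str | None, str, list[int]]:
        entry = self._columns.get((chrom, pos))
        if entry is None:
            return None, "", []
        return entry


class AlignmentPileupSource:
    """Pileup source over a SAM/BAM/CRAM file via pysam.

    Reads the whole file once (``until_eof``, so plain SAM works without an
    index) and materializes per-position columns from aligned pairs.
    Unmapped, secondary and duplicate reads are skipped, as are deletions
    and reference skips.  Suitable for desk-scale fixtures; real deployments
    with indexed BAMs can subclass and use random access instead.
    """

    def __init__(self, path: str | Path,
                 reference: "ReferenceTable | None" = None) -> None:
        import pysam  # deferred: TSV-only deployments never need it

        self.path = Path(path)
        self._columns: dict[tuple[str, int], tuple[list[str], list[int]]] = {}
        self.contigs: set[str] = set()
        self._reference = reference
        with pysam.AlignmentFile(str(self.path), check_sq=False) as af:
            self.contigs.update(af.references)
            for read in af.fetch(until_eof=True):
                if (read.is_unmapped or read.is_secondary
                        or read.is_supplementary or read.is_duplicate):
                    continue
                seq = read.query_sequence
                quals = read.query_qualities
                if seq is None or quals is None:
                    continue
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    key = (read.reference_name, rpos + 1)
                    col = self._columns.setdefault(key, ([], []))
                    col[0].append(seq[qpos])
                    col[1].append(int(quals[qpos]))

    def column(self, chrom: str, pos: int) -> tuple[str | None, str, list[int]]:
        bases, quals = self._columns.get((chrom, pos), ([], []))
        ref = self._reference.get(chrom, pos) if self._reference else "N"
        return ref, "".join(bases), list(quals)


def open_pileup_source(path: str | Path,
                       reference: "ReferenceTable | None" = None):
    """Pick a source implementation from the file extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam", ".cram"):
        return AlignmentPileupSource(path, reference)
    return TsvPileupSource(path)


def pileup_at(source, chrom: str, pos: int,
              min_base_qual: int = 0) -> PileupColumn:
    """One pileup column at a 1-based position, quality-filtered.

    A contig absent from the source yields an empty column flagged
    ``contig_missing``; a covered contig with no reads at ``pos`` yields a
    plain depth-0 column.
    """
    if chrom not in source.contigs:
        return PileupColumn(chrom, pos, "N", [], [], flags=("contig_missing",))
    ref, bases, quals = source.column(chrom, pos)
    kept = [(b, q) for b, q in zip(bases, quals) if q >= min_base_qual]
    return PileupColumn(
        chrom, pos, ref if ref is not None else "N",
        [b for b, _ in kept], [q for _, q in kept])


# ---------------------------------------------------------------------------
# reference lookup


class ReferenceTable:
    """Sparse (chrom, pos) -> ref base lookup loaded from a TSV fixture.

    Columns: chrom, pos, base.  Defines the position universe for area
    queries.  ``from_fasta`` offers the same interface over a genome FASTA
    for real deployments.
    """

    def __init__(self, entries: dict[tuple[str, int], str] | None = None):
        self._entries = dict(entries or {})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceTable":
        entries = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entries[(row["chrom"], int(row["pos"]))] = row["base"].upper()
        return cls(entries)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "FastaReference":
        return FastaReference(path)

    def get(self, chrom: str, pos: int) -> str | None:
        return self._entries.get((chrom, pos))

    def positions_in(self, chrom: str, start: int, end: int) -> list[int]:
        """Known positions on ``chrom`` within [start, end], sorted."""
        return sorted(p for c, p in self._entries if c == chrom
                      and start <= p <= end)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["chrom", "pos", "base"])
            for (chrom, pos), base in sorted(self._entries.items()):
                writer.writerow([chrom, pos, base])


class FastaReference:
    """Reference lookup backed by an indexed FASTA (pysam)."""

    def __init__(self, path: str | Path) -> None:
        import pysam

        self._fasta = pysam.FastaFile(str(path))

    def get(self, chrom: str, pos: int) -> str | None:
        if chrom not in self._fasta.references:
            return None
        return self._fasta.fetch(chrom, pos - 1, pos).upper() or None

    def positions_in(self, chrom: str, start: int, end: int) -> list[int]:
        if chrom not in self._fasta.references:
            return []
        length = self._fasta.get_reference_length(chrom)
        return list(range(max(1, start), min(end, length) + 1))


# ---------------------------------------------------------------------------
# diploid likelihood model


def _base_log10_prob(base: str, allele: str, qual: int) -> float:
    err = 10.0 ** (-qual / 10.0)
    return math.log10(1.0 - err) if base == allele else math.log10(err / 3.0)


def genotype_likelihoods(column: PileupColumn, ref_base: str,
                         alt_base: str) -> tuple[float, float, float]:
    """log10 likelihoods of (hom-ref, het, hom-alt) for one column.

    Invariant under read permutation (a sum of per-read terms).  Raises
    :class:`NoDataError` on an empty column so callers can emit ``./.``.
    """
    if alt_base == ref_base:
        raise ValidationError("alt allele must differ from ref")
    if column.depth == 0:
        raise NoDataError("no_data")
    genotypes = ((ref_base, ref_base), (ref_base, alt_base),
                 (alt_base, alt_base))
    lls = [0.0, 0.0, 0.0]
    for base, qual in zip(column.bases, column.quals):
        err = 10.0 ** (-qual / 10.0)
        p_ref = 1.0 - err if base == ref_base else err / 3.0
        p_alt = 1.0 - err if base == alt_base else err / 3.0
        lls[0] += math.log10(p_ref)
        lls[1] += math.log10((p_ref + p_alt) / 2.0)
        lls[2] += math.log10(p_alt)
    return (lls[0], lls[1], lls[2])


@dataclass
class GenotypeCall:
    gt: str
    dp: int
    ad: tuple[int, int]
    gq: int
    pl: tuple[int, int, int]
    site_qual: float

    @property
    def is_genotyped(self) -> bool:
        return self.gt != GT_NO_CALL

    @property
    def is_polymorphic(self) -> bool:
        return self.gt in (GT_HET, GT_HOM_ALT)

    @property
    def second_best_pl(self) -> int:
        """Confidence margin of the call: the second-smallest PL."""
        return sorted(self.pl)[1]


_GTS = (GT_HOM_REF, GT_HET, GT_HOM_ALT)


def call_genotype(likelihoods: Sequence[float], dp: int = 0,
                  ad: tuple[int, int] = (0, 0)) -> GenotypeCall:
    """Turn log10 genotype likelihoods into a normalized diploid call.

    PLs are ``round(-10 * (ll - max_ll))``; GQ is the gap between the two
    smallest PLs capped at 99; ties prefer the genotype with more reference
    alleles.  Site quality is the phred-scaled posterior probability that
    the site is non-reference under a uniform genotype prior.
    """
    lls = list(likelihoods)
    if len(lls) != 3 or not all(math.isfinite(x) for x in lls):
        raise ValidationError("need three finite log10-likelihoods")
    max_ll = max(lls)
    pl = tuple(int(round(-10.0 * (ll - max_ll))) for ll in lls)
    best = min(range(3), key=lambda i: (pl[i], i))  # prefers more ref alleles
    gq = min(sorted(pl)[1] - min(pl), GQ_CAP)
    # posterior(non-ref) under a uniform prior, via normalized likelihoods
    weights = [10.0 ** (ll - max_ll) for ll in lls]
    p_hom_ref = weights[0] / sum(weights)
    if p_hom_ref <= 10.0 ** (-QUAL_CAP / 10.0):
        site_qual = QUAL_CAP
    else:
        site_qual = round(-10.0 * math.log10(p_hom_ref), 2)
    return GenotypeCall(gt=_GTS[best], dp=dp, ad=ad, gq=gq, pl=pl,
                        site_qual=site_qual)


def no_call(dp: int = 0) -> GenotypeCall:
    return GenotypeCall(GT_NO_CALL, dp, (0, 0), 0, (0, 0, 0), 0.0)


# ---------------------------------------------------------------------------
# site records


@dataclass
class SiteRecord:
    """One sample's VCF-like genotype record at one position."""

    chrom: str
    pos: int
    dbsnp_id: str
    ref: str
    alt: str
    qual: float
    filter: str
    call: GenotypeCall
    system_sample_id: str
    center_id: str
    source_build: str
    caller: str = "builtin-diploid"


def choose_alt(column: PileupColumn, ref_base: str) -> str | None:
    """Alt allele = the non-reference base with the highest summed quality.

    Biallelic by design: other non-reference bases are left out of AD.
    Returns None when every read matches the reference.
    """
    totals: dict[str, int] = {}
    for base, qual in zip(column.bases, column.quals):
        if base != ref_base and base in BASES:
            totals[base] = totals.get(base, 0) + qual
    if not totals:
        return None
    return max(sorted(totals), key=lambda b: totals[b])


def call_site(source, chrom: str, pos: int, ref_base: str,
              mode: str = "variants_only", *, alt_base: str | None = None,
              min_base_qual: int = 0, dbsnp_id: str = ".",
              system_sample_id: str = "", center_id: str = "",
              source_build: str = "") -> SiteRecord | None:
    """Genotype one sample at one site; None when nothing is to be emitted.

    ``all_sites`` mode always emits a record: hom-ref calls carry alt "."
    with their full PL triple, and uncovered positions come back as ``./.``
    with depth 0 — distinguishing reference-confirmed from missing.
    ``variants_only`` emits only polymorphic calls.
    """
    if mode not in ("variants_only", "all_sites"):
        raise ValidationError(f"unknown mode {mode!r}")
    meta = dict(dbsnp_id=dbsnp_id, system_sample_id=system_sample_id,
                center_id=center_id, source_build=source_build)
    if ref_base not in BASES:
        if mode == "all_sites":
            return SiteRecord(chrom, pos, dbsnp_id, ref_base or "N", ".", 0.0,
                              "REF_N", no_call(), system_sample_id, center_id,
                              source_build)
        return None
    column = pileup_at(source, chrom, pos, min_base_qual)
    if column.depth == 0:
        if mode == "all_sites":
            return SiteRecord(chrom, pos, dbsnp_id, ref_base, ".", 0.0, ".",
                              no_call(), system_sample_id, center_id,
                              source_build)
        return None
    alt = alt_base or choose_alt(column, ref_base)
    if alt is None:
        # pure-reference column; evaluate against an arbitrary alternative
        alt = next(b for b in BASES if b != ref_base)
        alt_is_observed = False
    else:
        alt_is_observed = True
    lls = genotype_likelihoods(column, ref_base, alt)
    ad = (sum(1 for b in column.bases if b == ref_base),
          sum(1 for b in column.bases if b == alt))
    call = call_genotype(lls, dp=column.depth, ad=ad)
    if mode == "variants_only" and not call.is_polymorphic:
        return None
    alt_field = alt if (call.is_polymorphic and alt_is_observed) else "."
    return SiteRecord(chrom, pos, meta["dbsnp_id"], ref_base, alt_field,
                      call.site_qual, ".", call, system_sample_id, center_id,
                      source_build)


# ---------------------------------------------------------------------------
# per-center execution


@dataclass
class CenterTask:
    """Everything a center needs to execute one query locally."""

    center_id: str
    data_root: Path
    samples: list  # SampleRecord-like: system_sample_id, data_path, build
    reference: ReferenceTable
    dbsnp: dict[tuple[str, int], str] = field(default_factory=dict)
    build: str = ""  # native build of this center's coordinates


@dataclass
class SampleFailure:
    system_sample_id: str
    center_id: str
    reason: str


#: Signature of a pluggable caller: must mirror :func:`call_site`.
CallerHook = Callable[..., SiteRecord | None]


def run_center_query(task: CenterTask, chrom: str, start: int, end: int,
                     mode: str = "variants_only", min_base_qual: int = 0,
                     caller: CallerHook = call_site,
                     ) -> tuple[list[SiteRecord], list[SampleFailure]]:
    """Genotype every sample of a center over [start, end] (1-based incl.).

    The reference table defines which positions exist; a sample whose data
    file cannot be read produces one failure entry and never disturbs the
    other samples.  Output is sorted by (chrom, pos, system_sample_id).
    """
    positions = task.reference.positions_in(chrom, start, end)
    records: list[SiteRecord] = []
    failures: list[SampleFailure] = []
    for sample in task.samples:
        path = Path(task.data_root) / sample.data_path
        try:
            source = open_pileup_source(path, task.reference)
        except (OSError, ValueError, KeyError, ValidationError) as exc:
            failures.append(SampleFailure(
                sample.system_sample_id, task.center_id,
                f"unreadable: {exc}"))
            continue
        for pos in positions:
            record = caller(
                source, chrom, pos, task.reference.get(chrom, pos) or "N",
                mode, min_base_qual=min_base_qual,
                dbsnp_id=task.dbsnp.get((chrom, pos), "."),
                system_sample_id=sample.system_sample_id,
                center_id=task.center_id,
                source_build=sample.reference_build)
            if record is not None:
                records.append(record)
    records.sort(key=lambda r: (r.chrom, r.pos, r.system_sample_id))
    return records, failures


def demote_to_no_call(record: SiteRecord) -> SiteRecord:
    """Copy of a record with its call replaced by ``./.`` (filter demotion)."""
    return replace(record, alt=".", call=no_call(record.call.dp))
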