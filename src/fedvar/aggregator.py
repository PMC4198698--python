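"""Turns harmonized per-sample records into privacy-tiered result views.

Three partitions structure every statistic: the user's *active* dataset,
the union of *control* datasets, and the *whole population* (every
registered sample across all centers, which contains the active set).
Detail-level rows appear only for samples at the ``detailed`` tier; every
other sample surfaces solely as a pseudonym + center + PI inside aggregate
counts, so the serialized views carry no local sample name anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .genotyper import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    SiteRecord,
    demote_to_no_call,
)
from .registry import Registry
from .vcfio import format_record

PARTITION_NAMES = ("active", "control", "whole_population")


def partition_samples(user_id: str, registry: Registry,
                      ) -> dict[str, set[str]]:
    """Active / control / whole-population sample-ID sets for one user.

    Active is empty when no dataset is activated; control is the union of
    datasets flagged as control cohorts; the whole population is every
    registered sample and always contains the active set.
    """
    user = registry.users[user_id]
    active: set[str] = set()
    if user.active_dataset_id is not None:
        active = set(
            registry.datasets[user.active_dataset_id].member_sample_ids)
    control: set[str] = set()
    for dataset in registry.datasets.values():
        if dataset.is_control:
            control |= dataset.member_sample_ids
    return {
        "active": active,
        "control": control,
        "whole_population": set(registry.samples),
    }


# ---------------------------------------------------------------------------
# filtering


def apply_filters(records: Sequence[SiteRecord], thresholds: Mapping | None,
                  ) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Split records into (kept, removed) by the user's quality thresholds.

    No thresholds means no filtering (the default).  Only non-hom-ref
    records can be removed; every supplied bound is inclusive.  ``min_pl``
    bounds the second-smallest PL — the confidence margin of the called
    genotype (same scale as GQ, but uncapped).  Removed records are meant
    to be demoted to no-call downstream, not deleted: see
    :func:`counting_records`.
    """
    thresholds = {k: v for k, v in (thresholds or {}).items() if v is not None}
    for name, value in thresholds.items():
        if value < 0:
            raise ValidationError(f"threshold {name} must be >= 0")
    unknown = set(thresholds) - {"min_qual", "min_dp", "min_gq", "min_pl"}
    if unknown:
        raise ValidationError(f"unknown thresholds: {sorted(unknown)}")
    kept: list[SiteRecord] = []
    removed: list[SiteRecord] = []
    for record in records:
        call = record.call
        if not call.is_polymorphic:
            kept.append(record)
            continue
        ok = (record.qual >= thresholds.get("min_qual", 0)
              and call.dp >= thresholds.get("min_dp", 0)
              and call.gq >= thresholds.get("min_gq", 0)
              and call.second_best_pl >= thresholds.get("min_pl", 0))
        (kept if ok else removed).append(record)
    return kept, removed


def counting_records(kept: Sequence[SiteRecord],
                     removed: Sequence[SiteRecord]) -> list[SiteRecord]:
    """Records used for counting: kept as-is, removed demoted to no-call."""
    return list(kept) + [demote_to_no_call(r) for r in removed]


# ---------------------------------------------------------------------------
# per-partition statistics


@dataclass
class PartitionSummary:
    partition_name: str
    n_queried: int = 0
    n_genotyped: int = 0
    n_no_call: int = 0
    counts: dict = field(default_factory=lambda: {
        "hom_ref": 0, "het": 0, "hom_alt": 0})
    maf: float | None = None  # None serializes as "NA" (no genotyped samples)
    qual_min: float | None = None
    qual_max: float | None = None
    qual_mean: float | None = None

    @property
    def n_same_as_ref(self) -> int:
        return self.counts["hom_ref"]

    @property
    def n_different(self) -> int:
        return self.counts["het"] + self.counts["hom_alt"]

    def to_dict(self) -> dict:
        return {
            "partition": self.partition_name,
            "n_queried": self.n_queried,
            "n_genotyped": self.n_genotyped,
            "n_no_call": self.n_no_call,
            "counts": dict(self.counts),
            "same_as_hom_ref": self.n_same_as_ref,
            "different_from_hom_ref": self.n_different,
            "maf": "NA" if self.maf is None else self.maf,
            "qual_min": self.qual_min,
            "qual_max": self.qual_max,
            "qual_mean": self.qual_mean,
        }


_GT_KEY = {GT_HOM_REF: "hom_ref", GT_HET: "het", GT_HOM_ALT: "hom_alt"}


def compute_maf(records: Sequence[SiteRecord],
                sample_set: set[str]) -> float | None:
    """Folded allele frequency min(p, 1-p) at one position within a set.

    p counts alt alleles over 2x the *genotyped* samples of the set;
    no-calls leave the denominator entirely.  None (reported "NA") when
    nothing in the set could be genotyped.
    """
    alt_alleles = 0
    genotyped = 0
    for record in records:
        if record.system_sample_id not in sample_set:
            continue
        if not record.call.is_genotyped:
            continue
        genotyped += 1
        alt_alleles += {GT_HOM_REF: 0, GT_HET: 1, GT_HOM_ALT: 2}[record.call.gt]
    if genotyped == 0:
        return None
    p = alt_alleles / (2 * genotyped)
    return min(p, 1.0 - p)


def summarize_partition(name: str, records: Sequence[SiteRecord],
                        sample_set: set[str]) -> PartitionSummary:
    summary = PartitionSummary(partition_name=name)
    quals: list[float] = []
    for record in records:
        if record.system_sample_id not in sample_set:
            continue
        summary.n_queried += 1
        if record.call.is_genotyped:
            summary.n_genotyped += 1
            summary.counts[_GT_KEY[record.call.gt]] += 1
            quals.append(record.qual)
        else:
            summary.n_no_call += 1
    if quals:
        summary.qual_min = min(quals)
        summary.qual_max = max(quals)
        summary.qual_mean = sum(quals) / len(quals)
    summary.maf = compute_maf(records, sample_set)
    return summary


def summarize_point(records: Sequence[SiteRecord],
                    partitions: Mapping[str, set[str]],
                    ) -> dict[str, object]:
    """Summary + Statistics sections for a single-position record set."""
    positions = {(r.chrom, r.pos) for r in records}
    if len(positions) > 1:
        raise ValidationError(
            f"point summary expects one position, got {sorted(positions)}")
    per_center: dict[str, int] = {}
    for record in records:
        per_center[record.center_id] = per_center.get(record.center_id, 0) + 1
    stats = {name: summarize_partition(name, records, sample_set)
             for name, sample_set in partitions.items()}
    return {
        "Summary": {
            "samples_queried_per_center": dict(sorted(per_center.items())),
            "same_as_hom_ref": stats["whole_population"].n_same_as_ref,
            "different_from_hom_ref": stats["whole_population"].n_different,
            "qual_min": stats["whole_population"].qual_min,
            "qual_max": stats["whole_population"].qual_max,
            "qual_mean": stats["whole_population"].qual_mean,
        },
        "Statistics": {name: stats[name].to_dict()
                       for name in PARTITION_NAMES},
    }


def summarize_area(records: Sequence[SiteRecord],
                   partitions: Mapping[str, set[str]],
                   accessible: set[str]) -> dict[str, object]:
    """Summary / Sample-to-Position / Position-to-Sample for a region.

    Position-to-Sample aggregates occurrence counts over all samples from
    all centers; Sample-to-Position lists non-hom-ref positions only for
    samples the user may see in detail.
    """
    per_center: dict[str, set[str]] = {}
    for record in records:
        per_center.setdefault(record.center_id, set()).add(
            record.system_sample_id)
    sample_to_pos: dict[str, list[dict]] = {}
    pos_to_sample: dict[tuple[str, int], dict] = {}
    for record in records:
        key = (record.chrom, record.pos)
        entry = pos_to_sample.setdefault(key, {
            "chrom": record.chrom, "pos": record.pos, "ref": record.ref,
            "alt": ".", "dbsnp_id": record.dbsnp_id,
            "genotype_counts": {"hom_ref": 0, "het": 0, "hom_alt": 0,
                                "no_call": 0},
        })
        if record.alt != ".":
            entry["alt"] = record.alt
        gt_key = _GT_KEY.get(record.call.gt, "no_call")
        entry["genotype_counts"][gt_key] += 1
        if record.call.is_polymorphic and \
                record.system_sample_id in accessible:
            sample_to_pos.setdefault(record.system_sample_id, []).append({
                "chrom": record.chrom, "pos": record.pos,
                "gt": record.call.gt, "dbsnp_id": record.dbsnp_id,
            })
    return {
        "Summary": {
            "samples_queried_per_center": {
                c: len(s) for c, s in sorted(per_center.items())},
            "samples_accessible": len(
                accessible & {r.system_sample_id for r in records}),
        },
        "Sample-to-Position": dict(sorted(sample_to_pos.items())),
        "Position-to-Sample": [pos_to_sample[k]
                               for k in sorted(pos_to_sample)],
    }


# ---------------------------------------------------------------------------
# sample-to-SNV clustering


@dataclass
class SnvCluster:
    genotype: str
    dbsnp_id: str
    center_id: str
    pi_name: str
    members: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"genotype": self.genotype, "dbsnp_id": self.dbsnp_id,
                "center": self.center_id, "pi_name": self.pi_name,
                "members": list(self.members)}


def cluster_sample_to_snv(records: Sequence[SiteRecord], user_id: str,
                          registry: Registry) -> list[SnvCluster]:
    """Group polymorphic samples by (genotype, dbSNP ID, center, PI).

    Every member is tagged with its access tier; inaccessible members (the
    grey ones) expose only pseudonym, center and PI.
    """
    clusters: dict[tuple, SnvCluster] = {}
    for record in records:
        if not record.call.is_polymorphic:
            continue
        sample = registry.samples[record.system_sample_id]
        key = (record.call.gt, record.dbsnp_id, record.center_id,
               sample.pi_name)
        cluster = clusters.setdefault(key, SnvCluster(*key))
        accessible = registry.check_access(
            user_id, record.system_sample_id) == "detailed"
        cluster.members.append({
            "system_sample_id": record.system_sample_id,
            "center": record.center_id,
            "pi_name": sample.pi_name,
            "accessible": accessible,
        })
    return [clusters[key] for key in sorted(clusters)]


# ---------------------------------------------------------------------------
# co-carrier analysis


def co_carrier_counts(records_a: Sequence[SiteRecord],
                      records_b: Sequence[SiteRecord]) -> dict:
    """Overlap of heterozygous carriers between two positions.

    When every het carrier of either site carries both variants, the
    variants are consistent with lying on the same allele.
    """
    hets_a = {r.system_sample_id for r in records_a if r.call.gt == GT_HET}
    hets_b = {r.system_sample_id for r in records_b if r.call.gt == GT_HET}
    both = hets_a & hets_b
    return {
        "both_het": len(both),
        "only_A": len(hets_a - hets_b),
        "only_B": len(hets_b - hets_a),
        "same_allele_consistent": len(both) > 0
        and not (hets_a - hets_b) and not (hets_b - hets_a),
    }


# ---------------------------------------------------------------------------
# result views


@dataclass
class ResultView:
    kind: str  # "point" | "area"
    request_id: str
    query: dict
    sections: dict

    def to_dict(self) -> dict:
        return {"kind": self.kind, "request_id": self.request_id,
                "query": self.query, "sections": self.sections}

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _detail_rows(records: Sequence[SiteRecord], detailed: set[str],
                 ) -> list[dict]:
    rows = []
    for record in records:
        if record.system_sample_id not in detailed:
            continue
        rows.append({
            "system_sample_id": record.system_sample_id,
            "center": record.center_id,
            "chrom": record.chrom, "pos": record.pos,
            "dbsnp_id": record.dbsnp_id,
            "ref": record.ref, "alt": record.alt,
            "qual": record.qual, "filter": record.filter,
            "gt": record.call.gt, "dp": record.call.dp,
            "ad": list(record.call.ad), "gq": record.call.gq,
            "pl": list(record.call.pl),
            "vcf": format_record(record),
        })
    return rows


def build_point_view(user_id: str, registry: Registry,
                     records: Sequence[SiteRecord],
                     request_id: str = "", query: dict | None = None,
                     thresholds: Mapping | None = None) -> ResultView:
    """Assemble the four point-query sections, already redacted.

    Filtering demotes failing records to no-call before any counting, so
    thresholds affect Statistics and Sample-to-SNV consistently.
    """
    kept, removed = apply_filters(records, thresholds)
    counted = counting_records(kept, removed)
    partitions = partition_samples(user_id, registry)
    detailed = {sid for sid in {r.system_sample_id for r in counted}
                if registry.check_access(user_id, sid) == "detailed"}
    sections = summarize_point(counted, partitions)
    sections["Detail"] = _detail_rows(counted, detailed)
    sections["Sample-to-SNV"] = [
        c.to_dict() for c in cluster_sample_to_snv(counted, user_id, registry)]
    view = ResultView("point", request_id, dict(query or {}), sections)
    return privacy_filter(user_id, view, registry)


def build_area_view(user_id: str, registry: Registry,
                    records: Sequence[SiteRecord],
                    request_id: str = "", query: dict | None = None,
                    thresholds: Mapping | None = None) -> ResultView:
    kept, removed = apply_filters(records, thresholds)
    counted = counting_records(kept, removed)
    partitions = partition_samples(user_id, registry)
    detailed = {sid for sid in {r.system_sample_id for r in counted}
                if registry.check_access(user_id, sid) == "detailed"}
    sections = summarize_area(counted, partitions, detailed)
    view = ResultView("area", request_id, dict(query or {}), sections)
    return privacy_filter(user_id, view, registry)


def privacy_filter(user_id: str, view: ResultView,
                   registry: Registry) -> ResultView:
    """Enforce the tier rules on an assembled view (idempotent).

    Detail rows are restricted to samples at the ``detailed`` tier, and the
    serialized view is audited for local sample names — a leak raises
    rather than ships.
    """
    detailed = {sid for sid in registry.samples
                if registry.check_access(user_id, sid) == "detailed"}
    sections = view.sections
    if "Detail" in sections:
        sections["Detail"] = [row for row in sections["Detail"]
                              if row["system_sample_id"] in detailed]
    if "Sample-to-Position" in sections:
        sections["Sample-to-Position"] = {
            sid: rows for sid, rows in sections["Sample-to-Position"].items()
            if sid in detailed}
    if "Sample-to-SNV" in sections:
        for cluster in sections["Sample-to-SNV"]:
            for member in cluster["members"]:
                member["accessible"] = \
                    member["system_sample_id"] in detailed
    serialized = view.to_json()
    for sample in registry.samples.values():
        if sample.sample_local_name in serialized:
            raise ValidationError(
                "privacy violation: local sample name would be exposed")
    return view
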