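import json

import numpy as np
import pytest

from fedvar.aggregator import (
    apply_filters,
    build_area_view,
    build_point_view,
    cluster_sample_to_snv,
    co_carrier_counts,
    compute_maf,
    counting_records,
    partition_samples,
    summarize_area,
    summarize_point,
)
from fedvar.errors import ValidationError
from fedvar.genotyper import GenotypeCall, SiteRecord, no_call
from fedvar.registry import Registry

from conftest import manifest_row


def rec(sample, gt="0/1", pl=(90, 0, 90), dp=20, qual=500.0, pos=100,
        center="C1", dbsnp=".", gq=None, chrom="chr1"):
    if gt == "./.":
        call = no_call(dp)
    else:
        gq = min(sorted(pl)[1] - min(pl), 99) if gq is None else gq
        ad = {"0/0": (dp, 0), "0/1": (dp // 2, dp - dp // 2),
              "1/1": (0, dp)}[gt]
        call = GenotypeCall(gt, dp, ad, gq, pl, qual)
    alt = "." if gt in ("0/0", "./.") else "A"
    return SiteRecord(chrom, pos, dbsnp, "G", alt, qual, ".", call,
                      sample, center, "hg19")


@pytest.fixture
def scenario(registry):
    """4 samples at C1 (PI_A) + 2 at C2 (PI_B); res1 activates dataset D1
    holding the first two; last C1 sample sits in a control dataset."""
    reg = registry
    reg.add_user("sysadmin", "res1", "researcher")
    ids = []
    for i in range(4):
        row = manifest_row(local_name=f"LOCAL-A{i}", pi="PI_A")
        ids.append(reg.register_sample("admin1", "C1", row).system_sample_id)
    for i in range(2):
        row = manifest_row(local_name=f"LOCAL-B{i}", pi="PI_B")
        ids.append(reg.register_sample("admin2", "C2", row).system_sample_id)
    reg.create_dataset("sysadmin", "D1", "active set")
    for sid in ids[:2]:
        reg.add_to_dataset("sysadmin", "D1", sid)
    reg.create_dataset("sysadmin", "CTRL", "controls", is_control=True)
    reg.add_to_dataset("sysadmin", "CTRL", ids[3])
    reg.grant_dataset_access("sysadmin", "D1", "res1")
    reg.activate_dataset("res1", "D1")
    return reg, ids


class TestPartitionSamples:
    def test_three_partitions(self, scenario):
        reg, ids = scenario
        parts = partition_samples("res1", reg)
        assert parts["active"] == set(ids[:2])
        assert parts["control"] == {ids[3]}
        assert parts["whole_population"] == set(ids)
        assert parts["active"] <= parts["whole_population"]

    def test_no_activation_gives_empty_active(self, scenario):
        reg, ids = scenario
        reg.deactivate_dataset("res1")
        parts = partition_samples("res1", reg)
        assert parts["active"] == set()
        assert parts["whole_population"] == set(ids)

    def test_no_control_datasets(self, registry):
        registry.add_user("sysadmin", "res1", "researcher")
        parts = partition_samples("res1", registry)
        assert parts["control"] == set()


class TestApplyFilters:
    def test_no_thresholds_keeps_everything(self):
        records = [rec("s1"), rec("s2", gt="0/0"), rec("s3", gt="./.")]
        kept, removed = apply_filters(records, None)
        assert kept == records and removed == []

    def test_min_pl_uses_confidence_margin(self):
        low = rec("s1", pl=(60, 0, 95))   # margin 60: filtered at 70
        high = rec("s2", pl=(90, 0, 95))  # margin 90: kept
        kept, removed = apply_filters([low, high], {"min_pl": 70})
        assert kept == [high] and removed == [low]

    def test_boundary_is_inclusive(self):
        record = rec("s1", dp=10)
        kept, removed = apply_filters([record], {"min_dp": 10})
        assert kept == [record]

    def test_hom_ref_never_removed(self):
        record = rec("s1", gt="0/0", dp=1, qual=0.0)
        kept, removed = apply_filters([record],
                                      {"min_dp": 50, "min_qual": 100})
        assert kept == [record]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            apply_filters([], {"min_dp": -1})

    def test_unknown_threshold_rejected(self):
        with pytest.raises(ValidationError):
            apply_filters([], {"min_depth": 3})

    def test_removed_records_demoted_not_deleted(self):
        low = rec("s1", pl=(60, 0, 95))
        kept, removed = apply_filters([low], {"min_pl": 70})
        counted = counting_records(kept, removed)
        assert len(counted) == 1
        assert counted[0].call.gt == "./."

    def test_monotonicity_raising_thresholds(self):
        rng = np.random.default_rng(8)
        records = []
        for i in range(50):
            second = int(rng.integers(0, 120))
            records.append(rec(f"s{i}", pl=(second, 0, second + 5),
                               dp=int(rng.integers(1, 40)),
                               qual=float(rng.integers(0, 900))))
        last = None
        for threshold in (0, 20, 40, 60, 80, 100, 120):
            kept, _ = apply_filters(records, {"min_pl": threshold})
            n_poly = sum(r.call.is_polymorphic for r in kept)
            if last is not None:
                assert n_poly <= last
            last = n_poly


class TestComputeMaf:
    def test_one_het_in_ten(self):
        records = [rec(f"s{i}", gt="0/0") for i in range(9)] + [rec("s9")]
        samples = {f"s{i}" for i in range(10)}
        assert compute_maf(records, samples) == pytest.approx(0.05)

    def test_22_hets_among_367(self):
        records = [rec(f"s{i}") for i in range(22)] + \
            [rec(f"s{i}", gt="0/0") for i in range(22, 367)]
        samples = {f"s{i}" for i in range(367)}
        maf = compute_maf(records, samples)
        assert maf == pytest.approx(22 / 734)
        assert round(maf, 2) == 0.03

    def test_all_hom_alt_folds_to_zero(self):
        records = [rec(f"s{i}", gt="1/1") for i in range(5)]
        assert compute_maf(records, {f"s{i}" for i in range(5)}) == 0.0

    def test_no_calls_leave_denominator(self):
        records = [rec("s0"), rec("s1", gt="./."), rec("s2", gt="0/0")]
        # 1 alt allele over 2 genotyped samples
        assert compute_maf(records, {"s0", "s1", "s2"}) == pytest.approx(0.25)

    def test_zero_genotyped_is_na(self):
        assert compute_maf([rec("s0", gt="./.")], {"s0"}) is None

    def test_always_folded_and_matches_allele_tally(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            gts = rng.integers(0, 3, size=n)
            records = [rec(f"s{i}", gt=("0/0", "0/1", "1/1")[g])
                       for i, g in enumerate(gts)]
            maf = compute_maf(records, {f"s{i}" for i in range(n)})
            p = gts.sum() / (2 * n)
            assert 0.0 <= maf <= 0.5
            assert maf == pytest.approx(min(p, 1 - p))


class TestSummarizePoint:
    def test_carrier_outside_active_dataset(self, scenario):
        reg, ids = scenario
        records = [rec(sid, gt="0/0") for sid in ids[:5]] + [rec(ids[5])]
        parts = partition_samples("res1", reg)
        sections = summarize_point(records, parts)
        active = sections["Statistics"]["active"]
        whole = sections["Statistics"]["whole_population"]
        assert active["counts"]["het"] == 0
        assert whole["counts"]["het"] == 1
        assert whole["different_from_hom_ref"] == 1

    def test_all_hom_ref(self, scenario):
        reg, ids = scenario
        records = [rec(sid, gt="0/0") for sid in ids]
        sections = summarize_point(records, partition_samples("res1", reg))
        whole = sections["Statistics"]["whole_population"]
        assert whole["different_from_hom_ref"] == 0
        assert whole["maf"] == 0.0

    def test_quality_stats_match_independent_pass(self, scenario):
        reg, ids = scenario
        rng = np.random.default_rng(2)
        records = [rec(sid, qual=float(q))
                   for sid, q in zip(ids, rng.integers(10, 900, size=6))]
        sections = summarize_point(records, partition_samples("res1", reg))
        quals = [r.qual for r in records]
        whole = sections["Statistics"]["whole_population"]
        assert whole["qual_min"] == min(quals)
        assert whole["qual_max"] == max(quals)
        assert whole["qual_mean"] == pytest.approx(sum(quals) / len(quals))

    def test_conservation_per_partition(self, scenario):
        reg, ids = scenario
        records = [rec(ids[0]), rec(ids[1], gt="./."),
                   rec(ids[2], gt="0/0"), rec(ids[3], gt="1/1"),
                   rec(ids[4], gt="0/0"), rec(ids[5], gt="./.")]
        sections = summarize_point(records, partition_samples("res1", reg))
        for stats in sections["Statistics"].values():
            counted = sum(stats["counts"].values()) + stats["n_no_call"]
            assert counted == stats["n_queried"]

    def test_empty_control_reported_as_na(self, registry):
        registry.add_user("sysadmin", "res1", "researcher")
        sid = registry.register_sample(
            "admin1", "C1", manifest_row()).system_sample_id
        sections = summarize_point([rec(sid, gt="0/0")],
                                   partition_samples("res1", registry))
        control = sections["Statistics"]["control"]
        assert control["n_queried"] == 0
        assert control["maf"] == "NA"

    def test_mixed_positions_rejected(self, scenario):
        reg, ids = scenario
        with pytest.raises(ValidationError):
            summarize_point([rec(ids[0], pos=1), rec(ids[1], pos=2)],
                            partition_samples("res1", reg))


class TestSummarizeArea:
    def test_single_planted_snv(self, scenario):
        reg, ids = scenario
        records = [rec(sid, gt="0/0", pos=p)
                   for sid in ids for p in (100, 150)]
        records[0] = rec(ids[0], pos=100)  # one het carrier at pos 100
        parts = partition_samples("res1", reg)
        sections = summarize_area(records, parts, accessible=set(ids[:2]))
        by_pos = {e["pos"]: e for e in sections["Position-to-Sample"]}
        assert by_pos[100]["genotype_counts"]["het"] == 1
        assert by_pos[150]["genotype_counts"]["het"] == 0

    def test_zero_accessible_samples_keeps_counts(self, scenario):
        reg, ids = scenario
        records = [rec(sid) for sid in ids]
        sections = summarize_area(records,
                                  partition_samples("res1", reg),
                                  accessible=set())
        assert sections["Sample-to-Position"] == {}
        assert sections["Position-to-Sample"][0]["genotype_counts"]["het"] == 6

    def test_counts_equal_genotype_matrix_column_sums(self, scenario):
        reg, ids = scenario
        rng = np.random.default_rng(21)
        matrix = rng.integers(0, 3, size=(6, 3))
        positions = (100, 200, 300)
        records = [rec(sid, gt=("0/0", "0/1", "1/1")[matrix[i, j]], pos=p)
                   for i, sid in enumerate(ids)
                   for j, p in enumerate(positions)]
        sections = summarize_area(records, partition_samples("res1", reg),
                                  accessible=set(ids))
        for j, pos in enumerate(positions):
            entry = next(e for e in sections["Position-to-Sample"]
                         if e["pos"] == pos)
            col = matrix[:, j]
            assert entry["genotype_counts"] == {
                "hom_ref": int((col == 0).sum()),
                "het": int((col == 1).sum()),
                "hom_alt": int((col == 2).sum()),
                "no_call": 0,
            }


class TestClusterSampleToSnv:
    def test_grouping_by_key(self, scenario):
        reg, ids = scenario
        records = [rec(ids[0]), rec(ids[1]), rec(ids[2]),
                   rec(ids[4], gt="1/1", center="C2")]
        clusters = cluster_sample_to_snv(records, "res1", reg)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 3]

    def test_inaccessible_members_marked_grey(self, scenario):
        reg, ids = scenario
        records = [rec(ids[0]), rec(ids[5], center="C2")]
        clusters = cluster_sample_to_snv(records, "res1", reg)
        flags = {m["system_sample_id"]: m["accessible"]
                 for c in clusters for m in c.members}
        assert flags[ids[0]] is True    # in active dataset D1
        assert flags[ids[5]] is False   # other PI, never shared

    def test_members_partition_polymorphic_samples(self, scenario):
        reg, ids = scenario
        rng = np.random.default_rng(13)
        gts = [("0/0", "0/1", "1/1")[g]
               for g in rng.integers(0, 3, size=len(ids))]
        records = [rec(sid, gt=gt, dbsnp=rng.choice(["rs1", "rs2"]))
                   for sid, gt in zip(ids, gts)]
        clusters = cluster_sample_to_snv(records, "res1", reg)
        members = [m["system_sample_id"]
                   for c in clusters for m in c.members]
        polymorphic = [r.system_sample_id for r in records
                       if r.call.is_polymorphic]
        assert sorted(members) == sorted(polymorphic)


class TestCoCarriers:
    def test_identical_22_carriers(self):
        carriers = [f"s{i}" for i in range(22)]
        others = [f"s{i}" for i in range(22, 367)]
        records_a = [rec(s, pos=100) for s in carriers] + \
            [rec(s, gt="0/0", pos=100) for s in others]
        records_b = [rec(s, pos=200) for s in carriers] + \
            [rec(s, gt="0/0", pos=200) for s in others]
        result = co_carrier_counts(records_a, records_b)
        assert result == {"both_het": 22, "only_A": 0, "only_B": 0,
                          "same_allele_consistent": True}

    def test_disjoint_carriers_not_consistent(self):
        result = co_carrier_counts([rec("s1")], [rec("s2")])
        assert result["both_het"] == 0
        assert result["same_allele_consistent"] is False

    def test_strict_subset_not_consistent(self):
        records_a = [rec("s1")]
        records_b = [rec("s1", pos=200), rec("s2", pos=200)]
        result = co_carrier_counts(records_a, records_b)
        assert result["both_het"] == 1 and result["only_B"] == 1
        assert result["same_allele_consistent"] is False

    def test_hom_alt_is_not_a_het_carrier(self):
        result = co_carrier_counts([rec("s1", gt="1/1")],
                                   [rec("s1", gt="1/1")])
        assert result["both_het"] == 0


class TestViewsAndPrivacy:
    def test_no_active_dataset_empty_detail(self, scenario):
        reg, ids = scenario
        reg.deactivate_dataset("res1")
        view = build_point_view("res1", reg, [rec(sid) for sid in ids])
        assert view.sections["Detail"] == []
        assert view.sections["Statistics"]["whole_population"]["n_queried"] \
            == 6

    def test_active_dataset_detail_rows_exact(self, scenario):
        reg, ids = scenario
        view = build_point_view("res1", reg, [rec(sid) for sid in ids])
        detail_ids = {row["system_sample_id"]
                      for row in view.sections["Detail"]}
        assert detail_ids == set(ids[:2])

    def test_serialized_view_never_leaks_local_names(self, scenario):
        reg, ids = scenario
        view = build_point_view("res1", reg, [rec(sid) for sid in ids])
        serialized = view.to_json()
        for sample in reg.samples.values():
            assert sample.sample_local_name not in serialized

    def test_area_view_respects_tiers(self, scenario):
        reg, ids = scenario
        records = [rec(sid, pos=p) for sid in ids for p in (100, 120)]
        view = build_area_view("res1", reg, records)
        assert set(view.sections["Sample-to-Position"]) <= set(ids[:2])
        assert len(view.sections["Position-to-Sample"]) == 2

    def test_filter_thresholds_flow_into_views(self, scenario):
        reg, ids = scenario
        records = [rec(ids[0], pl=(60, 0, 95))] + \
            [rec(sid, gt="0/0") for sid in ids[1:]]
        view = build_point_view("res1", reg, records,
                                thresholds={"min_pl": 70})
        whole = view.sections["Statistics"]["whole_population"]
        assert whole["counts"]["het"] == 0
        assert whole["n_no_call"] == 1  # demoted, not deleted

    def test_fuzzed_registries_never_leak(self):
        rng = np.random.default_rng(99)
        for trial in range(25):
            reg = Registry(salt=f"fuzz-{trial}")
            reg.add_user("boot", "sysadmin", "system_admin")
            reg.add_center("sysadmin", "C1", "one", ["a1"])
            reg.add_user("sysadmin", "user", "researcher")
            n = int(rng.integers(2, 12))
            ids = []
            for i in range(n):
                row = manifest_row(
                    local_name=f"PATIENT-{trial}-{i}",
                    pi=str(rng.choice(["PI_X", "PI_Y"])))
                ids.append(reg.register_sample(
                    "admin1" if "a1" not in reg.users else "a1",
                    "C1", row).system_sample_id)
            if rng.random() < 0.7:
                reg.create_dataset("sysadmin", "D", "d")
                for sid in rng.choice(ids, size=rng.integers(0, n),
                                      replace=False):
                    reg.add_to_dataset("sysadmin", "D", str(sid))
                reg.grant_dataset_access("sysadmin", "D", "user")
                if rng.random() < 0.8:
                    reg.activate_dataset("user", "D")
            gts = ("0/0", "0/1", "1/1", "./.")
            records = [rec(sid, gt=str(rng.choice(gts))) for sid in ids]
            view = build_point_view("user", reg, records)
            serialized = view.to_json()
            for sample in reg.samples.values():
                assert sample.sample_local_name not in serialized
            active = reg.users["user"].active_dataset_id
            members = (reg.datasets[active].member_sample_ids
                       if active else set())
            detail_ids = {row["system_sample_id"]
                          for row in view.sections["Detail"]}
            assert detail_ids <= members
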