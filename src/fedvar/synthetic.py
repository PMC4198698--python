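"""Self-contained federation fixtures: cohorts, pileups, chains, registries.

Everything a multi-center deployment needs is generated from a seed —
planted genotype truth tables, per-sample pileup files with a stated
per-base error rate, manifests, reference tables, gene BED, chain files for
a second genome build — so the whole stack is testable offline.  Generation
is fully deterministic: the same (seed, parameters) yields a byte-identical
fixture tree.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .coordinator import Coordinator, load_gene_table
from .errors import ValidationError
from .genotyper import BASES, CenterTask, ReferenceTable
from .liftover import LiftoverMap, load_chain_file
from .registry import Registry

DEPLOYMENT_FILE = "deployment.yaml"


@dataclass(frozen=True)
class Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_freq: float
    dbsnp_id: str = "."


@dataclass
class TruthTable:
    """Planted genotypes: matrix of {0,1,2} alt-allele counts, sample x site."""

    sites: list[Site]
    sample_names: list[str]
    genotypes: np.ndarray
    seed: int

    def genotype(self, sample: str, site_index: int) -> int:
        return int(self.genotypes[self.sample_names.index(sample), site_index])

    def column_counts(self, site_index: int) -> dict[str, int]:
        column = self.genotypes[:, site_index]
        return {"hom_ref": int(np.sum(column == 0)),
                "het": int(np.sum(column == 1)),
                "hom_alt": int(np.sum(column == 2))}

    def truth_maf(self, site_index: int) -> float:
        p = float(self.genotypes[:, site_index].sum()) / (
            2 * len(self.sample_names))
        return min(p, 1.0 - p)

    def carriers(self, site_index: int, genotype: int = 1) -> set[str]:
        column = self.genotypes[:, site_index]
        return {name for name, gt in zip(self.sample_names, column)
                if gt == genotype}


def simulate_cohort(n_samples: int, sites: list[Site], seed: int,
                    plant_overrides: dict[tuple[str, int], int] | None = None,
                    ) -> TruthTable:
    """Draw genotypes under Hardy-Weinberg, then apply explicit plants.

    Unplanted genotypes are Binomial(2, allele_freq) draws; overrides map
    (sample_name, site_index) to a forced genotype in {0, 1, 2} and take
    precedence over sampling.
    """
    for site in sites:
        if not 0.0 <= site.allele_freq <= 1.0:
            raise ValidationError(
                f"allele_freq must be in [0,1], got {site.allele_freq}")
    names = [f"SMP-{i:04d}" for i in range(1, n_samples + 1)]
    rng = np.random.default_rng(seed)
    genotypes = np.column_stack([
        rng.binomial(2, site.allele_freq, size=n_samples) for site in sites
    ]).astype(np.int8) if sites else np.zeros((n_samples, 0), dtype=np.int8)
    for (sample, site_index), gt in (plant_overrides or {}).items():
        if sample not in names:
            raise ValidationError(f"override for unknown sample {sample!r}")
        if not 0 <= site_index < len(sites):
            raise ValidationError(f"override for unknown site {site_index}")
        if gt not in (0, 1, 2):
            raise ValidationError(f"genotype override must be 0/1/2, got {gt}")
        genotypes[names.index(sample), site_index] = gt
    return TruthTable(list(sites), names, genotypes, seed)


def _qual_for_error(base_error_rate: float) -> int:
    if base_error_rate <= 0:
        return 60  # treated as e = 1e-6 by the caller
    return max(2, min(60, round(-10.0 * math.log10(base_error_rate))))


def simulate_pileups(truth: TruthTable, mean_depth: float,
                     base_error_rate: float, seed: int,
                     fixed_depth: int | None = None,
                     pileup_overrides: dict[tuple[str, int],
                                            tuple[str, list[int]]] | None = None,
                     ) -> dict[str, list[tuple[str, int, str, str, list[int]]]]:
    """Per-sample pileup rows (chrom, pos, ref, bases, quals) from the truth.

    Read counts are Poisson around ``mean_depth`` (or exactly
    ``fixed_depth``); each read draws an allele from the sample's genotype
    and is corrupted with the per-base error rate, substituting uniformly
    among the other three bases.  Base qualities encode the error rate.
    ``pileup_overrides`` replaces whole columns — used to plant
    low-confidence calls with hand-chosen base/quality stacks.
    """
    if mean_depth <= 0 and fixed_depth is None:
        raise ValidationError("depth must be > 0")
    if not 0.0 <= base_error_rate < 0.5:
        raise ValidationError("error rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    qual = _qual_for_error(base_error_rate)
    others = {b: [o for o in BASES if o != b] for b in BASES}
    result: dict[str, list] = {}
    overrides = pileup_overrides or {}
    for row_index, sample in enumerate(truth.sample_names):
        rows = []
        for site_index, site in enumerate(truth.sites):
            override = overrides.get((sample, site_index))
            if override is not None:
                bases, quals = override
                rows.append((site.chrom, site.pos, site.ref,
                             bases, list(quals)))
                continue
            depth = fixed_depth if fixed_depth is not None else \
                int(rng.poisson(mean_depth))
            gt = int(truth.genotypes[row_index, site_index])
            alleles = {0: (site.ref, site.ref), 1: (site.ref, site.alt),
                       2: (site.alt, site.alt)}[gt]
            bases = []
            for pick in rng.integers(0, 2, size=depth):
                base = alleles[int(pick)]
                if base_error_rate > 0 and rng.random() < base_error_rate:
                    base = others[base][int(rng.integers(0, 3))]
                bases.append(base)
            rows.append((site.chrom, site.pos, site.ref,
                         "".join(bases), [qual] * depth))
        result[sample] = rows
    return result


def write_pileup_tsv(rows: list[tuple], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "ref", "bases", "quals"])
        for chrom, pos, ref, bases, quals in sorted(rows, key=lambda r: r[:2]):
            writer.writerow([chrom, pos, ref,
                             bases or ".",
                             ",".join(str(q) for q in quals) or "."])


# ---------------------------------------------------------------------------
# chain fixtures


def offset_chain_text(chrom: str, start0: int, end0: int, offset: int,
                      size: int = 400_000_000) -> str:
    """Single-block chain shifting [start0, end0) by a constant offset."""
    q_start, q_end = start0 + offset, end0 + offset
    return (f"chain 1000 {chrom} {size} + {start0} {end0} "
            f"{chrom} {size} + {q_start} {q_end} 1\n"
            f"{end0 - start0}\n\n")


# ---------------------------------------------------------------------------
# federation assembly


@dataclass
class Deployment:
    """A runnable fixture tree plus its in-memory runtime objects."""

    root: Path
    registry: Registry
    coordinator: Coordinator
    maps: dict[tuple[str, str], LiftoverMap]
    target_build: str
    local_to_system: dict[str, str] = field(default_factory=dict)

    def system_id(self, local_name: str) -> str:
        return self.local_to_system[local_name]

    def system_ids(self, local_names) -> set[str]:
        return {self.local_to_system[n] for n in local_names}


def _reference_entries(truth: TruthTable, flank: int, seed: int,
                       shift: int = 0) -> dict[tuple[str, int], str]:
    """Site refs plus deterministic flanking reference positions."""
    rng = np.random.default_rng(seed + 7)
    entries: dict[tuple[str, int], str] = {}
    for site in sorted(truth.sites, key=lambda s: (s.chrom, s.pos)):
        for delta in range(-flank, flank + 1):
            pos = site.pos + delta
            if pos < 1:
                continue
            key = (site.chrom, pos + shift)
            if delta == 0:
                entries[key] = site.ref
            else:
                entries.setdefault(key, BASES[int(rng.integers(0, 4))])
    return entries


def build_federation(out_dir: str | Path, truth: TruthTable,
                     n_centers: int = 2,
                     split: dict[str, str] | None = None,
                     builds: dict[str, str] | None = None,
                     target_build: str = "hg19",
                     alt_build_offset: int = 1000,
                     mean_depth: float = 20.0,
                     base_error_rate: float = 0.0,
                     fixed_depth: int | None = None,
                     seed: int = 0,
                     salt: str = "fixture-salt",
                     flank: int = 2,
                     genes: list[tuple[str, str, int, int]] | None = None,
                     pi_names: dict[str, str] | None = None,
                     pileup_overrides: dict | None = None) -> Deployment:
    """Materialize a complete multi-center deployment directory.

    ``split`` maps each sample to a center id (default: round-robin over
    ``C1..Cn``); ``builds`` maps centers to genome builds — any build other
    than the target is modeled as the target shifted by
    ``alt_build_offset``, with forward and inverse chain files written.
    ``genes`` rows are (name, chrom, start, end) in 1-based inclusive
    target coordinates.
    """
    root = Path(out_dir)
    center_ids = [f"C{i}" for i in range(1, n_centers + 1)]
    if split is None:
        split = {name: center_ids[i % n_centers]
                 for i, name in enumerate(truth.sample_names)}
    assigned = set(split)
    if assigned != set(truth.sample_names):
        orphans = sorted(set(truth.sample_names) ^ assigned)
        raise ValidationError(f"split must assign every sample exactly once; "
                              f"mismatch for {orphans[:5]}")
    bad_centers = sorted(set(split.values()) - set(center_ids))
    if bad_centers:
        raise ValidationError(f"split names unknown centers: {bad_centers}")
    builds = {cid: (builds or {}).get(cid, target_build)
              for cid in center_ids}
    alt_builds = sorted({b for b in builds.values() if b != target_build})
    if len(alt_builds) > 1:
        raise ValidationError("at most one alternative build is supported")

    pileups = simulate_pileups(truth, mean_depth, base_error_rate, seed,
                               fixed_depth=fixed_depth,
                               pileup_overrides=pileup_overrides)

    root.mkdir(parents=True, exist_ok=True)
    chains_cfg = []
    if alt_builds:
        alt = alt_builds[0]
        chain_dir = root / "chains"
        chain_dir.mkdir(exist_ok=True)
        spans: dict[str, tuple[int, int]] = {}
        for site in truth.sites:
            lo, hi = spans.get(site.chrom, (site.pos, site.pos))
            spans[site.chrom] = (min(lo, site.pos), max(hi, site.pos))
        pad = flank + 10
        fwd = "".join(
            offset_chain_text(chrom, max(0, lo - pad) + alt_build_offset,
                              hi + pad + alt_build_offset, -alt_build_offset)
            for chrom, (lo, hi) in sorted(spans.items()))
        inv = "".join(
            offset_chain_text(chrom, max(0, lo - pad), hi + pad,
                              alt_build_offset)
            for chrom, (lo, hi) in sorted(spans.items()))
        (chain_dir / f"{alt}_to_{target_build}.chain").write_text(fwd)
        (chain_dir / f"{target_build}_to_{alt}.chain").write_text(inv)
        chains_cfg = [
            {"from": alt, "to": target_build,
             "path": f"chains/{alt}_to_{target_build}.chain"},
            {"from": target_build, "to": alt,
             "path": f"chains/{target_build}_to_{alt}.chain"},
        ]

    centers_cfg = []
    for center_id in center_ids:
        build = builds[center_id]
        shift = alt_build_offset if build != target_build else 0
        center_dir = root / "centers" / center_id
        (center_dir / "data").mkdir(parents=True, exist_ok=True)
        members = sorted(n for n, c in split.items() if c == center_id)
        with (center_dir / "manifest.tsv").open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["SampleLocalName", "PIName", "SampleType",
                             "SampleReferenceVersion", "DataPath"])
            for name in members:
                pi = (pi_names or {}).get(name, f"PI-{center_id}")
                writer.writerow([name, pi, "Research", build,
                                 f"data/{name}.pileup.tsv"])
        for name in members:
            rows = [(chrom, pos + shift, ref, bases, quals)
                    for chrom, pos, ref, bases, quals in pileups[name]]
            write_pileup_tsv(rows, center_dir / "data" / f"{name}.pileup.tsv")
        ReferenceTable(_reference_entries(truth, flank, truth.seed, shift)
                       ).write_tsv(center_dir / "reference.tsv")
        centers_cfg.append({
            "center_id": center_id,
            "name": f"Center {center_id}",
            "build": build,
            "data_root": f"centers/{center_id}",
            "manifest": f"centers/{center_id}/manifest.tsv",
            "reference": f"centers/{center_id}/reference.tsv",
            "local_admin": f"admin-{center_id}",
        })

    with (root / "dbsnp.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chrom", "pos", "dbsnp_id"])
        for site in sorted(truth.sites, key=lambda s: (s.chrom, s.pos)):
            if site.dbsnp_id != ".":
                writer.writerow([site.chrom, site.pos, site.dbsnp_id])

    with (root / "genes.bed").open("w") as fh:
        for name, chrom, start, end in sorted(genes or []):
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")

    config = {
        "salt": salt,
        "target_build": target_build,
        "centers": centers_cfg,
        "chains": chains_cfg,
        "genes": "genes.bed",
        "dbsnp": "dbsnp.tsv",
    }
    (root / DEPLOYMENT_FILE).write_text(
        yaml.safe_dump(config, sort_keys=True))
    return load_deployment(root)


def load_deployment(root: str | Path) -> Deployment:
    """Rebuild registry + coordinator from a deployment directory.

    Registration order is deterministic (sorted manifests), so pseudonyms
    are reproducible for a given salt.
    """
    root = Path(root)
    config = yaml.safe_load((root / DEPLOYMENT_FILE).read_text())
    clock = _counter_clock()
    registry = Registry(salt=config["salt"], clock=clock)
    registry.add_user("bootstrap", "sysadmin", "system_admin")

    maps: dict[tuple[str, str], LiftoverMap] = {}
    for chain in config.get("chains", []):
        maps[(chain["from"], chain["to"])] = load_chain_file(
            root / chain["path"], chain["from"], chain["to"])

    target_build = config["target_build"]
    tasks: dict[str, CenterTask] = {}
    local_to_system: dict[str, str] = {}
    dbsnp_target: dict[tuple[str, int], str] = {}
    dbsnp_path = root / config.get("dbsnp", "dbsnp.tsv")
    if dbsnp_path.exists():
        with dbsnp_path.open(newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                dbsnp_target[(row["chrom"], int(row["pos"]))] = \
                    row["dbsnp_id"]

    for center_cfg in sorted(config["centers"],
                             key=lambda c: c["center_id"]):
        center_id = center_cfg["center_id"]
        registry.add_center(
            "sysadmin", center_id, center_cfg["name"],
            [center_cfg["local_admin"]],
            data_root=center_cfg["data_root"],
            build_default=center_cfg["build"])
        records = registry.register_manifest(
            center_cfg["local_admin"], center_id, root / center_cfg["manifest"])
        for record in records:
            local_to_system[record.sample_local_name] = \
                record.system_sample_id
        build = center_cfg["build"]
        dbsnp = dict(dbsnp_target)
        if build != target_build and (target_build, build) in maps:
            from .liftover import lift_position
            lift = maps[(target_build, build)]
            dbsnp = {}
            for (chrom, pos), rsid in dbsnp_target.items():
                lifted = lift_position(lift, chrom, pos)
                if not isinstance(lifted, tuple):
                    continue
                dbsnp[lifted] = rsid
        tasks[center_id] = CenterTask(
            center_id=center_id,
            data_root=root / center_cfg["data_root"],
            samples=records,
            reference=ReferenceTable.from_tsv(root / center_cfg["reference"]),
            dbsnp=dbsnp,
            build=build,
        )

    gene_table = None
    genes_path = root / config.get("genes", "genes.bed")
    if genes_path.exists() and genes_path.stat().st_size > 0:
        gene_table = load_gene_table(genes_path)

    coordinator = Coordinator(registry, tasks, gene_table=gene_table,
                              maps=maps, target_build=target_build,
                              clock=clock)
    return Deployment(root, registry, coordinator, maps, target_build,
                      local_to_system)


def _counter_clock():
    """Deterministic monotone clock for reproducible fixtures."""
    state = {"t": 0.0}

    def clock() -> float:
        state["t"] += 1.0
        return state["t"]

    return clock
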