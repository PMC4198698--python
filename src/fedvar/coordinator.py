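"""Query lifecycle: build, submit, dispatch per center, track, collect.

Centers communicate with the coordinator exclusively through their staged
result batches (one staging slot per center), so a failed or unreachable
center can never block the others.  Dispatch runs in-process here; the
contract — per-center tasks moving PENDING → RUNNING → DONE/FAILED,
results collected only once every task is terminal — is what matters.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

from .audit import AuditLog
from .errors import (
    ConfigurationError,
    NotFoundError,
    NotReadyError,
    ValidationError,
)
from .genotyper import (
    CenterTask,
    SampleFailure,
    SiteRecord,
    call_site,
    run_center_query,
)
from .liftover import DropEntry, LiftoverMap, Unmapped, harmonize_batch, lift_position
from .registry import Registry

PENDING, RUNNING, DONE, FAILED = "PENDING", "RUNNING", "DONE", "FAILED"
_FORWARD = {PENDING: {RUNNING}, RUNNING: {DONE, FAILED},
            DONE: set(), FAILED: set()}


@dataclass
class QuerySpec:
    """A point or area query as entered by the user."""

    kind: str  # "point" | "area"
    chrom: str
    pos: int | None = None
    start: int | None = None
    end: int | None = None
    gene_name: str | None = None
    mode: str = "variants_only"
    caller_name: str = "builtin-diploid"
    filter_thresholds: dict = field(default_factory=dict)
    min_base_qual: int = 0  # by default no base-quality filtering

    def validate(self) -> None:
        if self.kind not in ("point", "area"):
            raise ValidationError(f"unknown query kind {self.kind!r}")
        if self.mode not in ("variants_only", "all_sites"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.kind == "point":
            if self.pos is None or self.start is not None \
                    or self.end is not None or self.gene_name is not None:
                raise ValidationError("point query takes exactly a position")
        else:
            has_coords = self.start is not None and self.end is not None
            if has_coords == (self.gene_name is not None):
                raise ValidationError(
                    "area query takes start/end or a gene name, not both")
            if has_coords and self.start > self.end:
                raise ValidationError("area start must be <= end")
        for name, value in self.filter_thresholds.items():
            if value is not None and value < 0:
                raise ValidationError(f"threshold {name} must be >= 0")


# ---------------------------------------------------------------------------
# gene table


def load_gene_table(bed_path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Gene name -> [(chrom, start, end)] from BED, converted to 1-based
    inclusive at this boundary.  Names are matched case-insensitively."""
    table: dict[str, list[tuple[str, int, int]]] = {}
    for line in Path(bed_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValidationError(f"BED line lacks a name field: {line!r}")
        chrom, start0, end0, name = fields[:4]
        table.setdefault(name.lower(), []).append(
            (chrom, int(start0) + 1, int(end0)))
    return table


def resolve_region(spec: QuerySpec,
                   gene_table: Mapping[str, list[tuple[str, int, int]]] | None,
                   ) -> tuple[str, int, int]:
    """(chrom, start, end) in 1-based inclusive coordinates for any spec."""
    spec.validate()
    if spec.kind == "point":
        return spec.chrom, spec.pos, spec.pos
    if spec.gene_name is None:
        return spec.chrom, spec.start, spec.end
    if not gene_table:
        raise ConfigurationError("no gene table loaded; cannot resolve names")
    hits = gene_table.get(spec.gene_name.lower())
    if not hits:
        raise NotFoundError(f"unknown gene {spec.gene_name!r}")
    if len(hits) > 1:
        listing = ", ".join(f"{c}:{s}-{e}" for c, s, e in hits)
        raise ValidationError(
            f"gene {spec.gene_name!r} is ambiguous: {listing}")
    return hits[0]


# ---------------------------------------------------------------------------
# requests


@dataclass
class QueryRequest:
    request_id: str
    user_id: str
    spec: QuerySpec
    task_states: dict[str, str]
    created_at: float
    region: tuple[str, int, int]  # in target-build coordinates
    target_build: str = ""
    failure_reasons: dict[str, str] = field(default_factory=dict)


@dataclass
class CollectedResults:
    request_id: str
    target_build: str
    records: list[SiteRecord]
    drop_report: list[DropEntry]
    failure_report: list[SampleFailure]
    center_failures: dict[str, str]


class Coordinator:
    """Main-system side: owns requests and the per-center staging slots."""

    def __init__(self, registry: Registry,
                 center_tasks: Mapping[str, CenterTask],
                 gene_table: Mapping[str, list] | None = None,
                 maps: Mapping[tuple[str, str], LiftoverMap] | None = None,
                 target_build: str | None = None,
                 clock: Callable[[], float] = time.time,
                 audit: AuditLog | None = None) -> None:
        if set(center_tasks) - set(registry.centers):
            unknown = sorted(set(center_tasks) - set(registry.centers))
            raise ConfigurationError(f"tasks for unregistered centers: {unknown}")
        self.registry = registry
        self.target_build = target_build
        self.center_tasks = dict(center_tasks)
        self.gene_table = gene_table
        self.maps = dict(maps or {})
        self.requests: dict[str, QueryRequest] = {}
        self._staging: dict[str, dict[str, tuple[list[SiteRecord],
                                                 list[SampleFailure]]]] = {}
        self._seq = 0
        self._clock = clock
        self.audit = audit if audit is not None else registry.audit

    # -- submission -------------------------------------------------------

    def _next_request_id(self) -> str:
        self._seq += 1
        day = time.strftime("%Y%m%d", time.gmtime(self._clock()))
        return f"{day}-{self._seq:06d}"

    def submit_query(self, user_id: str, spec: QuerySpec) -> QueryRequest:
        if user_id not in self.registry.users:
            raise NotFoundError(f"unknown user {user_id!r}")
        region = resolve_region(spec, self.gene_table)  # validates too
        if not self.center_tasks:
            raise ConfigurationError("no_centers")
        request = QueryRequest(
            request_id=self._next_request_id(),
            user_id=user_id,
            spec=spec,
            task_states={cid: PENDING for cid in sorted(self.center_tasks)},
            created_at=self._clock(),
            region=region,
            target_build=self.target_build or self.default_target_build(),
        )
        self.requests[request.request_id] = request
        self._staging[request.request_id] = {}
        self.audit.append(user_id, "submit_query",
                          {"request_id": request.request_id,
                           "region": list(region), "mode": spec.mode})
        return request

    # -- dispatch ---------------------------------------------------------

    def _advance(self, request: QueryRequest, center_id: str,
                 state: str) -> None:
        current = request.task_states[center_id]
        if state not in _FORWARD[current]:
            raise ValidationError(
                f"task {center_id} cannot move {current} -> {state}")
        request.task_states[center_id] = state

    def _center_region(self, request: QueryRequest,
                       task: CenterTask) -> tuple[str, int, int]:
        """Query region in the center's native build coordinates.

        Queries are expressed on the target build; a center aligned to
        another build needs the region lifted through the reverse chain
        before its local engine can run.
        """
        chrom, start, end = request.region
        if not task.build or task.build == request.target_build:
            return chrom, start, end
        lift = self.maps.get((request.target_build, task.build))
        if lift is None:
            raise ConfigurationError(
                f"no chain configured for {request.target_build} -> "
                f"{task.build}")
        lifted = [lift_position(lift, chrom, pos) for pos in (start, end)]
        if any(isinstance(hit, Unmapped) for hit in lifted):
            raise ConfigurationError(
                f"query region unmappable to build {task.build}")
        (chrom_a, pos_a), (chrom_b, pos_b) = lifted
        if chrom_a != chrom_b:
            raise ConfigurationError(
                f"query region splits across contigs on build {task.build}")
        return chrom_a, min(pos_a, pos_b), max(pos_a, pos_b)

    def dispatch(self, request_id: str) -> QueryRequest:
        """Run every PENDING per-center task; idempotent once terminal."""
        request = self._request(request_id)
        for center_id in sorted(request.task_states):
            if request.task_states[center_id] != PENDING:
                continue  # re-dispatch is a no-op for settled tasks
            self._advance(request, center_id, RUNNING)
            task = self.center_tasks[center_id]
            try:
                if not Path(task.data_root).is_dir():
                    raise OSError(f"data root {task.data_root} unreachable")
                chrom, start, end = self._center_region(request, task)
                batch = run_center_query(
                    task, chrom, start, end, mode=request.spec.mode,
                    min_base_qual=request.spec.min_base_qual,
                    caller=call_site)
            except Exception as exc:  # a center failure must not propagate
                self._advance(request, center_id, FAILED)
                request.failure_reasons[center_id] = str(exc)
                continue
            self._staging[request_id][center_id] = batch
            self._advance(request, center_id, DONE)
        self.audit.append(request.user_id, "dispatch",
                          {"request_id": request_id,
                           "states": dict(request.task_states)})
        return request

    def track_status(self, request_id: str) -> dict[str, str]:
        return dict(self._request(request_id).task_states)

    def _request(self, request_id: str) -> QueryRequest:
        try:
            return self.requests[request_id]
        except KeyError:
            raise NotFoundError(f"unknown request {request_id!r}") from None

    # -- collection -------------------------------------------------------

    def default_target_build(self) -> str:
        """Build of the majority of registered samples (ties: lexicographic)."""
        counts: dict[str, int] = {}
        for sample in self.registry.samples.values():
            counts[sample.reference_build] = \
                counts.get(sample.reference_build, 0) + 1
        if not counts:
            raise ConfigurationError("no samples registered")
        return max(sorted(counts), key=lambda b: counts[b])

    def collect_results(self, request_id: str,
                        target_build: str | None = None) -> CollectedResults:
        """Concatenate DONE batches and harmonize them onto one build."""
        request = self._request(request_id)
        if any(state in (PENDING, RUNNING)
               for state in request.task_states.values()):
            raise NotReadyError("not_ready")
        if target_build is None:
            target_build = request.target_build or self.default_target_build()
        raw: list[SiteRecord] = []
        failures: list[SampleFailure] = []
        for center_id in sorted(self._staging[request_id]):
            batch, center_failures = self._staging[request_id][center_id]
            raw.extend(batch)
            failures.extend(center_failures)
        records, dropped = harmonize_batch(raw, target_build, self.maps)
        records.sort(key=lambda r: (r.chrom, r.pos, r.system_sample_id))
        self.audit.append(request.user_id, "collect_results",
                          {"request_id": request_id,
                           "n_records": len(records),
                           "n_dropped": len(dropped)})
        return CollectedResults(
            request_id=request_id,
            target_build=target_build,
            records=records,
            drop_report=dropped,
            failure_report=failures,
            center_failures=dict(request.failure_reasons),
        )

    def run(self, user_id: str, spec: QuerySpec,
            target_build: str | None = None) -> CollectedResults:
        """Submit, dispatch and collect in one call (the common CLI path)."""
        request = self.submit_query(user_id, spec)
        self.dispatch(request.request_id)
        return self.collect_results(request.request_id, target_build)
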