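"""Centers, users, samples, datasets, and the access rules between them.

The registry is the administrative backbone: it pseudonymizes samples on
insertion, tracks dataset membership and activation, and answers the single
question every result view depends on — at which tier (``detailed`` or
``summary_only``) may a given user see a given sample.

State lives in memory and round-trips through a plain JSON document so that
a deployment stays inspectable text.  Every mutating call appends to the
audit log.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .audit import AuditLog
from .errors import (
    AuthorizationError,
    ConflictError,
    NotFoundError,
    ValidationError,
)

ROLES = frozenset({"system_admin", "local_admin", "pi", "researcher"})
SAMPLE_TYPES = frozenset({"Research", "Diagnostics"})

#: Manifest columns, in order.  Extra columns are preserved but ignored.
MANIFEST_COLUMNS = (
    "SampleLocalName",
    "PIName",
    "SampleType",
    "SampleReferenceVersion",
    "DataPath",
)

# Maps manifest headers to the human-readable field names used in errors.
_COMPULSORY = {
    "SampleLocalName": "Sample Local Name",
    "PIName": "PI Name",
    "SampleType": "Sample Type",
    "SampleReferenceVersion": "Sample Reference version",
}

PSEUDONYM_PREFIX = "FV-"


@dataclass
class Center:
    center_id: str
    name: str
    local_admins: set[str]
    data_root: str
    build_default: str


@dataclass
class User:
    user_id: str
    role: str
    center_id: str | None = None
    accessible_dataset_ids: set[str] = field(default_factory=set)
    active_dataset_id: str | None = None
    granted_sample_ids: set[str] = field(default_factory=set)


@dataclass
class SampleRecord:
    sample_local_name: str
    pi_name: str
    sample_type: str
    reference_build: str
    center_id: str
    system_sample_id: str
    data_path: str = ""


@dataclass
class Dataset:
    dataset_id: str
    name: str
    owner_user_id: str
    visibility: str = "private"  # private | public
    member_sample_ids: set[str] = field(default_factory=set)
    is_control: bool = False


@dataclass
class AccessRequest:
    requester_user_id: str
    system_sample_id: str
    status: str  # pending | granted | denied
    created_at: float
    updated_at: float


def make_pseudonym(center_id: str, counter: int, salt: str = "fedvar") -> str:
    """Deterministic opaque token for (center, insertion counter).

    Keyed hash so the token embeds nothing recoverable about the sample; the
    salt is a deployment secret.  Stable across restarts by construction.
    """
    blob = f"{salt}|{center_id}|{counter}".encode()
    return PSEUDONYM_PREFIX + hashlib.sha256(blob).hexdigest()[:8]


class Registry:
    """One deployment's administrative state."""

    def __init__(self, salt: str = "fedvar",
                 clock: Callable[[], float] = time.time,
                 audit_path: str | Path | None = None) -> None:
        self.salt = salt
        self.centers: dict[str, Center] = {}
        self.users: dict[str, User] = {}
        self.samples: dict[str, SampleRecord] = {}
        self.datasets: dict[str, Dataset] = {}
        self.access_requests: dict[tuple[str, str], AccessRequest] = {}
        self._by_local: dict[tuple[str, str], str] = {}
        self._counters: dict[str, int] = {}
        self._clock = clock
        self.audit = AuditLog(audit_path, clock=clock)

    # -- administration ---------------------------------------------------

    def add_center(self, actor: str, center_id: str, name: str,
                   local_admins: Iterable[str], data_root: str = "",
                   build_default: str = "hg19") -> Center:
        admins = set(local_admins)
        if center_id in self.centers:
            raise ConflictError(f"center {center_id!r} already exists")
        if not admins:
            raise ValidationError("a center needs at least one local admin")
        center = Center(center_id, name, admins, data_root, build_default)
        self.centers[center_id] = center
        for admin in admins:
            self.users.setdefault(admin, User(admin, "local_admin", center_id))
        self.audit.append(actor, "add_center", {"center_id": center_id})
        return center

    def add_user(self, actor: str, user_id: str, role: str,
                 center_id: str | None = None) -> User:
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r}")
        if user_id in self.users:
            raise ConflictError(f"user {user_id!r} already exists")
        user = User(user_id, role, center_id)
        self.users[user_id] = user
        self.audit.append(actor, "add_user", {"user_id": user_id, "role": role})
        return user

    def _require_admin(self, actor: str, center_id: str) -> None:
        user = self.users.get(actor)
        if user is None:
            raise AuthorizationError(f"unknown user {actor!r}")
        if user.role == "system_admin":
            return
        center = self.centers[center_id]
        if user.role == "local_admin" and actor in center.local_admins:
            return
        raise AuthorizationError(
            f"user {actor!r} is not an admin of center {center_id!r}")

    # -- samples ----------------------------------------------------------

    def register_sample(self, actor: str, center_id: str,
                        manifest_row: dict) -> SampleRecord:
        """Insert one sample, pseudonymize it, and file it under its PI.

        ``manifest_row`` uses the manifest dialect headers
        (:data:`MANIFEST_COLUMNS`).  The four compulsory fields are
        validated; a named validation error identifies the first missing
        one.
        """
        if center_id not in self.centers:
            raise NotFoundError(f"unknown center {center_id!r}")
        self._require_admin(actor, center_id)
        for column, label in _COMPULSORY.items():
            if not str(manifest_row.get(column, "")).strip():
                raise ValidationError(f"missing compulsory field: {label}")
        local_name = manifest_row["SampleLocalName"].strip()
        sample_type = manifest_row["SampleType"].strip()
        if sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"Sample Type must be one of {sorted(SAMPLE_TYPES)}, "
                f"got {sample_type!r}")
        key = (center_id, local_name)
        if key in self._by_local:
            raise ConflictError(
                f"sample {local_name!r} already registered at {center_id!r}")
        counter = self._counters.get(center_id, 0) + 1
        self._counters[center_id] = counter
        system_id = make_pseudonym(center_id, counter, self.salt)
        while system_id in self.samples or system_id == local_name:
            counter += 1
            self._counters[center_id] = counter
            system_id = make_pseudonym(center_id, counter, self.salt)
        record = SampleRecord(
            sample_local_name=local_name,
            pi_name=manifest_row["PIName"].strip(),
            sample_type=sample_type,
            reference_build=manifest_row["SampleReferenceVersion"].strip(),
            center_id=center_id,
            system_sample_id=system_id,
            data_path=str(manifest_row.get("DataPath", "")).strip(),
        )
        self.samples[system_id] = record
        self._by_local[key] = system_id
        self._pi_dataset(record.pi_name).member_sample_ids.add(system_id)
        self.audit.append(actor, "register_sample",
                          {"center_id": center_id, "system_id": system_id})
        return record

    def register_manifest(self, actor: str, center_id: str,
                          manifest_path: str | Path) -> list[SampleRecord]:
        """Load a header-bearing TSV manifest and register every row."""
        records = []
        with open(manifest_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                records.append(self.register_sample(actor, center_id, row))
        return records

    def _pi_dataset(self, pi_name: str) -> Dataset:
        """Implicit per-PI dataset collecting that PI's samples."""
        dataset_id = f"pi::{pi_name}"
        if dataset_id not in self.datasets:
            self.datasets[dataset_id] = Dataset(
                dataset_id=dataset_id,
                name=f"{pi_name} samples",
                owner_user_id=pi_name,
            )
            if pi_name in self.users:
                self.users[pi_name].accessible_dataset_ids.add(dataset_id)
        return self.datasets[dataset_id]

    def sample_by_local_name(self, center_id: str, local_name: str) -> SampleRecord:
        try:
            return self.samples[self._by_local[(center_id, local_name)]]
        except KeyError:
            raise NotFoundError(
                f"no sample {local_name!r} at center {center_id!r}") from None

    # -- datasets ---------------------------------------------------------

    def create_dataset(self, actor: str, dataset_id: str, name: str,
                       visibility: str = "private",
                       is_control: bool = False) -> Dataset:
        if dataset_id in self.datasets:
            raise ConflictError(f"dataset {dataset_id!r} already exists")
        if visibility not in ("private", "public"):
            raise ValidationError("visibility must be 'private' or 'public'")
        if actor not in self.users:
            raise NotFoundError(f"unknown user {actor!r}")
        ds = Dataset(dataset_id, name, actor, visibility, set(), is_control)
        self.datasets[dataset_id] = ds
        self.users[actor].accessible_dataset_ids.add(dataset_id)
        self.audit.append(actor, "create_dataset", {"dataset_id": dataset_id})
        return ds

    def add_to_dataset(self, actor: str, dataset_id: str,
                       system_sample_id: str) -> None:
        ds = self._dataset(dataset_id)
        if system_sample_id not in self.samples:
            raise NotFoundError(f"unknown sample {system_sample_id!r}")
        sample = self.samples[system_sample_id]
        user = self.users.get(actor)
        allowed = (
            user is not None and user.role == "system_admin"
            or actor == ds.owner_user_id and (
                actor == sample.pi_name
                or system_sample_id in (user.granted_sample_ids if user else ()))
        )
        if not allowed:
            raise AuthorizationError(
                f"user {actor!r} may not assign sample {system_sample_id!r} "
                f"to dataset {dataset_id!r}")
        ds.member_sample_ids.add(system_sample_id)
        self.audit.append(actor, "add_to_dataset",
                          {"dataset_id": dataset_id, "sample": system_sample_id})

    def grant_dataset_access(self, actor: str, dataset_id: str,
                             user_id: str) -> None:
        ds = self._dataset(dataset_id)
        actor_user = self.users.get(actor)
        if actor != ds.owner_user_id and (
                actor_user is None or actor_user.role != "system_admin"):
            raise AuthorizationError(
                f"only the owner or a system admin may share {dataset_id!r}")
        self._user(user_id).accessible_dataset_ids.add(dataset_id)
        self.audit.append(actor, "grant_dataset_access",
                          {"dataset_id": dataset_id, "user_id": user_id})

    def _dataset(self, dataset_id: str) -> Dataset:
        try:
            return self.datasets[dataset_id]
        except KeyError:
            raise NotFoundError(f"unknown dataset {dataset_id!r}") from None

    def _user(self, user_id: str) -> User:
        try:
            return self.users[user_id]
        except KeyError:
            raise NotFoundError(f"unknown user {user_id!r}") from None

    def accessible_datasets(self, user_id: str) -> set[str]:
        """Datasets the user may activate: explicit grants plus public ones."""
        user = self._user(user_id)
        public = {d.dataset_id for d in self.datasets.values()
                  if d.visibility == "public"}
        return user.accessible_dataset_ids | public

    # -- activation and tiers --------------------------------------------

    def activate_dataset(self, user_id: str, dataset_id: str) -> User:
        user = self._user(user_id)
        if dataset_id not in self.accessible_datasets(user_id):
            raise AuthorizationError(
                f"dataset {dataset_id!r} is not accessible to {user_id!r}")
        user.active_dataset_id = dataset_id
        self.audit.append(user_id, "activate_dataset",
                          {"dataset_id": dataset_id})
        return user

    def deactivate_dataset(self, user_id: str) -> User:
        user = self._user(user_id)
        user.active_dataset_id = None
        self.audit.append(user_id, "deactivate_dataset", None)
        return user

    def check_access(self, user_id: str, system_sample_id: str) -> str:
        """Tier for one (user, sample) pair: ``detailed`` or ``summary_only``.

        Detailed access requires the sample to be a member of the user's
        *currently active* dataset; everything else — including samples in
        accessible but non-active datasets — is summary-only.  Pure read.
        """
        user = self._user(user_id)
        if system_sample_id not in self.samples:
            raise NotFoundError(f"unknown sample {system_sample_id!r}")
        if user.active_dataset_id is None:
            return "summary_only"
        active = self._dataset(user.active_dataset_id)
        if system_sample_id in active.member_sample_ids:
            return "detailed"
        return "summary_only"

    # -- access requests --------------------------------------------------

    def request_access(self, user_id: str,
                       system_sample_id: str) -> AccessRequest:
        sample = self.samples.get(system_sample_id)
        if sample is None:
            raise NotFoundError(f"unknown sample {system_sample_id!r}")
        if user_id == sample.pi_name:
            raise ValidationError("owner cannot request access to own sample")
        key = (user_id, system_sample_id)
        existing = self.access_requests.get(key)
        if existing is not None and existing.status == "pending":
            return existing  # idempotent
        now = self._clock()
        req = AccessRequest(user_id, system_sample_id, "pending", now, now)
        self.access_requests[key] = req
        self.audit.append(user_id, "request_access",
                          {"sample": system_sample_id})
        return req

    def pending_requests_for(self, pi_name: str) -> list[AccessRequest]:
        return [r for r in self.access_requests.values()
                if r.status == "pending"
                and self.samples[r.system_sample_id].pi_name == pi_name]

    def resolve_access(self, owner: str, requester: str,
                       system_sample_id: str, grant: bool) -> AccessRequest:
        key = (requester, system_sample_id)
        req = self.access_requests.get(key)
        if req is None:
            raise NotFoundError("no such access request")
        sample = self.samples[system_sample_id]
        owner_user = self.users.get(owner)
        if owner != sample.pi_name and (
                owner_user is None or owner_user.role != "system_admin"):
            raise AuthorizationError(
                f"only {sample.pi_name!r} may resolve this request")
        req.status = "granted" if grant else "denied"
        req.updated_at = self._clock()
        if grant:
            self._user(requester).granted_sample_ids.add(system_sample_id)
        self.audit.append(owner, "resolve_access",
                          {"requester": requester, "sample": system_sample_id,
                           "granted": grant})
        return req

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "salt": self.salt,
            "centers": [
                {**vars(c), "local_admins": sorted(c.local_admins)}
                for c in self.centers.values()
            ],
            "users": [
                {**vars(u),
                 "accessible_dataset_ids": sorted(u.accessible_dataset_ids),
                 "granted_sample_ids": sorted(u.granted_sample_ids)}
                for u in self.users.values()
            ],
            "samples": [vars(s) for s in self.samples.values()],
            "datasets": [
                {**vars(d), "member_sample_ids": sorted(d.member_sample_ids)}
                for d in self.datasets.values()
            ],
            "access_requests": [vars(r) for r in self.access_requests.values()],
            "counters": dict(self._counters),
        }

    @classmethod
    def from_dict(cls, data: dict, **kwargs) -> "Registry":
        reg = cls(salt=data.get("salt", "fedvar"), **kwargs)
        for c in data.get("centers", []):
            reg.centers[c["center_id"]] = Center(
                c["center_id"], c["name"], set(c["local_admins"]),
                c["data_root"], c["build_default"])
        for u in data.get("users", []):
            reg.users[u["user_id"]] = User(
                u["user_id"], u["role"], u.get("center_id"),
                set(u.get("accessible_dataset_ids", [])),
                u.get("active_dataset_id"),
                set(u.get("granted_sample_ids", [])))
        for s in data.get("samples", []):
            rec = SampleRecord(**s)
            reg.samples[rec.system_sample_id] = rec
            reg._by_local[(rec.center_id, rec.sample_local_name)] = \
                rec.system_sample_id
        for d in data.get("datasets", []):
            reg.datasets[d["dataset_id"]] = Dataset(
                d["dataset_id"], d["name"], d["owner_user_id"],
                d.get("visibility", "private"),
                set(d.get("member_sample_ids", [])),
                d.get("is_control", False))
        for r in data.get("access_requests", []):
            req = AccessRequest(**r)
            reg.access_requests[(req.requester_user_id,
                                 req.system_sample_id)] = req
        reg._counters = dict(data.get("counters", {}))
        return reg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "Registry":
        return cls.from_dict(json.loads(Path(path).read_text()), **kwargs)
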