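"""File-backed version control for engineered cell lines.

A :class:`Store` is a directory of repositories; each repository is a branch
set plus an append-only commit graph.  Commits carry the strain-engineering
record (genotype/phenotype notes, storage location, safety and MTA notes,
content-hashed attachments) and an optional DNA barcode whose payload is the
commit's unique identifier, so a sequenced strain can be traced back to its
full digital history.

Layout (all JSON canonical: sorted keys, LF, trailing newline — so digests
and diffs are stable and a save/load/save cycle is byte-identical)::

    <root>/authors.json
    <root>/<repo_id>/repo.json
    <root>/<repo_id>/commits/<uid>.json
    <root>/<repo_id>/attachments/<digest>

Identifiers are 40-bit random values rendered as 8 Crockford base-32
characters — short enough to quote on a tube label, wide enough that the
store-level collision check never has real work to do.  Branches are named
pointers with an origin commit; every commit has at most one parent and
merging is deliberately unsupported.

Visibility (``public`` / ``team`` / ``private``) is advisory in a local
store: there is no authentication, the caller identity is simply a parameter
to :meth:`Store.search`.
"""

from __future__ import annotations

import hashlib
import random
import re
import shutil
import tarfile
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable

from . import codec
from .util import dump_canonical_json, uid_to_str
import json

__all__ = [
    "Author",
    "Attachment",
    "Commit",
    "Branch",
    "Repository",
    "Store",
    "StoreError",
    "VISIBILITIES",
]

VISIBILITIES = ("public", "team", "private")

UID_BITS = 40
_DNA_QUERY_RE = re.compile(r"^[ACGTacgt]+$")


class StoreError(ValueError):
    """Domain error raised by store operations (duplicate names, unknown ids...)."""


@dataclass
class Author:
    author_id: str
    display_name: str
    email: str

    def __post_init__(self) -> None:
        if not self.author_id:
            raise StoreError("author_id must be non-empty")
        if not self.email:
            raise StoreError("author email must be non-empty")


@dataclass
class Attachment:
    filename: str
    media_hint: str
    digest: str
    size_bytes: int


@dataclass
class Commit:
    uid: str
    parent: str | None
    author_id: str
    timestamp: str
    title: str
    description: str = ""
    genotype_notes: str = ""
    phenotype_notes: str = ""
    storage_location: str = ""
    safety_notes: str = ""
    mta_notes: str = ""
    attachments: list[Attachment] = field(default_factory=list)
    barcode: dict | None = None  # {"insert", "cassette", "seed_used", "spec_digest"}

    @property
    def barcode_ref(self) -> str | None:
        return self.barcode["insert"] if self.barcode else None


@dataclass
class Branch:
    name: str
    origin: str | None  # commit uid; None only for the root branch
    commits: list[str] = field(default_factory=list)

    @property
    def tip(self) -> str | None:
        return self.commits[-1] if self.commits else None


@dataclass
class Repository:
    repo_id: str
    name: str
    description: str
    species: dict  # {"name": ..., "taxon_ref": ...}
    visibility: str
    leader_branch: str
    owner: str
    branches: dict[str, Branch] = field(default_factory=dict)
    team: list[str] = field(default_factory=list)
    created_at: str = ""

    def visible_to(self, caller: str | None) -> bool:
        if self.visibility == "public":
            return True
        if caller is None:
            return False
        if caller == self.owner:
            return True
        return self.visibility == "team" and caller in self.team


class Store:
    """A directory-backed collection of strain repositories.

    ``rng`` and ``clock`` are injectable for deterministic tests; by default
    identifiers come from a fresh :class:`random.Random` and timestamps from
    the UTC wall clock (ISO-8601, seconds precision).
    """

    def __init__(
        self,
        root: str | Path,
        barcode_spec: codec.BarcodeSpec | None = None,
        rng: random.Random | None = None,
        clock: Callable[[], datetime] | None = None,
        min_dna_query_len: int = 12,
    ) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.barcode_spec = barcode_spec or codec.BarcodeSpec()
        self.rng = rng or random.Random()
        self.clock = clock or (lambda: datetime.now(timezone.utc))
        self.min_dna_query_len = min_dna_query_len
        self.authors: dict[str, Author] = {}
        self._repos: dict[str, Repository] = {}
        self._commits: dict[str, tuple[str, Commit]] = {}  # uid -> (repo_id, commit)
        self._load()

    # -- persistence --------------------------------------------------------

    def _load(self) -> None:
        authors_path = self.root / "authors.json"
        if authors_path.exists():
            data = json.loads(authors_path.read_text())
            self.authors = {k: Author(**v) for k, v in data.items()}
        for repo_dir in sorted(p for p in self.root.iterdir() if p.is_dir()):
            repo_json = repo_dir / "repo.json"
            if not repo_json.exists():
                continue
            raw = json.loads(repo_json.read_text())
            branches = {
                name: Branch(**b) for name, b in raw.pop("branches").items()
            }
            repo = Repository(branches=branches, **raw)
            self._repos[repo.repo_id] = repo
            commits_dir = repo_dir / "commits"
            if commits_dir.exists():
                for cpath in sorted(commits_dir.glob("*.json")):
                    c = json.loads(cpath.read_text())
                    c["attachments"] = [Attachment(**a) for a in c["attachments"]]
                    commit = Commit(**c)
                    if commit.uid in self._commits:
                        raise StoreError(f"duplicate commit uid {commit.uid} on load")
                    self._commits[commit.uid] = (repo.repo_id, commit)
        self._verify()

    def _verify(self) -> None:
        """Invariant check on every load: single parent, acyclic ancestry."""
        for uid, (_, commit) in self._commits.items():
            seen = {uid}
            cur = commit
            while cur.parent is not None:
                if cur.parent in seen:
                    raise StoreError(f"commit graph cycle through {cur.parent}")
                if cur.parent not in self._commits:
                    raise StoreError(f"commit {cur.uid} has unknown parent {cur.parent}")
                seen.add(cur.parent)
                cur = self._commits[cur.parent][1]

    def _save_authors(self) -> None:
        dump_canonical_json(
            {k: asdict(v) for k, v in sorted(self.authors.items())},
            self.root / "authors.json",
        )

    def _save_repo(self, repo: Repository) -> None:
        d = asdict(repo)
        (self.root / repo.repo_id).mkdir(exist_ok=True)
        dump_canonical_json(d, self.root / repo.repo_id / "repo.json")

    def _save_commit(self, repo_id: str, commit: Commit) -> None:
        cdir = self.root / repo_id / "commits"
        cdir.mkdir(parents=True, exist_ok=True)
        dump_canonical_json(asdict(commit), cdir / f"{commit.uid}.json")

    # -- identifiers --------------------------------------------------------

    def _fresh_uid(self) -> str:
        while True:
            uid = uid_to_str(self.rng.getrandbits(UID_BITS), UID_BITS)
            if uid not in self._commits:
                return uid

    def _fresh_repo_id(self) -> str:
        while True:
            rid = "R" + uid_to_str(self.rng.getrandbits(UID_BITS), UID_BITS)
            if rid not in self._repos:
                return rid

    def _now(self) -> str:
        return self.clock().replace(microsecond=0).isoformat()

    # -- operations ---------------------------------------------------------

    def register_author(self, author: Author) -> Author:
        self.authors[author.author_id] = author
        self._save_authors()
        return author

    def init_repository(
        self,
        name: str,
        description: str,
        species: dict,
        visibility: str,
        leader_branch_name: str = "main",
        owner: str = "",
    ) -> Repository:
        """Create and persist a repository with one empty leader branch."""
        if not name:
            raise StoreError("repository name must be non-empty")
        if visibility not in VISIBILITIES:
            raise StoreError(
                f"invalid visibility {visibility!r}; expected one of {VISIBILITIES}"
            )
        if any(r.name == name for r in self._repos.values()):
            raise StoreError(f"a repository named {name!r} already exists in this store")
        repo = Repository(
            repo_id=self._fresh_repo_id(),
            name=name,
            description=description,
            species=dict(species),
            visibility=visibility,
            leader_branch=leader_branch_name,
            owner=owner,
            branches={leader_branch_name: Branch(name=leader_branch_name, origin=None)},
            created_at=self._now(),
        )
        self._repos[repo.repo_id] = repo
        self._save_repo(repo)
        return repo

    def get_repository(self, repo_id: str) -> Repository:
        try:
            return self._repos[repo_id]
        except KeyError:
            raise StoreError(f"unknown repository {repo_id!r}") from None

    def list_repositories(self) -> list[Repository]:
        return sorted(self._repos.values(), key=lambda r: r.repo_id)

    def new_commit(
        self,
        repo: Repository | str,
        branch: str,
        author: Author | str,
        title: str,
        description: str = "",
        genotype_notes: str = "",
        phenotype_notes: str = "",
        storage_location: str = "",
        safety_notes: str = "",
        mta_notes: str = "",
        attachments: Iterable[str | Path] = (),
        request_barcode: bool = False,
    ) -> Commit:
        """Append a commit to a branch; optionally mint a milestone barcode.

        The barcode payload is the commit's own 40-bit identifier, so
        ``codec.decode(commit.barcode["insert"]) == commit.uid`` always holds.
        """
        repo = self._repos[repo] if isinstance(repo, str) else repo
        if branch not in repo.branches:
            raise StoreError(f"unknown branch {branch!r} in repository {repo.name!r}")
        if isinstance(author, Author):
            self.authors.setdefault(author.author_id, author)
            self._save_authors()
            author_id = author.author_id
        else:
            author_id = author
        br = repo.branches[branch]
        parent = br.tip if br.tip is not None else br.origin
        uid = self._fresh_uid()
        stored_attachments = [self._store_attachment(repo, p) for p in attachments]
        barcode = None
        if request_barcode:
            bc = codec.encode(int(_uid_value(uid)), self.barcode_spec)
            barcode = {
                "insert": bc.insert,
                "cassette": bc.cassette,
                "seed_used": bc.seed_used,
                "spec_digest": bc.spec_digest,
            }
        commit = Commit(
            uid=uid,
            parent=parent,
            author_id=author_id,
            timestamp=self._now(),
            title=title,
            description=description,
            genotype_notes=genotype_notes,
            phenotype_notes=phenotype_notes,
            storage_location=storage_location,
            safety_notes=safety_notes,
            mta_notes=mta_notes,
            attachments=stored_attachments,
            barcode=barcode,
        )
        br.commits.append(uid)
        self._commits[uid] = (repo.repo_id, commit)
        self._save_commit(repo.repo_id, commit)
        self._save_repo(repo)
        return commit

    def _store_attachment(self, repo: Repository, path: str | Path) -> Attachment:
        path = Path(path)
        try:
            data = path.read_bytes()
        except OSError as exc:
            raise StoreError(f"attachment {path} unreadable: {exc}") from exc
        digest = hashlib.sha256(data).hexdigest()
        adir = self.root / repo.repo_id / "attachments"
        adir.mkdir(parents=True, exist_ok=True)
        target = adir / digest
        if not target.exists():
            target.write_bytes(data)
        return Attachment(
            filename=path.name,
            media_hint=path.suffix.lstrip(".").lower(),
            digest=digest,
            size_bytes=len(data),
        )

    def new_branch(
        self, repo: Repository | str, from_commit_uid: str, branch_name: str
    ) -> Branch:
        repo = self._repos[repo] if isinstance(repo, str) else repo
        if branch_name in repo.branches:
            raise StoreError(f"branch {branch_name!r} already exists")
        if from_commit_uid not in self._commits:
            raise StoreError(f"unknown commit {from_commit_uid!r}")
        br = Branch(name=branch_name, origin=from_commit_uid)
        repo.branches[branch_name] = br
        self._save_repo(repo)
        return br

    def get_commit(self, uid: str) -> Commit:
        try:
            return self._commits[uid][1]
        except KeyError:
            raise StoreError(f"unknown commit {uid!r}") from None

    def state_at(self, repo: Repository | str, commit_uid: str) -> list[Commit]:
        """Full history root → target, following parent links across branches."""
        if commit_uid not in self._commits:
            raise StoreError(f"unknown commit {commit_uid!r}")
        chain: list[Commit] = []
        cur: str | None = commit_uid
        while cur is not None:
            commit = self._commits[cur][1]
            chain.append(commit)
            cur = commit.parent
        chain.reverse()
        return chain

    def set_visibility(self, repo: Repository | str, visibility: str) -> Repository:
        repo = self._repos[repo] if isinstance(repo, str) else repo
        if visibility not in VISIBILITIES:
            raise StoreError(f"invalid visibility {visibility!r}")
        repo.visibility = visibility
        self._save_repo(repo)
        return repo

    def add_team_member(self, repo: Repository | str, author_id: str) -> Repository:
        repo = self._repos[repo] if isinstance(repo, str) else repo
        if author_id not in repo.team:  # idempotent
            repo.team.append(author_id)
            self._save_repo(repo)
        return repo

    # -- search -------------------------------------------------------------

    def search(
        self,
        query: str,
        caller: str | None = None,
        max_mismatch: int = 2,
    ) -> list[dict]:
        """Keyword or barcode search over repositories visible to ``caller``.

        A query that is pure ACGT of at least ``min_dna_query_len`` bases is
        treated as a DNA search against stored barcode inserts (exact and
        near matches up to ``max_mismatch`` substitutions; a query longer or
        shorter than an insert is slid over the longer sequence and the best
        offset counts).  Anything else is a case-insensitive substring search
        over repository names/descriptions and commit titles/descriptions.
        """
        dna_mode = (
            _DNA_QUERY_RE.match(query) is not None
            and len(query) >= self.min_dna_query_len
        )
        hits: list[dict] = []
        for repo in self.list_repositories():
            if not repo.visible_to(caller):
                continue
            if dna_mode:
                for uid in _repo_commit_uids(repo):
                    commit = self._commits[uid][1]
                    if not commit.barcode:
                        continue
                    dist = _best_substitution_distance(
                        query.upper(), commit.barcode["insert"]
                    )
                    if dist <= max_mismatch:
                        hits.append(
                            {"repo": repo, "commit": commit, "distance": dist}
                        )
            else:
                q = query.lower()
                if q in repo.name.lower() or q in repo.description.lower():
                    hits.append({"repo": repo, "commit": None, "distance": None})
                for uid in _repo_commit_uids(repo):
                    commit = self._commits[uid][1]
                    if q in commit.title.lower() or q in commit.description.lower():
                        hits.append({"repo": repo, "commit": commit, "distance": None})
        if dna_mode:
            hits.sort(key=lambda h: (h["distance"], h["repo"].repo_id, h["commit"].uid))
        return hits

    # -- archive ------------------------------------------------------------

    def export_archive(self, archive_path: str | Path) -> Path:
        """Export the store tree, contents unmodified, as a tar archive."""
        archive_path = Path(archive_path)
        with tarfile.open(archive_path, "w") as tar:
            for path in sorted(self.root.rglob("*")):
                tar.add(path, arcname=str(path.relative_to(self.root)), recursive=False)
        return archive_path

    @classmethod
    def import_archive(cls, archive_path: str | Path, root: str | Path, **kwargs) -> "Store":
        root = Path(root)
        if root.exists() and any(root.iterdir()):
            raise StoreError(f"import target {root} is not empty")
        root.mkdir(parents=True, exist_ok=True)
        with tarfile.open(archive_path) as tar:
            tar.extractall(root, filter="data")
        return cls(root, **kwargs)

    def delete(self) -> None:
        shutil.rmtree(self.root)


# ---------------------------------------------------------------------------

def _uid_value(uid: str) -> int:
    from .util import str_to_uid

    return str_to_uid(uid)


def _repo_commit_uids(repo: Repository) -> list[str]:
    uids: list[str] = []
    for name in sorted(repo.branches):
        uids.extend(repo.branches[name].commits)
    return uids


def _best_substitution_distance(query: str, insert: str) -> int:
    """Hamming distance at the best ungapped offset of the shorter in the longer."""
    short, long_ = (query, insert) if len(query) <= len(insert) else (insert, query)
    best = len(short)
    for off in range(len(long_) - len(short) + 1):
        d = sum(1 for a, b in zip(short, long_[off : off + len(short)]) if a != b)
        best = min(best, d)
        if best == 0:
            break
    return best
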