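"""Persistence for genomes, taxonomy, schemes, LINs and ANI records.

The store is a directory holding an embedded SQLite database plus a
signature file tree::

    <root>/linforge.sqlite
    <root>/signatures/representatives/<genome_id>.json
    <root>/signatures/groups/<group-prefix>/<genome_id>.json

The relational schema mirrors the pipeline's data model: a ``genome`` table
with file locations and insertion order, a ``taxonomy`` table, a ``scheme``
table of LIN scheme definitions, a ``lin`` table of assignments, and an
``ani`` table holding the single precise ANI computation recorded for each
genome added after the first. Each grouping-level LINgroup (by default the
95%-ANI prefix) owns one directory of member signatures; the first member by
insertion order is the group's representative and its signature is copied to
the representatives directory.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
import warnings
from dataclasses import dataclass
from pathlib import Path

from .scheme import LINScheme, get_scheme, scheme_from_config, BUILTIN_SCHEME_NAMES
from .sketch import Signature, load_signature_set, save_signature_set

DB_FILENAME = "linforge.sqlite"
DEFAULT_GROUP_ANI = 95.0

_SCHEMA = """
CREATE TABLE IF NOT EXISTS genome (
    genome_id TEXT PRIMARY KEY,
    fasta_path TEXT NOT NULL,
    checksum TEXT NOT NULL,
    insertion_order INTEGER NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS taxonomy (
    genome_id TEXT PRIMARY KEY REFERENCES genome(genome_id),
    info TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS scheme (
    name TEXT PRIMARY KEY,
    definition TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS lin (
    genome_id TEXT NOT NULL REFERENCES genome(genome_id),
    scheme_name TEXT NOT NULL REFERENCES scheme(name),
    lin TEXT NOT NULL,
    PRIMARY KEY (genome_id, scheme_name)
);
CREATE TABLE IF NOT EXISTS ani (
    query_id TEXT PRIMARY KEY REFERENCES genome(genome_id),
    subject_id TEXT NOT NULL REFERENCES genome(genome_id),
    ani REAL NOT NULL,
    created_order INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS reservation (
    scheme_name TEXT NOT NULL,
    prefix TEXT NOT NULL,
    position INTEGER NOT NULL,
    number INTEGER NOT NULL,
    PRIMARY KEY (scheme_name, prefix, position, number)
);
CREATE TABLE IF NOT EXISTS meta (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
"""


def lin_to_text(lin: list[int]) -> str:
    return ",".join(str(v) for v in lin)


def lin_from_text(text: str) -> list[int]:
    return [int(v) for v in text.split(",")]


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    fasta_path: str
    insertion_order: int


@dataclass(frozen=True)
class ANIRecord:
    query_id: str
    subject_id: str
    ani: float
    created_order: int


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Store:
    """Single-writer transactional store for one LINflow-style dataset."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        db = self.root / DB_FILENAME
        if not db.exists():
            raise FileNotFoundError(f"no store at {self.root} (missing {DB_FILENAME})")
        self._conn = sqlite3.connect(db)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._schemes: dict[str, LINScheme] = {}

    # -- lifecycle -----------------------------------------------------------

    @classmethod
    def create(
        cls,
        root: str | Path,
        scheme_names: tuple[str, ...] = ("lin20",),
        custom_schemes: list[LINScheme] | None = None,
        group_ani: float = DEFAULT_GROUP_ANI,
        force: bool = False,
    ) -> "Store":
        """Initialize an empty store; ``lin20`` is always registered."""
        root = Path(root)
        db = root / DB_FILENAME
        if db.exists() and not force:
            raise FileExistsError(f"store already exists at {root}; pass force=True to recreate")
        root.mkdir(parents=True, exist_ok=True)
        if db.exists():
            db.unlink()
        conn = sqlite3.connect(db)
        conn.executescript(_SCHEMA)
        names = list(dict.fromkeys(("lin20", *scheme_names)))
        with conn:
            for name in names:
                if name not in BUILTIN_SCHEME_NAMES:
                    raise KeyError(f"unknown built-in scheme {name!r}")
                conn.execute(
                    "INSERT INTO scheme (name, definition) VALUES (?, ?)",
                    (name, json.dumps({"builtin": name})),
                )
            for sch in custom_schemes or []:
                names.append(sch.name)
                conn.execute(
                    "INSERT INTO scheme (name, definition) VALUES (?, ?)",
                    (sch.name, json.dumps({"name": sch.name,
                                           "thresholds": list(sch.thresholds)})),
                )
            conn.execute("INSERT INTO meta VALUES ('active_schemes', ?)", (json.dumps(names),))
            conn.execute("INSERT INTO meta VALUES ('group_ani', ?)", (json.dumps(group_ani),))
        conn.close()
        store = cls(root)
        (store.signatures_dir / "representatives").mkdir(parents=True, exist_ok=True)
        (store.signatures_dir / "groups").mkdir(parents=True, exist_ok=True)
        return store

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- config --------------------------------------------------------------

    @property
    def signatures_dir(self) -> Path:
        return self.root / "signatures"

    def _meta(self, key: str):
        row = self._conn.execute("SELECT value FROM meta WHERE key = ?", (key,)).fetchone()
        return json.loads(row[0]) if row else None

    @property
    def active_schemes(self) -> list[str]:
        return self._meta("active_schemes")

    @property
    def group_ani(self) -> float:
        return float(self._meta("group_ani"))

    @property
    def grouping_scheme(self) -> LINScheme:
        """Scheme whose prefixes define the signature-group layout (first active)."""
        return self.get_scheme(self.active_schemes[0])

    def get_scheme(self, name: str) -> LINScheme:
        if name not in self._schemes:
            row = self._conn.execute(
                "SELECT definition FROM scheme WHERE name = ?", (name,)
            ).fetchone()
            if row is None:
                raise KeyError(f"scheme {name!r} not registered in this store")
            doc = json.loads(row[0])
            if "builtin" in doc:
                self._schemes[name] = get_scheme(doc["builtin"])
            else:
                self._schemes[name] = scheme_from_config(doc)
        return self._schemes[name]

    def group_depth(self, scheme: LINScheme | None = None) -> int:
        """Prefix length defining the grouping-level LINgroup (ANI >= group_ani)."""
        scheme = scheme or self.grouping_scheme
        return scheme.shared_depth(self.group_ani)

    # -- genomes & taxonomy ---------------------------------------------------

    def register_genome(
        self,
        fasta_path: str | Path,
        taxonomy: dict | None = None,
        genome_id: str | None = None,
    ) -> GenomeRecord:
        """Persist a genome with the next insertion order.

        Re-registering the same file (identical path and checksum) is
        idempotent: the existing record is returned with a warning.
        """
        fasta_path = Path(fasta_path)
        if not fasta_path.is_file() or fasta_path.stat().st_size == 0:
            raise FileNotFoundError(f"unreadable or empty FASTA: {fasta_path}")
        checksum = _checksum(fasta_path)
        genome_id = genome_id or fasta_path.stem
        row = self._conn.execute(
            "SELECT genome_id, fasta_path, checksum, insertion_order FROM genome "
            "WHERE genome_id = ?",
            (genome_id,),
        ).fetchone()
        if row is not None:
            if row[2] == checksum and Path(row[1]) == fasta_path:
                warnings.warn(f"genome {genome_id!r} already registered; returning existing record")
                return GenomeRecord(row[0], row[1], row[3])
            raise ValueError(f"genome id {genome_id!r} already used by a different file")
        order = self.genome_count() + 1
        with self._conn:
            self._conn.execute(
                "INSERT INTO genome (genome_id, fasta_path, checksum, insertion_order) "
                "VALUES (?, ?, ?, ?)",
                (genome_id, str(fasta_path), checksum, order),
            )
            if taxonomy:
                self._conn.execute(
                    "INSERT INTO taxonomy (genome_id, info) VALUES (?, ?)",
                    (genome_id, json.dumps(taxonomy)),
                )
        return GenomeRecord(genome_id, str(fasta_path), order)

    def genome_count(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM genome").fetchone()[0]

    def genomes(self) -> list[GenomeRecord]:
        rows = self._conn.execute(
            "SELECT genome_id, fasta_path, insertion_order FROM genome ORDER BY insertion_order"
        ).fetchall()
        return [GenomeRecord(*r) for r in rows]

    def genome(self, genome_id: str) -> GenomeRecord:
        row = self._conn.execute(
            "SELECT genome_id, fasta_path, insertion_order FROM genome WHERE genome_id = ?",
            (genome_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"unknown genome {genome_id!r}")
        return GenomeRecord(*row)

    def taxonomy(self, genome_id: str) -> dict | None:
        row = self._conn.execute(
            "SELECT info FROM taxonomy WHERE genome_id = ?", (genome_id,)
        ).fetchone()
        return json.loads(row[0]) if row else None

    # -- LINs ------------------------------------------------------------------

    def save_lin(self, genome_id: str, scheme_name: str, lin: list[int]) -> None:
        scheme = self.get_scheme(scheme_name)
        if len(lin) != len(scheme):
            raise ValueError(
                f"LIN length {len(lin)} does not match scheme {scheme_name!r} ({len(scheme)})"
            )
        with self._conn:
            self._conn.execute(
                "INSERT INTO lin (genome_id, scheme_name, lin) VALUES (?, ?, ?)",
                (genome_id, scheme_name, lin_to_text(lin)),
            )

    def get_lin(self, genome_id: str, scheme_name: str) -> list[int]:
        row = self._conn.execute(
            "SELECT lin FROM lin WHERE genome_id = ? AND scheme_name = ?",
            (genome_id, scheme_name),
        ).fetchone()
        if row is None:
            raise KeyError(f"no LIN for genome {genome_id!r} under scheme {scheme_name!r}")
        return lin_from_text(row[0])

    def lins(self, scheme_name: str) -> dict[str, list[int]]:
        rows = self._conn.execute(
            "SELECT l.genome_id, l.lin FROM lin l JOIN genome g ON g.genome_id = l.genome_id "
            "WHERE l.scheme_name = ? ORDER BY g.insertion_order",
            (scheme_name,),
        ).fetchall()
        return {gid: lin_from_text(text) for gid, text in rows}

    def allocate_number(self, scheme: LINScheme, prefix: list[int], position: int) -> int:
        """Smallest non-negative integer unused at ``position`` under ``prefix``.

        The returned number is reserved in the same transaction, so repeated
        calls before any LIN is saved still hand out distinct numbers.
        """
        if position >= len(scheme):
            raise ValueError(f"position {position} outside scheme of length {len(scheme)}")
        if len(prefix) != position:
            raise ValueError(f"prefix length {len(prefix)} must equal position {position}")
        prefix_txt = lin_to_text(prefix) if prefix else ""
        used: set[int] = set()
        for (lin_txt,) in self._conn.execute(
            "SELECT lin FROM lin WHERE scheme_name = ?", (scheme.name,)
        ):
            lin = lin_from_text(lin_txt)
            if lin[:position] == prefix:
                used.add(lin[position])
        for (num,) in self._conn.execute(
            "SELECT number FROM reservation WHERE scheme_name = ? AND prefix = ? AND position = ?",
            (scheme.name, prefix_txt, position),
        ):
            used.add(num)
        number = 0
        while number in used:
            number += 1
        with self._conn:
            self._conn.execute(
                "INSERT INTO reservation (scheme_name, prefix, position, number) "
                "VALUES (?, ?, ?, ?)",
                (scheme.name, prefix_txt, position, number),
            )
        return number

    # -- LINgroups, representatives, signatures --------------------------------

    def members_of(self, prefix: list[int], scheme_name: str | None = None) -> list[str]:
        """Genomes whose LIN starts with ``prefix``, in insertion order."""
        scheme_name = scheme_name or self.grouping_scheme.name
        p = len(prefix)
        return [
            gid for gid, lin in self.lins(scheme_name).items() if lin[:p] == list(prefix)
        ]

    def group_prefix_of(self, genome_id: str) -> list[int]:
        depth = self.group_depth()
        return self.get_lin(genome_id, self.grouping_scheme.name)[:depth]

    def representatives(self) -> list[str]:
        """First member (by insertion order) of each grouping-level LINgroup."""
        depth = self.group_depth()
        seen: set[tuple[int, ...]] = set()
        reps: list[str] = []
        for gid, lin in self.lins(self.grouping_scheme.name).items():
            key = tuple(lin[:depth])
            if key not in seen:
                seen.add(key)
                reps.append(gid)
        return reps

    def _group_dir(self, prefix: list[int]) -> Path:
        return self.signatures_dir / "groups" / "_".join(str(v) for v in prefix)

    def save_member_signature(self, genome_id: str, sigs: dict[int, Signature]) -> None:
        """File the genome's signatures in its LINgroup directory; promote a
        copy to the representatives directory when it founds a new group."""
        prefix = self.group_prefix_of(genome_id)
        gdir = self._group_dir(prefix)
        is_new_group = not gdir.exists()
        gdir.mkdir(parents=True, exist_ok=True)
        save_signature_set(sigs, gdir / f"{genome_id}.json")
        if is_new_group:
            save_signature_set(sigs, self.signatures_dir / "representatives" / f"{genome_id}.json")

    def load_member_signatures(self, genome_id: str) -> dict[int, Signature]:
        path = self._group_dir(self.group_prefix_of(genome_id)) / f"{genome_id}.json"
        return load_signature_set(path)

    def representative_signatures(self) -> dict[str, dict[int, Signature]]:
        out = {}
        for gid in self.representatives():
            path = self.signatures_dir / "representatives" / f"{gid}.json"
            out[gid] = load_signature_set(path)
        return out

    # -- ANI records -----------------------------------------------------------

    def record_ani(self, query_id: str, subject_id: str, ani: float) -> ANIRecord:
        order = self._conn.execute("SELECT COUNT(*) FROM ani").fetchone()[0] + 1
        with self._conn:
            self._conn.execute(
                "INSERT INTO ani (query_id, subject_id, ani, created_order) VALUES (?, ?, ?, ?)",
                (query_id, subject_id, ani, order),
            )
        return ANIRecord(query_id, subject_id, ani, order)

    def recorded_ani(self, query_id: str) -> ANIRecord | None:
        """The single precise ANI computation stored for this genome."""
        row = self._conn.execute(
            "SELECT query_id, subject_id, ani, created_order FROM ani WHERE query_id = ?",
            (query_id,),
        ).fetchone()
        return ANIRecord(*row) if row else None

    def ani_records(self) -> list[ANIRecord]:
        rows = self._conn.execute(
            "SELECT query_id, subject_id, ani, created_order FROM ani ORDER BY created_order"
        ).fetchall()
        return [ANIRecord(*r) for r in rows]

    # -- export ----------------------------------------------------------------

    def export_tables(self, out_dir: str | Path) -> None:
        """Dump every relational table as TSV."""
        import pandas as pd

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for table in ("genome", "taxonomy", "scheme", "lin", "ani"):
            df = pd.read_sql_query(f"SELECT * FROM {table}", self._conn)  # noqa: S608
            df.to_csv(out_dir / f"{table}.tsv", sep="\t", index=False)
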