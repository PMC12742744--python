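"""Event-driven local pipeline engine.

Reproduces the execution contract of a serverless deployment without any
cloud dependency: a submitted design job is broken into messages on four
queues (``genome_fetch``, ``index_build``, ``ontarget``, ``offtarget``),
each consumed in batches by stateless handlers that read everything from
the message and shared stores and persist results atomically per message.
Re-delivered messages are no-ops (idempotency keys), workers
checkpoint-and-requeue instead of overrunning their time budget, and no
worker runs while all queues are empty (scale-from-zero).

The job store, result store and queues live in a single SQLite file (or
in memory), a durable local binding of the pluggable storage contract;
handlers never touch it directly except through :class:`LocalStore`, so the
same handlers could bind to real queue/database services.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sqlite3
import threading
import time
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .config import PipelineConfig, WorkerLimits
from .genome_io import (
    GenomeAssembly,
    LocalFileFetcher,
    SequenceRecord,
    merge_portions,
    normalize_sequence,
    plan_chunked_fetch,
    read_fasta,
)
from .offtarget_index import ISSLIndex, OffTargetResult, SliceConfig, assess_offtarget, build_index
from .ontarget_consensus import evaluate
from .site_extraction import CandidateGuide, extract_candidates, genome_spacer_counts

logger = logging.getLogger("crisprdesk.orchestrator")

QUEUES = ("genome_fetch", "index_build", "ontarget", "offtarget")

_STATUS_ORDER = ("submitted", "preparing_genome", "indexing", "assessing", "complete")
_TERMINAL = {"complete", "failed"}


class OrchestratorError(RuntimeError):
    pass


class UnknownGenomeError(OrchestratorError):
    """Submission referenced a genome that is not registered."""


class UnknownJobError(OrchestratorError):
    """No job with the requested identifier."""


class StatusTransitionError(OrchestratorError):
    """Attempted to move a job backwards or out of a terminal state."""


@dataclass(frozen=True)
class Job:
    job_id: str
    gene_sequence: str
    genome_ref: str
    status: str
    created_at: float
    updated_at: float
    error: str | None
    total_candidates: int | None


@dataclass(frozen=True)
class TaskMessage:
    row_id: int
    message_id: str
    queue_name: str
    payload: dict
    delivery_count: int


@dataclass(frozen=True)
class ResultRecord:
    """One candidate locus with its (possibly partial) assessments."""

    job_id: str
    record_id: str
    start: int
    strand: str
    target23: str
    spacer20: str
    passes_g20: bool | None
    passes_composition: bool | None
    passes_structure: bool | None
    consensus_votes: int | None
    accepted: bool | None
    specificity: float | None
    neighbour_counts: dict[int, int] | None

    @property
    def both_complete(self) -> bool:
        return self.accepted is not None and self.specificity is not None


def _canonical(payload: dict) -> str:
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


class LocalStore:
    """Single-file durable store for jobs, queues, portions and results.

    All access is serialized through one lock; SQLite gives atomicity per
    statement and durability across CLI invocations.  ``:memory:`` gives a
    throwaway store for tests.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self._conn = sqlite3.connect(str(path), check_same_thread=False)
        self._conn.execute("PRAGMA journal_mode=MEMORY")
        self._conn.execute("PRAGMA synchronous=OFF")
        self._lock = threading.RLock()
        self._create_tables()

    def _create_tables(self) -> None:
        with self._lock, self._conn:
            self._conn.executescript(
                """
                CREATE TABLE IF NOT EXISTS jobs (
                    job_id TEXT PRIMARY KEY,
                    gene_sequence TEXT NOT NULL,
                    genome_ref TEXT NOT NULL,
                    status TEXT NOT NULL,
                    created_at REAL NOT NULL,
                    updated_at REAL NOT NULL,
                    error TEXT,
                    total_candidates INTEGER
                );
                CREATE TABLE IF NOT EXISTS genomes (
                    label TEXT PRIMARY KEY,
                    path TEXT NOT NULL,
                    total_bytes INTEGER,
                    expected_portions INTEGER
                );
                CREATE TABLE IF NOT EXISTS portions (
                    label TEXT NOT NULL,
                    start INTEGER NOT NULL,
                    end INTEGER NOT NULL,
                    data BLOB NOT NULL,
                    PRIMARY KEY (label, start, end)
                );
                CREATE TABLE IF NOT EXISTS messages (
                    row_id INTEGER PRIMARY KEY AUTOINCREMENT,
                    message_id TEXT NOT NULL,
                    queue_name TEXT NOT NULL,
                    payload TEXT NOT NULL,
                    delivery_count INTEGER NOT NULL DEFAULT 0,
                    state TEXT NOT NULL DEFAULT 'pending'
                );
                CREATE TABLE IF NOT EXISTS processed (
                    queue_name TEXT NOT NULL,
                    payload TEXT NOT NULL,
                    PRIMARY KEY (queue_name, payload)
                );
                CREATE TABLE IF NOT EXISTS results (
                    job_id TEXT NOT NULL,
                    record_id TEXT NOT NULL,
                    start INTEGER NOT NULL,
                    strand TEXT NOT NULL,
                    target23 TEXT NOT NULL,
                    spacer20 TEXT NOT NULL,
                    passes_g20 INTEGER,
                    passes_composition INTEGER,
                    passes_structure INTEGER,
                    consensus_votes INTEGER,
                    accepted INTEGER,
                    specificity REAL,
                    neighbour_counts TEXT,
                    PRIMARY KEY (job_id, record_id, start, strand)
                );
                """
            )

    # -- jobs --------------------------------------------------------------

    def create_job(self, job_id: str, gene_sequence: str, genome_ref: str) -> None:
        now = time.time()
        with self._lock, self._conn:
            self._conn.execute(
                "INSERT INTO jobs (job_id, gene_sequence, genome_ref, status,"
                " created_at, updated_at) VALUES (?,?,?,?,?,?)",
                (job_id, gene_sequence, genome_ref, "submitted", now, now),
            )

    def get_job(self, job_id: str) -> Job:
        with self._lock:
            row = self._conn.execute(
                "SELECT job_id, gene_sequence, genome_ref, status, created_at,"
                " updated_at, error, total_candidates FROM jobs WHERE job_id=?",
                (job_id,),
            ).fetchone()
        if row is None:
            raise UnknownJobError(f"unknown job: {job_id}")
        return Job(*row)

    def set_status(self, job_id: str, status: str, error: str | None = None) -> None:
        job = self.get_job(job_id)
        if job.status in _TERMINAL:
            if status == job.status:
                return
            raise StatusTransitionError(f"job {job_id} is terminal ({job.status})")
        if status == "failed":
            pass  # reachable from any non-terminal state
        elif _STATUS_ORDER.index(status) < _STATUS_ORDER.index(job.status):
            raise StatusTransitionError(
                f"cannot move job {job_id} from {job.status} back to {status}"
            )
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE jobs SET status=?, updated_at=?, error=? WHERE job_id=?",
                (status, time.time(), error, job_id),
            )

    def set_total_candidates(self, job_id: str, n: int) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE jobs SET total_candidates=?, updated_at=? WHERE job_id=?",
                (n, time.time(), job_id),
            )

    # -- genome registry and portions -------------------------------------

    def register_genome(self, label: str, path: str) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO genomes (label, path) VALUES (?,?)", (label, path)
            )

    def get_genome(self, label: str) -> tuple[str, int | None, int | None] | None:
        with self._lock:
            row = self._conn.execute(
                "SELECT path, total_bytes, expected_portions FROM genomes WHERE label=?",
                (label,),
            ).fetchone()
        return row

    def set_genome_plan(self, label: str, total_bytes: int, expected_portions: int) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE genomes SET total_bytes=?, expected_portions=? WHERE label=?",
                (total_bytes, expected_portions, label),
            )

    def put_portion(self, label: str, start: int, end: int, data: bytes) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "INSERT OR REPLACE INTO portions (label, start, end, data) VALUES (?,?,?,?)",
                (label, start, end, sqlite3.Binary(data)),
            )

    def portion_count(self, label: str) -> int:
        with self._lock:
            (n,) = self._conn.execute(
                "SELECT COUNT(*) FROM portions WHERE label=?", (label,)
            ).fetchone()
        return n

    def get_portions(self, label: str) -> list[tuple[tuple[int, int], bytes]]:
        with self._lock:
            rows = self._conn.execute(
                "SELECT start, end, data FROM portions WHERE label=? ORDER BY start", (label,)
            ).fetchall()
        return [((s, e), bytes(d)) for s, e, d in rows]

    def drop_portions(self, label: str) -> None:
        with self._lock, self._conn:
            self._conn.execute("DELETE FROM portions WHERE label=?", (label,))

    # -- queues ------------------------------------------------------------

    def enqueue(self, queue_name: str, payload: dict) -> str:
        message_id = uuid.uuid4().hex
        with self._lock, self._conn:
            self._conn.execute(
                "INSERT INTO messages (message_id, queue_name, payload) VALUES (?,?,?)",
                (message_id, queue_name, _canonical(payload)),
            )
        return message_id

    def pending_count(self, queue_name: str | None = None) -> int:
        with self._lock:
            if queue_name is None:
                (n,) = self._conn.execute(
                    "SELECT COUNT(*) FROM messages WHERE state='pending'"
                ).fetchone()
            else:
                (n,) = self._conn.execute(
                    "SELECT COUNT(*) FROM messages WHERE state='pending' AND queue_name=?",
                    (queue_name,),
                ).fetchone()
        return n

    def inflight_count(self) -> int:
        with self._lock:
            (n,) = self._conn.execute(
                "SELECT COUNT(*) FROM messages WHERE state='inflight'"
            ).fetchone()
        return n

    def receive(self, queue_name: str, max_messages: int) -> list[TaskMessage]:
        """Pop up to ``max_messages`` in FIFO order, incrementing delivery counts."""
        with self._lock, self._conn:
            rows = self._conn.execute(
                "SELECT row_id, message_id, payload, delivery_count FROM messages"
                " WHERE state='pending' AND queue_name=? ORDER BY row_id LIMIT ?",
                (queue_name, max_messages),
            ).fetchall()
            out = []
            for row_id, message_id, payload, dc in rows:
                self._conn.execute(
                    "UPDATE messages SET state='inflight', delivery_count=? WHERE row_id=?",
                    (dc + 1, row_id),
                )
                out.append(
                    TaskMessage(
                        row_id=row_id,
                        message_id=message_id,
                        queue_name=queue_name,
                        payload=json.loads(payload),
                        delivery_count=dc + 1,
                    )
                )
        return out

    def complete_message(self, msg: TaskMessage) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE messages SET state='done' WHERE row_id=?", (msg.row_id,)
            )

    def release_message(self, msg: TaskMessage) -> None:
        """Return an in-flight message to the queue (checkpoint or retry)."""
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE messages SET state='pending' WHERE row_id=?", (msg.row_id,)
            )

    def dead_letter(self, msg: TaskMessage) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE messages SET state='failed' WHERE row_id=?", (msg.row_id,)
            )

    def redeliver_done(self) -> int:
        """Re-enqueue a copy of every completed message (idempotency drills)."""
        with self._lock, self._conn:
            rows = self._conn.execute(
                "SELECT message_id, queue_name, payload, delivery_count FROM messages"
                " WHERE state='done'"
            ).fetchall()
            for message_id, queue_name, payload, dc in rows:
                self._conn.execute(
                    "INSERT INTO messages (message_id, queue_name, payload, delivery_count)"
                    " VALUES (?,?,?,?)",
                    (message_id, queue_name, payload, dc),
                )
        return len(rows)

    def mark_processed(self, queue_name: str, payload_key: str) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "INSERT OR IGNORE INTO processed (queue_name, payload) VALUES (?,?)",
                (queue_name, payload_key),
            )

    def is_processed(self, queue_name: str, payload_key: str) -> bool:
        with self._lock:
            row = self._conn.execute(
                "SELECT 1 FROM processed WHERE queue_name=? AND payload=?",
                (queue_name, payload_key),
            ).fetchone()
        return row is not None

    # -- results -----------------------------------------------------------

    def create_result_stub(self, job_id: str, candidate: CandidateGuide) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "INSERT OR IGNORE INTO results (job_id, record_id, start, strand,"
                " target23, spacer20) VALUES (?,?,?,?,?,?)",
                (
                    job_id,
                    candidate.record_id,
                    candidate.start,
                    candidate.strand,
                    candidate.target23,
                    candidate.spacer20,
                ),
            )

    def get_result_row(self, job_id: str, record_id: str, start: int, strand: str):
        with self._lock:
            return self._conn.execute(
                "SELECT target23, spacer20 FROM results WHERE job_id=? AND record_id=?"
                " AND start=? AND strand=?",
                (job_id, record_id, start, strand),
            ).fetchone()

    def update_ontarget(
        self, job_id: str, record_id: str, start: int, strand: str, verdict
    ) -> None:
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE results SET passes_g20=?, passes_composition=?, passes_structure=?,"
                " consensus_votes=?, accepted=? WHERE job_id=? AND record_id=? AND start=?"
                " AND strand=?",
                (
                    int(verdict.passes_g20),
                    int(verdict.passes_composition),
                    int(verdict.passes_structure),
                    verdict.consensus_votes,
                    int(verdict.accepted),
                    job_id,
                    record_id,
                    start,
                    strand,
                ),
            )

    def update_offtarget(
        self, job_id: str, record_id: str, start: int, strand: str, result: OffTargetResult
    ) -> None:
        counts = json.dumps({str(k): v for k, v in sorted(result.neighbour_counts.items())})
        with self._lock, self._conn:
            self._conn.execute(
                "UPDATE results SET specificity=?, neighbour_counts=? WHERE job_id=?"
                " AND record_id=? AND start=? AND strand=?",
                (result.specificity, counts, job_id, record_id, start, strand),
            )

    def assessment_counts(self, job_id: str) -> tuple[int, int, int, int]:
        """(ontarget done, offtarget done, both complete, total) for a job."""
        with self._lock:
            row = self._conn.execute(
                "SELECT SUM(accepted IS NOT NULL), SUM(specificity IS NOT NULL),"
                " SUM(accepted IS NOT NULL AND specificity IS NOT NULL), COUNT(*)"
                " FROM results WHERE job_id=?",
                (job_id,),
            ).fetchone()
        on_done, off_done, both, total = (int(x or 0) for x in row)
        return on_done, off_done, both, total

    def fetch_results(self, job_id: str) -> list[ResultRecord]:
        with self._lock:
            rows = self._conn.execute(
                "SELECT record_id, start, strand, target23, spacer20, passes_g20,"
                " passes_composition, passes_structure, consensus_votes, accepted,"
                " specificity, neighbour_counts FROM results WHERE job_id=?"
                " ORDER BY record_id, start, strand",
                (job_id,),
            ).fetchall()
        out = []
        for (
            record_id, start, strand, target23, spacer20, g20, comp, struct, votes,
            accepted, specificity, counts,
        ) in rows:
            out.append(
                ResultRecord(
                    job_id=job_id,
                    record_id=record_id,
                    start=start,
                    strand=strand,
                    target23=target23,
                    spacer20=spacer20,
                    passes_g20=None if g20 is None else bool(g20),
                    passes_composition=None if comp is None else bool(comp),
                    passes_structure=None if struct is None else bool(struct),
                    consensus_votes=votes,
                    accepted=None if accepted is None else bool(accepted),
                    specificity=specificity,
                    neighbour_counts=None
                    if counts is None
                    else {int(k): v for k, v in json.loads(counts).items()},
                )
            )
        return out

    def close(self) -> None:
        with self._lock:
            self._conn.close()


class Engine:
    """Binds the queue handlers to a store, a fetcher and a work directory.

    The engine itself holds no job state: everything a handler needs comes
    from the message payload and the shared store, mirroring a stateless
    function runtime.  The only engine-local data are the read-only index
    cache and instrumentation counters.
    """

    def __init__(
        self,
        store: LocalStore,
        workdir: str | Path,
        config: PipelineConfig | None = None,
        fetcher=None,
        clock: Callable[[], float] = time.monotonic,
    ):
        self.store = store
        self.workdir = Path(workdir)
        self.workdir.mkdir(parents=True, exist_ok=True)
        self.config = config or PipelineConfig()
        self.fetcher = fetcher or LocalFileFetcher()
        self.clock = clock
        self.counters = {"invocations": 0, "messages": 0}
        self._index_cache: dict[str, ISSLIndex | None] = {}
        self._cache_lock = threading.Lock()
        self._handlers = {
            "genome_fetch": self._handle_genome_fetch,
            "index_build": self._handle_index_build,
            "ontarget": self._handle_ontarget,
            "offtarget": self._handle_offtarget,
        }

    # -- public API --------------------------------------------------------

    def register_genome(self, label: str, path: str | Path) -> None:
        """Make a local FASTA file available under a genome label."""
        self.store.register_genome(label, str(path))

    def submit_job(self, gene_sequence: str, genome_ref: str) -> str:
        """Persist a job and enqueue its genome-preparation event.

        Returns immediately with a fresh job identifier; nothing is
        processed until workers run.  Identical submissions yield distinct
        jobs.
        """
        if self.store.get_genome(genome_ref) is None:
            raise UnknownGenomeError(f"genome not registered: {genome_ref}")
        job_id = uuid.uuid4().hex
        self.store.create_job(job_id, normalize_sequence(gene_sequence), genome_ref)
        self.store.enqueue("genome_fetch", {"op": "ensure", "job_id": job_id})
        logger.info("job submitted", extra={"job": job_id})
        return job_id

    def job_progress(self, job_id: str) -> tuple[float, float, str]:
        """(on-target fraction, off-target fraction, status) for a job."""
        job = self.store.get_job(job_id)
        on_done, off_done, _, total = self.store.assessment_counts(job_id)
        if total == 0:
            frac = 1.0 if job.status == "complete" else 0.0
            return frac, frac, job.status
        return on_done / total, off_done / total, job.status

    def job_results(self, job_id: str) -> list[ResultRecord]:
        self.store.get_job(job_id)  # raises UnknownJobError
        return self.store.fetch_results(job_id)

    def results_frame(self, job_id: str) -> pd.DataFrame:
        """Results as a DataFrame, sorted by (record_id, start, strand)."""
        records = self.job_results(job_id)
        rows = []
        for r in records:
            rows.append(
                {
                    "record_id": r.record_id,
                    "start": r.start,
                    "strand": r.strand,
                    "target23": r.target23,
                    "spacer20": r.spacer20,
                    "passes_g20": r.passes_g20,
                    "passes_composition": r.passes_composition,
                    "passes_structure": r.passes_structure,
                    "consensus_votes": r.consensus_votes,
                    "accepted": r.accepted,
                    "specificity": r.specificity,
                    "neighbour_counts": ""
                    if r.neighbour_counts is None
                    else json.dumps({str(k): v for k, v in sorted(r.neighbour_counts.items())}),
                    "both_complete": r.both_complete,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "record_id", "start", "strand", "target23", "spacer20", "passes_g20",
                "passes_composition", "passes_structure", "consensus_votes", "accepted",
                "specificity", "neighbour_counts", "both_complete",
            ],
        )

    def results_csv(self, job_id: str) -> str:
        return self.results_frame(job_id).to_csv(index=False)

    # -- worker loop -------------------------------------------------------

    def run_worker_batch(self, queue_name: str, limits: WorkerLimits | None = None) -> int:
        """One stateless worker invocation: consume up to one batch.

        Messages already processed (same queue and payload) are completed
        without re-running their handler.  A handler exception releases the
        message for retry until its delivery count exceeds the retry cap,
        after which the message is dead-lettered and the job failed.  If the
        invocation's time budget runs out mid-batch, the remaining messages
        are requeued untouched (checkpoint-and-requeue).
        """
        limits = limits or self.config.limits
        messages = self.store.receive(queue_name, self.config.batch_size(queue_name))
        if not messages:
            return 0
        self.counters["invocations"] += 1
        started = self.clock()
        processed = 0
        for i, msg in enumerate(messages):
            if i > 0 and self.clock() - started >= limits.max_task_seconds:
                for rest in messages[i:]:
                    self.store.release_message(rest)
                logger.info(
                    "checkpoint: requeued %d messages", len(messages) - i,
                )
                break
            key = _canonical(msg.payload)
            if self.store.is_processed(queue_name, key):
                self.store.complete_message(msg)
                processed += 1
                continue
            try:
                self._handlers[queue_name](msg.payload)
            except Exception as exc:  # noqa: BLE001 - retry semantics need breadth
                if msg.delivery_count > self.config.retry_cap:
                    self.store.dead_letter(msg)
                    job_id = msg.payload.get("job_id")
                    if job_id:
                        self._fail_job(job_id, f"{queue_name} handler failed: {exc}")
                    logger.error("message dead-lettered on %s: %s", queue_name, exc)
                else:
                    self.store.release_message(msg)
                continue
            self.store.mark_processed(queue_name, key)
            self.store.complete_message(msg)
            processed += 1
            self.counters["messages"] += 1
        return processed

    def run(self, workers: int = 1, limits: WorkerLimits | None = None) -> int:
        """Drain all queues with ``workers`` concurrent batch consumers.

        Event-driven: returns as soon as no pending or in-flight messages
        remain, performing zero invocations if the queues start empty.
        """
        workers = min(workers, self.config.max_concurrency)
        if workers <= 1:
            total = 0
            while self.store.pending_count() > 0:
                for queue_name in QUEUES:
                    total += self.run_worker_batch(queue_name, limits)
            return total

        totals = [0] * workers

        def loop(slot: int) -> None:
            while True:
                got = 0
                for queue_name in QUEUES:
                    got += self.run_worker_batch(queue_name, limits)
                totals[slot] += got
                if got == 0:
                    if self.store.pending_count() == 0 and self.store.inflight_count() == 0:
                        return
                    time.sleep(0.001)

        threads = [threading.Thread(target=loop, args=(i,)) for i in range(workers)]
        for t in threads:
            t.start()
        for t in threads:
            t.join()
        return sum(totals)

    # -- handlers (stateless: inputs from message + stores only) -----------

    def _handle_genome_fetch(self, payload: dict) -> None:
        if payload.get("op") == "ensure":
            self._ensure_genome(payload["job_id"])
        else:
            self._fetch_portion(payload)

    def ensure_genome(self, job_id: str) -> None:
        """Genome availability check: warm-skip, or plan and enqueue fetches."""
        self._ensure_genome(job_id)

    def _ensure_genome(self, job_id: str) -> None:
        job = self.store.get_job(job_id)
        if job.status == "failed":
            return
        label = job.genome_ref
        if self._index_available(label):
            # warm run: genome and index cached, no fetch or build tasks
            self._dispatch_from_gene(job)
            return
        self.store.set_status(job_id, "preparing_genome")
        if self._merged_path(label).exists():
            self.store.enqueue("index_build", {"job_id": job_id, "genome_ref": label})
            return
        entry = self.store.get_genome(label)
        if entry is None:
            raise UnknownGenomeError(f"genome not registered: {label}")
        path = entry[0]
        total = self.fetcher.size(path)
        plan = plan_chunked_fetch(total, self.config.chunk_bytes)
        self.store.set_genome_plan(label, total, len(plan.ranges))
        for start, end in plan.ranges:
            self.store.enqueue(
                "genome_fetch",
                {"op": "fetch", "job_id": job_id, "genome_ref": label,
                 "start": start, "end": end},
            )

    def _fetch_portion(self, payload: dict) -> None:
        label = payload["genome_ref"]
        entry = self.store.get_genome(label)
        path, total_bytes, expected = entry
        data = self.fetcher.fetch(path, payload["start"], payload["end"])
        self.store.put_portion(label, payload["start"], payload["end"], data)
        if self.store.portion_count(label) == expected:
            plan = plan_chunked_fetch(total_bytes, self.config.chunk_bytes)
            merged = merge_portions(plan, self.store.get_portions(label))
            self._merged_path(label).write_bytes(merged)
            self.store.drop_portions(label)
            self.store.enqueue(
                "index_build", {"job_id": payload["job_id"], "genome_ref": label}
            )

    def _handle_index_build(self, payload: dict) -> None:
        job = self.store.get_job(payload["job_id"])
        if job.status == "failed":
            return
        label = payload["genome_ref"]
        self.store.set_status(job.job_id, "indexing")
        if not self._index_available(label):
            assembly = read_fasta(self._merged_path(label), source_label=label)
            spacers = genome_spacer_counts(assembly)
            index_path = self._index_path(label)
            if spacers:
                index = build_index(spacers, SliceConfig(self.config.num_slices))
                index.save(index_path)
            else:
                index = None
                index_path.with_suffix(".empty").touch()
            with self._cache_lock:
                self._index_cache[label] = index
        self._dispatch_from_gene(job)

    def dispatch_assessments(self, job: Job, candidates: Sequence[CandidateGuide]) -> None:
        """Create result stubs and queue one on- and one off-target task each."""
        for cand in candidates:
            self.store.create_result_stub(job.job_id, cand)
        self.store.set_total_candidates(job.job_id, len(candidates))
        if not candidates:
            self.store.set_status(job.job_id, "complete")
            return
        self.store.set_status(job.job_id, "assessing")
        for cand in candidates:
            ref = {
                "job_id": job.job_id,
                "record_id": cand.record_id,
                "start": cand.start,
                "strand": cand.strand,
            }
            self.store.enqueue("ontarget", ref)
            self.store.enqueue("offtarget", ref)

    def _dispatch_from_gene(self, job: Job) -> None:
        record = SequenceRecord(identifier="gene", sequence=job.gene_sequence) \
            if job.gene_sequence else None
        candidates = extract_candidates(record) if record else []
        self.dispatch_assessments(job, candidates)

    def _handle_ontarget(self, payload: dict) -> None:
        job_id, record_id = payload["job_id"], payload["record_id"]
        start, strand = payload["start"], payload["strand"]
        job = self.store.get_job(job_id)
        if job.status == "failed":
            return
        row = self.store.get_result_row(job_id, record_id, start, strand)
        target23, _ = row
        candidate = CandidateGuide(
            target23=target23, record_id=record_id, start=start, strand=strand
        )
        verdict = evaluate(candidate, threshold=self.config.consensus_threshold)
        self.store.update_ontarget(job_id, record_id, start, strand, verdict)
        self._check_completion(job_id)

    def _handle_offtarget(self, payload: dict) -> None:
        job_id, record_id = payload["job_id"], payload["record_id"]
        start, strand = payload["start"], payload["strand"]
        job = self.store.get_job(job_id)
        if job.status == "failed":
            return
        row = self.store.get_result_row(job_id, record_id, start, strand)
        _, spacer20 = row
        index = self._get_index(job.genome_ref)
        if index is None:
            result = OffTargetResult(
                specificity=100.0,
                neighbour_counts={d: 0 for d in range(self.config.max_mismatches + 1)},
                max_mm=self.config.max_mismatches,
            )
        else:
            result = assess_offtarget(
                index,
                spacer20,
                max_mm=self.config.max_mismatches,
                weights=self.config.score_weights,
            )
        self.store.update_offtarget(job_id, record_id, start, strand, result)
        self._check_completion(job_id)

    # -- internals ---------------------------------------------------------

    def _fail_job(self, job_id: str, cause: str) -> None:
        try:
            self.store.set_status(job_id, "failed", error=cause)
        except (StatusTransitionError, UnknownJobError):
            pass

    def _check_completion(self, job_id: str) -> None:
        job = self.store.get_job(job_id)
        if job.status in _TERMINAL:
            return
        _, _, both, total = self.store.assessment_counts(job_id)
        if total > 0 and both == total:
            self.store.set_status(job_id, "complete")

    def _digest(self, label: str) -> str:
        return hashlib.sha1(label.encode()).hexdigest()[:16]

    def _index_path(self, label: str) -> Path:
        d = self.workdir / "indexes"
        d.mkdir(exist_ok=True)
        return d / f"{self._digest(label)}.issl"

    def _merged_path(self, label: str) -> Path:
        d = self.workdir / "merged"
        d.mkdir(exist_ok=True)
        return d / f"{self._digest(label)}.fa"

    def _index_available(self, label: str) -> bool:
        with self._cache_lock:
            if label in self._index_cache:
                return True
        p = self._index_path(label)
        return p.exists() or p.with_suffix(".empty").exists()

    def _get_index(self, label: str) -> ISSLIndex | None:
        with self._cache_lock:
            if label in self._index_cache:
                return self._index_cache[label]
        p = self._index_path(label)
        index = ISSLIndex.load(p) if p.exists() else None
        with self._cache_lock:
            self._index_cache[label] = index
        return index
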