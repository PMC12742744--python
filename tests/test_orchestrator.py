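"""Job lifecycle, queue semantics, worker contract, and determinism."""
from __future__ import annotations

import itertools

import pytest

from crisprdesk.config import PipelineConfig, WorkerLimits
from crisprdesk.fixtures import GenomeSpec, generate_gene_with_exact_guides, generate_genome
from crisprdesk.genome_io import GenomeAssembly, write_fasta
from crisprdesk.orchestrator import (
    Engine,
    LocalStore,
    StatusTransitionError,
    UnknownGenomeError,
    UnknownJobError,
)


@pytest.fixture
def genome_file(tmp_path):
    rec = generate_genome(GenomeSpec(length=5000, gc_fraction=0.5, seed=42))
    path = tmp_path / "genome.fa"
    write_fasta(GenomeAssembly(records=(rec,), source_label="syn"), path)
    return path


@pytest.fixture
def gene():
    return generate_gene_with_exact_guides(5, seed=7)


def make_engine(tmp_path, genome_file, name="work", **config_kwargs) -> Engine:
    config = PipelineConfig(**config_kwargs)
    engine = Engine(LocalStore(), tmp_path / name, config=config)
    engine.register_genome("syn", genome_file)
    return engine


class TestSubmission:
    def test_returns_fresh_unique_ids(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        a = engine.submit_job(gene, "syn")
        b = engine.submit_job(gene, "syn")
        assert a != b
        assert engine.store.get_job(a).status == "submitted"

    def test_unknown_genome_rejected_at_submission(self, tmp_path, genome_file):
        engine = make_engine(tmp_path, genome_file)
        with pytest.raises(UnknownGenomeError):
            engine.submit_job("ACGT", "nope")

    def test_submit_is_asynchronous(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        engine.submit_job(gene, "syn")
        # nothing processed yet: one preparation event pending, no results
        assert engine.store.pending_count() == 1
        assert engine.counters["invocations"] == 0

    def test_empty_gene_completes_with_zero_results(self, tmp_path, genome_file):
        engine = make_engine(tmp_path, genome_file)
        job_id = engine.submit_job("", "syn")
        engine.run()
        assert engine.store.get_job(job_id).status == "complete"
        assert engine.job_results(job_id) == []
        assert engine.job_progress(job_id) == (1.0, 1.0, "complete")


class TestGenomePreparation:
    def test_cold_run_chunked_fetch_tasks(self, tmp_path, genome_file, gene):
        # genome just over two chunks -> three fetch tasks
        size = genome_file.stat().st_size
        chunk = size // 3 + 1
        engine = make_engine(tmp_path, genome_file, chunk_bytes=chunk)
        job_id = engine.submit_job(gene, "syn")
        engine.run_worker_batch("genome_fetch")  # the ensure event
        assert engine.store.pending_count("genome_fetch") == 3
        engine.run()
        assert engine.store.get_job(job_id).status == "complete"

    def test_warm_run_enqueues_no_fetch_or_build(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        engine.submit_job(gene, "syn")
        engine.run()
        fetches_after_cold = engine.counters["messages"]
        engine.submit_job(gene, "syn")
        engine.run_worker_batch("genome_fetch")  # process the ensure event
        # warm: assessments queued directly, nothing on fetch/build queues
        assert engine.store.pending_count("genome_fetch") == 0
        assert engine.store.pending_count("index_build") == 0
        assert engine.store.pending_count("ontarget") == 5
        assert engine.store.pending_count("offtarget") == 5
        assert fetches_after_cold > 0

    def test_fetch_failure_fails_the_job(self, tmp_path, genome_file, gene):
        class BrokenFetcher:
            def size(self, label):
                return 1000

            def fetch(self, label, start, end):
                raise IOError("disk on fire")

        engine = make_engine(tmp_path, genome_file, retry_cap=2)
        engine.fetcher = BrokenFetcher()
        job_id = engine.submit_job(gene, "syn")
        engine.run()
        job = engine.store.get_job(job_id)
        assert job.status == "failed"
        assert "disk on fire" in job.error


class TestDispatch:
    def test_n_candidates_two_queues(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        engine.submit_job(gene, "syn")
        engine.run_worker_batch("genome_fetch")
        engine.run_worker_batch("genome_fetch")  # single-chunk fetch
        engine.run_worker_batch("index_build")
        assert engine.store.pending_count("ontarget") == 5
        assert engine.store.pending_count("offtarget") == 5


class TestWorkerBatch:
    def test_empty_queue_processes_nothing(self, tmp_path, genome_file):
        engine = make_engine(tmp_path, genome_file)
        assert engine.run_worker_batch("ontarget") == 0
        assert engine.counters["invocations"] == 0

    def test_batch_consumes_min_of_queue_and_batch_size(self, tmp_path, genome_file):
        engine = make_engine(tmp_path, genome_file, batch_ontarget=10)
        gene7 = generate_gene_with_exact_guides(7, seed=1)
        engine.submit_job(gene7, "syn")
        while engine.store.pending_count("ontarget") == 0:
            for q in ("genome_fetch", "index_build"):
                engine.run_worker_batch(q)
        assert engine.run_worker_batch("ontarget") == 7

    def test_redelivery_is_idempotent(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        job_id = engine.submit_job(gene, "syn")
        engine.run()
        baseline = engine.results_csv(job_id)
        redelivered = engine.store.redeliver_done()
        assert redelivered > 0
        engine.run()
        assert engine.results_csv(job_id) == baseline
        assert engine.store.get_job(job_id).status == "complete"

    def test_time_budget_checkpoints_and_requeues(self, tmp_path, genome_file):
        # fake clock: each tick advances 10 "seconds", budget allows ~2 messages
        ticks = itertools.count()
        engine = Engine(
            LocalStore(),
            tmp_path / "ck",
            config=PipelineConfig(batch_ontarget=100),
            clock=lambda: next(ticks) * 10.0,
        )
        engine.register_genome("syn", genome_file)
        gene10 = generate_gene_with_exact_guides(10, seed=2)
        engine.submit_job(gene10, "syn")
        for _ in range(3):
            engine.run_worker_batch("genome_fetch")
        engine.run_worker_batch("index_build")
        assert engine.store.pending_count("ontarget") == 10
        limits = WorkerLimits(max_task_seconds=25.0)
        done = engine.run_worker_batch("ontarget", limits=limits)
        # the invocation stopped early and requeued the remainder untouched
        assert 0 < done < 10
        assert engine.store.pending_count("ontarget") == 10 - done


class TestProgressAndResults:
    def _drained(self, tmp_path, genome_file, gene, **cfg) -> tuple[Engine, str]:
        engine = make_engine(tmp_path, genome_file, **cfg)
        job_id = engine.submit_job(gene, "syn")
        engine.run()
        return engine, job_id

    def test_unknown_job_errors(self, tmp_path, genome_file):
        engine = make_engine(tmp_path, genome_file)
        with pytest.raises(UnknownJobError):
            engine.job_progress("missing")
        with pytest.raises(UnknownJobError):
            engine.job_results("missing")

    def test_fresh_job_zero_progress(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        job_id = engine.submit_job(gene, "syn")
        assert engine.job_progress(job_id) == (0.0, 0.0, "submitted")

    def test_partial_progress_fractions(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file, batch_ontarget=3, batch_offtarget=100)
        job_id = engine.submit_job(gene, "syn")
        for _ in range(2):
            engine.run_worker_batch("genome_fetch")
        engine.run_worker_batch("index_build")
        engine.run_worker_batch("ontarget")  # 3 of 5
        engine.run_worker_batch("offtarget")  # 5 of 5
        on_frac, off_frac, status = engine.job_progress(job_id)
        assert (on_frac, off_frac) == (0.6, 1.0)
        assert status == "assessing"
        # partial results visible, flagged incomplete where one side pends
        records = engine.job_results(job_id)
        assert len(records) == 5
        assert sum(r.both_complete for r in records) == 3

    def test_completed_job_all_records_complete(self, tmp_path, genome_file, gene):
        engine, job_id = self._drained(tmp_path, genome_file, gene)
        records = engine.job_results(job_id)
        assert len(records) == 5
        assert all(r.both_complete for r in records)
        keys = [(r.record_id, r.start, r.strand) for r in records]
        assert keys == sorted(keys)

    def test_results_stable_across_retrievals(self, tmp_path, genome_file, gene):
        engine, job_id = self._drained(tmp_path, genome_file, gene)
        assert engine.results_csv(job_id) == engine.results_csv(job_id)

    def test_progress_monotone_over_drain(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file, batch_ontarget=1, batch_offtarget=1)
        job_id = engine.submit_job(gene, "syn")
        previous = (0.0, 0.0)
        while engine.store.pending_count() > 0:
            for q in ("genome_fetch", "index_build", "ontarget", "offtarget"):
                engine.run_worker_batch(q)
                on_frac, off_frac, _ = engine.job_progress(job_id)
                assert (on_frac, off_frac) >= previous
                previous = (on_frac, off_frac)
        assert previous == (1.0, 1.0)


class TestScheduleInvariance:
    def test_results_identical_across_batch_sizes_and_workers(
        self, tmp_path, genome_file
    ):
        gene = generate_gene_with_exact_guides(12, seed=3)
        tables = set()
        for i, (batch, workers) in enumerate(
            [(1, 1), (7, 1), (100, 1), (7, 8)]
        ):
            engine = make_engine(
                tmp_path, genome_file, name=f"w{i}",
                batch_ontarget=batch, batch_offtarget=batch,
            )
            job_id = engine.submit_job(gene, "syn")
            engine.run(workers=workers)
            tables.add(engine.results_csv(job_id))
        assert len(tables) == 1


class TestScaleFromZero:
    def test_no_invocations_while_queues_empty(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        assert engine.run() == 0
        assert engine.counters["invocations"] == 0
        job_id = engine.submit_job(gene, "syn")
        engine.run()
        busy = engine.counters["invocations"]
        assert busy > 0
        assert engine.run() == 0
        assert engine.counters["invocations"] == busy
        assert engine.store.get_job(job_id).status == "complete"


class TestStatusTransitions:
    def test_backwards_transition_rejected(self, tmp_path, genome_file, gene):
        engine, = (make_engine(tmp_path, genome_file),)
        job_id = engine.submit_job(gene, "syn")
        engine.run()
        with pytest.raises(StatusTransitionError):
            engine.store.set_status(job_id, "assessing")

    def test_failed_is_terminal(self, tmp_path, genome_file, gene):
        engine = make_engine(tmp_path, genome_file)
        job_id = engine.submit_job(gene, "syn")
        engine.store.set_status(job_id, "failed", error="boom")
        with pytest.raises(StatusTransitionError):
            engine.store.set_status(job_id, "assessing")
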