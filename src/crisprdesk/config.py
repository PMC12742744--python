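"""Plain-text configuration for the pipeline.

A config file is ``key = value`` lines (``#`` comments allowed); anything
not set falls back to the defaults below, and CLI flags override the file.
Values are coerced to the type of the corresponding default.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .genome_io import DEFAULT_CHUNK_BYTES


@dataclass(frozen=True)
class WorkerLimits:
    """Execution-contract limits for one worker invocation.

    Mirrors a function-as-a-service runtime: a hard per-invocation wall
    clock (workers checkpoint-and-requeue instead of overrunning), a memory
    ceiling, and a cap on concurrent workers.
    """

    max_task_seconds: float = 900.0  # 15 minutes
    max_memory_bytes: int = 10 * 2**30  # 10 GiB
    max_concurrency: int = 1000

    def __post_init__(self) -> None:
        if self.max_task_seconds <= 0 or self.max_memory_bytes <= 0 or self.max_concurrency <= 0:
            raise ValueError("worker limits must all be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the whole pipeline."""

    chunk_bytes: int = DEFAULT_CHUNK_BYTES
    num_slices: int = 5
    max_mismatches: int = 4
    score_weights: str = "uniform"  # or "literature"
    consensus_threshold: int = 2
    retry_cap: int = 3
    # per-queue batch sizes: fetches and index builds are heavyweight
    # single-item tasks; assessments are cheap and batched aggressively
    batch_genome_fetch: int = 1
    batch_index_build: int = 1
    batch_ontarget: int = 100
    batch_offtarget: int = 10
    max_task_seconds: float = 900.0
    max_memory_bytes: int = 10 * 2**30
    max_concurrency: int = 1000

    @property
    def limits(self) -> WorkerLimits:
        return WorkerLimits(
            max_task_seconds=self.max_task_seconds,
            max_memory_bytes=self.max_memory_bytes,
            max_concurrency=self.max_concurrency,
        )

    def batch_size(self, queue_name: str) -> int:
        return {
            "genome_fetch": self.batch_genome_fetch,
            "index_build": self.batch_index_build,
            "ontarget": self.batch_ontarget,
            "offtarget": self.batch_offtarget,
        }[queue_name]


class ConfigError(ValueError):
    """Malformed configuration file or unknown key."""


def parse_config_text(text: str) -> dict[str, str]:
    """Parse ``key = value`` lines, ignoring blanks and ``#`` comments."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional file, and overrides."""
    raw: dict[str, object] = {}
    if path is not None:
        raw.update(parse_config_text(Path(path).read_text()))
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name: f.type for f in fields(PipelineConfig)}
    defaults = PipelineConfig()
    coerced: dict[str, object] = {}
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"unknown config key: {key}")
        default = getattr(defaults, key)
        if isinstance(value, str) and not isinstance(default, str):
            value = type(default)(value)
        coerced[key] = value
    return PipelineConfig(**coerced)
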